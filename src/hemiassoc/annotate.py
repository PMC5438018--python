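"""Coding / splice-site classification of variants against gene models.

The gene-burden test counts coding and splice-site variants, where the
splice-site window is the 6 nt of intron flanking each internal exon
boundary (donor and acceptor ends).  Classification rules, per
(variant, gene) pair:

* ``coding`` — position falls in a CDS interval (synonymous status is
  unknowable without transcripts, so all CDS-overlapping variants count;
  restrict via ``qualifying_classes`` downstream if desired);
* ``splice_site`` — position lies within 6 nt of an internal exon
  boundary on the intronic side and is not coding;
* ``other`` — anywhere else inside the gene span.

Transcript start/end are not splice sites, and the window definition is
symmetric under strand reversal, so strand does not enter the rules.
Indels are classified by their leftmost affected base (VCF
left-alignment convention).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .region import Region

__all__ = [
    "GeneModel",
    "SPLICE_WINDOW_NT",
    "load_gene_models",
    "classify_position",
    "classify_variant",
    "annotate_variants",
    "write_gff3",
]

SPLICE_WINDOW_NT = 6

Interval = tuple[int, int]  # 1-based inclusive


def _check_sorted_disjoint(ivs: Sequence[Interval], what: str, gene_id: str) -> None:
    for (s1, e1) in ivs:
        if s1 > e1:
            raise ValueError(f"{gene_id}: inverted {what} interval ({s1}, {e1})")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"{gene_id}: {what} intervals overlap or are unsorted")


@dataclass(frozen=True)
class GeneModel:
    """One gene: sorted, disjoint exon and CDS intervals (1-based inclusive)."""

    gene_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        _check_sorted_disjoint(self.exons, "exon", self.gene_id)
        _check_sorted_disjoint(self.cds, "CDS", self.gene_id)
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS ({cs}, {ce}) not contained in any exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def splice_windows(self) -> tuple[Interval, ...]:
        """6 nt intronic flanks of every internal exon boundary."""
        out: list[Interval] = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, min(e1 + SPLICE_WINDOW_NT, s2 - 1)))
            out.append((max(s2 - SPLICE_WINDOW_NT, e1 + 1), s2 - 1))
        return tuple(out)


def load_gene_models(gff3_path: str | os.PathLike, region: Region) -> list[GeneModel]:
    """Parse a GFF3 and return models for every gene overlapping ``region``."""
    try:
        db = gffutils.create_db(
            os.fspath(gff3_path), ":memory:", force=True,
            merge_strategy="create_unique", keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        warnings.warn(f"no gene models in {gff3_path}", stacklevel=2)
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid != region.chrom or not region.overlaps(gene.start, gene.end):
            continue
        exons = sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        cds = sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(GeneModel(gene_id=gene.id, strand=gene.strand, exons=tuple(exons), cds=tuple(cds)))
    if not models:
        warnings.warn(f"no gene models overlap {region}", stacklevel=2)
    return models


def _in_any(pos: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify_position(pos: int, model: GeneModel) -> str | None:
    """Class of a single base against one gene; None if outside the gene span."""
    if not model.start <= pos <= model.end:
        return None
    if _in_any(pos, model.cds):
        return "coding"
    if _in_any(pos, model.splice_windows):
        return "splice_site"
    return "other"


def classify_variant(call, models: Sequence[GeneModel]) -> dict[str, str]:
    """Classify one variant against every overlapping gene.

    ``call`` may be a VariantCall or a bare 1-based position.  A variant
    can map to several genes; each gene classifies it independently.
    """
    pos = int(getattr(call, "pos", call))
    out: dict[str, str] = {}
    for m in models:
        cls = classify_position(pos, m)
        if cls is not None:
            out[m.gene_id] = cls
    return out


def annotate_variants(variants: Sequence, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-(variant, gene) classification table for a retained-variant list.

    Returns columns ``variant_index`` (position in ``variants``),
    ``variant`` (key if available), ``gene_id`` and ``v_class``.  Every
    gene appears at least once (untestable genes keep a placeholder row
    with class ``none``), so downstream burden testing can report them.
    """
    positions = np.array([int(getattr(v, "pos", v)) for v in variants])
    keys = [getattr(v, "key", str(p)) for v, p in zip(variants, positions)]
    rows: list[tuple[int, str, str, str]] = []
    for m in models:
        sw = m.splice_windows
        inside = np.nonzero((positions >= m.start) & (positions <= m.end))[0]
        hit = False
        for i in inside:
            p = int(positions[i])
            if _in_any(p, m.cds):
                cls = "coding"
            elif _in_any(p, sw):
                cls = "splice_site"
            else:
                cls = "other"
            rows.append((int(i), keys[i], m.gene_id, cls))
            hit = True
        if not hit:
            rows.append((-1, "", m.gene_id, "none"))
    return pd.DataFrame(rows, columns=["variant_index", "variant", "gene_id", "v_class"])


def gene_spans(models: Sequence[GeneModel], chrom: str) -> dict[str, tuple[str, int, int]]:
    """Gene id -> (chrom, start, end) span map for track output."""
    return {m.gene_id: (chrom, m.start, m.end) for m in models}


def write_gff3(models: Sequence[GeneModel], chrom: str, path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = m.gene_id
            fh.write(
                f"{chrom}\themiassoc\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{chrom}\themiassoc\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{chrom}\themiassoc\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={gid}.e{i};Parent={gid}.t1\n"
                )
            for i, (s, e) in enumerate(m.cds, start=1):
                fh.write(
                    f"{chrom}\themiassoc\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={gid}.c{i};Parent={gid}.t1\n"
                )
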