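"""Reading the cohort VCF and applying the variant retention filters.

The retained set feeding the association tests is defined by three
filters applied jointly to every (site, alt allele) call:

* caller-specific quality: SNVs need ``QUAL >= 50``, indels ``QUAL >= 600``
  (both bounds inclusive);
* population allele frequency: calls annotated with a public-database
  allele frequency above 0.30 are excluded as common; calls with no
  annotation are retained (novel variants are the hypothesis class);
* dataset occurrence: calls carried by fewer than two samples of the
  cohort (dataset singletons) are excluded.

Genotypes in a hemizygous region are carrier/non-carrier: the single
remaining allele either bears the alternate allele or it does not.
Callers run in default diploid mode emit "1/1" (or occasionally "0/1")
at such sites, so any genotype containing at least one alt allele counts
as carrier; "./." and "0"-only genotypes are non-carriers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .region import Region

__all__ = [
    "VariantCall",
    "CarrierMatrix",
    "NoVariantsRetainedError",
    "read_manifest",
    "read_cohort_vcf",
    "filter_variants",
    "filter_audit",
    "build_carrier_matrix",
    "write_filtered_vcf",
    "write_cohort_vcf",
]

QS_MIN_SNV = 50.0
QS_MIN_INDEL = 600.0
MAX_POP_AF = 0.30
MIN_DATASET_OCCURRENCE = 2


class NoVariantsRetainedError(ValueError):
    """Raised when filtering leaves no variant to test."""


@dataclass(frozen=True)
class VariantCall:
    """One (site, alt allele) call with its carriers across the cohort."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str  # "snv" | "indel"
    qual: float
    pop_af: float | None  # public-database allele frequency; None = unannotated
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")
        if self.pop_af is not None and not 0.0 <= self.pop_af <= 1.0:
            raise ValueError(f"pop_af outside [0,1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def infer_caller(ref: str, alt: str) -> str:
    """Fallback caller dispatch when the VCF lacks a CALLER INFO key."""
    return "snv" if len(ref) == 1 and len(alt) == 1 else "indel"


def read_manifest(path: str | os.PathLike | pd.DataFrame) -> pd.DataFrame:
    """Load the sample manifest (sample_id, group in {case, control}, age)."""
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels in manifest: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in manifest")
    return df


def _is_carrier(gt: tuple, alt_index: int) -> bool:
    return any(allele == alt_index for allele in gt if allele is not None)


def read_cohort_vcf(
    vcf_path: str | os.PathLike,
    manifest: str | os.PathLike | pd.DataFrame,
    region: Region,
) -> list[VariantCall]:
    """Parse a multi-sample VCF into per-(site, alt) calls within ``region``.

    Multi-allelic records are split into one call per alt allele, with a
    sample attributed to an alt iff its genotype contains that allele.
    Haploid ("1"), diploid-homozygous ("1/1") and diploid-heterozygous
    ("0/1") encodings all count as carrier.
    """
    mf = read_manifest(manifest)
    known = set(mf["sample_id"])
    calls: list[VariantCall] = []
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        vcf_samples = list(vf.header.samples)
        unknown = set(vcf_samples) - known
        if unknown:
            raise ValueError(f"VCF samples missing from manifest: {sorted(unknown)[:5]}")
        for rec in vf:
            if rec.chrom != region.chrom or not region.contains(rec.pos):
                continue
            info = dict(rec.info)
            caller = info.get("CALLER")
            pop_af_raw = info.get("POP_AF")
            gts = {s: rec.samples[s].get("GT", (None,)) for s in vcf_samples}
            for ai, alt in enumerate(rec.alts or (), start=1):
                carriers = frozenset(s for s, gt in gts.items() if _is_carrier(gt, ai))
                pop_af = None
                if pop_af_raw is not None:
                    # per-alt A-typed values arrive as tuples
                    pop_af = float(pop_af_raw[ai - 1]) if isinstance(pop_af_raw, tuple) else float(pop_af_raw)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        caller=str(caller) if caller is not None else infer_caller(rec.ref, alt),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        pop_af=pop_af,
                        carriers=carriers,
                    )
                )
    return calls


def _filter_flags(
    calls: Sequence[VariantCall],
    qs_min_snv: float,
    qs_min_indel: float,
    max_pop_af: float,
    min_dataset_occurrence: int,
) -> pd.DataFrame:
    qual = np.array([c.qual for c in calls])
    is_snv = np.array([c.caller == "snv" for c in calls])
    af = np.array([np.nan if c.pop_af is None else c.pop_af for c in calls])
    nc = np.array([c.n_carriers for c in calls])
    pass_qual = np.where(is_snv, qual >= qs_min_snv, qual >= qs_min_indel)
    pass_af = ~(af > max_pop_af)  # NaN (missing annotation) passes
    pass_occ = nc >= min_dataset_occurrence
    return pd.DataFrame(
        {
            "variant": [c.key for c in calls],
            "caller": [c.caller for c in calls],
            "qual": qual,
            "pop_af": af,
            "n_carriers": nc,
            "pass_qual": pass_qual,
            "pass_pop_af": pass_af,
            "pass_occurrence": pass_occ,
            "retained": pass_qual & pass_af & pass_occ,
        }
    )


def filter_variants(
    calls: Sequence[VariantCall],
    qs_min_snv: float = QS_MIN_SNV,
    qs_min_indel: float = QS_MIN_INDEL,
    max_pop_af: float = MAX_POP_AF,
    min_dataset_occurrence: int = MIN_DATASET_OCCURRENCE,
) -> list[VariantCall]:
    """Apply the quality / population-AF / singleton filters (all bounds inclusive)."""
    if min(qs_min_snv, qs_min_indel) <= 0 or not 0 < max_pop_af <= 1:
        raise ValueError("filter thresholds must be positive")
    if not calls:
        return []
    flags = _filter_flags(calls, qs_min_snv, qs_min_indel, max_pop_af, min_dataset_occurrence)
    keep = flags["retained"].to_numpy()
    return [c for c, k in zip(calls, keep) if k]


def filter_audit(
    calls: Sequence[VariantCall],
    qs_min_snv: float = QS_MIN_SNV,
    qs_min_indel: float = QS_MIN_INDEL,
    max_pop_af: float = MAX_POP_AF,
    min_dataset_occurrence: int = MIN_DATASET_OCCURRENCE,
) -> pd.DataFrame:
    """Per-variant pass/fail table for every filter (the audit log)."""
    if not calls:
        return _filter_flags([], qs_min_snv, qs_min_indel, max_pop_af, min_dataset_occurrence)
    return _filter_flags(calls, qs_min_snv, qs_min_indel, max_pop_af, min_dataset_occurrence)


@dataclass
class CarrierMatrix:
    """Binary samples x retained-variants carrier indicator.

    Rows follow the manifest order; columns follow the retained-variant
    order.  ``ages`` is carried along for the control-age sensitivity
    subset.
    """

    sample_ids: list[str]
    groups: np.ndarray  # "case"/"control" per sample
    variants: list[VariantCall]
    indicator: np.ndarray  # bool, (n_samples, n_variants)
    ages: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def case_mask(self) -> np.ndarray:
        return self.groups == "case"

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return int((~self.case_mask).sum())

    def subset_samples(self, keep: np.ndarray) -> "CarrierMatrix":
        """Row subset (e.g. dropping young controls); variants unchanged."""
        keep = np.asarray(keep, dtype=bool)
        return CarrierMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            groups=self.groups[keep],
            variants=self.variants,
            indicator=self.indicator[keep],
            ages=None if self.ages is None else self.ages[keep],
        )


def build_carrier_matrix(
    retained: Sequence[VariantCall],
    manifest: str | os.PathLike | pd.DataFrame,
) -> CarrierMatrix:
    """Assemble the analysis-ready indicator matrix from retained calls."""
    if not retained:
        raise NoVariantsRetainedError("no variants after filtering")
    mf = read_manifest(manifest)
    sample_ids = list(mf["sample_id"])
    index = {s: i for i, s in enumerate(sample_ids)}
    mat = np.zeros((len(sample_ids), len(retained)), dtype=bool)
    for j, call in enumerate(retained):
        for s in call.carriers:
            try:
                mat[index[s], j] = True
            except KeyError:
                raise ValueError(f"carrier {s!r} of {call.key} missing from manifest") from None
    ages = mf["age"].to_numpy(dtype=float) if "age" in mf.columns else None
    return CarrierMatrix(
        sample_ids=sample_ids,
        groups=mf["group"].to_numpy(dtype=object),
        variants=list(retained),
        indicator=mat,
        ages=ages,
    )


# ---------------------------------------------------------------------------
# plain-text VCF writing (shared by the simulator and the filter stage)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=POP_AF,Number=A,Type=Float,Description="Population (public database) allele frequency">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller class: snv or indel">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID={chrom},length={length}>
"""


def write_cohort_vcf(
    calls: Sequence[VariantCall],
    sample_ids: Sequence[str],
    path: str | os.PathLike,
    region: Region,
) -> Path:
    """Write calls as a VCF 4.2 text file with haploid genotypes."""
    path = Path(path)
    cols = {s: i for i, s in enumerate(sample_ids)}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=region.chrom, length=region.end + 1))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for c in sorted(calls, key=lambda v: (v.pos, v.alt)):
            gts = ["0"] * len(sample_ids)
            for s in c.carriers:
                gts[cols[s]] = "1"
            info = f"CALLER={c.caller}"
            if c.pop_af is not None:
                info = f"POP_AF={c.pop_af:.6g};" + info
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.qual:.6g}\t.\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def write_filtered_vcf(
    retained: Sequence[VariantCall],
    sample_ids: Sequence[str],
    path: str | os.PathLike,
    region: Region,
) -> Path:
    """Write the retained set as a filtered VCF (same dialect as the input)."""
    return write_cohort_vcf(retained, sample_ids, path, region)
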