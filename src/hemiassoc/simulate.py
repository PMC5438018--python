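"""Synthetic cohort generator for the hemizygous-region association pipeline.

The study design emulated here is a case-control cohort of individuals
hemizygous for one ~4.2 Mb chromosomal region (40 cases with a psychotic
disorder, 48 unaffected controls by default), sequenced over that region.
No real sequence is simulated — only the statistical objects the
analysis consumes:

* a multi-sample VCF of hemizygous variant calls (haploid genotypes,
  per-variant caller quality in QUAL, population allele frequency and
  caller class in INFO),
* a sample manifest (id, group, age),
* GFF3 gene models tiling the region (73 genes by default),
* per-sample per-base depth tracks for the coverage-based CNV test.

Background variants are independent across loci (no linkage
disequilibrium): each locus gets a population allele frequency from a
rare/common mixture and carriers are Bernoulli draws at that frequency,
matching the hemizygous model in which the carrier probability equals
the allele frequency.  The locus count is calibrated so the expected
number of variants per sample matches ``mean_variants_per_sample``
(default 4,600, the scale reported for such cohorts).  An optional risk
variant with configurable control carrier frequency ``p0`` and odds
ratio is injected with case carrier probability
``p1 = OR*p0 / (1 - p0 + OR*p0)``; optional depth CNVs multiply carrier
coverage by a fold change over an interval.

All randomness flows from a single seed through named substreams, so
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_gff3
from .filtering import VariantCall, write_cohort_vcf
from .power import case_carrier_freq
from .region import DEFAULT_REGION, Region

__all__ = [
    "RiskVariant",
    "CnvInjection",
    "CohortConfig",
    "SimulatedCohort",
    "DepthSet",
    "simulate_manifest",
    "simulate_gene_models",
    "simulate_cohort",
    "simulate_depth",
    "generate_cohort",
    "generate_depth_tracks",
]

_BASES = np.array(list("ACGT"))

# substream labels -> index into the spawned seed sequences
_STREAMS = ("manifest", "loci", "carriers", "genes", "depth")


@dataclass(frozen=True)
class RiskVariant:
    """An injected candidate risk variant."""

    pos: int
    raf_p0: float  # carrier (risk-allele) frequency among controls
    odds_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.raf_p0 < 1:
            raise ValueError("raf_p0 must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class CnvInjection:
    """An injected depth CNV over an interval (1-based inclusive)."""

    start: int
    end: int
    fold_change: float
    case_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("CNV interval start must precede end")
        if self.fold_change < 0:
            raise ValueError("fold_change must be non-negative")
        if not 0 < self.case_fraction <= 1:
            raise ValueError("case_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one synthetic cohort.

    ``mean_variants_per_sample`` calibrates the background locus count:
    the expected number of carried variants per sample (the per-bp rate
    is this value divided by the region length).  The allele-frequency
    mixture deliberately places mass both below and above the 0.30
    common-variant filter cutoff, and ``singleton_fraction`` of loci are
    emitted as dataset singletons, so every retention filter is
    exercised on default data.
    """

    n_case: int = 40
    n_control: int = 48
    region: Region = DEFAULT_REGION
    mean_variants_per_sample: float = 4_600.0
    #: (weight, af_lo, af_hi) components of the population-AF mixture.
    #: Most of a sample's variants are common polymorphisms (AF > 0.30,
    #: removed by the common-variant filter); the rare and low-frequency
    #: components supply the ~4,200 loci that survive all filters.
    af_mixture: tuple[tuple[float, float, float], ...] = (
        (0.37, 0.001, 0.05),
        (0.15, 0.05, 0.30),
        (0.48, 0.30, 0.95),
    )
    singleton_fraction: float = 0.10
    missing_af_fraction: float = 0.05
    indel_fraction: float = 0.10
    snv_qual: tuple[float, float] = (120.0, 60.0)  # mean, sd: straddles the 50 cutoff
    indel_qual: tuple[float, float] = (900.0, 250.0)  # straddles the 600 cutoff
    n_genes: int = 73
    risk_variant: RiskVariant | None = None
    cnv_injection: CnvInjection | None = None
    depth_region: Region | None = None  # default: first 50 kb of the region
    depth_mean: float = 100.0
    depth_sd: float = 15.0
    depth_dispersion: float = 80.0
    age_mean: float = 22.2
    age_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one sample")
        Region(*self.region).validate()
        if self.mean_variants_per_sample <= 0:
            raise ValueError("mean_variants_per_sample must be positive")
        if abs(sum(w for w, _, _ in self.af_mixture) - 1.0) > 1e-9:
            raise ValueError("af_mixture weights must sum to 1")
        for w, lo, hi in self.af_mixture:
            if not (0 <= w <= 1 and 0 < lo < hi <= 1):
                raise ValueError(f"invalid af_mixture component ({w}, {lo}, {hi})")
        if not 0 <= self.singleton_fraction < 1:
            raise ValueError("singleton_fraction must lie in [0, 1)")
        if self.risk_variant is not None and not Region(*self.region).contains(self.risk_variant.pos):
            raise ValueError("risk variant position outside region")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    def resolved_depth_region(self) -> Region:
        if self.depth_region is not None:
            return Region(*self.depth_region).validate()
        r = Region(*self.region)
        return Region(r.chrom, r.start, min(r.end, r.start + 49_999))


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: calls, manifest and gene models."""

    config: CohortConfig
    calls: list[VariantCall]
    manifest: pd.DataFrame
    gene_models: list[GeneModel]


@dataclass
class DepthSet:
    """Per-base depth for every sample over the coverage window."""

    config: CohortConfig
    region: Region
    positions: np.ndarray  # 1-based, contiguous
    depth: np.ndarray  # int, (n_samples, n_positions), manifest sample order
    sample_ids: list[str]
    cnv_carriers: list[str]  # truth: samples carrying the injected CNV


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def simulate_manifest(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"case{i:03d}" for i in range(1, config.n_case + 1)] + [
        f"ctrl{i:03d}" for i in range(1, config.n_control + 1)
    ]
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    ages = rng.normal(config.age_mean, config.age_sd, size=config.n_samples)
    # controls were enrolled at >= 15 years (to limit not-yet-affected
    # misclassification); cases have no such floor but stay plausible
    floor = np.where(np.array(groups) == "control", 15.0, 12.0)
    ages = np.round(np.maximum(ages, floor), 1)
    return pd.DataFrame({"sample_id": ids, "group": groups, "age": ages})


def _expected_af(config: CohortConfig) -> float:
    return float(sum(w * (lo + hi) / 2.0 for w, lo, hi in config.af_mixture))


def _n_loci(config: CohortConfig) -> int:
    """Locus count whose expected per-sample carried-variant count hits the target."""
    s = config.singleton_fraction
    per_locus = (1.0 - s) * _expected_af(config) + s / config.n_samples
    return max(1, round(config.mean_variants_per_sample / per_locus))


def _draw_positions(rng: np.random.Generator, region: Region, n: int, exclude: set[int]) -> np.ndarray:
    want = n
    pos = np.empty(0, dtype=np.int64)
    while len(pos) < want:
        extra = rng.integers(region.start, region.end + 1, size=int(want * 1.05) + 64)
        pos = np.setdiff1d(np.unique(np.concatenate([pos, extra])), np.fromiter(exclude, dtype=np.int64, count=len(exclude)))
    if len(pos) > want:
        keep = rng.choice(len(pos), size=want, replace=False)
        pos = np.sort(pos[keep])
    return pos


def _alleles(rng: np.random.Generator, n: int, is_indel: np.ndarray) -> tuple[list[str], list[str]]:
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + 1 + rng.integers(0, 3, size=n)) % 4
    refs = list(_BASES[ref_i])
    alts = list(_BASES[alt_i])
    idx = np.nonzero(is_indel)[0]
    ins = rng.random(len(idx)) < 0.5
    lens = rng.integers(1, 5, size=len(idx))
    for k, i in enumerate(idx):
        tail = "".join(_BASES[rng.integers(0, 4, size=lens[k])])
        base = refs[i]
        if ins[k]:
            refs[i], alts[i] = base, base + tail
        else:
            refs[i], alts[i] = base + tail, base
    return refs, alts


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort in memory (no files written)."""
    streams = _streams(config.seed)
    manifest = simulate_manifest(config, streams["manifest"])
    sample_ids = np.array(manifest["sample_id"])
    is_case = (manifest["group"] == "case").to_numpy()
    n = config.n_samples
    region = Region(*config.region)

    rng = streams["loci"]
    T = _n_loci(config)
    exclude = {config.risk_variant.pos} if config.risk_variant else set()
    pos = _draw_positions(rng, region, T, exclude)

    is_indel = rng.random(T) < config.indel_fraction
    qual = np.where(
        is_indel,
        rng.normal(*config.indel_qual, size=T),
        rng.normal(*config.snv_qual, size=T),
    )
    qual = np.maximum(qual, 1.0)
    refs, alts = _alleles(rng, T, is_indel)

    weights = np.array([w for w, _, _ in config.af_mixture])
    comp = rng.choice(len(weights), size=T, p=weights)
    lo = np.array([c[1] for c in config.af_mixture])[comp]
    hi = np.array([c[2] for c in config.af_mixture])[comp]
    af = rng.uniform(lo, hi)
    af = np.clip(af, 1e-6, 1.0)
    qual = np.round(qual, 1)
    af = np.round(af, 6)
    af_missing = rng.random(T) < config.missing_af_fraction
    is_singleton = rng.random(T) < config.singleton_fraction

    crng = streams["carriers"]
    mat = crng.random((T, n)) < af[:, None]
    single_idx = np.nonzero(is_singleton)[0]
    mat[single_idx] = False
    mat[single_idx, crng.integers(0, n, size=len(single_idx))] = True

    keep = mat.any(axis=1)  # a caller only reports sites seen in >= 1 sample
    rows, cols = np.nonzero(mat[keep])
    counts = np.bincount(rows, minlength=int(keep.sum()))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    kept = np.nonzero(keep)[0]

    calls: list[VariantCall] = []
    for j, i in enumerate(kept):
        carriers = frozenset(sample_ids[cols[offsets[j]:offsets[j + 1]]].tolist())
        calls.append(
            VariantCall(
                chrom=region.chrom,
                pos=int(pos[i]),
                ref=refs[i],
                alt=alts[i],
                caller="indel" if is_indel[i] else "snv",
                qual=float(qual[i]),
                pop_af=None if af_missing[i] else float(af[i]),
                carriers=carriers,
            )
        )

    if config.risk_variant is not None:
        rv = config.risk_variant
        p1 = case_carrier_freq(rv.raf_p0, rv.odds_ratio)
        probs = np.where(is_case, p1, rv.raf_p0)
        carrier_mask = crng.random(n) < probs
        carriers = frozenset(sample_ids[carrier_mask].tolist())
        if carriers:
            calls.append(
                VariantCall(
                    chrom=region.chrom,
                    pos=rv.pos,
                    ref="G",
                    alt="A",
                    caller="snv",
                    qual=500.0,
                    pop_af=float(rv.raf_p0),
                    carriers=carriers,
                )
            )
    calls.sort(key=lambda c: (c.pos, c.alt))

    models = simulate_gene_models(region, config.n_genes, streams["genes"])
    return SimulatedCohort(config=config, calls=calls, manifest=manifest, gene_models=models)


def simulate_gene_models(
    region: Region, n_genes: int, rng: np.random.Generator | int
) -> list[GeneModel]:
    """Non-overlapping multi-exon gene models tiling the region.

    Genes are placed one per equal-width slot; exon counts, exon lengths
    and intron lengths are drawn within plausible compact-gene ranges.
    CDS covers internal exons fully and trims into the terminal exons
    (UTR stubs), so CDS is always contained in exons.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    slot = region.length // n_genes
    models = []
    for g in range(n_genes):
        slot_start = region.start + g * slot
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(80, 301, size=n_exons)
        intron_lens = rng.integers(200, 2001, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        max_offset = max(1, slot - span - 10)
        start = slot_start + int(rng.integers(0, max_offset))
        exons = []
        cur = start
        for k in range(n_exons):
            exons.append((cur, cur + int(exon_lens[k]) - 1))
            if k < n_exons - 1:
                cur = exons[-1][1] + 1 + int(intron_lens[k])
        utr5 = int(rng.integers(10, min(60, exon_lens[0] - 10)))
        utr3 = int(rng.integers(10, min(60, exon_lens[-1] - 10)))
        cds = [list(iv) for iv in exons]
        cds[0][0] += utr5
        cds[-1][1] -= utr3
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(
                gene_id=f"G22_{g + 1:03d}",
                strand=strand,
                exons=tuple(tuple(iv) for iv in exons),
                cds=tuple(tuple(iv) for iv in cds),
            )
        )
    return models


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the synthetic cohort (VCF, manifest TSV, GFF3) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(config)
    region = Region(*config.region)
    paths = {
        "vcf": out / "cohort.vcf",
        "manifest": out / "manifest.tsv",
        "gff3": out / "genes.gff3",
    }
    write_cohort_vcf(sim.calls, list(sim.manifest["sample_id"]), paths["vcf"], region)
    sim.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    write_gff3(sim.gene_models, region.chrom, paths["gff3"])
    return paths


def simulate_depth(config: CohortConfig) -> DepthSet:
    """Draw per-sample per-base depth over the coverage window.

    Baseline depth per sample is negative-binomially distributed around
    a per-sample mean ~ Normal(depth_mean, depth_sd) (library-size
    variation), with dispersion ``depth_dispersion`` (overdispersed
    relative to Poisson).  An injected CNV multiplies the mean of
    carrier samples by ``fold_change`` over its interval.
    """
    streams = _streams(config.seed)
    manifest = simulate_manifest(config, streams["manifest"])
    sample_ids = list(manifest["sample_id"])
    is_case = (manifest["group"] == "case").to_numpy()
    dregion = config.resolved_depth_region()
    positions = np.arange(dregion.start, dregion.end + 1)
    P = len(positions)
    rng = streams["depth"]
    means = np.maximum(rng.normal(config.depth_mean, config.depth_sd, size=config.n_samples), 5.0)

    cnv = config.cnv_injection
    cnv_carriers: list[str] = []
    if cnv is not None:
        if cnv.start < dregion.start or cnv.end > dregion.end:
            raise ValueError("CNV interval outside the depth region")
        case_idx = np.nonzero(is_case)[0]
        n_carry = max(1, round(cnv.case_fraction * len(case_idx)))
        chosen = rng.choice(case_idx, size=n_carry, replace=False)
        cnv_carriers = [sample_ids[i] for i in sorted(chosen)]

    r = config.depth_dispersion
    depth = np.empty((config.n_samples, P), dtype=np.int32)
    for i in range(config.n_samples):
        mu = np.full(P, means[i])
        if cnv is not None and sample_ids[i] in cnv_carriers:
            sel = (positions >= cnv.start) & (positions <= cnv.end)
            mu[sel] *= cnv.fold_change
        p = r / (r + np.maximum(mu, 1e-9))
        depth[i] = rng.negative_binomial(r, p)
    return DepthSet(
        config=config,
        region=dregion,
        positions=positions,
        depth=depth,
        sample_ids=sample_ids,
        cnv_carriers=cnv_carriers,
    )


def generate_depth_tracks(config: CohortConfig, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write one samtools-depth-style TSV (chrom, pos, depth) per sample."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_depth(config)
    paths: dict[str, Path] = {}
    for i, sid in enumerate(ds.sample_ids):
        p = out / f"{sid}.depth.tsv"
        pd.DataFrame(
            {"chrom": ds.region.chrom, "pos": ds.positions, "depth": ds.depth[i]}
        ).to_csv(p, sep="\t", index=False, header=False)
        paths[sid] = p
    return paths
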