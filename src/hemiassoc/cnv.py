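"""Coverage-based CNV association: per-nucleotide case-control testing.

Each sample's coverage is normalised per nucleotide as (reads overlapping
the nucleotide) / (total reads for that sample), removing library-size
differences.  A Fisher exact test is then run independently at every
nucleotide — which requires dichotomising the continuous coverage value.
The dichotomisation used here follows standard read-depth CNV heuristics
and is fully parameterised: at each position, the median of normalised
coverage over a reference sample set (all samples, or the controls when
case-enriched CNVs are sought) is the reference level; a sample is a
*loss* below ``loss_ratio`` x reference (default 0.75, the decision
boundary midway between the normal and a halved coverage state), a
*gain* above ``gain_ratio`` x reference (default 1.5, midway between
normal and doubled), and *normal* otherwise (both comparisons strict).
Aberrant (loss or gain) vs normal by group forms the 2x2 at each
position.

Positions where fewer than ``min_covered_fraction`` of samples have
nonzero raw depth (capture gaps) or where the reference level is zero
are skipped and logged.  Runs of adjacent Bonferroni-significant
positions are merged into reported intervals.

An ingestion hook for externally called CNVs (per-sample BED intervals,
e.g. from a dedicated read-depth caller) exposes the same 2x2 test
without re-implementing the caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import fisher_pvalues, odds_ratio_estimate

__all__ = [
    "DepthTrack",
    "read_depth_tsv",
    "read_depth_dir",
    "normalize_tracks",
    "call_position_status",
    "position_association",
    "CnvAssociation",
    "bed_cnv_association",
]

LOSS, NORMAL, GAIN = -1, 0, 1


@dataclass
class DepthTrack:
    """Per-base read depth for one sample over a contiguous range."""

    sample_id: str
    chrom: str
    positions: np.ndarray  # 1-based, contiguous ascending
    raw_depth: np.ndarray
    total_reads: float | None = None  # library size; defaults to sum of depths

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.raw_depth = np.asarray(self.raw_depth)
        if len(self.positions) != len(self.raw_depth):
            raise ValueError(f"{self.sample_id}: positions/depth length mismatch")
        if (self.raw_depth < 0).any():
            raise ValueError(f"{self.sample_id}: negative depth")
        if self.total_reads is None:
            self.total_reads = float(self.raw_depth.sum())

    @property
    def normalized(self) -> np.ndarray:
        if self.total_reads <= 0:
            raise ValueError(f"{self.sample_id}: total_reads must be positive")
        return self.raw_depth / self.total_reads


def read_depth_tsv(path: str | os.PathLike, sample_id: str | None = None) -> DepthTrack:
    """Read a samtools-depth-style TSV (chrom, 1-based pos, depth)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    sid = sample_id or Path(path).name.split(".")[0]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: depth track must cover a single contig")
    return DepthTrack(
        sample_id=sid,
        chrom=str(chroms[0]),
        positions=df["pos"].to_numpy(),
        raw_depth=df["depth"].to_numpy(),
    )


def read_depth_dir(depth_dir: str | os.PathLike, sample_ids: Sequence[str]) -> list[DepthTrack]:
    """Load ``<sample>.depth.tsv`` tracks for every manifest sample."""
    out = []
    for sid in sample_ids:
        p = Path(depth_dir) / f"{sid}.depth.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing depth track for sample {sid}: {p}")
        out.append(read_depth_tsv(p, sample_id=sid))
    return out


def normalize_tracks(tracks: Sequence[DepthTrack]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack tracks into (positions, normalized matrix, sample order).

    All tracks must cover identical positions; each row is the sample's
    depth divided by its total read count, so the result is invariant to
    per-sample rescaling of (depths, total_reads).
    """
    if not tracks:
        raise ValueError("no depth tracks given")
    pos = tracks[0].positions
    for t in tracks[1:]:
        if len(t.positions) != len(pos) or not np.array_equal(t.positions, pos):
            raise ValueError(f"track {t.sample_id} covers different positions")
    norm = np.vstack([t.normalized for t in tracks])
    return pos, norm, [t.sample_id for t in tracks]


def call_position_status(
    normalized: np.ndarray,
    raw_depth: np.ndarray | None = None,
    loss_ratio: float = 0.75,
    gain_ratio: float = 1.5,
    min_covered_fraction: float = 0.8,
    reference_rows: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomise normalised coverage into loss/normal/gain per (sample, position).

    The reference level at each position is the median of normalised
    coverage over ``reference_rows`` (default: all samples).  When a CNV
    may be carried by a large fraction of one group, pass the control
    rows as the reference so the median is not dragged toward the
    aberrant level.  The default ``loss_ratio`` of 0.75 places the loss
    boundary midway between the normal level and a halved (0.5x) state;
    ``gain_ratio`` 1.5 sits midway between normal and a doubled state.

    Returns ``(status, tested)``: ``status`` is an int8 matrix with -1 =
    loss, 0 = normal, 1 = gain, and ``tested`` flags positions where the
    call is defined (reference median > 0 and, when raw depth is given,
    at least ``min_covered_fraction`` of samples non-zero).
    """
    rows = np.arange(normalized.shape[0]) if reference_rows is None else np.nonzero(np.asarray(reference_rows))[0]
    if len(rows) < 3:
        raise ValueError("need >= 3 reference samples for a positional median")
    ref = np.median(normalized[rows], axis=0)
    tested = ref > 0
    if raw_depth is not None:
        covered = (raw_depth > 0).mean(axis=0) >= min_covered_fraction
        tested &= covered
    status = np.zeros_like(normalized, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        status[normalized < loss_ratio * ref[None, :]] = LOSS
        status[normalized > gain_ratio * ref[None, :]] = GAIN
    status[:, ~tested] = NORMAL
    return status, tested


@dataclass
class CnvAssociation:
    """Per-position results plus merged significant intervals."""

    results: pd.DataFrame  # pos, a, b, c, d, p_value, odds_ratio, direction, significant
    intervals: pd.DataFrame  # chrom, start (0-based), end — BED-compatible
    threshold: float
    n_tested: int


def position_association(
    status: np.ndarray,
    groups: Sequence[str] | np.ndarray,
    positions: np.ndarray,
    chrom: str = "chr22",
    tested: np.ndarray | None = None,
    alpha: float = 0.05,
) -> CnvAssociation:
    """Fisher test of aberrant-vs-normal status by group at every position.

    ``status`` is the (samples x positions) matrix from
    :func:`call_position_status`; the Bonferroni threshold is ``alpha``
    divided by the number of tested positions.  Direction at a position
    is the majority aberration among aberrant samples.
    """
    groups = np.asarray(groups, dtype=object)
    case = groups == "case"
    n_case, n_control = int(case.sum()), int((~case).sum())
    if min(n_case, n_control) < 1:
        raise ValueError("need both cases and controls")
    if tested is None:
        tested = np.ones(status.shape[1], dtype=bool)
    aberrant = status != NORMAL
    a = aberrant[case].sum(axis=0)
    c = aberrant[~case].sum(axis=0)
    n_tested = int(tested.sum())
    threshold = alpha / max(n_tested, 1)
    p = np.ones(status.shape[1])
    p[tested] = fisher_pvalues(a[tested], c[tested], n_case, n_control)
    orr = odds_ratio_estimate(a, n_case - a, c, n_control - c)
    losses = (status == LOSS).sum(axis=0)
    gains = (status == GAIN).sum(axis=0)
    direction = np.where(losses > gains, "loss", np.where(gains > losses, "gain", "none"))
    direction[(losses + gains) == 0] = "none"
    significant = tested & (p < threshold)
    results = pd.DataFrame(
        {
            "pos": positions,
            "a": a,
            "b": n_case - a,
            "c": c,
            "d": n_control - c,
            "p_value": p,
            "odds_ratio": orr,
            "direction": direction,
            "tested": tested,
            "significant": significant,
        }
    )
    intervals = _merge_runs(positions, significant, chrom)
    return CnvAssociation(results=results, intervals=intervals, threshold=threshold, n_tested=n_tested)


def _merge_runs(positions: np.ndarray, flag: np.ndarray, chrom: str) -> pd.DataFrame:
    """Merge runs of adjacent flagged positions into BED rows (0-based, half-open)."""
    rows = []
    idx = np.nonzero(flag)[0]
    if len(idx):
        breaks = np.nonzero(np.diff(positions[idx]) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(idx) - 1]])
        for s, e in zip(starts, ends):
            rows.append((chrom, int(positions[idx[s]]) - 1, int(positions[idx[e]])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def bed_cnv_association(
    cnv_calls: pd.DataFrame,
    manifest: pd.DataFrame,
    interval: tuple[str, int, int],
    alpha: float = 0.05,
) -> dict:
    """2x2 test on externally called CNVs (ingestion hook).

    ``cnv_calls`` has columns (sample_id, chrom, start, end) with 1-based
    inclusive coordinates, one row per called CNV; a sample is aberrant
    over ``interval`` iff any of its calls overlaps it.
    """
    chrom, start, end = interval
    hits = cnv_calls[
        (cnv_calls["chrom"] == chrom)
        & (cnv_calls["start"] <= end)
        & (cnv_calls["end"] >= start)
    ]
    aberrant = set(hits["sample_id"])
    case = manifest["group"] == "case"
    a = int(manifest.loc[case, "sample_id"].isin(aberrant).sum())
    c = int(manifest.loc[~case, "sample_id"].isin(aberrant).sum())
    n_case, n_control = int(case.sum()), int((~case).sum())
    p = float(fisher_pvalues(np.array([a]), np.array([c]), n_case, n_control)[0])
    return {
        "interval": interval,
        "a": a,
        "b": n_case - a,
        "c": c,
        "d": n_control - c,
        "p_value": p,
        "significant": p < alpha,
    }
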