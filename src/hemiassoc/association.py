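"""Case-control association tests for hemizygous carrier data.

Every test in this module reduces to a two-sided Fisher exact test on a
2x2 table of carrier status (carrier / non-carrier) by diagnostic group
(case / control).  Because each sample contributes exactly one allele of
the hemizygous region, carrier counting is the natural unit: a sample
either bears the alternate allele on its remaining copy or it does not.

Three test families are provided:

* :func:`variant_test` — one table per retained variant.
* :func:`gene_burden_test` — per gene, samples carrying at least one
  coding or splice-site variant of that gene are burden carriers.
* :func:`window_test` — per retained variant, a fixed-length window
  centred on that variant defines a region unit; a sample is a burden
  carrier if it carries any retained variant inside the window.  With
  variant-centred windows the number of windows equals the number of
  variants, which is the multiplicity used for the Bonferroni family.

Family-wise error is controlled by Bonferroni at ``alpha / m``; the
rounded order-of-magnitude threshold (nearest power of ten) is reported
alongside for readability, and a Benjamini–Hochberg adjusted p-value is
emitted as a side column but never drives the significance flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .filtering import CarrierMatrix

__all__ = [
    "TwoByTwo",
    "AssociationResult",
    "AssociationBundle",
    "fisher_exact",
    "fisher_pvalues",
    "pvalue_table",
    "odds_ratio_estimate",
    "bonferroni_threshold",
    "magnitude_threshold",
    "variant_test",
    "gene_burden_test",
    "window_test",
    "run_association_suite",
    "results_to_frame",
]

# Relative tolerance for probability ties in the two-sided ordering; the
# convention used by R's fisher.test, which keeps near-equal hypergeometric
# probabilities (equal up to floating-point noise) on the same side.
_TIE_REL = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Carrier-by-group contingency table.

    ``a``/``b`` are case carriers / case non-carriers, ``c``/``d`` the
    control equivalents; row margins are the group sizes.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"2x2 cells must be non-negative, got {self}")

    @property
    def n_case(self) -> int:
        return self.a + self.b

    @property
    def n_control(self) -> int:
        return self.c + self.d

    def swapped(self) -> "TwoByTwo":
        """Swap groups and carrier labels simultaneously (p is invariant)."""
        return TwoByTwo(self.d, self.c, self.b, self.a)


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one tested unit (variant, gene or window)."""

    unit_id: str
    unit_kind: str  # "variant" | "gene" | "window"
    table: TwoByTwo
    p_value: float
    odds_ratio: float
    threshold: float
    threshold_magnitude: float
    significant: bool
    testable: bool = True
    chrom: str | None = None
    start: int | None = None  # 1-based inclusive span of the unit
    end: int | None = None


@lru_cache(maxsize=64)
def pvalue_table(n_case: int, n_control: int) -> np.ndarray:
    """Two-sided Fisher p-values for every table with fixed group sizes.

    Returns an ``(n_case+1, n_control+1)`` array ``P`` with ``P[a, c]``
    the two-sided p-value of ``TwoByTwo(a, n_case-a, c, n_control-c)``.
    Precomputing the table makes repeated testing (thousands of variants,
    Monte-Carlo power replicates) a vectorised lookup.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both group sizes must be positive")
    N = n_case + n_control
    P = np.ones((n_case + 1, n_control + 1))
    for k in range(N + 1):  # k = total carriers
        lo, hi = max(0, k - n_control), min(n_case, k)
        xs = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(xs, N, k, n_case)
        # two-sided by probability ordering: sum tables no more probable
        # than the observed one
        mask = pmf[None, :] <= pmf[:, None] * (1.0 + _TIE_REL)
        P[xs, k - xs] = np.minimum((pmf[None, :] * mask).sum(axis=1), 1.0)
    P.setflags(write=False)
    return P


def fisher_pvalues(a: np.ndarray, c: np.ndarray, n_case: int, n_control: int) -> np.ndarray:
    """Vectorised two-sided p-values for carrier counts ``a`` (cases) and ``c`` (controls)."""
    a = np.asarray(a, dtype=np.intp)
    c = np.asarray(c, dtype=np.intp)
    return pvalue_table(n_case, n_control)[a, c]


def odds_ratio_estimate(a, b, c, d) -> np.ndarray | float:
    """Sample odds ratio (a*d)/(b*c); +0.5 to every cell when any cell is zero."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    h = np.where(zero, 0.5, 0.0)
    out = ((a + h) * (d + h)) / ((b + h) * (c + h))
    return out if out.ndim else float(out)


def fisher_exact(table: TwoByTwo) -> tuple[float, float]:
    """Two-sided Fisher exact p-value and odds-ratio point estimate.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed table.
    The odds ratio is ``(a*d)/(b*c)`` with a 0.5 continuity correction
    applied to every cell only when some cell is zero.
    """
    if table.n_case < 1 or table.n_control < 1:
        raise ValueError("both margins must be positive")
    p = float(pvalue_table(table.n_case, table.n_control)[table.a, table.c])
    orr = float(odds_ratio_estimate(table.a, table.b, table.c, table.d))
    return p, orr


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def magnitude_threshold(alpha: float, m: int) -> float:
    """Bonferroni threshold rounded to the nearest power of ten.

    Published analyses often print the corrected threshold as an order
    of magnitude (e.g. 0.05/4176 ~ 1.2e-5 reported as 1e-5); this helper
    reproduces that convention.
    """
    return 10.0 ** round(math.log10(bonferroni_threshold(alpha, m)))


def _results_from_counts(
    unit_ids: Sequence[str],
    unit_kind: str,
    a: np.ndarray,
    c: np.ndarray,
    n_case: int,
    n_control: int,
    alpha: float,
    m: int | None = None,
    testable: np.ndarray | None = None,
    spans: Sequence[tuple[str, int, int]] | None = None,
) -> list[AssociationResult]:
    m = len(unit_ids) if m is None else m
    thr = bonferroni_threshold(alpha, m)
    thr_mag = magnitude_threshold(alpha, m)
    p = fisher_pvalues(a, c, n_case, n_control)
    orr = odds_ratio_estimate(a, n_case - a, c, n_control - c)
    out = []
    for i, uid in enumerate(unit_ids):
        ok = True if testable is None else bool(testable[i])
        pi = float(p[i]) if ok else 1.0
        span = spans[i] if spans is not None else (None, None, None)
        out.append(
            AssociationResult(
                unit_id=uid,
                unit_kind=unit_kind,
                table=TwoByTwo(int(a[i]), n_case - int(a[i]), int(c[i]), n_control - int(c[i])),
                p_value=pi,
                odds_ratio=float(orr[i]) if ok else 1.0,
                threshold=thr,
                threshold_magnitude=thr_mag,
                significant=ok and pi < thr,
                testable=ok,
                chrom=span[0],
                start=span[1],
                end=span[2],
            )
        )
    return out


def _group_counts(matrix: CarrierMatrix, burden: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Case and control carrier counts for a (samples x units) boolean array."""
    case = matrix.case_mask
    a = burden[case].sum(axis=0)
    c = burden[~case].sum(axis=0)
    return a, c


def variant_test(matrix: CarrierMatrix, alpha: float = 0.05) -> list[AssociationResult]:
    """Per-variant carrier-frequency comparison between cases and controls.

    One Fisher exact test per retained variant; the family threshold is
    ``alpha`` divided by the number of variants.
    """
    _require_both_groups(matrix)
    a, c = _group_counts(matrix, matrix.indicator)
    spans = [(v.chrom, v.pos, v.pos) for v in matrix.variants]
    return _results_from_counts(
        [v.key for v in matrix.variants], "variant", a, c,
        matrix.n_case, matrix.n_control, alpha, spans=spans,
    )


def gene_burden_test(
    matrix: CarrierMatrix,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    qualifying_classes: Sequence[str] = ("coding", "splice_site"),
    gene_spans: Mapping[str, tuple[str, int, int]] | None = None,
) -> list[AssociationResult]:
    """Per-gene burden of coding and splice-site variants.

    ``annotations`` is the per-(variant, gene) classification table
    produced by :func:`hemiassoc.annotate.annotate_variants`, with
    columns ``variant_index``, ``gene_id`` and ``v_class``.  For each
    gene, a sample is a burden carrier iff it carries at least one
    qualifying variant of that gene (the union, never the sum, of the
    per-variant carrier sets).  Genes with no qualifying variant are
    reported untestable with p = 1.  The family threshold is ``alpha``
    divided by the number of genes.
    """
    _require_both_groups(matrix)
    required = {"variant_index", "gene_id", "v_class"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    genes = list(dict.fromkeys(annotations["gene_id"]))
    qual = annotations[annotations["v_class"].isin(qualifying_classes)]
    by_gene = {g: idx["variant_index"].to_numpy() for g, idx in qual.groupby("gene_id", sort=False)}
    n = matrix.n_samples
    burden = np.zeros((n, len(genes)), dtype=bool)
    testable = np.zeros(len(genes), dtype=bool)
    for j, g in enumerate(genes):
        cols = by_gene.get(g)
        if cols is not None and len(cols):
            burden[:, j] = matrix.indicator[:, cols].any(axis=1)
            testable[j] = True
    a, c = _group_counts(matrix, burden)
    spans = None
    if gene_spans is not None:
        spans = [gene_spans.get(g, (None, None, None)) for g in genes]
    return _results_from_counts(
        genes, "gene", a, c, matrix.n_case, matrix.n_control, alpha,
        testable=testable, spans=spans,
    )


def window_test(
    matrix: CarrierMatrix,
    window_sizes: Sequence[int] = (1_000, 5_000, 10_000),
    alpha: float = 0.05,
) -> dict[int, list[AssociationResult]]:
    """Region burden in fixed-length windows centred on each variant.

    For each window size ``w`` and each retained variant, the unit is the
    interval of length ``w`` centred on the variant's position, so the
    number of windows equals the number of variants.  A sample is a
    burden carrier if it carries any retained variant inside the window.
    Each window size forms its own Bonferroni family (``alpha / n_windows``).
    """
    _require_both_groups(matrix)
    if matrix.n_variants == 0:
        raise ValueError("empty carrier matrix")
    pos = np.array([v.pos for v in matrix.variants])
    order = np.argsort(pos, kind="stable")
    spos = pos[order]
    ind = matrix.indicator[:, order]
    # prefix sums along the position-sorted variant axis let every window
    # burden be two gathers and a subtraction
    prefix = np.zeros((matrix.n_samples, matrix.n_variants + 1), dtype=np.int32)
    np.cumsum(ind, axis=1, out=prefix[:, 1:])
    chrom = matrix.variants[0].chrom
    out: dict[int, list[AssociationResult]] = {}
    for w in window_sizes:
        half = w // 2
        lo = np.searchsorted(spos, spos - half, side="left")
        hi = np.searchsorted(spos, spos + half, side="right")
        burden = (prefix[:, hi] - prefix[:, lo]) > 0
        a, c = _group_counts(matrix, burden)
        ids = [f"{chrom}:{p - half}-{p + half}|w{w}" for p in spos]
        spans = [(chrom, int(p - half), int(p + half)) for p in spos]
        out[w] = _results_from_counts(
            ids, "window", a, c, matrix.n_case, matrix.n_control, alpha, spans=spans
        )
    return out


def suite_minima(
    matrix: CarrierMatrix,
    annotations: pd.DataFrame,
    window_sizes: Sequence[int] = (1_000, 5_000, 10_000),
    alpha: float = 0.05,
    qualifying_classes: Sequence[str] = ("coding", "splice_site"),
) -> dict[str, dict]:
    """Per-family minimum p-value and rejection count, fully vectorised.

    Computes exactly the carrier counts and Fisher p-values of
    :func:`variant_test`, :func:`gene_burden_test` and
    :func:`window_test` but skips materialising per-unit result objects,
    which makes replicate studies (null calibration, power-by-injection)
    fast.  Returns ``family -> {n_units, min_p, threshold, n_significant}``.
    """
    _require_both_groups(matrix)
    n1, n2 = matrix.n_case, matrix.n_control
    case = matrix.case_mask
    out: dict[str, dict] = {}

    def fam(name: str, a: np.ndarray, c: np.ndarray, m: int, tested: np.ndarray | None = None):
        p = fisher_pvalues(a, c, n1, n2)
        if tested is not None:
            p = np.where(tested, p, 1.0)
        thr = bonferroni_threshold(alpha, m)
        out[name] = {
            "n_units": m,
            "min_p": float(p.min()) if len(p) else 1.0,
            "threshold": thr,
            "n_significant": int((p < thr).sum()),
        }

    a = matrix.indicator[case].sum(axis=0)
    c = matrix.indicator[~case].sum(axis=0)
    fam("variant", a, c, matrix.n_variants)

    qual = annotations[annotations["v_class"].isin(qualifying_classes)]
    genes = list(dict.fromkeys(annotations["gene_id"]))
    by_gene = {g: idx["variant_index"].to_numpy() for g, idx in qual.groupby("gene_id", sort=False)}
    ga = np.zeros(len(genes), dtype=np.intp)
    gc = np.zeros(len(genes), dtype=np.intp)
    tested = np.zeros(len(genes), dtype=bool)
    for j, g in enumerate(genes):
        cols = by_gene.get(g)
        if cols is not None and len(cols):
            burden = matrix.indicator[:, cols].any(axis=1)
            ga[j] = burden[case].sum()
            gc[j] = burden[~case].sum()
            tested[j] = True
    fam("gene", ga, gc, len(genes), tested)

    pos = np.array([v.pos for v in matrix.variants])
    order = np.argsort(pos, kind="stable")
    spos = pos[order]
    prefix = np.zeros((matrix.n_samples, matrix.n_variants + 1), dtype=np.int32)
    np.cumsum(matrix.indicator[:, order], axis=1, out=prefix[:, 1:])
    for w in window_sizes:
        half = w // 2
        lo = np.searchsorted(spos, spos - half, side="left")
        hi = np.searchsorted(spos, spos + half, side="right")
        burden = (prefix[:, hi] - prefix[:, lo]) > 0
        fam(f"window_{w}", burden[case].sum(axis=0), burden[~case].sum(axis=0), matrix.n_variants)
    return out


@dataclass
class AssociationBundle:
    """All three test families plus a plotting track and a summary."""

    families: dict[str, list[AssociationResult]]
    track: pd.DataFrame  # BED-like: chrom, start (0-based), end, family, minus_log10_p
    summary: dict
    n_case: int
    n_control: int


def run_association_suite(
    matrix: CarrierMatrix,
    annotations: pd.DataFrame,
    window_sizes: Sequence[int] = (1_000, 5_000, 10_000),
    alpha: float = 0.05,
    min_control_age: float | None = None,
    gene_spans: Mapping[str, tuple[str, int, int]] | None = None,
) -> AssociationBundle:
    """Run variant, gene-burden and window tests on one carrier matrix.

    If ``min_control_age`` is set, controls younger than the cutoff are
    dropped before testing (sensitivity analysis against prodromal
    misclassification of young controls); cases are never dropped.
    """
    if min_control_age is not None:
        if matrix.ages is None:
            raise ValueError("manifest carries no ages; cannot subset controls by age")
        keep = matrix.case_mask | (matrix.ages >= min_control_age)
        matrix = matrix.subset_samples(keep)
        if matrix.n_control < 2:
            raise ValueError("age subset leaves fewer than 2 controls")
    families: dict[str, list[AssociationResult]] = {
        "variant": variant_test(matrix, alpha=alpha),
        "gene": gene_burden_test(matrix, annotations, alpha=alpha, gene_spans=gene_spans),
    }
    for w, res in window_test(matrix, window_sizes=window_sizes, alpha=alpha).items():
        families[f"window_{w}"] = res
    track = _pvalue_track(families)
    summary = {
        "n_case": matrix.n_case,
        "n_control": matrix.n_control,
        "alpha": alpha,
        "families": {
            name: {
                "n_units": len(res),
                "n_significant": sum(r.significant for r in res),
                "min_p": min((r.p_value for r in res), default=1.0),
                "threshold": res[0].threshold if res else None,
                "threshold_magnitude": res[0].threshold_magnitude if res else None,
            }
            for name, res in families.items()
        },
    }
    summary["any_significant"] = any(
        f["n_significant"] > 0 for f in summary["families"].values()
    )
    return AssociationBundle(families, track, summary, matrix.n_case, matrix.n_control)


def _pvalue_track(families: Mapping[str, list[AssociationResult]]) -> pd.DataFrame:
    rows = []
    for name, res in families.items():
        for r in res:
            if r.chrom is None:
                continue
            rows.append(
                (r.chrom, max(0, r.start - 1), r.end, name, -math.log10(max(r.p_value, 1e-300)))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "minus_log10_p"])


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Flatten results into a table, with a BH-adjusted p side column."""
    rows = [
        {
            "unit_id": r.unit_id,
            "unit_kind": r.unit_kind,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "p_value": r.p_value,
            "odds_ratio": r.odds_ratio,
            "threshold": r.threshold,
            "threshold_magnitude": r.threshold_magnitude,
            "significant": r.significant,
            "testable": r.testable,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bh"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df


def _require_both_groups(matrix: CarrierMatrix) -> None:
    if matrix.n_case < 1 or matrix.n_control < 1:
        raise ValueError("carrier matrix must contain both cases and controls")
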