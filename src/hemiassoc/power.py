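"""Monte-Carlo power of the two-sided Fisher exact test for carrier data.

The study design is two independent binomial proportions: carrier
frequency ``p0`` among controls and ``p1`` among cases, linked by the
odds ratio ``OR = odds(p1)/odds(p0)``.  Each sample contributes one
hemizygous allele, so carrier counts are Binomial(n, p) draws per group.
Power at a design is the fraction of simulated cohorts whose two-sided
Fisher p-value falls below the per-test significance level.

Because every replicate shares the group sizes, p-values come from one
precomputed (n_case+1) x (n_control+1) lookup table, so large replicate
counts are cheap; an exact (fully enumerated) power is also available
as :func:`exact_power` for validation and fast curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .association import pvalue_table

__all__ = [
    "PowerDesign",
    "PowerEstimate",
    "MinDetectableOR",
    "PowerTargetUnreachable",
    "case_carrier_freq",
    "risk_ratio",
    "odds_ratio_from_freqs",
    "exact_power",
    "simulate_power",
    "power_curve",
    "min_detectable_or",
]


class PowerTargetUnreachable(RuntimeError):
    """Raised when no odds ratio below the search cap reaches the target power."""


@dataclass(frozen=True)
class PowerDesign:
    """A two-proportion Fisher power scenario."""

    p0: float  # control carrier (risk-allele) frequency
    odds_ratio: float
    n_case: int = 40
    n_control: int = 48
    alpha: float = 0.05
    reps: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def p1(self) -> float:
        return case_carrier_freq(self.p0, self.odds_ratio)


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power with its binomial standard error."""

    design: PowerDesign
    power: float
    mc_se: float


@dataclass(frozen=True)
class MinDetectableOR:
    """Smallest odds ratio reaching the target power, with its search bracket."""

    or_star: float
    bracket: tuple[float, float]
    power_at_or_star: float
    target_power: float


def case_carrier_freq(p0: float, odds_ratio: float) -> float:
    """Case carrier frequency implied by an odds ratio on a control frequency.

    Inverts ``OR = [p1/(1-p1)] / [p0/(1-p0)]``:
    ``p1 = OR * p0 / (1 - p0 + OR * p0)``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def risk_ratio(p_exposed: float, p_unexposed: float) -> float:
    """Plain prevalence (risk) ratio p_exposed / p_unexposed."""
    if p_unexposed <= 0:
        raise ValueError("unexposed prevalence must be positive")
    return p_exposed / p_unexposed


def odds_ratio_from_freqs(p1: float, p0: float) -> float:
    """Odds ratio implied by two prevalences (distinct from their risk ratio)."""
    return (p1 / (1 - p1)) / (p0 / (1 - p0))


def exact_power(design: PowerDesign) -> float:
    """Exact power by full enumeration of the two binomial carrier counts."""
    P = pvalue_table(design.n_case, design.n_control)
    pa = binom.pmf(np.arange(design.n_case + 1), design.n_case, design.p1)
    pc = binom.pmf(np.arange(design.n_control + 1), design.n_control, design.p0)
    return float((pa[:, None] * pc[None, :] * (P < design.alpha)).sum())


def simulate_power(design: PowerDesign) -> PowerEstimate:
    """Monte-Carlo power estimate at a design.

    Per replicate, case carriers ~ Binomial(n_case, p1) and control
    carriers ~ Binomial(n_control, p0); power is the fraction of
    replicates whose two-sided Fisher p-value is below ``alpha``.
    Deterministic under the design's seed.
    """
    rng = np.random.default_rng(design.seed)
    a = rng.binomial(design.n_case, design.p1, size=design.reps)
    c = rng.binomial(design.n_control, design.p0, size=design.reps)
    P = pvalue_table(design.n_case, design.n_control)
    power = float((P[a, c] < design.alpha).mean())
    mc_se = math.sqrt(power * (1.0 - power) / design.reps)
    return PowerEstimate(design=design, power=power, mc_se=mc_se)


def power_curve(
    p0: float,
    or_grid: Sequence[float],
    n_case: int = 40,
    n_control: int = 48,
    alpha: float = 0.05,
    reps: int = 20_000,
    seed: int = 0,
    plot_path: str | None = None,
):
    """Power estimates over an increasing odds-ratio grid.

    Returns a DataFrame (odds_ratio, p1, power, mc_se); optionally writes
    a power-vs-OR plot with the target line at 0.8.
    """
    import pandas as pd

    or_grid = list(or_grid)
    if not or_grid or any(b <= a for a, b in zip(or_grid, or_grid[1:])):
        raise ValueError("or_grid must be non-empty and strictly increasing")
    rows = []
    for i, orr in enumerate(or_grid):
        est = simulate_power(
            PowerDesign(p0=p0, odds_ratio=orr, n_case=n_case, n_control=n_control,
                        alpha=alpha, reps=reps, seed=seed + i)
        )
        rows.append({"odds_ratio": orr, "p1": est.design.p1, "power": est.power, "mc_se": est.mc_se})
    df = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["odds_ratio"], df["power"], marker="o")
        ax.axhline(0.8, ls="--", color="grey", lw=1)
        ax.set_xlabel("odds ratio")
        ax.set_ylabel("power")
        ax.set_ylim(0, 1.02)
        ax.set_title(f"Fisher exact power, p0={p0}, n={n_case}/{n_control}, alpha={alpha}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df


def min_detectable_or(
    p0: float,
    n_case: int = 40,
    n_control: int = 48,
    alpha: float = 0.05,
    target_power: float = 0.8,
    reps: int = 20_000,
    seed: int = 0,
    or_max: float = 1_000.0,
    rel_tol: float = 0.02,
) -> MinDetectableOR:
    """Smallest odds ratio whose simulated power reaches ``target_power``.

    Bisection on log(OR) with common random numbers: the same uniform
    draws underlie every evaluated OR, so the estimated power is
    monotone in OR along the search and the crossing is stable.  The
    returned bracket (lo, hi) satisfies power(lo) < target <= power(hi)
    with hi/lo <= 1 + rel_tol.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    u_case = rng.random((reps, n_case))
    u_ctrl = rng.random((reps, n_control))
    c = (u_ctrl < p0).sum(axis=1)
    P = pvalue_table(n_case, n_control)

    def power_at(orr: float) -> float:
        a = (u_case < case_carrier_freq(p0, orr)).sum(axis=1)
        return float((P[a, c] < alpha).mean())

    if power_at(1.0) >= target_power:
        return MinDetectableOR(1.0, (1.0, 1.0), power_at(1.0), target_power)
    if power_at(or_max) < target_power:
        raise PowerTargetUnreachable(
            f"power {power_at(or_max):.3f} at OR={or_max} below target {target_power}"
        )
    lo, hi = 1.0, or_max
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return MinDetectableOR(hi, (lo, hi), power_at(hi), target_power)
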