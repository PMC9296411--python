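"""ANOVA interaction power via the noncentral F distribution, sample-size
search, Kendall tau, and cohort summary tables.

Two G*Power-style formulations of interaction power are provided:

* ``fixed_effects_interaction_power`` — "ANOVA: fixed effects, special,
  main effects and interactions": lambda = f^2 * N, df1 = effect df,
  df2 = N - (number of design cells).  With the 2 (group) x 2 (condition)
  x 3 (age) design the three-way interaction has df1 = 1*1*2 = 2 and 12
  cells; this is the package default for the study design, and reproduces
  the design's planning numbers (N = 64 for power 0.80 at f = 0.40,
  power 0.91 at N = 84).
* ``repeated_measures_interaction_power`` — "repeated measures,
  within-between interaction": lambda = f^2 * N * m / (1 + (m-1) * rho),
  df1 = (k-1)(m-1)e, df2 = (N-k)(m-1)e for k between-subject cells, m
  within-subject levels, repeated-measures correlation rho and
  nonsphericity e.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import kendalltau, ncf

__all__ = [
    "PowerSpec",
    "anova_interaction_power",
    "fixed_effects_interaction_power",
    "repeated_measures_interaction_power",
    "min_n_for_power",
    "kendall_tau",
    "summarize_cohort",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design description for the interaction power computation.

    Defaults encode the study's 2 x 2 x 3 planning design with a large
    effect (Cohen's f = 0.40) at alpha = 0.05.  ``design`` selects the
    formulation; the repeated-measures fields (``k_groups``,
    ``m_measurements``, ``rho``, ``epsilon``) only enter for
    ``design="within_between"``.
    """

    effect_f: float = 0.40
    alpha: float = 0.05
    design: Literal["fixed_effects", "within_between"] = "fixed_effects"
    # fixed-effects design: three-way interaction of 2 x 2 x 3
    df_effect: int = 2
    n_cells: int = 12
    # repeated-measures design
    k_groups: int = 6
    m_measurements: int = 2
    rho: float = 0.5
    epsilon: float = 1.0
    n_total: int | None = None

    def __post_init__(self) -> None:
        if self.effect_f <= 0:
            raise ValueError("effect_f must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.design not in ("fixed_effects", "within_between"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.df_effect < 1 or self.n_cells < 2:
            raise ValueError("df_effect >= 1 and n_cells >= 2 required")
        if self.k_groups < 2 or self.m_measurements < 2:
            raise ValueError("k_groups >= 2 and m_measurements >= 2 required")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")


def _ncf_power(df1: float, df2: float, lam: float, alpha: float) -> float:
    if df2 <= 0:
        raise ValueError("non-positive error degrees of freedom; N too small")
    f_crit = f_dist.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - ncf.cdf(f_crit, df1, df2, lam))


def fixed_effects_interaction_power(
    effect_f: float, n_total: int, df_effect: int = 2, n_cells: int = 12,
    alpha: float = 0.05,
) -> float:
    """Power of a fixed-effects ANOVA effect test (lambda = f^2 * N)."""
    lam = effect_f ** 2 * n_total
    return _ncf_power(df_effect, n_total - n_cells, lam, alpha)


def repeated_measures_interaction_power(
    effect_f: float, n_total: int, k_groups: int = 6, m_measurements: int = 2,
    rho: float = 0.5, epsilon: float = 1.0, alpha: float = 0.05,
) -> float:
    """Power of the within-between interaction in a mixed repeated-measures
    ANOVA (G*Power convention)."""
    m, k, e = m_measurements, k_groups, epsilon
    lam = effect_f ** 2 * n_total * m / (1.0 + (m - 1) * rho)
    return _ncf_power((k - 1) * (m - 1) * e, (n_total - k) * (m - 1) * e, lam, alpha)


def anova_interaction_power(spec: PowerSpec, n_total: int | None = None) -> float:
    """Interaction power for ``spec`` at sample size ``n_total``."""
    n = n_total if n_total is not None else spec.n_total
    if n is None:
        raise ValueError("n_total must be given in the spec or as an argument")
    if spec.design == "fixed_effects":
        return fixed_effects_interaction_power(
            spec.effect_f, n, spec.df_effect, spec.n_cells, spec.alpha)
    return repeated_measures_interaction_power(
        spec.effect_f, n, spec.k_groups, spec.m_measurements, spec.rho,
        spec.epsilon, spec.alpha)


def min_n_for_power(
    spec: PowerSpec, target_power: float = 0.80, step: int = 2, n_max: int = 10_000,
) -> int:
    """Smallest total N (searched in increments of ``step``, so it can split
    evenly between two groups) reaching ``target_power``."""
    if not spec.alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    n_min = (spec.n_cells if spec.design == "fixed_effects" else spec.k_groups) + 1
    n = n_min + (-n_min) % step
    if n <= n_min:
        n += step
    while n <= n_max:
        if anova_interaction_power(spec, n) >= target_power:
            return n
        n += step
    raise ValueError(f"target power {target_power} not reached by N = {n_max}")


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected) rank correlation.

    Returns NaN (with a warning) for a constant sequence, where tau is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D sequences, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("kendall_tau undefined for a constant sequence; returning NaN")
        return float("nan")
    return float(kendalltau(x, y, variant="b").statistic)


def summarize_cohort(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD cross-tabulation of d' by (group, age, task, condition).

    ``scores`` needs columns group, age_cohort, task, condition, d_prime.
    Every combination present in the data's categories appears in the
    output; cells with no participants have NaN mean and n = 0, and cells
    with one participant have NaN SD.
    """
    required = {"group", "age_cohort", "task", "condition", "d_prime"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    keys = ["group", "age_cohort", "task", "condition"]
    grouped = scores.groupby(keys, observed=True)["d_prime"]
    table = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    levels = [sorted(scores[k].unique()) for k in keys]
    full = pd.MultiIndex.from_product(levels, names=keys).to_frame(index=False)
    table = full.merge(table, on=keys, how="left")
    table["n"] = table["n"].fillna(0).astype(int)
    return table
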