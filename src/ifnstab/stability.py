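"""Split-half stability cross-validation of the association screen.

The cohort is randomly bipartitioned into two equally sized halves
``n_iter`` times (1000 in the original design). On every iteration the
same bipartition is shared across all variables, each variable's test is
run on each half, and we tabulate how often the p value clears alpha in
both halves, exactly one, or neither. An association that replicates in
disjoint halves of the cohort is far less likely to be a one-off: under
an iid null the halves are independent, so the both-halves significance
rate calibrates to about alpha squared.

Reported per variable: the both/one/neither counts, the median p per set
across iterations, and (for continuous variables) the median Spearman rho
pooled over both sets — set labels are arbitrary, so pooling loses nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import (
    ClinicalCohort,
    DEFAULT_VARIABLE_SPEC,
    _align,
    _test_variable,
)

logger = logging.getLogger(__name__)

__all__ = ["StabilityResult", "split_half", "stability_screen", "summarize_stability"]


@dataclass
class StabilityResult:
    """Split-half concordance record for one variable."""

    variable: str
    test: str
    n_iter: int
    alpha: float
    count_both: int
    count_one: int
    count_neither: int
    median_p_set1: float
    median_p_set2: float
    median_statistic: float = np.nan  # continuous variables only

    def __post_init__(self) -> None:
        total = self.count_both + self.count_one + self.count_neither
        if total != self.n_iter:
            raise ValueError(
                f"{self.variable}: counts sum to {total}, expected n_iter = {self.n_iter}"
            )


def split_half(
    n: int, rng: np.random.Generator, min_n: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random bipartition into halves of floor(n/2) and ceil(n/2).

    Positions 0..n-1 are permuted with ``rng`` and split; the two sorted
    index arrays are disjoint and cover every position. ``min_n`` guards
    against cohorts too small for half-set testing to mean anything.
    """
    if n < min_n:
        raise ValueError(f"n = {n} too small for split-half testing (min {min_n})")
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def stability_screen(
    scores: pd.Series,
    cohort: ClinicalCohort,
    variable_spec: list[tuple[str, str]] | None = None,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_n: int = 8,
) -> list[StabilityResult]:
    """Run the split-half screen: one shared bipartition per iteration.

    Parameters
    ----------
    scores, cohort : aligned on the intersection of patient ids, in cohort
        row order.
    variable_spec : ordered (variable, test) list; defaults to the
        25-variable screen.
    n_iter : number of random bipartitions (>= 1).
    alpha : per-test significance level; a half "hits" when p < alpha.
    seed, rng : exactly one source of randomness; a fresh
        ``numpy.random.default_rng(seed)`` is used when ``rng`` is None.
        Iteration i's bipartition is the i-th draw from this single stream,
        so results are fully reproducible given the seed.

    A half-set in which a test is not computable (e.g. one treatment group
    empty in that half) counts as not-significant for that set; its p is
    excluded from the medians.
    """
    if variable_spec is None:
        variable_spec = DEFAULT_VARIABLE_SPEC
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    common = _align(scores, cohort)
    s = scores.loc[common]
    columns = {var: cohort.variable(var).loc[common] for var, _ in variable_spec}
    n = len(common)

    n_var = len(variable_spec)
    p_vals = np.full((n_var, n_iter, 2), np.nan)
    stat_vals = np.full((n_var, n_iter, 2), np.nan)
    n_not_computable = 0

    for it in range(n_iter):
        idx_a, idx_b = split_half(n, rng, min_n=min_n)
        halves = (s.iloc[idx_a], s.iloc[idx_b])
        for vi, (var, test) in enumerate(variable_spec):
            col = columns[var]
            for hi, half_scores in enumerate(halves):
                idx = idx_a if hi == 0 else idx_b
                out = _test_variable(half_scores, col.iloc[idx], test)
                if out.computable:
                    p_vals[vi, it, hi] = out.p
                    stat_vals[vi, it, hi] = out.statistic
                else:
                    n_not_computable += 1
    if n_not_computable:
        logger.info(
            "%d half-set test(s) were not computable and count as not-significant",
            n_not_computable,
        )

    results = []
    with np.errstate(invalid="ignore"):
        sig = p_vals < alpha  # NaN compares False: not-computable = not significant
    for vi, (var, test) in enumerate(variable_spec):
        hits = sig[vi].sum(axis=1)  # per-iteration: 0, 1 or 2 significant halves
        both = int((hits == 2).sum())
        one = int((hits == 1).sum())
        neither = int((hits == 0).sum())
        med1 = _nanmedian(p_vals[vi, :, 0])
        med2 = _nanmedian(p_vals[vi, :, 1])
        med_stat = _nanmedian(stat_vals[vi].ravel()) if test == "spearman" else np.nan
        results.append(
            StabilityResult(
                variable=var,
                test=test,
                n_iter=n_iter,
                alpha=alpha,
                count_both=both,
                count_one=one,
                count_neither=neither,
                median_p_set1=med1,
                median_p_set2=med2,
                median_statistic=med_stat,
            )
        )
    return results


def _nanmedian(a: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    return float(np.median(a)) if a.size else np.nan


def summarize_stability(results: list[StabilityResult]) -> pd.DataFrame:
    """Tabulate stability results, one row per variable in input order."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "both": r.count_both,
                "one": r.count_one,
                "neither": r.count_neither,
                "median_p_set1": r.median_p_set1,
                "median_p_set2": r.median_p_set2,
                "median_statistic": r.median_statistic,
            }
            for r in results
        ],
        columns=[
            "variable",
            "both",
            "one",
            "neither",
            "median_p_set1",
            "median_p_set2",
            "median_statistic",
        ],
    )
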