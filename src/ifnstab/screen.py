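"""Full-cohort association screening of the IFN score against clinical variables.

Continuous variables are tested with Spearman rank correlation, dichotomous
variables with the Mann-Whitney U test, each on pairwise-complete cases.
Multiple testing is corrected with Benjamini-Hochberg in one of two
dialects:

``monotone``
    The standard step-up estimate q_(i) = min_{j >= i} p_(j) * m / j
    (capped at 1). This is the library default.
``plain``
    q_i = min(1, p_i * m / rank_i) without monotone enforcement, ties
    sharing the smaller rank. Some statistics packages print this variant;
    it is the replication default for reproducing published screens of
    this design.

Both accept ``m`` larger than the number of supplied p values, for screens
in which some of the m planned tests have no reportable p.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalCohort",
    "TestOutcome",
    "AssociationResult",
    "DEFAULT_VARIABLE_SPEC",
    "spearman_test",
    "mann_whitney_test",
    "bh_adjust",
    "screen_cohort",
    "subgroup_filter",
    "group_compare",
    "add_derived_columns",
    "read_cohort",
]

CONTINUOUS = "continuous"
DICHOTOMOUS = "dichotomous"

#: The 25-variable screen of an established-RA cohort: disease duration,
#: DAS28 and its components, damage markers, laboratory/autoantibody
#: variables (with their conventional dichotomizations) and medication use.
DEFAULT_VARIABLE_SPEC: list[tuple[str, str]] = [
    ("disease_duration", "spearman"),
    ("das28", "spearman"),
    ("tjc28", "spearman"),
    ("sjc28", "spearman"),
    ("vas", "spearman"),
    ("erosions", "mann_whitney"),
    ("nodules", "mann_whitney"),
    ("esr", "spearman"),
    ("esr_gt20", "mann_whitney"),
    ("crp", "spearman"),
    ("crp_ge10", "mann_whitney"),
    ("rf_titer", "spearman"),
    ("rf_positive", "mann_whitney"),
    ("acpa_titer", "spearman"),
    ("acpa_positive", "mann_whitney"),
    ("acpa_high", "mann_whitney"),
    ("rf_and_acpa_positive", "mann_whitney"),
    ("rf_and_acpa_negative", "mann_whitney"),
    ("mtx_use", "mann_whitney"),
    ("mtx_dose", "spearman"),
    ("prednisone_use", "mann_whitney"),
    ("prednisone_dose", "spearman"),
    ("hcq_use", "mann_whitney"),
    ("ssz_use", "mann_whitney"),
    ("any_suppressor", "mann_whitney"),
]

#: Default treatment variables whose use suppresses the IFN score.
SUPPRESSOR_FLAGS = ("prednisone_use", "hcq_use", "ssz_use")


@dataclass
class ClinicalCohort:
    """One row per patient; each variable declared continuous or dichotomous.

    ``data`` is indexed by patient_id. Dichotomous columns may contain only
    {0, 1, NaN}. ``types`` maps variable name -> "continuous"/"dichotomous"
    for every analyzable column.
    """

    data: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, kind in self.types.items():
            if kind not in (CONTINUOUS, DICHOTOMOUS):
                raise ValueError(f"variable {var!r} has unknown type {kind!r}")
            if var not in self.data.columns:
                raise KeyError(f"declared variable {var!r} missing from cohort table")
            if kind == DICHOTOMOUS:
                vals = self.data[var].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise ValueError(
                        f"dichotomous variable {var!r} contains values other "
                        f"than 0/1/missing: {sorted(vals)[:5]}"
                    )

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def variable(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown cohort variable {name!r}")
        return self.data[name]


@dataclass(frozen=True)
class TestOutcome:
    """Result of a single rank-based test."""

    statistic: float
    p: float
    n_used: int
    computable: bool = True
    note: str = ""


@dataclass
class AssociationResult:
    """One screen row: variable, test used, statistic, raw and adjusted p."""

    variable: str
    test: str
    n_used: int
    statistic: float
    p: float
    q: float = np.nan
    computable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# Single tests


def _pairwise_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman_test(x, y, method: str = "asymptotic") -> TestOutcome:
    """Spearman rank correlation with a two-sided p value.

    Ranks are averaged over ties. The asymptotic p comes from the
    t approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 df, with
    p = 0 at |rho| = 1. ``method="exact"`` enumerates all permutations of
    y's ranks (n <= 9) and reports P(|rho'| >= |rho|).

    Missing values are removed pairwise; n < 4 or a zero-variance vector
    yields a not-computable outcome rather than an exception.
    """
    x, y = _pairwise_complete(x, y)
    n = len(x)
    if n < 4:
        return TestOutcome(np.nan, np.nan, n, False, f"n = {n} < 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestOutcome(np.nan, np.nan, n, False, "zero variance")
    if method == "asymptotic":
        rho, p = stats.spearmanr(x, y)
        if abs(rho) == 1.0:
            p = 0.0
        return TestOutcome(float(rho), float(p), n)
    if method == "exact":
        return _spearman_exact(x, y)
    raise ValueError(f"unknown method {method!r}")


def _spearman_exact(x, y, max_n: int = 9) -> TestOutcome:
    """Exact permutation distribution of rho over all n! orderings of y."""
    n = len(x)
    if n > max_n:
        raise ValueError(f"exact Spearman enumeration limited to n <= {max_n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    sx = np.sqrt((rx_c ** 2).sum())

    def rho_of(perm_ry: np.ndarray) -> float:
        ry_c = perm_ry - perm_ry.mean()
        sy = np.sqrt((ry_c ** 2).sum())
        return float((rx_c * ry_c).sum() / (sx * sy))

    rho_obs = rho_of(ry)
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(np.asarray(perm))) >= thresh:
            count += 1
    return TestOutcome(rho_obs, count / total, n)


def mann_whitney_test(a, b, method: str = "asymptotic") -> TestOutcome:
    """Mann-Whitney U test; the statistic is U for the first group.

    The asymptotic two-sided p uses the normal approximation with tie and
    continuity corrections. ``method="exact"`` enumerates all
    C(n_a+n_b, n_a) assignments of the pooled (tie-averaged) ranks, valid
    for n_a + n_b <= 12, and reports P(|U' - n_a n_b / 2| >= |U - n_a n_b / 2|).
    ``method="auto"`` picks exact for n_a + n_b <= 12.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return TestOutcome(np.nan, np.nan, na + nb, False, "a group is empty")
    if method == "auto":
        method = "exact" if na + nb <= 12 else "asymptotic"
    if method == "asymptotic":
        if np.ptp(np.concatenate([a, b])) == 0:
            # all pooled values tied: no evidence either way
            return TestOutcome(na * nb / 2.0, 1.0, na + nb)
        u, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return TestOutcome(float(u), float(p), na + nb)
    if method == "exact":
        return _mann_whitney_exact(a, b)
    raise ValueError(f"unknown method {method!r}")


def _mann_whitney_exact(a, b, max_total: int = 12) -> TestOutcome:
    """Exact two-sided MWU p by enumeration of rank assignments (tie-aware)."""
    na, nb = len(a), len(b)
    total_n = na + nb
    if total_n > max_total:
        raise ValueError(f"exact MWU enumeration limited to n_a + n_b <= {max_total}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    mu = na * nb / 2.0
    dev_obs = abs(u_obs - mu) - 1e-9
    count = 0
    n_comb = 0
    for idx in itertools.combinations(range(total_n), na):
        n_comb += 1
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        if abs(u - mu) >= dev_obs:
            count += 1
    return TestOutcome(u_obs, count / n_comb, total_n)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p_values, m: int | None = None, mode: str = "monotone") -> np.ndarray:
    """Benjamini-Hochberg adjustment in the plain or monotone dialect.

    Parameters
    ----------
    p_values : sequence of float in [0, 1]
    m : int, optional
        Number of tests in the family; defaults to ``len(p_values)`` and
        may exceed it when some of the family's tests have no reported p.
    mode : {"monotone", "plain"}
        See the module docstring.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    if np.isnan(p).any():
        raise ValueError("p values must not be missing; filter before adjusting")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m = {m} is smaller than the number of p values ({p.size})")
    if p.size == 0:
        return np.empty(0)

    if mode == "plain":
        # ties share the smaller rank
        ranks = np.array([1 + np.sum(p < pi) for pi in p], dtype=float)
        return np.minimum(1.0, p * m / ranks)
    if mode == "monotone":
        order = np.argsort(p, kind="stable")
        p_sorted = p[order]
        scaled = p_sorted * m / np.arange(1, p.size + 1)
        q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
        return q
    raise ValueError(f"unknown BH mode {mode!r}")


# ---------------------------------------------------------------------------
# Cohort-level operations


def _align(scores: pd.Series, cohort: ClinicalCohort) -> pd.Index:
    common = cohort.data.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no patient ids shared between scores and cohort")
    return common


def _test_variable(
    scores: pd.Series, values: pd.Series, test: str
) -> TestOutcome:
    if test == "spearman":
        return spearman_test(scores.to_numpy(), values.to_numpy())
    if test == "mann_whitney":
        v = values.to_numpy(dtype=float)
        s = scores.to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(s)
        return mann_whitney_test(s[ok & (v == 1)], s[ok & (v == 0)])
    raise ValueError(f"unknown test {test!r}")


def screen_cohort(
    scores: pd.Series,
    cohort: ClinicalCohort,
    variable_spec: list[tuple[str, str]] | None = None,
    bh_mode: str = "monotone",
    bh_m: int | None = None,
) -> list[AssociationResult]:
    """Test every variable in the spec against the IFN score, then adjust.

    Each test uses the pairwise-complete cases for that variable. BH is
    applied across the whole spec: ``m`` defaults to the number of spec
    entries, counting variables whose test was not computable.
    """
    if variable_spec is None:
        variable_spec = DEFAULT_VARIABLE_SPEC
    if not variable_spec:
        raise ValueError("variable spec must be non-empty")
    common = _align(scores, cohort)
    s = scores.loc[common]
    results: list[AssociationResult] = []
    for var, test in variable_spec:
        values = cohort.variable(var).loc[common]
        out = _test_variable(s, values, test)
        results.append(
            AssociationResult(
                variable=var,
                test=test,
                n_used=out.n_used,
                statistic=out.statistic,
                p=out.p,
                computable=out.computable,
                note=out.note,
            )
        )
    m = bh_m if bh_m is not None else len(variable_spec)
    computable = [r for r in results if r.computable]
    if computable:
        qs = bh_adjust([r.p for r in computable], m=m, mode=bh_mode)
        for r, q in zip(computable, qs):
            r.q = float(q)
    return results


def subgroup_filter(
    cohort: ClinicalCohort,
    exclude_if_any: "tuple[str, ...] | list[str]" = SUPPRESSOR_FLAGS,
) -> ClinicalCohort:
    """Keep patients with value 0 for every listed treatment flag.

    Patients missing any listed flag are excluded (their count is logged):
    treatment status unknown means untreated cannot be asserted.
    """
    for var in exclude_if_any:
        if cohort.types.get(var) != DICHOTOMOUS:
            raise ValueError(f"subgroup filter variable {var!r} must be dichotomous")
    flags = cohort.data[list(exclude_if_any)]
    untreated = (flags == 0).all(axis=1)
    n_missing = int((flags.isna().any(axis=1) & ~(flags == 1).any(axis=1)).sum())
    if n_missing:
        logger.info(
            "subgroup filter excluded %d patient(s) with missing treatment flags",
            n_missing,
        )
    kept = cohort.data.loc[untreated]
    if len(kept) == 0:
        logger.warning("subgroup filter retained no patients")
    return ClinicalCohort(data=kept.copy(), types=dict(cohort.types))


@dataclass
class GroupComparison:
    """Strata summaries and pairwise tests for agent-count groups."""

    strata: pd.DataFrame  # index: stratum label; columns: n, median, q1, q3
    pairwise: pd.DataFrame  # columns: group_a, group_b, U, p, computable


def group_compare(
    scores: pd.Series,
    cohort: ClinicalCohort,
    agents: "tuple[str, ...] | list[str]" = SUPPRESSOR_FLAGS,
) -> GroupComparison:
    """Compare IFN scores across 0 / 1 / >=2 suppressing-agent strata.

    Patients with a missing agent flag (that cannot be resolved by an
    observed 1) are excluded. Per-stratum n, median and quartiles are
    reported with Mann-Whitney tests between each pair of strata.
    """
    for var in agents:
        if cohort.types.get(var) != DICHOTOMOUS:
            raise ValueError(f"agent variable {var!r} must be dichotomous")
    common = _align(scores, cohort)
    flags = cohort.data.loc[common, list(agents)]
    counts = flags.sum(axis=1, skipna=True)
    # a missing flag only matters if it could change the stratum
    ambiguous = flags.isna().any(axis=1) & (counts < 2)
    if ambiguous.any():
        logger.info(
            "group_compare excluded %d patient(s) with unresolvable agent flags",
            int(ambiguous.sum()),
        )
    counts = counts[~ambiguous]
    s = scores.loc[counts.index]
    strata_labels = ["0", "1", "2+"]
    members = {
        "0": s[counts == 0],
        "1": s[counts == 1],
        "2+": s[counts >= 2],
    }
    strata = pd.DataFrame(
        {
            label: {
                "n": len(vals),
                "median": float(vals.median()) if len(vals) else np.nan,
                "q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
            for label, vals in members.items()
        }
    ).T
    strata["n"] = strata["n"].astype(int)
    strata.index.name = "stratum"

    rows = []
    for la, lb in itertools.combinations(strata_labels, 2):
        va, vb = members[la], members[lb]
        if len(va) == 0 or len(vb) == 0:
            rows.append((la, lb, np.nan, np.nan, False))
            continue
        out = mann_whitney_test(va.to_numpy(), vb.to_numpy())
        rows.append((la, lb, out.statistic, out.p, out.computable))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p", "computable"])
    return GroupComparison(strata=strata, pairwise=pairwise)


# ---------------------------------------------------------------------------
# Derived clinical columns


def add_derived_columns(cohort: ClinicalCohort, acpa_cutoff: float = 500.0) -> ClinicalCohort:
    """(Re)compute the rule-based derived columns from their parents.

    Derived columns are never trusted as stored: esr_gt20 (> 20 mm/h),
    crp_ge10 (>= 10 mg/L), acpa_high (titer >= 3 x assay cutoff),
    rf_and_acpa_positive / _negative, and any_suppressor (prednisone,
    HCQ or SSZ use).
    """
    df = cohort.data.copy()
    types = dict(cohort.types)

    def _flag(series: pd.Series, predicate) -> pd.Series:
        out = predicate(series).astype(float)
        out[series.isna()] = np.nan
        return out

    if "esr" in df:
        df["esr_gt20"] = _flag(df["esr"], lambda s: s > 20)
        types["esr_gt20"] = DICHOTOMOUS
    if "crp" in df:
        df["crp_ge10"] = _flag(df["crp"], lambda s: s >= 10)
        types["crp_ge10"] = DICHOTOMOUS
    if "acpa_titer" in df:
        df["acpa_high"] = _flag(df["acpa_titer"], lambda s: s >= 3 * acpa_cutoff)
        types["acpa_high"] = DICHOTOMOUS
    if "rf_positive" in df and "acpa_positive" in df:
        rf, ac = df["rf_positive"], df["acpa_positive"]
        both_pos = ((rf == 1) & (ac == 1)).astype(float)
        both_pos[rf.isna() | ac.isna()] = np.nan
        both_neg = ((rf == 0) & (ac == 0)).astype(float)
        both_neg[rf.isna() | ac.isna()] = np.nan
        df["rf_and_acpa_positive"] = both_pos
        df["rf_and_acpa_negative"] = both_neg
        types["rf_and_acpa_positive"] = DICHOTOMOUS
        types["rf_and_acpa_negative"] = DICHOTOMOUS
    present = [v for v in SUPPRESSOR_FLAGS if v in df]
    if present:
        flags = df[present]
        any_use = (flags == 1).any(axis=1).astype(float)
        unknown = flags.isna().any(axis=1) & ~(flags == 1).any(axis=1)
        any_use[unknown] = np.nan
        df["any_suppressor"] = any_use
        types["any_suppressor"] = DICHOTOMOUS
    return ClinicalCohort(data=df, types=types)


def read_cohort(path, types: dict[str, str], acpa_cutoff: float = 500.0) -> ClinicalCohort:
    """Read a patient table (first column patient_id) and derive rule columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    base_types = {v: k for v, k in types.items() if v in df.columns}
    cohort = ClinicalCohort(data=df, types=base_types)
    return add_derived_columns(cohort, acpa_cutoff=acpa_cutoff)
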