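"""Synthetic RA cohort generator for pipeline testing and calibration.

Emulates the statistical structure the analysis assumes, not any real
patient: clinical variables are drawn independently from marginal
distributions typical of an established-RA cohort (n = 182; mean DAS28
about 5.1, three quarters female, 84% on methotrexate, ...), and the
19-gene expression panel follows an equicorrelated common-factor model

    x_gj = mu + sigma * (sqrt(rho) * f_j + sqrt(1 - rho) * e_gj)

with f_j, e_gj iid standard normal, so that every gene pair has
correlation rho and the panel-mean IFN score has exactly the configured
mean and SD. Treatment effects enter as an additive suppression: each
suppressing agent a patient takes subtracts ``delta * score_sd`` (delta
in score-SD units) from every panel gene, making the total suppression
grow with the number of agents.

Because no clinical variable other than the treatment flags influences
expression, any non-treatment association a downstream screen finds in
this data is a false positive by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quantify import ExpressionMatrix
from .screen import (
    ClinicalCohort,
    CONTINUOUS,
    DICHOTOMOUS,
    add_derived_columns,
)

__all__ = [
    "SyntheticCohortConfig",
    "default_marginals",
    "generate_clinical",
    "generate_expression",
    "generate_cohort",
]


def default_marginals() -> dict[str, tuple]:
    """Marginal distribution specs for the default cohort.

    Forms: ("normal", mean, sd); ("truncnormal", mean, sd, lo, hi) — a
    normal truncated to [lo, hi] with the *underlying* parameters solved
    so the truncated distribution itself has the stated mean and sd;
    ("count", mean, sd, lo, hi) — same, rounded to integers;
    ("lognormal", mean, sd) — log-normal matched to the stated moments
    (titers: sd >> mean makes normal draws mostly negative);
    ("bernoulli", prevalence).

    Disease duration and CRP also use moment-matched log-normals: their
    stated sd exceeds the mean, and a normal left-truncated at zero cannot
    have coefficient of variation >= 1, so no truncated normal reproduces
    those moments. Right-skew is the realistic shape for both anyway.
    """
    return {
        "age": ("normal", 54.2, 11.8),
        "female": ("bernoulli", 0.75),
        "disease_duration": ("lognormal", 9.7, 10.3),
        "das28": ("truncnormal", 5.1, 1.2, 0.0, 9.4),
        "tjc28": ("count", 8.0, 6.0, 0.0, 28.0),
        "sjc28": ("count", 6.0, 4.0, 0.0, 28.0),
        "vas": ("truncnormal", 50.0, 22.0, 0.0, 100.0),
        "erosions": ("bernoulli", 0.72),
        "nodules": ("bernoulli", 0.24),
        "esr": ("truncnormal", 24.5, 18.0, 0.0, np.inf),
        "crp": ("lognormal", 17.8, 22.1),
        "rf_titer": ("lognormal", 124.7, 279.0),
        "rf_positive": ("bernoulli", 0.59),
        "acpa_titer": ("lognormal", 1563.0, 2680.0),
        "acpa_positive": ("bernoulli", 0.75),
        "mtx_use": ("bernoulli", 0.84),
        "mtx_dose": ("truncnormal", 21.0, 6.3, 0.0, np.inf),
        "prednisone_use": ("bernoulli", 0.29),
        "prednisone_dose": ("truncnormal", 7.2, 3.5, 0.0, np.inf),
        "hcq_use": ("bernoulli", 0.19),
        "ssz_use": ("bernoulli", 0.15),
    }


#: Dose columns are drawn for users of the matching flag only (missing
#: otherwise), mirroring how dosage is recorded in clinic tables.
DOSE_OF_FLAG = {"mtx_use": "mtx_dose", "prednisone_use": "prednisone_dose"}

TREATMENT_FLAGS = ("mtx_use", "prednisone_use", "hcq_use", "ssz_use")


@dataclass
class SyntheticCohortConfig:
    """All distributional parameters of the generator.

    ``suppression_delta`` maps a treatment flag to its per-agent score
    shift in units of ``score_sd`` (additive across agents; all zero for a
    null cohort). ``missingness`` maps a missingness group to its
    probability; the "rf" and "acpa" groups blank titer and positivity
    together, as assay availability does.
    """

    n_patients: int = 182
    n_genes: int = 19
    inter_gene_correlation: float = 0.8
    score_mean: float = 0.26
    score_sd: float = 1.01
    marginals: dict[str, tuple] = field(default_factory=default_marginals)
    suppression_delta: dict[str, float] = field(
        default_factory=lambda: {"prednisone_use": 0.0, "hcq_use": 0.0, "ssz_use": 0.0}
    )
    missingness: dict[str, float] = field(
        default_factory=lambda: {"nodules": 6 / 182, "rf": 21 / 182, "acpa": 7 / 182}
    )
    acpa_cutoff: float = 500.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.inter_gene_correlation < 1):
            raise ValueError("inter_gene_correlation must lie in [0, 1)")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("n_patients and n_genes must be positive")
        for name, spec in self.marginals.items():
            if spec[0] == "bernoulli" and not (0 <= spec[1] <= 1):
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
            if spec[0] in ("normal", "truncnormal", "count", "lognormal") and spec[2] <= 0:
                raise ValueError(f"sd of {name!r} must be positive")
        for name, prob in self.missingness.items():
            if not (0 <= prob <= 1):
                raise ValueError(f"missingness of {name!r} outside [0, 1]")

    def truth(self) -> dict[str, Any]:
        """Ground-truth record sufficient to recompute every injected effect."""
        sigma = self.score_sd / np.sqrt(
            self.inter_gene_correlation
            + (1 - self.inter_gene_correlation) / self.n_genes
        )
        return {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "n_genes": self.n_genes,
            "inter_gene_correlation": self.inter_gene_correlation,
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "gene_mu": self.score_mean,
            "gene_sigma": float(sigma),
            "suppression_delta": dict(self.suppression_delta),
            "suppression_per_agent_log2": {
                k: float(v * self.score_sd) for k, v in self.suppression_delta.items()
            },
        }


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments."""

    def moments(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, [mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for sane inputs
        raise RuntimeError(f"truncated-normal moment match failed for mean={mean}, sd={sd}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_marginal(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    if kind in ("truncnormal", "count"):
        _, mean, sd, lo, hi = spec
        mu, sigma = _truncnorm_params(mean, sd, lo, hi)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)
        return np.round(draws) if kind == "count" else draws
    if kind == "lognormal":
        _, mean, sd = spec
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        return rng.lognormal(mu, np.sqrt(s2), size=n)
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    raise ValueError(f"unknown marginal kind {kind!r}")


#: Blanking groups: one missingness draw blanks all columns in the group.
_MISSING_GROUPS = {
    "nodules": ("nodules",),
    "rf": ("rf_titer", "rf_positive"),
    "acpa": ("acpa_titer", "acpa_positive"),
}


def generate_clinical(
    config: SyntheticCohortConfig, rng: np.random.Generator | None = None
) -> ClinicalCohort:
    """Draw a clinical table from the configured marginals.

    Treatment flags are drawn first (expression generation conditions on
    them), then every other variable in the fixed order of the marginals
    dict; doses only for users of the matching drug; missingness masks
    last; derived columns recomputed by rule.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    df = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    types: dict[str, str] = {}

    for flag in TREATMENT_FLAGS:
        if flag in config.marginals:
            df[flag] = _draw_marginal(config.marginals[flag], n, rng)
            types[flag] = DICHOTOMOUS

    dose_cols = set(DOSE_OF_FLAG.values())
    for name, spec in config.marginals.items():
        if name in df.columns or name in dose_cols:
            continue
        df[name] = _draw_marginal(spec, n, rng)
        types[name] = DICHOTOMOUS if spec[0] == "bernoulli" else CONTINUOUS

    for flag, dose in DOSE_OF_FLAG.items():
        if dose in config.marginals and flag in df.columns:
            values = _draw_marginal(config.marginals[dose], n, rng)
            values[df[flag].to_numpy() != 1] = np.nan
            df[dose] = values
            types[dose] = CONTINUOUS

    for group, prob in config.missingness.items():
        cols = _MISSING_GROUPS.get(group, (group,))
        mask = rng.random(n) < prob
        for col in cols:
            if col in df.columns:
                df.loc[mask, col] = np.nan

    cohort = ClinicalCohort(data=df, types=types)
    return add_derived_columns(cohort, acpa_cutoff=config.acpa_cutoff)


def generate_expression(
    config: SyntheticCohortConfig,
    treatment_flags: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Draw the equicorrelated panel, then apply treatment suppression.

    ``treatment_flags`` holds one 0/1 column per suppressing agent named
    in ``config.suppression_delta`` (missing flags count as untreated);
    None means an untreated cohort.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, g = config.n_patients, config.n_genes
    rho = config.inter_gene_correlation
    sigma = config.score_sd / np.sqrt(rho + (1 - rho) / g)
    mu = config.score_mean

    factor = rng.normal(size=(n, 1))
    noise = rng.normal(size=(n, g))
    x = mu + sigma * (np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise)

    if treatment_flags is not None:
        ids = treatment_flags.index
        if len(ids) != n:
            raise ValueError("treatment_flags must have one row per patient")
        total = np.zeros(n)
        for agent, delta in config.suppression_delta.items():
            if agent in treatment_flags.columns:
                flags = treatment_flags[agent].fillna(0).to_numpy(dtype=float)
                total += delta * config.score_sd * flags
        x -= total[:, None]
    else:
        ids = pd.Index([f"P{i:04d}" for i in range(1, n + 1)], name="patient_id")

    genes = [f"IRG{i:02d}" for i in range(1, g + 1)]
    values = pd.DataFrame(x, index=ids, columns=genes)
    return ExpressionMatrix(values=values, reference_gene=None)


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[ExpressionMatrix, ClinicalCohort, dict[str, Any]]:
    """Clinical table + conditioned expression + ground-truth record.

    A single RNG stream seeded from ``config.seed`` drives both draws
    (clinical first), so identical configs give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    cohort = generate_clinical(config, rng=rng)
    flag_cols = [a for a in config.suppression_delta if a in cohort.data.columns]
    expr = generate_expression(config, cohort.data[flag_cols], rng=rng)
    return expr, cohort, config.truth()


def write_truth(truth: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
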