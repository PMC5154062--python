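"""Assemble screen and stability outputs into one report; pipeline driver.

The report mirrors the shape of a two-sided screen table: per variable the
complete-group p and BH-adjusted q on the left, the split-half concordance
counts and per-set median p values on the right. Numbers are stored at
full precision in a JSON sidecar; rounding (3 significant figures) happens
only when rendering the human-readable TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quantify import (
    ExpressionMatrix,
    ct_table_to_expression,
    read_ct_table,
    read_dilution_series,
    read_expression,
)
from .score import compute_ifn_score, correlation_qc
from .screen import (
    AssociationResult,
    ClinicalCohort,
    CONTINUOUS,
    DICHOTOMOUS,
    DEFAULT_VARIABLE_SPEC,
    SUPPRESSOR_FLAGS,
    read_cohort,
    screen_cohort,
    subgroup_filter,
)
from .stability import StabilityResult, stability_screen, summarize_stability

logger = logging.getLogger(__name__)

__all__ = ["ScreenReport", "build_report", "run_pipeline"]

MISSING_TOKEN = "."


@dataclass
class ScreenReport:
    """Fused screen + stability table with a provenance block."""

    rows: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        """Render rounded to 3 significant figures; full precision stays in JSON."""
        out = self.rows.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(
                    lambda v: MISSING_TOKEN if not np.isfinite(v) else f"{v:.3g}"
                )
        out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "rows": json.loads(self.rows.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_report(
    assoc: list[AssociationResult],
    stab: list[StabilityResult],
    provenance: dict[str, Any] | None = None,
) -> ScreenReport:
    """Left-join screen rows with stability rows on the shared variable spec.

    Pure formatting: every cell equals its source field, nothing is
    recomputed. The two inputs must list the same variables in the same
    order.
    """
    assoc_vars = [r.variable for r in assoc]
    stab_vars = [r.variable for r in stab]
    if assoc_vars != stab_vars:
        offending = next(
            (a for a, s in zip(assoc_vars, stab_vars) if a != s), None
        )
        if offending is None:  # one list is a prefix of the other
            longer = assoc_vars if len(assoc_vars) > len(stab_vars) else stab_vars
            offending = longer[min(len(assoc_vars), len(stab_vars))]
        raise ValueError(
            f"screen and stability variable specs differ (first offender: {offending!r})"
        )
    left = pd.DataFrame(
        [
            {
                "variable": r.variable,
                "test": r.test,
                "n": r.n_used,
                "statistic": r.statistic,
                "p": r.p,
                "q": r.q,
            }
            for r in assoc
        ],
        columns=["variable", "test", "n", "statistic", "p", "q"],
    )
    right = summarize_stability(stab).drop(columns=["variable"])
    rows = pd.concat([left, right.set_index(left.index)], axis=1)
    prov = dict(provenance or {})
    prov.setdefault("software_version", __version__)
    return ScreenReport(rows=rows, provenance=prov)


# ---------------------------------------------------------------------------
# End-to-end driver


def _load_expression(config: dict) -> ExpressionMatrix:
    if "expression" in config:
        return read_expression(config["expression"], config.get("reference_gene"))
    if "ct_table" in config and "curves" in config:
        ct = read_ct_table(config["ct_table"])
        curves = read_dilution_series(config["curves"])
        return ct_table_to_expression(ct, curves, config["reference_gene"])
    raise KeyError("config must provide 'expression' or both 'ct_table' and 'curves'")


def _variable_types(spec: list[tuple[str, str]], extra: dict | None) -> dict[str, str]:
    types = {
        var: (CONTINUOUS if test == "spearman" else DICHOTOMOUS) for var, test in spec
    }
    # parents of derived columns that the spec itself may not mention
    types.setdefault("esr", CONTINUOUS)
    types.setdefault("crp", CONTINUOUS)
    types.setdefault("acpa_titer", CONTINUOUS)
    types.setdefault("rf_positive", DICHOTOMOUS)
    types.setdefault("acpa_positive", DICHOTOMOUS)
    for flag in SUPPRESSOR_FLAGS:
        types.setdefault(flag, DICHOTOMOUS)
    if extra:
        types.update(extra)
    return types


def run_pipeline(config: dict, out_prefix: str | None = None) -> dict[str, Any]:
    """Execute quantify (if needed) -> score -> screen -> stability -> report.

    ``config`` is the parsed YAML mapping (see the repository README for
    the schema). Returns the full report plus intermediate artifacts; when
    ``out_prefix`` is given, writes ``<prefix>report.tsv``,
    ``<prefix>report.json`` (and the subgroup variants when enabled).
    """
    spec = [tuple(entry) for entry in config.get("spec", DEFAULT_VARIABLE_SPEC)]
    stab_cfg = config.get("stability", {})
    n_iter = int(stab_cfg.get("n_iter", 1000))
    alpha = float(stab_cfg.get("alpha", 0.05))
    seed = stab_cfg.get("seed")
    bh_cfg = config.get("bh", {})
    bh_mode = bh_cfg.get("mode", "monotone")
    bh_m = bh_cfg.get("m")

    expr = _load_expression(config)
    panel = config.get("panel")
    scores = compute_ifn_score(expr, panel, config.get("min_fraction", 1.0))
    qc = correlation_qc(expr) if config.get("run_qc", True) else None

    types = _variable_types(spec, config.get("variable_types"))
    cohort = read_cohort(
        config["cohort"], types, acpa_cutoff=config.get("acpa_cutoff", 500.0)
    )

    provenance = {
        "seed": seed,
        "n_iter": n_iter,
        "alpha": alpha,
        "bh_mode": bh_mode,
        "bh_m": bh_m if bh_m is not None else len(spec),
        "n_patients": len(cohort),
        "software_version": __version__,
    }

    def _one_pass(cohort_pass: ClinicalCohort) -> ScreenReport:
        assoc = screen_cohort(scores, cohort_pass, spec, bh_mode=bh_mode, bh_m=bh_m)
        stab = stability_screen(
            scores, cohort_pass, spec, n_iter=n_iter, alpha=alpha, seed=seed
        )
        return build_report(assoc, stab, provenance)

    try:
        report = _one_pass(cohort)
    except Exception as exc:
        raise RuntimeError(f"screen/stability stage failed: {exc}") from exc

    artifacts: dict[str, Any] = {
        "scores": scores,
        "qc": qc,
        "cohort": cohort,
        "report": report,
    }

    sub_cfg = config.get("subgroup", {})
    if sub_cfg.get("enabled", False):
        exclude = tuple(sub_cfg.get("exclude_if_any", SUPPRESSOR_FLAGS))
        sub = subgroup_filter(cohort, exclude)
        logger.info("subgroup pass retains %d of %d patients", len(sub), len(cohort))
        # treatment variables are constant zero in the subgroup; screen the rest
        sub_spec = [(v, t) for v, t in spec if v not in set(exclude) | {"any_suppressor"}]
        sub_report = build_report(
            screen_cohort(scores, sub, sub_spec, bh_mode=bh_mode, bh_m=len(sub_spec)),
            stability_screen(scores, sub, sub_spec, n_iter=n_iter, alpha=alpha, seed=seed),
            {**provenance, "subgroup": list(exclude), "n_patients": len(sub)},
        )
        artifacts["subgroup_report"] = sub_report

    if out_prefix is not None:
        report.to_tsv(f"{out_prefix}report.tsv")
        report.to_json(f"{out_prefix}report.json")
        if "subgroup_report" in artifacts:
            artifacts["subgroup_report"].to_tsv(f"{out_prefix}subgroup_report.tsv")
            artifacts["subgroup_report"].to_json(f"{out_prefix}subgroup_report.json")
    return artifacts


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
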