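"""qPCR standard-curve relative quantification.

Converts raw Ct values into reference-normalized log2 relative expression.
A standard curve is an ordinary least-squares line Ct = intercept +
slope * log10(quantity) fitted to a dilution series of known template
quantities; an unknown well's relative quantity is read off the inverted
line, divided by the same sample's reference-gene quantity (GAPDH in the
original assay design) and log2-transformed.

Pre-computed log2 relative expression can bypass this module entirely via
:func:`read_expression`; downstream scoring and screening only ever see the
:class:`ExpressionMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "CalibrationError",
    "ExpressionMatrix",
    "fit_standard_curve",
    "ct_to_quantity",
    "quantity_to_ct",
    "normalize_and_log",
    "ct_table_to_expression",
    "read_ct_table",
    "read_dilution_series",
    "read_expression",
    "write_expression",
]


class CalibrationError(ValueError):
    """A standard curve could not be fitted or is unusable."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(quantity) calibration for one gene.

    Parameters
    ----------
    gene_id : str
        Assay/gene identifier.
    intercept : float
        Ct at quantity 1 (cycles).
    slope : float
        Ct change per log10 unit of template quantity; negative for a
        working assay (more template amplifies earlier).

    The implied amplification efficiency per cycle is ``10**(-1/slope)``;
    2.0 is perfect doubling. Values outside (1.0, 2.5] trigger a warning
    and the curve is flagged unusable when the slope is non-negative.
    """

    gene_id: str
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            warnings.warn(
                f"standard curve for {self.gene_id!r} has non-negative slope "
                f"{self.slope:.4g}; curve is unusable",
                stacklevel=2,
            )
        else:
            eff = self.efficiency
            if not (1.0 < eff <= 2.5):
                warnings.warn(
                    f"standard curve for {self.gene_id!r} implies amplification "
                    f"efficiency {eff:.3f} outside (1.0, 2.5]",
                    stacklevel=2,
                )

    @property
    def efficiency(self) -> float:
        """Implied per-cycle amplification factor, ``10**(-1/slope)``."""
        return float(10.0 ** (-1.0 / self.slope))

    @property
    def usable(self) -> bool:
        return self.slope < 0


@dataclass
class ExpressionMatrix:
    """Samples x genes table of log2 relative expression.

    ``values`` holds one row per sample and one column per panel gene; the
    reference gene used for normalization is recorded but excluded from the
    columns. Missing measurements are NaN; infinities are never stored.
    """

    values: pd.DataFrame
    reference_gene: str | None = None
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.panel:
            self.panel = list(self.values.columns)
        if self.reference_gene is not None and self.reference_gene in self.values.columns:
            raise ValueError(
                f"reference gene {self.reference_gene!r} must not appear among "
                "the normalized panel columns"
            )
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values.to_numpy(dtype=float)).any():
                raise ValueError("expression matrix contains non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def fit_standard_curve(
    dilution_points: "list[tuple[float, float]] | np.ndarray",
    gene_id: str = "",
) -> StandardCurve:
    """Fit Ct = intercept + slope * log10(quantity) by ordinary least squares.

    Parameters
    ----------
    dilution_points : sequence of (known_quantity, ct)
        At least two points with distinct, strictly positive quantities.
    gene_id : str
        Identifier stored on the returned curve.

    Raises
    ------
    CalibrationError
        Fewer than two distinct quantities, or non-positive quantities.
    """
    pts = np.asarray(dilution_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise CalibrationError("need at least two (quantity, ct) dilution points")
    q, ct = pts[:, 0], pts[:, 1]
    if np.any(~np.isfinite(q)) or np.any(q <= 0):
        raise CalibrationError("dilution quantities must be finite and > 0")
    if np.unique(q).size < 2:
        raise CalibrationError("dilution series needs >= 2 distinct quantities")
    slope, intercept = np.polyfit(np.log10(q), ct, 1)
    return StandardCurve(gene_id=gene_id, intercept=float(intercept), slope=float(slope))


def ct_to_quantity(ct, curve: StandardCurve):
    """Invert the standard curve: quantity = 10**((ct - intercept)/slope).

    Accepts scalars or arrays; missing Ct (NaN) propagates as missing
    quantity rather than zero.
    """
    if not curve.usable:
        raise CalibrationError(
            f"standard curve for {curve.gene_id!r} is unusable (slope >= 0)"
        )
    ct = np.asarray(ct, dtype=float)
    out = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return float(out) if out.ndim == 0 else out


def quantity_to_ct(quantity, curve: StandardCurve):
    """Forward map of the standard curve (used for round-trip checks)."""
    if not curve.usable:
        raise CalibrationError(
            f"standard curve for {curve.gene_id!r} is unusable (slope >= 0)"
        )
    quantity = np.asarray(quantity, dtype=float)
    out = curve.intercept + curve.slope * np.log10(quantity)
    return float(out) if out.ndim == 0 else out


def normalize_and_log(
    quantities: pd.DataFrame, reference_gene: str
) -> ExpressionMatrix:
    """Divide each gene's quantity by the sample's reference quantity, log2.

    Samples with a missing reference quantity are dropped (and logged);
    zero or negative quantities become missing with a warning so the
    matrix never holds infinities.
    """
    if reference_gene not in quantities.columns:
        raise KeyError(f"reference gene {reference_gene!r} not in quantity table")
    ref = quantities[reference_gene].astype(float)
    bad_ref = ~np.isfinite(ref) | (ref <= 0)
    if bad_ref.any():
        dropped = list(quantities.index[bad_ref])
        logger.warning(
            "dropping %d sample(s) lacking a usable reference quantity: %s",
            len(dropped), dropped,
        )
    kept = quantities.loc[~bad_ref].astype(float)
    panel_cols = [c for c in kept.columns if c != reference_gene]
    grid = kept[panel_cols]
    nonpos = (grid <= 0).to_numpy()
    if nonpos.any():
        warnings.warn(
            f"{int(nonpos.sum())} non-positive quantity value(s) set to missing",
            stacklevel=2,
        )
        grid = grid.mask(grid <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(grid.div(kept[reference_gene], axis=0))
    return ExpressionMatrix(values=values, reference_gene=reference_gene)


def ct_table_to_expression(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    reference_gene: str,
) -> ExpressionMatrix:
    """Full standard-curve pipeline: Ct grid -> quantities -> normalized log2."""
    missing = [g for g in ct_table.columns if g not in curves]
    if missing:
        raise CalibrationError(f"no standard curve provided for gene(s): {missing}")
    quantities = pd.DataFrame(
        {g: ct_to_quantity(ct_table[g].to_numpy(dtype=float), curves[g]) for g in ct_table.columns},
        index=ct_table.index,
    )
    return normalize_and_log(quantities, reference_gene)


# ---------------------------------------------------------------------------
# I/O: CSV/TSV with first column sample_id, header row gene ids, NA = missing


def _read_table(path, **kwargs) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def read_ct_table(path) -> pd.DataFrame:
    """Read a samples x genes Ct grid (empty field or NA = non-amplification)."""
    df = _read_table(path, index_col=0, na_values=["NA"])
    ct = df.astype(float)
    if ((ct <= 0) & ct.notna()).any().any():
        raise ValueError("Ct values must be > 0 where present")
    return ct


def read_dilution_series(path) -> dict[str, StandardCurve]:
    """Read a long-format dilution CSV (gene_id, quantity, ct) and fit curves."""
    df = _read_table(path)
    required = {"gene_id", "quantity", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"dilution series file needs columns {sorted(required)}")
    return {
        str(g): fit_standard_curve(sub[["quantity", "ct"]].to_numpy(), gene_id=str(g))
        for g, sub in df.groupby("gene_id")
    }


def read_expression(path, reference_gene: str | None = None) -> ExpressionMatrix:
    """Read pre-computed log2 relative expression (bypass mode)."""
    df = _read_table(path, index_col=0, na_values=["NA"]).astype(float)
    if reference_gene is not None and reference_gene in df.columns:
        df = df.drop(columns=[reference_gene])
    return ExpressionMatrix(values=df, reference_gene=reference_gene)


def write_expression(expr: ExpressionMatrix, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    expr.values.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")
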