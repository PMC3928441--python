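"""Standard-curve quantification: replicate averaging, curve fitting,
amplification efficiency, Ct-to-quantity transformation, and assembly of the
relative-expression matrix.

Relative quantities are anchored to the dilution series (arbitrary units);
no absolute copy numbers are produced. Technical replicates are averaged on
the Ct scale before transformation, per standard qPCR practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Per-gene linear calibration ``Ct = intercept + slope * log10(q)``.

    ``efficiency_percent`` is the Pfaffl efficiency
    ``(10**(-1/slope) - 1) * 100`` (NaN when the slope is non-negative and
    the curve is therefore unusable for efficiency estimation).
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    n_points: int
    warnings: tuple[str, ...] = ()


@dataclass
class ExpressionMatrix:
    """Strictly positive relative quantities, genes x samples, with group
    labels and a record of samples dropped by the missing-data policy."""

    data: pd.DataFrame                 # genes x samples, all entries > 0
    groups: pd.Series                  # sample -> group label (may hold NaN)
    dropped_samples: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes], self.groups, list(self.dropped_samples))


def average_replicates(
    ct_table: pd.DataFrame, discordance_threshold: float = 0.5
) -> pd.DataFrame:
    """Average technical replicate Cts per (sample, gene).

    Undetermined replicates are excluded from the mean; a (sample, gene)
    cell whose replicates are all undetermined is returned with
    ``missing=True``. A ``discordant`` flag is set when the replicate range
    (max - min Ct) exceeds ``discordance_threshold`` cycles.
    """
    table = ct_table.copy()
    if "undetermined" not in table.columns:
        table["undetermined"] = table["ct"].isna()
    table.loc[table["undetermined"].astype(bool), "ct"] = np.nan
    has_group = "group" in table.columns
    keys = ["sample_id", "gene"] + (["group"] if has_group else [])

    grouped = table.groupby(keys, sort=False, dropna=False)["ct"]
    out = grouped.agg(ct="mean", _min="min", _max="max", n_replicates="count").reset_index()
    out["discordant"] = (out["_max"] - out["_min"]) > discordance_threshold
    out["missing"] = out["n_replicates"] == 0
    out.loc[out["missing"], "discordant"] = False
    out = out.drop(columns=["_min", "_max"])
    out["n_replicates"] = out["n_replicates"].astype(int)
    n_disc = int(out["discordant"].sum())
    if n_disc:
        log.warning("%d sample x gene cells have discordant replicates", n_disc)
    return out


def fit_standard_curve(
    points: pd.DataFrame | np.ndarray,
    gene: str = "",
    r2_warning_threshold: float = 0.98,
) -> StandardCurve:
    """Ordinary least-squares fit of ``Ct = intercept + slope * log10(q)``.

    ``points`` is either a DataFrame with ``log10_quantity`` and ``ct``
    columns or an (n, 2) array of (log10_quantity, ct) rows. QC warnings
    (non-negative slope, low r^2) are attached to the returned curve and
    emitted via :mod:`warnings`; the curve is returned regardless.
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_quantity"].to_numpy(dtype=float)
        y = points["ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(np.unique(x)) < 2:
        raise QuantificationError(
            f"standard curve for {gene or '?'}: need >= 2 distinct quantity levels"
        )
    res = sps.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    notes: list[str] = []
    if slope >= 0:
        notes.append(f"non-negative slope {slope:.4g}: curve unusable for efficiency")
        eff = float("nan")
    else:
        eff = efficiency_from_slope(slope)
    if r2 < r2_warning_threshold:
        notes.append(f"r^2 = {r2:.4f} below threshold {r2_warning_threshold}")
    for msg in notes:
        warnings.warn(f"standard curve {gene or '?'}: {msg}", stacklevel=2)
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        efficiency_percent=eff,
        n_points=len(x),
        warnings=tuple(notes),
    )


def fit_standard_curves(
    dilution_table: pd.DataFrame, r2_warning_threshold: float = 0.98
) -> dict[str, StandardCurve]:
    """Fit one curve per gene from a long-format dilution table."""
    return {
        gene: fit_standard_curve(sub, gene=gene, r2_warning_threshold=r2_warning_threshold)
        for gene, sub in dilution_table.groupby("gene", sort=False)
    }


def efficiency_from_slope(slope: float) -> float:
    """Pfaffl amplification efficiency in percent from a standard-curve
    slope: ``(10**(-1/slope) - 1) * 100``. A slope of -3.32 cycles per
    decade corresponds to perfect doubling (100 %)."""
    if slope >= 0:
        raise QuantificationError(f"slope must be negative, got {slope}")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


def slope_from_efficiency(efficiency_percent: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    if efficiency_percent <= 0:
        raise QuantificationError("efficiency must be > 0")
    return float(-1.0 / np.log10(1.0 + efficiency_percent / 100.0))


def ct_to_quantity(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Invert the standard curve: ``q = 10**((ct - intercept) / slope)``.

    Strictly positive and monotone decreasing in Ct. Extrapolation beyond
    the dilution range is permitted.
    """
    if not curve.slope < 0:
        raise QuantificationError(f"curve for {curve.gene!r} has invalid slope")
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def build_expression_matrix(
    averaged: pd.DataFrame,
    curves: dict[str, StandardCurve],
    missing_policy: str = "drop_sample",
    min_group_size: int = 3,
) -> ExpressionMatrix:
    """Transform averaged Cts into a complete positive expression matrix.

    Samples with any missing cell are dropped (complete-case policy; geNorm
    and NormFinder require complete matrices). Raises when fewer than
    ``min_group_size`` samples remain in any labelled group.
    """
    if missing_policy != "drop_sample":
        raise QuantificationError(f"unknown missing policy {missing_policy!r}")
    genes = list(dict.fromkeys(averaged["gene"]))
    absent = [g for g in genes if g not in curves]
    if absent:
        raise QuantificationError(f"no standard curve for genes: {absent}")

    tab = averaged.copy()
    tab["quantity"] = [
        float(ct_to_quantity(ct, curves[g])) if np.isfinite(ct) else np.nan
        for ct, g in zip(tab["ct"], tab["gene"])
    ]
    wide = tab.pivot(index="gene", columns="sample_id", values="quantity").loc[genes]
    incomplete = wide.columns[wide.isna().any(axis=0)].tolist()
    if incomplete:
        log.warning(
            "dropping %d incomplete sample(s): %s", len(incomplete), incomplete
        )
    kept = wide.drop(columns=incomplete)

    if "group" in tab.columns:
        groups = (
            tab.drop_duplicates("sample_id").set_index("sample_id")["group"]
        ).reindex(kept.columns)
        counts = groups.dropna().value_counts()
        if len(counts) and (counts < min_group_size).any():
            small = counts[counts < min_group_size].to_dict()
            raise QuantificationError(
                f"insufficient data after dropping samples: group sizes {small} "
                f"below minimum {min_group_size}"
            )
    else:
        groups = pd.Series(index=kept.columns, dtype=object)
    return ExpressionMatrix(data=kept, groups=groups, dropped_samples=incomplete)
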