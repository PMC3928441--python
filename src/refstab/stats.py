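"""Downstream statistics: normalization of genes of interest, fold changes,
nonparametric group comparison (Mann-Whitney), echocardiographic index
derivation, and rank correlation (Spearman) between expression and echo
indices.

No multiple-testing correction is applied by default (a handful of genes of
interest, tested at alpha = 0.05); a Holm adjustment is available as an
option on :func:`compare_strategies`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GROUP_HYPERCHOL, GROUP_NORMAL
from .genorm import normalization_factor
from .quantify import ExpressionMatrix


class StatsError(ValueError):
    pass


@dataclass
class ComparisonResult:
    gene: str
    strategy: str
    reference_genes: tuple[str, ...]
    fold_change: float                  # hyperchol / normal ratio of group means
    mean_normal: float
    sem_normal: float
    mean_hyperchol: float
    sem_hyperchol: float
    u_statistic: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "strategy": self.strategy,
            "reference_genes": ",".join(self.reference_genes),
            "fold_change": self.fold_change,
            "mean_normal": self.mean_normal,
            "sem_normal": self.sem_normal,
            "mean_hyperchol": self.mean_hyperchol,
            "sem_hyperchol": self.sem_hyperchol,
            "U": self.u_statistic,
            "p": self.p_value,
        }


@dataclass
class CorrelationResult:
    gene: str
    echo_index: str
    rho: float
    p_value: float
    n: int


def normalize_goi(
    matrix: ExpressionMatrix | pd.DataFrame, nf: pd.Series
) -> pd.DataFrame:
    """Divide each sample's quantities by its normalization factor."""
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)
    nf = pd.Series(nf)
    if not set(data.columns) <= set(nf.index):
        missing = sorted(set(data.columns) - set(nf.index))
        raise StatsError(f"normalization factor missing for samples: {missing}")
    nf = nf.reindex(data.columns)
    if (nf <= 0).any():
        raise StatsError("normalization factors must be strictly positive")
    return data.div(nf, axis=1)


def fold_change(
    normalized: pd.Series | np.ndarray,
    groups: pd.Series,
    numerator: str = GROUP_HYPERCHOL,
    denominator: str = GROUP_NORMAL,
    geometric: bool = False,
) -> dict:
    """Group fold change with per-group mean +/- SEM.

    The default is the ratio of arithmetic group means (means +/- SEM being
    the reporting convention); ``geometric=True`` uses geometric means.
    """
    vals = pd.Series(np.asarray(normalized, dtype=float), index=groups.index)
    x_den = vals[groups == denominator]
    x_num = vals[groups == numerator]
    if len(x_den) == 0 or len(x_num) == 0:
        raise StatsError("both groups must be non-empty")
    if geometric:
        fc = float(np.exp(np.log(x_num).mean() - np.log(x_den).mean()))
    else:
        fc = float(x_num.mean() / x_den.mean())
    return {
        "fold_change": fc,
        "mean_normal": float(x_den.mean()),
        "sem_normal": float(x_den.std(ddof=1) / math.sqrt(len(x_den))) if len(x_den) > 1 else float("nan"),
        "mean_hyperchol": float(x_num.mean()),
        "sem_hyperchol": float(x_num.std(ddof=1) / math.sqrt(len(x_num))) if len(x_num) > 1 else float("nan"),
    }


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U is the statistic of the first sample
    (``U + U' = n1 * n2``). ``mode``:

    - ``"exact"``: exact null distribution (requires no ties);
    - ``"approx"``: normal approximation with tie and continuity correction;
    - ``"auto"``: exact when there are no ties and n1 + n2 <= 20, else the
      approximation.

    Identical pooled values in both groups give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; p = 1 by convention", stacklevel=2)
        return float(len(x) * len(y) / 2.0), 1.0
    if mode == "auto":
        method = "exact" if (not has_ties and len(pooled) <= 20) else "asymptotic"
    elif mode == "exact":
        if has_ties:
            raise StatsError("exact mode requires tie-free data; use approx or auto")
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise StatsError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p-value for Spearman rho on midranks,
    by vectorised enumeration of all n! orderings of one variable."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]                       # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho_all = (ry_c @ rx_c) / denom
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    return float(np.mean(np.abs(rho_all) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with exact small-sample p-value.

    rho is the Pearson correlation of midranks. For n <= ``exact_max_n``
    the two-sided p-value is exact (full permutation enumeration, correct
    under ties); larger n uses the t approximation. Zero variance in either
    vector is undefined: returns ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(sps.spearmanr(x, y).statistic)
    n = len(x)
    if n <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _spearman_exact_p(rx, ry)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# Echocardiographic indices

#: input columns understood by :func:`derive_echo_indices` (units noted)
ECHO_COLUMNS = {
    "e_velocity": "cm/s",
    "a_velocity": "cm/s",
    "a_duration": "ms",
    "deceleration_time": "ms",
    "deceleration_rate": "m/s^2 (measured; optional)",
    "em_lateral": "cm/s",
    "em_septal": "cm/s",
    "am_lateral": "cm/s",
    "am_septal": "cm/s",
    "s_velocity": "cm/s",
    "d_velocity": "cm/s",
    "ar_duration_left": "ms",
    "ar_duration_right": "ms",
}


def _ratio(df: pd.DataFrame, num: str, den: str) -> pd.Series:
    if num not in df.columns or den not in df.columns:
        return pd.Series(np.nan, index=df.index)
    d = df[den].where(df[den] != 0)
    return df[num] / d


def derive_echo_indices(measurements: pd.DataFrame) -> pd.DataFrame:
    """Derive diastolic-function indices from raw echo measurements.

    Computed per row: E/A, S/D, E/Em (lateral, septal), Em/Am (lateral,
    septal), A-Ar durations (ms, mitral A duration minus pulmonary venous
    Ar duration, left and right), and the E-wave deceleration rate in
    m/s^2. A measured ``deceleration_rate`` column takes precedence; when
    absent it is approximated as (E in m/s) / (deceleration time in s).
    Missing operands yield NaN (absent), never zero.
    """
    df = measurements
    out = pd.DataFrame(index=df.index)
    out["e_a_ratio"] = _ratio(df, "e_velocity", "a_velocity")
    out["s_d_ratio"] = _ratio(df, "s_velocity", "d_velocity")
    out["e_em_lateral"] = _ratio(df, "e_velocity", "em_lateral")
    out["e_em_septal"] = _ratio(df, "e_velocity", "em_septal")
    out["em_am_lateral"] = _ratio(df, "em_lateral", "am_lateral")
    out["em_am_septal"] = _ratio(df, "em_septal", "am_septal")
    for side in ("left", "right"):
        ar = f"ar_duration_{side}"
        if "a_duration" in df.columns and ar in df.columns:
            out[f"a_ar_{side}"] = df["a_duration"] - df[ar]
        else:
            out[f"a_ar_{side}"] = np.nan
    if "deceleration_rate" in df.columns:
        rate = df["deceleration_rate"].copy()
    else:
        rate = pd.Series(np.nan, index=df.index)
    if "e_velocity" in df.columns and "deceleration_time" in df.columns:
        # cm/s -> m/s and ms -> s: (E/100) / (DT/1000) = 10 * E / DT
        approx = 10.0 * df["e_velocity"] / df["deceleration_time"].where(
            df["deceleration_time"] != 0
        )
        rate = rate.fillna(approx)
    out["deceleration_rate"] = rate
    return out


def correlate_expression_with_echo(
    normalized: pd.DataFrame, echo: pd.DataFrame, genes: list[str] | None = None
) -> list[CorrelationResult]:
    """Spearman correlation of each gene's normalized expression with each
    echo index, over the samples present in both tables."""
    genes = list(normalized.index) if genes is None else genes
    common = [s for s in normalized.columns if s in echo.index]
    results = []
    for gene in genes:
        expr = normalized.loc[gene, common]
        for index_name in echo.columns:
            vals = echo.loc[common, index_name]
            ok = expr.notna() & vals.notna()
            if ok.sum() < 3:
                continue
            rho, p = spearman(expr[ok], vals[ok])
            results.append(CorrelationResult(gene, index_name, rho, p, int(ok.sum())))
    return results


# ---------------------------------------------------------------------------
# Normalization-strategy comparison


def compare_strategies(
    matrix: ExpressionMatrix,
    goi: list[str],
    strategies: dict[str, list[str]],
    mode: str = "auto",
    holm: bool = False,
) -> pd.DataFrame:
    """Fold change and Mann-Whitney test per gene of interest under each
    normalization strategy (a named list of reference genes whose geometric
    mean forms the normalization factor).

    Returns a tidy DataFrame (one row per gene x strategy). Optional Holm
    adjustment adds a ``p_holm`` column (off by default). Use
    :func:`percent_difference_matrix` for the pairwise fold-change
    discrepancies between strategies.
    """
    groups = matrix.groups
    results = []
    for name, ref_genes in strategies.items():
        if len(ref_genes) == 0:
            raise StatsError(f"strategy {name!r} names no reference genes")
        missing = [g for g in ref_genes if g not in matrix.data.index]
        if missing:
            raise StatsError(f"strategy {name!r} references absent genes: {missing}")
        nf = normalization_factor(matrix, ref_genes)
        normalized = normalize_goi(matrix, nf)
        for gene in goi:
            if gene not in normalized.index:
                raise StatsError(f"gene of interest {gene!r} not in matrix")
            vals = normalized.loc[gene]
            fc = fold_change(vals, groups)
            u, p = mann_whitney(
                vals[groups == GROUP_HYPERCHOL], vals[groups == GROUP_NORMAL], mode=mode
            )
            results.append(
                ComparisonResult(
                    gene=gene,
                    strategy=name,
                    reference_genes=tuple(ref_genes),
                    fold_change=fc["fold_change"],
                    mean_normal=fc["mean_normal"],
                    sem_normal=fc["sem_normal"],
                    mean_hyperchol=fc["mean_hyperchol"],
                    sem_hyperchol=fc["sem_hyperchol"],
                    u_statistic=u,
                    p_value=p,
                ).as_dict()
            )
    table = pd.DataFrame(results)
    if holm and len(table):
        table["p_holm"] = _holm(table["p"].to_numpy())
    return table


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def percent_difference_matrix(comparisons: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Pairwise percent difference of fold changes between strategies for
    one gene: entry (a, b) = |FC_a - FC_b| / FC_b * 100."""
    sub = comparisons[comparisons["gene"] == gene].set_index("strategy")["fold_change"]
    out = pd.DataFrame(index=sub.index, columns=sub.index, dtype=float)
    for a in sub.index:
        for b in sub.index:
            out.loc[a, b] = abs(sub[a] - sub[b]) / sub[b] * 100.0
    return out
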