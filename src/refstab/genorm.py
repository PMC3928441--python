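"""geNorm reference-gene stability analysis.

The stability measure of gene j is the average pairwise variation

    M_j = mean over k != j of V_jk,
    V_jk = SD over samples of log2(a_j / a_k)   (n-1 denominator),

so a gene perfectly co-regulated with every other candidate has M = 0 and
sample-specific loading factors cancel in every ratio. Genes are ranked by
stepwise exclusion of the least stable gene; the last two cannot be
separated (with two genes M_1 = M_2 = V_12) and are reported as an
unordered best pair. The number of reference genes worth including in the
normalization factor is chosen from the pairwise variation

    V_{n/n+1} = SD over samples of log2(NF_n / NF_{n+1}),

where NF_n is the geometric mean of the n best-ranked genes; the smallest
n with V below the cutoff (0.15 by convention) suffices.

All ratios use log base 2; changing the base rescales every M and V by the
same constant and leaves rankings and the relative position of V against a
base-consistent cutoff unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

log = logging.getLogger(__name__)

HIGH_STABILITY_M = 0.5   # genes below this M are conventionally called highly stable
DEFAULT_CUTOFF = 0.15


class GenormError(ValueError):
    pass


@dataclass
class GenormResult:
    m_values: pd.Series                  # final M per gene (M at exclusion; pair M for best two)
    ranking: list[str]                   # best -> worst; first two are the unordered best pair
    best_pair: tuple[str, str]
    exclusion_order: list[str]           # worst-first removal order
    m_trajectory: list[pd.Series]        # M values at each elimination round
    v_series: pd.Series                  # index n=2..I-1, value V_{n/n+1}
    recommended_n: int
    cutoff: float
    highly_stable: pd.Series             # boolean flag: final M < 0.5

    def rank_table(self) -> pd.DataFrame:
        """Per-gene table of final M, rank (best two share rank 1) and the
        high-stability classification."""
        ranks = {}
        ranks[self.ranking[0]] = 1
        ranks[self.ranking[1]] = 1
        for pos, gene in enumerate(self.ranking[2:], start=3):
            ranks[gene] = pos
        return pd.DataFrame(
            {
                "m_value": self.m_values,
                "rank": pd.Series(ranks),
                "highly_stable": self.highly_stable,
            }
        ).loc[self.ranking]


def _as_frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if (np.asarray(data, dtype=float) <= 0).any():
        raise GenormError("expression quantities must be strictly positive")
    return pd.DataFrame(data, dtype=float)


def pairwise_variation(a_j, a_k) -> float:
    """SD (n-1 denominator) of log2(a_j / a_k) across samples."""
    a_j = np.asarray(a_j, dtype=float)
    a_k = np.asarray(a_k, dtype=float)
    if a_j.shape != a_k.shape or a_j.ndim != 1:
        raise GenormError("inputs must be 1-D and of equal length")
    if len(a_j) < 2:
        raise GenormError("need at least 2 samples")
    if (a_j <= 0).any() or (a_k <= 0).any():
        raise GenormError("quantities must be strictly positive")
    return float(np.std(np.log2(a_j / a_k), ddof=1))


def stability_m(matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """Per-gene M: average pairwise variation with every other gene."""
    data = _as_frame(matrix)
    if data.shape[0] < 2:
        raise GenormError("M is undefined for fewer than 2 genes")
    if data.shape[1] < 2:
        raise GenormError("need at least 2 samples")
    logs = np.log2(data.to_numpy())
    # V_jk = SD of (log a_j - log a_k); vectorised over all pairs
    diff = logs[:, None, :] - logs[None, :, :]
    v = diff.std(axis=2, ddof=1)
    m = v.sum(axis=1) / (data.shape[0] - 1)
    return pd.Series(m, index=data.index, name="m_value")


def rank_genes_stepwise(
    matrix: ExpressionMatrix | pd.DataFrame,
) -> tuple[list[str], list[str], list[pd.Series], pd.Series]:
    """Stepwise exclusion of the least stable gene.

    Returns (ranking best->worst, exclusion order worst-first, M trajectory
    per round, final per-gene M). Ties at removal are broken by input gene
    order: the first-listed tied gene is removed first.
    """
    data = _as_frame(matrix)
    genes = list(data.index)
    if len(genes) < 3:
        raise GenormError("stepwise ranking needs at least 3 genes")
    remaining = list(genes)
    exclusion: list[str] = []
    trajectory: list[pd.Series] = []
    final_m: dict[str, float] = {}
    while len(remaining) > 2:
        m = stability_m(data.loc[remaining])
        trajectory.append(m)
        worst_val = m.max()
        ties = m.index[np.isclose(m.to_numpy(), worst_val, rtol=0, atol=0)]
        if len(ties) > 1:
            log.info("tie at removal between %s; removing first-listed", list(ties))
        worst = ties[0]
        final_m[worst] = float(m[worst])
        exclusion.append(worst)
        remaining.remove(worst)
    m_last = stability_m(data.loc[remaining])
    trajectory.append(m_last)
    for g in remaining:
        final_m[g] = float(m_last[g])      # equal by construction: both = V_12
    ranking = list(remaining) + exclusion[::-1]
    return ranking, exclusion, trajectory, pd.Series(final_m).loc[genes]


def normalization_factor(
    matrix: ExpressionMatrix | pd.DataFrame, gene_subset: list[str]
) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the subset genes."""
    if len(gene_subset) == 0:
        raise GenormError("gene subset must be non-empty")
    data = _as_frame(matrix)
    missing = [g for g in gene_subset if g not in data.index]
    if missing:
        raise GenormError(f"genes not in matrix: {missing}")
    sub = np.log(data.loc[pd.Index(gene_subset)].to_numpy())
    nf = np.exp(sub.mean(axis=0))
    return pd.Series(nf, index=data.columns, name="nf")


def optimal_gene_count(
    matrix: ExpressionMatrix | pd.DataFrame,
    ranking: list[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[pd.Series, int]:
    """Pairwise variation V_{n/n+1} between NF_n and NF_{n+1} over the full
    ranking, and the smallest n with V below the cutoff (all genes, with a
    warning, if none qualifies)."""
    data = _as_frame(matrix)
    n_genes = len(ranking)
    if n_genes < 3:
        raise GenormError("V series needs at least 3 ranked genes")
    v_vals = {}
    for n in range(2, n_genes):
        nf_n = normalization_factor(data, ranking[:n])
        nf_n1 = normalization_factor(data, ranking[: n + 1])
        v_vals[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    v_series = pd.Series(v_vals, name="v_n_n+1")
    below = [n for n, v in v_vals.items() if v < cutoff]
    if below:
        recommended = min(below)
    else:
        recommended = n_genes
        warnings.warn(
            f"no V_n/n+1 below cutoff {cutoff}; recommending all {n_genes} genes",
            stacklevel=2,
        )
    return v_series, recommended


def genorm(
    matrix: ExpressionMatrix | pd.DataFrame, cutoff: float = DEFAULT_CUTOFF
) -> GenormResult:
    """Full geNorm analysis: stepwise ranking, V series and recommendation."""
    ranking, exclusion, trajectory, final_m = rank_genes_stepwise(matrix)
    v_series, recommended = optimal_gene_count(matrix, ranking, cutoff=cutoff)
    return GenormResult(
        m_values=final_m,
        ranking=ranking,
        best_pair=(ranking[0], ranking[1]),
        exclusion_order=exclusion,
        m_trajectory=trajectory,
        v_series=v_series,
        recommended_n=recommended,
        cutoff=cutoff,
        highly_stable=final_m < HIGH_STABILITY_M,
    )
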