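"""NormFinder model-based reference-gene stability analysis.

Log2 expression of gene i in sample j of group g is modelled as

    y_igj = alpha_ig + beta_gj + eps_igj,   eps ~ N(0, sigma2_ig),

where beta_gj is a sample effect common to all genes (loading) and the
gene-by-group means alpha_ig decompose into a gene level plus a systematic
intergroup deviation d_ig. A candidate reference gene is good when both its
intragroup variance sigma2_ig and its intergroup deviation are small.

Estimation (groups weighted equally throughout):

1. Two-way centering within each group gives residuals
   r_igj = y_igj - ybar_ig - ybar_gj + ybar_g, and
   u_ig = sum_j r^2 / (n_g - 1).
2. Bias correction (exact for the model above):
   sigma2_ig = max(0, I/(I-2) * (u_ig - T_g / (I (I-1)))),  T_g = sum_i u_ig.
3. Intergroup deviations d_ig = z_ig - mean_g z_ig with z_ig = ybar_ig -
   ybar_g; they sum to zero across groups for every gene (so with two
   groups d_i1 = -d_i2 exactly) and across genes within every group.
4. The deviations are shrunk towards zero in proportion to their sampling
   noise: dtilde_ig = d_ig * gamma2 / (gamma2 + sigma2_ig / n_g), with the
   between-gene dispersion gamma2 estimated by method of moments,
   gamma2 = max(0, sum d^2 / ((I-1) G) - mean(sigma2_ig / n_g)).

The per-gene stability value combines both variance sources,

    rho_i = (1/G) sum_g ( |dtilde_ig| + sqrt(sigma2_ig / n_g) ),

and the best two-gene combination minimises the same quantity for the pair
average, which rewards genes whose intergroup deviations are similar in
size but opposite in direction:

    dtilde_pair,g = (dtilde_ig + dtilde_kg) / 2,
    sigma2_pair,g = (sigma2_ig + sigma2_kg) / 4.

The search over pairs is exhaustive. Log base 2 is used for consistency
with the geNorm module; stability values scale with the base, rankings do
not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix


class NormfinderError(ValueError):
    pass


@dataclass
class NormfinderDecomposition:
    genes: list[str]
    group_names: list[str]
    group_sizes: pd.Series               # n_g per group
    sigma2: pd.DataFrame                 # genes x groups, intragroup variance (clamped >= 0)
    d: pd.DataFrame                      # genes x groups, raw intergroup deviation
    d_shrunk: pd.DataFrame               # genes x groups, shrunk deviation
    gamma2: float                        # between-gene dispersion of d


@dataclass
class NormfinderResult:
    rho: pd.Series                       # per-gene stability value, lower = more stable
    ranking: list[str]                   # ascending rho
    best_gene: str
    best_pair: tuple[str, str]           # unordered
    pair_stability: float
    decomposition: NormfinderDecomposition


def _validate(matrix: ExpressionMatrix | pd.DataFrame, groups=None) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(matrix, ExpressionMatrix):
        data = matrix.data
        if groups is None:
            groups = matrix.groups
    else:
        data = pd.DataFrame(matrix, dtype=float)
    if groups is None:
        raise NormfinderError("group labels are required")
    groups = pd.Series(groups).reindex(data.columns)
    if groups.isna().any():
        raise NormfinderError("every sample needs a group label")
    if (data.to_numpy(dtype=float) <= 0).any():
        raise NormfinderError("expression quantities must be strictly positive")
    return pd.DataFrame(data, dtype=float), groups


def decompose_variation(
    matrix: ExpressionMatrix | pd.DataFrame, groups: pd.Series | None = None
) -> NormfinderDecomposition:
    """Estimate intra-group variances and inter-group deviations.

    Requires I >= 3 genes (the unbiasing factor divides by I - 2) and at
    least 2 samples per group. With a single group all deviations are zero
    and the decomposition reduces to the intragroup part.
    """
    data, groups = _validate(matrix, groups)
    genes = list(data.index)
    n_genes = len(genes)
    if n_genes < 3:
        raise NormfinderError("NormFinder bias correction requires >= 3 genes")
    group_names = list(dict.fromkeys(groups))
    y = np.log2(data.to_numpy())

    sizes = {}
    u = np.empty((n_genes, len(group_names)))
    z = np.empty((n_genes, len(group_names)))
    for gi, g in enumerate(group_names):
        cols = (groups == g).to_numpy()
        n_g = int(cols.sum())
        if n_g < 2:
            raise NormfinderError(f"group {g!r} has fewer than 2 samples")
        sizes[g] = n_g
        yg = y[:, cols]
        gene_mean = yg.mean(axis=1, keepdims=True)
        sample_mean = yg.mean(axis=0, keepdims=True)
        grand = yg.mean()
        resid = yg - gene_mean - sample_mean + grand
        u[:, gi] = (resid**2).sum(axis=1) / (n_g - 1)
        z[:, gi] = gene_mean[:, 0] - grand

    t_g = u.sum(axis=0)
    sigma2 = np.maximum(
        0.0, (n_genes / (n_genes - 2)) * (u - t_g[None, :] / (n_genes * (n_genes - 1)))
    )
    # mean of pairwise differences == deviation from the group mean, but is
    # exactly antisymmetric for two groups in floating point
    d = (z[:, :, None] - z[:, None, :]).mean(axis=2)

    sizes_arr = np.array([sizes[g] for g in group_names], dtype=float)
    samp_var = sigma2 / sizes_arr[None, :]
    gamma2 = max(0.0, (d**2).sum() / ((n_genes - 1) * len(group_names)) - samp_var.mean())
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    d_shrunk = d * factor

    gsizes = pd.Series(sizes, name="n")
    return NormfinderDecomposition(
        genes=genes,
        group_names=group_names,
        group_sizes=gsizes,
        sigma2=pd.DataFrame(sigma2, index=genes, columns=group_names),
        d=pd.DataFrame(d, index=genes, columns=group_names),
        d_shrunk=pd.DataFrame(d_shrunk, index=genes, columns=group_names),
        gamma2=float(gamma2),
    )


def stability_values(dec: NormfinderDecomposition) -> NormfinderResult:
    """Per-gene stability rho and the exhaustive best two-gene combination."""
    n_groups = len(dec.group_names)
    sizes = dec.group_sizes.loc[dec.group_names].to_numpy(dtype=float)
    sigma2 = dec.sigma2.to_numpy()
    d_sh = dec.d_shrunk.to_numpy()
    rho = (np.abs(d_sh) + np.sqrt(sigma2 / sizes[None, :])).sum(axis=1) / n_groups
    rho_s = pd.Series(rho, index=dec.genes, name="rho")
    ranking = list(rho_s.sort_values(kind="stable").index)
    pair, pair_rho = best_pair_from_decomposition(dec)
    return NormfinderResult(
        rho=rho_s,
        ranking=ranking,
        best_gene=ranking[0],
        best_pair=pair,
        pair_stability=pair_rho,
        decomposition=dec,
    )


def best_pair_from_decomposition(
    dec: NormfinderDecomposition,
) -> tuple[tuple[str, str], float]:
    """Exhaustive search for the two-gene combination with minimal pair
    stability; ties resolved in favour of the first pair in input order."""
    if len(dec.genes) < 2:
        raise NormfinderError("pair search needs >= 2 genes")
    sizes = dec.group_sizes.loc[dec.group_names].to_numpy(dtype=float)
    sigma2 = dec.sigma2.to_numpy()
    d_sh = dec.d_shrunk.to_numpy()
    n_groups = len(dec.group_names)
    best: tuple[str, str] | None = None
    best_val = np.inf
    for i, k in combinations(range(len(dec.genes)), 2):
        d_pair = (d_sh[i] + d_sh[k]) / 2.0
        var_pair = (sigma2[i] + sigma2[k]) / 4.0
        val = float((np.abs(d_pair) + np.sqrt(var_pair / sizes)).sum() / n_groups)
        if val < best_val:
            best_val = val
            best = (dec.genes[i], dec.genes[k])
    assert best is not None
    return best, best_val


def normfinder(
    matrix: ExpressionMatrix | pd.DataFrame, groups: pd.Series | None = None
) -> NormfinderResult:
    """Full NormFinder analysis on a positive expression matrix."""
    return stability_values(decompose_variation(matrix, groups))
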