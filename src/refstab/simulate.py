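"""Seeded synthetic-data generator for RT-qPCR reference-gene studies.

Generative model, per sample j in group g, gene i, technical replicate r:

    y_ij  = log2(fold_i) * [g = hyperchol] + shift_i * [g = hyperchol]
            + beta_j + eps_ij,      eps ~ N(0, residual_sd_i^2)
    Ct_ijr = baseline_ct_i - y_ij * ln 2 / ln(1 + E_i/100) + tau_ijr,
            tau ~ N(0, tech_rep_sd_i^2)

``y`` is the true log2 relative abundance, ``beta_j ~ N(0, loading_sd^2)``
a sample-specific loading factor applied identically to every gene of the
sample (cDNA input variation -- precisely the nuisance that reference-gene
normalization removes), and the Ct conversion uses the gene's own
amplification efficiency: one cycle corresponds to one factor of
``1 + E/100`` in template, i.e. ``log2(1 + E/100)`` log2 units.

Standard-curve dilution series follow

    Ct = intercept_i + slope_i * log10(q),  slope_i = -1 / log10(1 + E_i/100)

with ``intercept_i = baseline_ct_i`` (the Ct at relative quantity 1), so
quantification against the simulated curves recovers ``2^y`` exactly in the
noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    GROUP_HYPERCHOL,
    GROUP_NORMAL,
    ConfigurationError,
    EchoLink,
    SimulationConfig,
)

CT_COLUMNS = ["sample_id", "group", "gene", "replicate", "ct", "undetermined"]
DILUTION_COLUMNS = ["gene", "log10_quantity", "replicate", "ct"]


@dataclass
class GroundTruth:
    """True generating parameters aligned 1:1 with the emitted samples/genes."""

    fold_changes: dict[str, float]              # true hyperchol/normal ratio incl. shift
    loading_log2: pd.Series                     # beta_j per sample
    groups: pd.Series                           # group label per sample
    unstable_genes: list[str]                   # genes with injected instability
    true_quantity: pd.DataFrame                 # 2^y, genes x samples
    echo_links: dict[str, EchoLink] = field(default_factory=dict)


def cycles_per_log2(efficiency_percent: float) -> float:
    """Cycles of Ct shift per log2 unit of abundance at the given efficiency."""
    return float(np.log(2.0) / np.log1p(efficiency_percent / 100.0))


def slope_for_efficiency(efficiency_percent: float) -> float:
    """Standard-curve slope (cycles per log10 quantity) for an efficiency."""
    return float(-1.0 / np.log10(1.0 + efficiency_percent / 100.0))


def _sample_frame(config: SimulationConfig) -> tuple[list[str], list[str]]:
    ids = [f"N{k + 1}" for k in range(config.n_normal)]
    ids += [f"H{k + 1}" for k in range(config.n_hyperchol)]
    groups = [GROUP_NORMAL] * config.n_normal + [GROUP_HYPERCHOL] * config.n_hyperchol
    return ids, groups


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long-format Ct table and its ground truth.

    Returns a DataFrame with columns ``sample_id, group, gene, replicate,
    ct, undetermined`` and a :class:`GroundTruth`. Deterministic given
    ``config`` and the seed (``config.seed`` unless overridden).
    """
    if config.n_normal < 1 or config.n_hyperchol < 1:
        raise ConfigurationError("group sizes must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sample_ids, groups = _sample_frame(config)
    n = len(sample_ids)
    is_hc = np.array([g == GROUP_HYPERCHOL for g in groups])

    beta = rng.normal(0.0, config.loading_sd_log2, size=n)
    genes = list(config.genes)
    y = np.empty((len(genes), n))
    for i, gene in enumerate(genes):
        effect = np.log2(gene.fold_change_hyperchol) + gene.extra_group_shift_log2
        eps = rng.normal(0.0, gene.residual_sd_log2, size=n)
        y[i] = effect * is_hc + beta + eps

    records = []
    for i, gene in enumerate(genes):
        scale = cycles_per_log2(gene.efficiency_percent)
        ct_mean = gene.baseline_ct - y[i] * scale
        tau = rng.normal(0.0, gene.tech_rep_sd_ct, size=(config.n_tech_reps, n))
        for r in range(config.n_tech_reps):
            for j, sid in enumerate(sample_ids):
                records.append(
                    (sid, groups[j], gene.name, r + 1, ct_mean[j] + tau[r, j], False)
                )
    table = pd.DataFrame(records, columns=CT_COLUMNS)
    table = table.sort_values(["sample_id", "gene", "replicate"], kind="stable").reset_index(
        drop=True
    )

    unstable = [
        g.name
        for g in genes
        if g.role == "reference"
        and (g.extra_group_shift_log2 != 0.0 or g.fold_change_hyperchol != 1.0)
    ]
    truth = GroundTruth(
        fold_changes={
            g.name: g.fold_change_hyperchol * 2.0**g.extra_group_shift_log2
            for g in genes
        },
        loading_log2=pd.Series(beta, index=sample_ids, name="loading_log2"),
        groups=pd.Series(groups, index=sample_ids, name="group"),
        unstable_genes=unstable,
        true_quantity=pd.DataFrame(
            2.0**y, index=[g.name for g in genes], columns=sample_ids
        ),
        echo_links=dict(config.echo_links),
    )
    return table, truth


def simulate_standard_curves(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate per-gene dilution-series Ct observations.

    Returns a DataFrame with columns ``gene, log10_quantity, replicate, ct``
    covering ``config.dilution.n_points`` log-spaced quantities per gene.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    quantities = np.asarray(config.dilution.quantities())
    log_q = np.log10(quantities)
    records = []
    for gene in config.genes:
        slope = slope_for_efficiency(gene.efficiency_percent)
        ct_line = gene.baseline_ct + slope * log_q
        tau = rng.normal(0.0, gene.tech_rep_sd_ct, size=(config.n_tech_reps, len(log_q)))
        for r in range(config.n_tech_reps):
            for k in range(len(log_q)):
                records.append((gene.name, log_q[k], r + 1, ct_line[k] + tau[r, k]))
    return pd.DataFrame(records, columns=DILUTION_COLUMNS)


def simulate_echo(
    bnp_normalized: pd.Series,
    links: dict[str, EchoLink] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate echocardiographic indices as monotone functions of Bnp.

    Each index is ``intercept + slope * log2(bnp) + N(0, noise_sd^2)``;
    with ``noise_sd = 0`` the link is strictly monotone, so Spearman rho
    between Bnp and the index is exactly +1 or -1 depending on the slope
    sign.

    Parameters
    ----------
    bnp_normalized : pd.Series
        Strictly positive normalized Bnp quantity per sample.
    links : dict, optional
        Index name -> :class:`EchoLink`. Defaults to the package's LVDD
        index set. Unknown names are rejected with the supported list.
    """
    from .config import default_echo_links

    supported = default_echo_links()
    if links is None:
        links = supported
    unknown = sorted(set(links) - set(supported))
    if unknown:
        raise ValueError(
            f"unknown echo indices {unknown}; supported: {sorted(supported)}"
        )
    bnp = pd.Series(bnp_normalized, dtype=float)
    if (bnp <= 0).any():
        raise ValueError("Bnp quantities must be strictly positive")
    rng = np.random.default_rng(seed)
    log_bnp = np.log2(bnp.to_numpy())
    out = {}
    for name, link in links.items():
        noise = rng.normal(0.0, link.noise_sd, size=len(bnp)) if link.noise_sd > 0 else 0.0
        out[name] = link.intercept + link.slope * log_bnp + noise
    return pd.DataFrame(out, index=bnp.index)
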