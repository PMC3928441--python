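"""End-to-end pipeline: simulate or load Ct data, fit standard curves,
quantify, rank reference genes (geNorm and NormFinder), compare
normalization strategies for the genes of interest, and correlate
expression with echocardiographic indices.

All stage outputs are written under the configured output directory; a
``provenance.json`` records the configuration hash, seed, package version
and accumulated warnings, and suffices to reproduce the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import io as rio
from .config import GROUP_HYPERCHOL, GROUP_NORMAL, PipelineConfig, SimulationConfig
from .genorm import GenormResult, genorm, normalization_factor
from .normfinder import NormfinderResult, normfinder
from .quantify import (
    ExpressionMatrix,
    average_replicates,
    build_expression_matrix,
    fit_standard_curves,
)
from .simulate import simulate_echo, simulate_experiment, simulate_standard_curves
from .stats import (
    compare_strategies,
    correlate_expression_with_echo,
    normalize_goi,
    percent_difference_matrix,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    curves: dict
    matrix: ExpressionMatrix
    genorm: GenormResult
    normfinder: NormfinderResult
    comparisons: pd.DataFrame
    percent_differences: dict[str, pd.DataFrame]
    correlations: pd.DataFrame | None
    provenance: dict[str, Any]
    out_dir: Path | None = None


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)   # output location does not affect results
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_strategies(
    gn: GenormResult, nf: NormfinderResult, extra_single: list[str] | None = None
) -> dict[str, list[str]]:
    """Strategy set mirroring the study: the geNorm top genes (its
    recommended count, at least 3 when available), the NormFinder best pair,
    and single-gene normalizers for the worst-ranked gene of each method."""
    n_top = max(3, gn.recommended_n)
    n_top = min(n_top, len(gn.ranking))
    strategies = {
        f"genorm_top{n_top}": gn.ranking[:n_top],
        "normfinder_pair": list(nf.best_pair),
        f"single_{gn.ranking[-1]}": [gn.ranking[-1]],
        f"single_{nf.ranking[-1]}": [nf.ranking[-1]],
    }
    for gene in extra_single or []:
        strategies.setdefault(f"single_{gene}", [gene])
    return strategies


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage; deterministic given config and seed."""
    captured: list[str] = []
    stage = "setup"
    out_dir = Path(config.out_dir)
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            stage = "input"
            truth = None
            echo = None
            if config.ct_table is not None:
                ct_table = rio.read_ct_table(config.ct_table)
                if config.dilution_table is None:
                    raise PipelineError("a dilution table is required with a Ct table")
                dilution = rio.read_dilution_table(config.dilution_table)
                if config.echo_table is not None:
                    echo_raw = rio.read_echo_table(config.echo_table)
                else:
                    echo_raw = None
            else:
                sim: SimulationConfig = config.simulation  # type: ignore[assignment]
                ct_table, truth = simulate_experiment(sim, seed=config.seed)
                dilution = simulate_standard_curves(sim, seed=config.seed)
                echo_raw = None

            stage = "fit-curves"
            curves = fit_standard_curves(
                dilution, r2_warning_threshold=config.r2_warning_threshold
            )

            stage = "quantify"
            averaged = average_replicates(
                ct_table, discordance_threshold=config.discordance_threshold_ct
            )
            matrix = build_expression_matrix(averaged, curves, config.missing_policy)

            stage = "genorm"
            ref_genes = config.reference_genes
            if ref_genes is None:
                if config.simulation is not None:
                    ref_genes = config.simulation.reference_genes
                else:
                    ref_genes = list(matrix.data.index)
            gn = genorm(matrix.restrict(ref_genes), cutoff=config.genorm_cutoff)

            stage = "normfinder"
            nf = normfinder(matrix.restrict(ref_genes))

            stage = "compare"
            goi = config.goi_genes
            if goi is None:
                if config.simulation is not None:
                    goi = config.simulation.goi_genes
                else:
                    goi = [g for g in matrix.data.index if g not in ref_genes]
            strategies = default_strategies(
                gn, nf, extra_single=config.extra_single_gene_strategies
            )
            comparisons = compare_strategies(
                matrix, goi, strategies, mode=config.mann_whitney_mode
            )
            pct = {g: percent_difference_matrix(comparisons, g) for g in goi}

            stage = "correlate"
            correlations = None
            if truth is not None and "Bnp" in matrix.data.index:
                # emulate the echo examinations from the true Bnp expression
                top_nf = normalization_factor(matrix, gn.ranking[: max(3, gn.recommended_n)])
                bnp_norm = normalize_goi(matrix, top_nf).loc["Bnp"]
                echo = simulate_echo(
                    bnp_norm, truth.echo_links, seed=config.seed + 2
                )
            elif echo_raw is not None:
                from .stats import derive_echo_indices

                echo = derive_echo_indices(echo_raw)
            if echo is not None and goi:
                best_nf = normalization_factor(matrix, gn.ranking[: max(3, gn.recommended_n)])
                normalized = normalize_goi(matrix, best_nf)
                corr = correlate_expression_with_echo(normalized, echo, genes=goi)
                correlations = pd.DataFrame(
                    [
                        {
                            "gene": c.gene,
                            "echo_index": c.echo_index,
                            "rho": c.rho,
                            "p": c.p_value,
                            "n": c.n,
                        }
                        for c in corr
                    ]
                )

            captured = [str(w.message) for w in wrec]
    except Exception as err:
        if write:
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise PipelineError(f"stage {stage}: {err}") from err

    provenance = {
        "package": "refstab",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "simulated": config.simulation is not None and config.ct_table is None,
        "n_samples_used": len(matrix.samples),
        "dropped_samples": matrix.dropped_samples,
        "warnings": captured,
    }
    result = PipelineResult(
        curves=curves,
        matrix=matrix,
        genorm=gn,
        normfinder=nf,
        comparisons=comparisons,
        percent_differences=pct,
        correlations=correlations,
        provenance=provenance,
        out_dir=out_dir if write else None,
    )
    if write:
        _write_bundle(result, config, ct_table, dilution, echo)
    return result


def _write_bundle(
    result: PipelineResult,
    config: PipelineConfig,
    ct_table: pd.DataFrame,
    dilution: pd.DataFrame,
    echo: pd.DataFrame | None,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_ct_table(ct_table, out / "ct_table.csv")
    rio.write_dilution_table(dilution, out / "dilution.csv")
    rio.write_curve_table(result.curves, out / "standard_curves.csv")
    rio.write_expression_matrix(result.matrix, out / "expression_matrix.csv")
    result.genorm.rank_table().to_csv(out / "genorm_m_values.csv", index_label="gene")
    result.genorm.v_series.rename_axis("n").to_csv(out / "genorm_v_series.csv")
    gn_summary = {
        "ranking": result.genorm.ranking,
        "best_pair": list(result.genorm.best_pair),
        "recommended_n": result.genorm.recommended_n,
        "cutoff": result.genorm.cutoff,
    }
    (out / "genorm_summary.json").write_text(json.dumps(gn_summary, indent=2))
    nf_table = pd.DataFrame(
        {
            "rho": result.normfinder.rho,
            "rank": pd.Series(
                {g: i + 1 for i, g in enumerate(result.normfinder.ranking)}
            ),
        }
    )
    for g in result.normfinder.decomposition.group_names:
        nf_table[f"sigma2_{g}"] = result.normfinder.decomposition.sigma2[g]
        nf_table[f"d_{g}"] = result.normfinder.decomposition.d[g]
    nf_table.to_csv(out / "normfinder.csv", index_label="gene")
    (out / "normfinder_summary.json").write_text(
        json.dumps(
            {
                "best_gene": result.normfinder.best_gene,
                "best_pair": list(result.normfinder.best_pair),
                "pair_stability": result.normfinder.pair_stability,
            },
            indent=2,
        )
    )
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    for gene, mat in result.percent_differences.items():
        mat.to_csv(out / f"fc_percent_difference_{gene}.csv")
    if result.correlations is not None:
        result.correlations.to_csv(out / "correlations.csv", index=False)
    if echo is not None:
        rio.write_echo_table(echo, out / "echo_indices.csv")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
    if config.make_plots:
        from . import plotting

        plotting.plot_m_ranking(result.genorm, out / "genorm_ranking.png")
        plotting.plot_v_series(result.genorm, out / "genorm_v_series.png")
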