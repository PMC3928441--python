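"""Configuration objects for simulation and pipeline runs.

The default :class:`SimulationConfig` encodes the design of a two-group
hypercholesterolemia study in rabbits: 7 control and 11 diet animals, ten
candidate reference genes and four genes of interest measured by SYBR-green
RT-qPCR in technical duplicate, with five-point ten-fold standard curves per
gene. Amplification efficiencies follow the per-gene values estimated from
the standard-curve slopes (91.8-103.8 %).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

REFERENCE = "reference"
GOI = "goi"
GROUP_NORMAL = "normal"
GROUP_HYPERCHOL = "hyperchol"
GROUPS = (GROUP_NORMAL, GROUP_HYPERCHOL)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class GeneSpec:
    """Per-gene simulation parameters.

    Parameters
    ----------
    name : str
        Gene symbol.
    role : str
        ``"reference"`` for a candidate normalization gene, ``"goi"`` for a
        gene of interest.
    baseline_ct : float
        Threshold cycle of an average normal-group sample (the Ct observed
        at relative quantity 1), in cycles.
    efficiency_percent : float
        PCR amplification efficiency E in percent; one cycle multiplies the
        template by ``1 + E/100`` (100 % = perfect doubling).
    fold_change_hyperchol : float
        True expression ratio hypercholesterolemic / normal. 1.0 means no
        group effect (expected for a well-behaved reference gene).
    extra_group_shift_log2 : float
        Additional deterministic group shift in log2 units, used to inject
        reference-gene instability (a covert group regulation).
    residual_sd_log2 : float
        SD of per-sample biological/handling noise on the log2 abundance.
    tech_rep_sd_ct : float
        SD of technical replicate noise, in cycles.
    """

    name: str
    role: str
    baseline_ct: float
    efficiency_percent: float
    fold_change_hyperchol: float = 1.0
    extra_group_shift_log2: float = 0.0
    residual_sd_log2: float = 0.15
    tech_rep_sd_ct: float = 0.1

    def __post_init__(self) -> None:
        if self.role not in (REFERENCE, GOI):
            raise ConfigurationError(
                f"gene {self.name!r}: role must be {REFERENCE!r} or {GOI!r}, "
                f"got {self.role!r}"
            )
        if self.efficiency_percent <= 0:
            raise ConfigurationError(f"gene {self.name!r}: efficiency must be > 0")
        if self.fold_change_hyperchol <= 0:
            raise ConfigurationError(f"gene {self.name!r}: fold change must be > 0")
        if self.residual_sd_log2 < 0 or self.tech_rep_sd_ct < 0:
            raise ConfigurationError(f"gene {self.name!r}: SDs must be >= 0")


@dataclass(frozen=True)
class DilutionSpec:
    """Standard-curve dilution series: ``n_points`` quantities starting at
    ``top_quantity`` and descending by factor ``step``."""

    n_points: int = 5
    step: float = 10.0
    top_quantity: float = 10.0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigurationError("dilution series needs >= 2 points")
        if self.step <= 1 or self.top_quantity <= 0:
            raise ConfigurationError("dilution step must be > 1 and top quantity > 0")

    def quantities(self) -> list[float]:
        return [self.top_quantity / self.step**k for k in range(self.n_points)]


@dataclass(frozen=True)
class EchoLink:
    """Affine link from log2 of normalized Bnp expression to one
    echocardiographic index: ``value = intercept + slope * log2(bnp) + noise``.

    A positive slope models indices that rise with filling pressure
    (E velocity, deceleration rate, E/Em); a negative slope models indices
    that fall (deceleration time, A-Ar durations).
    """

    intercept: float
    slope: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("echo noise_sd must be >= 0")


def default_echo_links() -> dict[str, EchoLink]:
    """Default monotone links, scaled to plausible pre-sacrifice values for
    normal (Bnp ~ 1) and diseased (Bnp ~ 6) animals."""
    return {
        "e_velocity": EchoLink(70.0, 14.0, 8.0),           # cm/s
        "deceleration_time": EchoLink(35.0, -4.0, 3.0),    # ms
        "deceleration_rate": EchoLink(20.0, 10.0, 4.0),    # m/s^2
        "e_em_lateral": EchoLink(6.5, 2.0, 0.8),
        "e_em_septal": EchoLink(7.0, 1.6, 0.7),
        "a_ar_left": EchoLink(-6.0, -7.0, 3.0),            # ms
        "a_ar_right": EchoLink(-6.0, -6.5, 3.0),           # ms
    }


def default_gene_panel() -> list[GeneSpec]:
    """The 14-gene study panel: 10 candidate reference genes and 4 genes of
    interest, with the per-gene amplification efficiencies estimated in the
    study and group effects of ~6-fold (Bnp) down to ~2-fold (Nox-2)."""
    refs = [
        ("Gapdh", 18.5, 94.2),
        ("Hprt1", 24.0, 96.1),
        ("Ppia", 20.0, 96.6),
        ("Sdha", 23.0, 96.1),
        ("Eef1e1", 26.0, 91.8),
        ("G6pd", 25.5, 93.1),
        ("Pgk1", 22.0, 92.2),
        ("Rpl5", 21.0, 98.0),
        ("Actb", 19.0, 98.0),
        ("Ywhaz", 24.5, 103.8),
    ]
    gois = [
        ("Anp", 26.0, 95.9, 3.0),
        ("Bnp", 27.0, 100.5, 6.0),
        ("Mcp-1", 28.0, 100.2, 2.5),
        ("Nox-2", 27.5, 98.0, 2.0),
    ]
    panel = [
        GeneSpec(name=n, role=REFERENCE, baseline_ct=ct, efficiency_percent=e)
        for n, ct, e in refs
    ]
    panel += [
        GeneSpec(
            name=n,
            role=GOI,
            baseline_ct=ct,
            efficiency_percent=e,
            fold_change_hyperchol=fc,
        )
        for n, ct, e, fc in gois
    ]
    return panel


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment."""

    n_normal: int = 7
    n_hyperchol: int = 11
    genes: tuple[GeneSpec, ...] = field(
        default_factory=lambda: tuple(default_gene_panel())
    )
    loading_sd_log2: float = 0.5
    n_tech_reps: int = 2
    dilution: DilutionSpec = field(default_factory=DilutionSpec)
    echo_links: dict[str, EchoLink] = field(default_factory=default_echo_links)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 1 or self.n_hyperchol < 1:
            raise ConfigurationError("group sizes must be positive")
        if self.n_tech_reps < 1:
            raise ConfigurationError("n_tech_reps must be >= 1")
        if self.loading_sd_log2 < 0:
            raise ConfigurationError("loading_sd_log2 must be >= 0")
        if not self.genes:
            raise ConfigurationError("gene panel is empty")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names in panel")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def reference_genes(self) -> list[str]:
        return [g.name for g in self.genes if g.role == REFERENCE]

    @property
    def goi_genes(self) -> list[str]:
        return [g.name for g in self.genes if g.role == GOI]

    def with_overrides(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: either file inputs or a simulation."""

    out_dir: Path = Path("refstab_out")
    ct_table: Path | None = None
    dilution_table: Path | None = None
    echo_table: Path | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    genorm_cutoff: float = 0.15
    log_base: float = 2.0
    discordance_threshold_ct: float = 0.5
    r2_warning_threshold: float = 0.98
    missing_policy: str = "drop_sample"
    mann_whitney_mode: str = "auto"
    alpha: float = 0.05
    reference_genes: list[str] | None = None
    goi_genes: list[str] | None = None
    extra_single_gene_strategies: list[str] = field(default_factory=list)
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.genorm_cutoff < 1):
            raise ConfigurationError("genorm cutoff must lie in (0, 1)")
        if self.ct_table is None and self.simulation is None:
            # default to simulating the study design
            self.simulation = SimulationConfig(seed=self.seed)


def _gene_from_dict(d: dict[str, Any]) -> GeneSpec:
    return GeneSpec(**d)


def simulation_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = dict(d)
    if "genes" in d:
        d["genes"] = tuple(_gene_from_dict(g) for g in d["genes"])
    if "dilution" in d:
        d["dilution"] = DilutionSpec(**d["dilution"])
    if "echo_links" in d:
        d["echo_links"] = {k: EchoLink(**v) for k, v in d["echo_links"].items()}
    return SimulationConfig(**d)


def load_config(path: str | Path, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML pipeline configuration; ``overrides`` maps dotted keys
    (e.g. ``simulation.seed``) to replacement values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        node = raw
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    if "simulation" in raw and raw["simulation"] is not None:
        raw["simulation"] = simulation_config_from_dict(raw["simulation"])
    for key in ("out_dir", "ct_table", "dilution_table", "echo_table"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    return PipelineConfig(**raw)
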