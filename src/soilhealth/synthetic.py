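"""Synthetic multi-treatment soil indicator data with known ground truth.

The generator emulates the kind of dataset a pot/pool biofortification
experiment produces: a small number of treatments (control + amendments),
a handful of biological replicates, and a panel of positive-valued soil and
plant indicators whose correlation structure is block-wise — carbon and
nutrient pools move together, trace elements move together, physical
properties move together, community diversity metrics move together.

Model
-----
Each indicator *i* in block *b* gets a latent standard-normal score

    z_i = l_i * f_b + sqrt(1 - l_i^2) * eps_i

where ``f_b`` is the block factor and ``l_i = sqrt(rho_block)`` the loading,
so the latent (and hence Spearman, by monotonicity) correlation within a
block is ``rho_block`` and zero across blocks (Gaussian copula). Designated
*hub* indicators may carry a boosted loading so they are the most strongly
connected node of their block — the planted answer the network/MDS stage
should recover. The observed value is a lognormal transform

    value = baseline_mean * effect(treatment, i) * exp(sigma * z_i - sigma^2/2)

with ``sigma^2 = ln(1 + cv^2)``, giving exact mean ``baseline * effect`` and
coefficient of variation ``cv``; values are strictly positive and the rank
correlation of the latent scores survives the monotone transform.

Community counts are Dirichlet-multinomial: per-sample taxon proportions
drawn from a symmetric Dirichlet whose concentration is treatment-specific
(higher concentration → more even community → higher expected Shannon),
then multinomial counts at a fixed sequencing depth.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
substreams, so identical config + seed reproduces identical tables.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .indicators import VALID_DIRECTIONS, IndicatorMeta, IndicatorTable

MAX_LOADING = 0.995  # cap so boosted hub loadings stay a valid correlation


@dataclass(frozen=True)
class IndicatorSpec:
    """One synthetic indicator: name, scoring direction, marginal moments."""

    name: str
    direction: str = "more_is_better"
    baseline_mean: float = 1.0
    cv: float = 0.10
    optimum_target: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ConfigurationError(
                f"indicator {self.name!r}: direction must be one of "
                f"{VALID_DIRECTIONS}, got {self.direction!r}"
            )
        if self.baseline_mean <= 0:
            raise ConfigurationError(
                f"indicator {self.name!r}: baseline_mean must be > 0, "
                f"got {self.baseline_mean}"
            )
        if not 0 <= self.cv < 1:
            raise ConfigurationError(
                f"indicator {self.name!r}: cv must be in [0, 1), got {self.cv}"
            )
        if self.direction == "optimum" and (
            self.optimum_target is None or self.optimum_target <= 0
        ):
            raise ConfigurationError(
                f"indicator {self.name!r}: direction='optimum' needs optimum_target > 0"
            )

    @property
    def meta(self) -> IndicatorMeta:
        return IndicatorMeta(self.direction, self.optimum_target)


@dataclass(frozen=True)
class CommunityConfig:
    """Dirichlet-multinomial community model parameters."""

    n_taxa: int = 120
    sequencing_depth: int = 20_000
    #: symmetric Dirichlet concentration per treatment; larger = more even
    concentration: Mapping[str, float] = field(default_factory=dict)
    default_concentration: float = 0.5

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ConfigurationError(f"n_taxa must be >= 1, got {self.n_taxa}")
        if self.sequencing_depth <= 0:
            raise ConfigurationError(
                f"sequencing_depth must be > 0, got {self.sequencing_depth}"
            )
        for trt, conc in self.concentration.items():
            if conc <= 0:
                raise ConfigurationError(
                    f"concentration for treatment {trt!r} must be > 0, got {conc}"
                )
        if self.default_concentration <= 0:
            raise ConfigurationError("default_concentration must be > 0")

    def concentration_for(self, treatment: str) -> float:
        return float(self.concentration.get(treatment, self.default_concentration))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic experiment."""

    seed: int
    treatments: Sequence[str]
    replicates: int
    indicators: Sequence[IndicatorSpec]
    #: block name -> list of member indicator names (a partition)
    blocks: Mapping[str, Sequence[str]]
    #: block name -> hub indicator (one per block)
    hubs: Mapping[str, str]
    #: within-block latent correlation, in [0, 1)
    rho_block: float = 0.9
    #: multiplier applied to hub loadings (capped so loading < 1)
    hub_loading_boost: float = 1.0
    #: treatment -> indicator -> multiplicative effect (> 0); missing = 1.0
    treatment_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    community: CommunityConfig = field(default_factory=CommunityConfig)

    def __post_init__(self) -> None:
        if len(self.treatments) < 2:
            raise ConfigurationError(
                f"need at least 2 treatments, got {len(self.treatments)}"
            )
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatment names must be unique")
        if self.replicates < 3:
            raise ConfigurationError(
                "replicates must be >= 3 (correlation p-values are undefined "
                f"for fewer samples), got {self.replicates}"
            )
        names = [s.name for s in self.indicators]
        if len(set(names)) != len(names):
            raise ConfigurationError("indicator names must be unique")
        block_members = [m for members in self.blocks.values() for m in members]
        if sorted(block_members) != sorted(names):
            raise ConfigurationError(
                "blocks must partition the indicator set exactly; "
                f"blocks cover {sorted(block_members)} vs indicators {sorted(names)}"
            )
        if set(self.hubs) != set(self.blocks):
            raise ConfigurationError("hubs must name exactly one hub per block")
        for block, hub in self.hubs.items():
            if hub not in self.blocks[block]:
                raise ConfigurationError(
                    f"hub {hub!r} is not a member of block {block!r}"
                )
        if not 0 <= self.rho_block < 1:
            raise ConfigurationError(f"rho_block must be in [0, 1), got {self.rho_block}")
        if self.hub_loading_boost <= 0:
            raise ConfigurationError("hub_loading_boost must be > 0")
        for trt, effects in self.treatment_effects.items():
            if trt not in self.treatments:
                raise ConfigurationError(f"treatment_effects for unknown treatment {trt!r}")
            for ind, eff in effects.items():
                if ind not in names:
                    raise ConfigurationError(
                        f"treatment_effects[{trt!r}] for unknown indicator {ind!r}"
                    )
                if eff <= 0:
                    raise ConfigurationError(
                        f"treatment_effects[{trt!r}][{ind!r}] must be > 0, got {eff}"
                    )

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def indicator_names(self) -> list[str]:
        return [s.name for s in self.indicators]

    def effect(self, treatment: str, indicator: str) -> float:
        return float(self.treatment_effects.get(treatment, {}).get(indicator, 1.0))

    def meta(self) -> dict[str, IndicatorMeta]:
        return {s.name: s.meta for s in self.indicators}


@dataclass
class GroundTruth:
    """Planted structure: what a successful MDS selection should recover."""

    block_membership: dict[str, str]  # indicator -> block
    hubs: list[str]
    expected_means: pd.DataFrame  # treatments × indicators, baseline × effect

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "block_membership": self.block_membership,
            "hubs": self.hubs,
            "expected_means": {
                trt: {k: float(v) for k, v in row.items()}
                for trt, row in self.expected_means.iterrows()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


# ---------------------------------------------------------------------------
# Default experiment: control + nanocomposite + two single-element treatments,
# three replicate pools, 14 indicators in 4 blocks.
# ---------------------------------------------------------------------------

_DEFAULT_PANEL: list[IndicatorSpec] = [
    # carbon / nutrient pool block — hub SOC
    IndicatorSpec("SOC", "more_is_better", baseline_mean=12.0),   # g·kg⁻¹
    IndicatorSpec("DOC", "more_is_better", baseline_mean=150.0),  # mg·kg⁻¹
    IndicatorSpec("AN", "more_is_better", baseline_mean=80.0),    # mg·kg⁻¹
    IndicatorSpec("AP", "more_is_better", baseline_mean=25.0),    # mg·kg⁻¹
    IndicatorSpec("AK", "more_is_better", baseline_mean=120.0),   # mg·kg⁻¹
    # trace element block — hub Se
    IndicatorSpec("Se", "more_is_better", baseline_mean=0.3),     # mg·kg⁻¹
    IndicatorSpec("Zn", "more_is_better", baseline_mean=60.0),    # mg·kg⁻¹
    # physical / electrochemical block — hub SMC
    IndicatorSpec("SMC", "more_is_better", baseline_mean=22.0),   # %
    IndicatorSpec("pH", "optimum", baseline_mean=6.8, optimum_target=6.8),
    IndicatorSpec("EC", "less_is_better", baseline_mean=0.35),    # mS·cm⁻¹
    IndicatorSpec("ORP", "more_is_better", baseline_mean=320.0),  # mV
    # soil biology block — hub shannon
    IndicatorSpec("chao1", "more_is_better", baseline_mean=900.0),
    IndicatorSpec("ace", "more_is_better", baseline_mean=920.0),
    IndicatorSpec("shannon", "more_is_better", baseline_mean=5.5),
]

_DEFAULT_BLOCKS = {
    "nutrients": ["SOC", "DOC", "AN", "AP", "AK"],
    "elements": ["Se", "Zn"],
    "physical": ["SMC", "pH", "EC", "ORP"],
    "biology": ["chao1", "ace", "shannon"],
}

_DEFAULT_HUBS = {
    "nutrients": "SOC",
    "elements": "Se",
    "physical": "SMC",
    "biology": "shannon",
}


def default_config(seed: int, improvement: float = 1.20) -> SyntheticConfig:
    """The default four-treatment experiment.

    The nanocomposite treatment uniformly improves every more-is-better
    indicator by the given factor (default +20%); the two single-element
    treatments get a milder +10%.
    """
    more = [s.name for s in _DEFAULT_PANEL if s.direction == "more_is_better"]
    effects = {
        "NanoZSe": {name: improvement for name in more},
        "Se": {name: 1.10 for name in more},
        "Zn": {name: 1.10 for name in more},
    }
    return SyntheticConfig(
        seed=seed,
        treatments=("CK", "NanoZSe", "Se", "Zn"),
        replicates=3,
        indicators=tuple(_DEFAULT_PANEL),
        blocks=_DEFAULT_BLOCKS,
        hubs=_DEFAULT_HUBS,
        rho_block=0.9,
        treatment_effects=effects,
        community=CommunityConfig(
            concentration={"CK": 0.4, "NanoZSe": 0.8, "Se": 0.5, "Zn": 0.5}
        ),
    )


def recovery_config(seed: int, replicates: int = 50) -> SyntheticConfig:
    """Hub-recovery benchmark: boosted hub loadings, no treatment effects.

    Two treatments × ``replicates`` samples each, rho_block = 0.9, hub
    loadings boosted 1.2× (capped below 1) so each block's hub is its most
    strongly connected member.
    """
    return SyntheticConfig(
        seed=seed,
        treatments=("CK", "T"),
        replicates=replicates,
        indicators=tuple(_DEFAULT_PANEL),
        blocks=_DEFAULT_BLOCKS,
        hubs=_DEFAULT_HUBS,
        rho_block=0.9,
        hub_loading_boost=1.2,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _substreams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Two independent per-stage generators (indicator table, community)."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def generate_indicator_table(
    config: SyntheticConfig,
) -> tuple[IndicatorTable, GroundTruth]:
    """Draw the samples × indicators table and its planted ground truth."""
    rng, _ = _substreams(config.seed)
    names = config.indicator_names
    n_ind = len(names)
    n_samples = config.n_treatments * config.replicates

    block_of = {m: b for b, members in config.blocks.items() for m in members}
    base_loading = float(np.sqrt(config.rho_block))
    loadings = np.empty(n_ind)
    for k, name in enumerate(names):
        l = base_loading
        if config.hubs[block_of[name]] == name:
            l = min(l * config.hub_loading_boost, MAX_LOADING)
        loadings[k] = l

    block_names = list(config.blocks)
    block_idx = {b: i for i, b in enumerate(block_names)}
    factors = rng.standard_normal((n_samples, len(block_names)))
    eps = rng.standard_normal((n_samples, n_ind))
    z = np.empty((n_samples, n_ind))
    for k, name in enumerate(names):
        f = factors[:, block_idx[block_of[name]]]
        l = loadings[k]
        z[:, k] = l * f + np.sqrt(1.0 - l * l) * eps[:, k]

    rows = []
    values = np.empty((n_samples, n_ind))
    i = 0
    for trt in config.treatments:
        for rep in range(1, config.replicates + 1):
            rows.append((f"{trt}_r{rep}", trt, rep))
            for k, spec in enumerate(config.indicators):
                sigma = float(np.sqrt(np.log1p(spec.cv**2)))
                mean = spec.baseline_mean * config.effect(trt, spec.name)
                values[i, k] = mean * np.exp(sigma * z[i, k] - 0.5 * sigma**2)
            i += 1

    frame = pd.DataFrame(rows, columns=["sample_id", "treatment", "replicate"])
    frame[names] = values
    table = IndicatorTable(frame, config.meta())

    expected = pd.DataFrame(
        {
            name: [
                spec.baseline_mean * config.effect(trt, name)
                for trt in config.treatments
            ]
            for name, spec in zip(names, config.indicators)
        },
        index=list(config.treatments),
    )
    truth = GroundTruth(
        block_membership=block_of,
        hubs=[config.hubs[b] for b in block_names],
        expected_means=expected,
    )
    return table, truth


def generate_community_counts(config: SyntheticConfig) -> pd.DataFrame:
    """Dirichlet-multinomial taxa × samples count table.

    One column per sample (same sample ids as the indicator table), one row
    per taxon. Proportions are symmetric-Dirichlet with a treatment-specific
    concentration; counts are multinomial at the configured depth.
    """
    _, rng = _substreams(config.seed)
    comm = config.community
    taxa = [f"taxon_{j + 1}" for j in range(comm.n_taxa)]
    data: dict[str, np.ndarray] = {}
    for trt in config.treatments:
        conc = comm.concentration_for(trt)
        for rep in range(1, config.replicates + 1):
            if comm.n_taxa == 1:
                props = np.ones(1)
            else:
                props = rng.dirichlet(np.full(comm.n_taxa, conc))
            data[f"{trt}_r{rep}"] = rng.multinomial(comm.sequencing_depth, props)
    return pd.DataFrame(data, index=pd.Index(taxa, name="taxon"))


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def config_from_dict(raw: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a parsed YAML/JSON mapping.

    Raises ConfigurationError naming the offending field.
    """
    try:
        indicators = tuple(
            IndicatorSpec(**spec) for spec in raw.get("indicators", [])
        )
    except TypeError as exc:
        raise ConfigurationError(f"indicators: {exc}") from exc
    community_raw = dict(raw.get("community", {}))
    try:
        community = CommunityConfig(**community_raw)
    except TypeError as exc:
        raise ConfigurationError(f"community: {exc}") from exc
    known = {
        "seed",
        "treatments",
        "replicates",
        "rho_block",
        "hub_loading_boost",
        "blocks",
        "hubs",
        "treatment_effects",
    }
    unknown = set(raw) - known - {"indicators", "community"}
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
    return SyntheticConfig(
        seed=int(raw["seed"]),
        treatments=tuple(raw["treatments"]),
        replicates=int(raw["replicates"]),
        indicators=indicators,
        blocks=raw["blocks"],
        hubs=raw["hubs"],
        rho_block=float(raw.get("rho_block", 0.9)),
        hub_loading_boost=float(raw.get("hub_loading_boost", 1.0)),
        treatment_effects=raw.get("treatment_effects", {}),
        community=community,
    )


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a SyntheticConfig from YAML or JSON."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        return config_from_dict(raw)
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing required field {exc}") from exc
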