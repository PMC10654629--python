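"""Analysis configuration: schema, validation, and the shipped default parameter set.

The configuration is a single YAML document with five blocks: global model
``settings``, health-state ``utilities``, per-arm ``costs`` (shared across
populations), per-population Weibull ``populations`` (survival parameters for
each arm), and ``owsa``/``psa`` sensitivity-analysis settings.  The default
shipped with the package encodes the published base-case parameter table.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .economics import CostProfile, UtilitySet
from .exceptions import ConfigError
from .markov import ModelSettings
from .survival import WeibullParams

__all__ = [
    "StrategyDefinition",
    "OWSASettings",
    "PSASettings",
    "AnalysisConfig",
    "load_config",
    "default_config",
]

ARMS = ("intervention", "comparator")


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment arm: cost profile plus fitted PFS/OS survival parameters."""

    name: str
    costs: CostProfile
    pfs: WeibullParams
    os: WeibullParams


@dataclass(frozen=True)
class OWSASettings:
    span: float = 0.20
    parameters: tuple[str, ...] = ()


@dataclass(frozen=True)
class PSASettings:
    iterations: int = 1000
    se_fraction: float = 0.20
    seed: int = 0
    wtp_grid: tuple[float, ...] = ()


@dataclass
class AnalysisConfig:
    """Fully validated analysis configuration."""

    settings: ModelSettings
    utilities: UtilitySet
    costs: dict[str, CostProfile]  # keyed by arm
    populations: dict[str, dict[str, dict[str, WeibullParams]]]  # pop -> arm -> endpoint
    owsa: OWSASettings
    psa: PSASettings

    def strategy(self, population: str, arm: str) -> StrategyDefinition:
        if population not in self.populations:
            raise ConfigError(
                f"populations.{population}: unknown population "
                f"(have {sorted(self.populations)})"
            )
        if arm not in ARMS:
            raise ConfigError(f"arm must be one of {ARMS}, got {arm!r}")
        surv = self.populations[population][arm]
        return StrategyDefinition(
            name=arm, costs=self.costs[arm], pfs=surv["pfs"], os=surv["os"]
        )

    def copy(self) -> "AnalysisConfig":
        return copy.deepcopy(self)


def _require(block: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in block:
        raise ConfigError(f"{path}.{key}: missing required field")
    return block[key]


def _parse_weibull(block: Mapping[str, Any], path: str) -> WeibullParams:
    try:
        return WeibullParams(
            float(_require(block, "scale_lambda", path)),
            float(_require(block, "shape_gamma", path)),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{path}: {exc}") from exc


def parse_config(raw: Mapping[str, Any]) -> AnalysisConfig:
    """Validate a raw YAML mapping into an :class:`AnalysisConfig`.

    Raises :class:`ConfigError` whose message names the offending field path.
    """
    if not isinstance(raw, Mapping):
        raise ConfigError("top level: expected a mapping")
    s = _require(raw, "settings", "")
    try:
        settings = ModelSettings(
            cycle_length_months=float(s.get("cycle_length_months", 1)),
            horizon_cycles=int(_require(s, "horizon_cycles", "settings")),
            discount_rate_annual=float(_require(s, "discount_rate_annual", "settings")),
            wtp_per_qaly=float(_require(s, "wtp_per_qaly", "settings")),
            half_cycle_correction=bool(s.get("half_cycle_correction", True)),
        )
    except ValueError as exc:
        raise ConfigError(f"settings: {exc}") from exc

    u = _require(raw, "utilities", "")
    try:
        utilities = UtilitySet(
            u_pfs=float(_require(u, "pfs", "utilities")),
            u_pd=float(_require(u, "pd", "utilities")),
        )
    except ValueError as exc:
        raise ConfigError(f"utilities: {exc}") from exc

    cblock = _require(raw, "costs", "")
    costs: dict[str, CostProfile] = {}
    for arm in ARMS:
        ab = _require(cblock, arm, "costs")
        comp = _require(ab, "pfs_components", f"costs.{arm}")
        try:
            costs[arm] = CostProfile(
                pfs_components={str(k): float(v) for k, v in comp.items()},
                pd_per_cycle=float(_require(ab, "pd_per_cycle", f"costs.{arm}")),
            )
        except ValueError as exc:
            raise ConfigError(f"costs.{arm}: {exc}") from exc

    pblock = _require(raw, "populations", "")
    if not pblock:
        raise ConfigError("populations: at least one population is required")
    populations: dict[str, dict[str, dict[str, WeibullParams]]] = {}
    for pop, arms in pblock.items():
        populations[pop] = {}
        for arm in ARMS:
            ab = _require(arms, arm, f"populations.{pop}")
            populations[pop][arm] = {
                "pfs": _parse_weibull(
                    _require(ab, "pfs_weibull", f"populations.{pop}.{arm}"),
                    f"populations.{pop}.{arm}.pfs_weibull",
                ),
                "os": _parse_weibull(
                    _require(ab, "os_weibull", f"populations.{pop}.{arm}"),
                    f"populations.{pop}.{arm}.os_weibull",
                ),
            }

    ob = raw.get("owsa", {})
    owsa = OWSASettings(
        span=float(ob.get("span", 0.20)),
        parameters=tuple(ob.get("parameters", ())),
    )
    if owsa.span < 0:
        raise ConfigError("owsa.span: must be >= 0")

    pb = raw.get("psa", {})
    grid_spec = pb.get("wtp_grid", {"start": 0, "stop": 250_000, "step": 2_500})
    if isinstance(grid_spec, Mapping):
        start = float(grid_spec.get("start", 0))
        stop = float(grid_spec.get("stop", 250_000))
        step = float(grid_spec.get("step", 2_500))
        if step <= 0 or stop < start:
            raise ConfigError("psa.wtp_grid: need step > 0 and stop >= start")
        n = int(round((stop - start) / step))
        grid = tuple(start + i * step for i in range(n + 1))
    else:
        grid = tuple(float(x) for x in grid_spec)
    psa = PSASettings(
        iterations=int(pb.get("iterations", 1000)),
        se_fraction=float(pb.get("se_fraction", 0.20)),
        seed=int(pb.get("seed", 0)),
        wtp_grid=grid,
    )
    if psa.iterations < 1:
        raise ConfigError("psa.iterations: must be >= 1")
    if psa.se_fraction < 0:
        raise ConfigError("psa.se_fraction: must be >= 0")

    return AnalysisConfig(
        settings=settings,
        utilities=utilities,
        costs=costs,
        populations=populations,
        owsa=owsa,
        psa=psa,
    )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def default_config() -> AnalysisConfig:
    """The packaged default configuration (published base-case parameter set)."""
    text = resources.files("escc_cea").joinpath("data/default_config.yaml").read_text()
    return parse_config(yaml.safe_load(text))


def config_hash(path_or_config: str | Path | AnalysisConfig) -> str:
    """SHA-256 of the configuration file (or of the default if none on disk)."""
    if isinstance(path_or_config, (str, Path)):
        data = Path(path_or_config).read_bytes()
    else:
        data = repr(path_or_config).encode()
    return hashlib.sha256(data).hexdigest()[:16]
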