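"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic sensitivity analysis (OWSA) re-runs the full model with
each parameter set to base*(1-span) and base*(1+span) — the conventional ±20%
— holding everything else fixed, and ranks parameters by the width of the
resulting INMB interval (tornado order).

Probabilistic sensitivity analysis (PSA) jointly resamples all uncertain
parameters: cost components follow moment-matched gamma distributions and
utilities moment-matched beta distributions; the fitted Weibull survival
parameters are treated as fixed, as in the source analysis.  The standard
errors are not published, so they default to 20% of the mean (configurable),
mirroring the OWSA span.  The cost-effectiveness acceptability curve (CEAC)
reports, over a willingness-to-pay grid, the fraction of draws with positive
incremental net monetary benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARMS, AnalysisConfig
from .economics import CostProfile, UtilitySet
from .exceptions import ValidationError
from .markov import build_trace
from .model import evaluate_population
from . import economics

__all__ = [
    "OWSAEntry",
    "OWSAResult",
    "PSAResult",
    "CEACCurve",
    "owsa",
    "sample_gamma",
    "sample_beta",
    "psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


def _apply_parameter(config: AnalysisConfig, path: str, factor: float) -> AnalysisConfig:
    """Return a copy of ``config`` with the parameter at ``path`` scaled by ``factor``.

    Recognized paths:
      utilities.pfs | utilities.pd
      costs.<arm>.pfs_total                (joint scaling of all PFS-phase components)
      costs.<arm>.components.<name>
      costs.<arm>.pd_per_cycle
    """
    cfg = config.copy()
    parts = path.split(".")
    try:
        if parts[0] == "utilities" and len(parts) == 2:
            u = cfg.utilities
            if parts[1] == "pfs":
                cfg.utilities = UtilitySet(u_pfs=min(u.u_pfs * factor, 1.0), u_pd=u.u_pd)
            elif parts[1] == "pd":
                new_pd = min(u.u_pd * factor, u.u_pfs)
                cfg.utilities = UtilitySet(u_pfs=u.u_pfs, u_pd=new_pd)
            else:
                raise KeyError(parts[1])
            return cfg
        if parts[0] == "costs" and len(parts) >= 3 and parts[1] in ARMS:
            arm = parts[1]
            prof = cfg.costs[arm]
            if parts[2] == "pfs_total" and len(parts) == 3:
                comps = {k: v * factor for k, v in prof.pfs_components.items()}
                cfg.costs[arm] = CostProfile(comps, prof.pd_per_cycle)
                return cfg
            if parts[2] == "pd_per_cycle" and len(parts) == 3:
                cfg.costs[arm] = CostProfile(
                    dict(prof.pfs_components), prof.pd_per_cycle * factor
                )
                return cfg
            if parts[2] == "components" and len(parts) == 4:
                comps = dict(prof.pfs_components)
                comps[parts[3]] = comps[parts[3]] * factor  # KeyError if unknown
                cfg.costs[arm] = CostProfile(comps, prof.pd_per_cycle)
                return cfg
        raise KeyError(path)
    except KeyError as exc:
        raise ValidationError(f"unknown OWSA parameter path: {path}") from exc


@dataclass(frozen=True)
class OWSAEntry:
    """Tornado entry for one parameter varied to base*(1±span)."""

    name: str
    icer_at_low: float
    icer_at_high: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def range_width(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


@dataclass(frozen=True)
class OWSAResult:
    """Tornado-ordered one-way sensitivity results (descending INMB range)."""

    population: str
    span: float
    base_icer: float
    base_inmb: float
    entries: tuple[OWSAEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.name,
                    "icer_at_low": e.icer_at_low,
                    "icer_at_high": e.icer_at_high,
                    "inmb_at_low": e.inmb_at_low,
                    "inmb_at_high": e.inmb_at_high,
                    "inmb_range": e.range_width,
                }
                for e in self.entries
            ]
        )


def owsa(
    config: AnalysisConfig,
    population: str,
    parameters: list[str] | None = None,
    span: float | None = None,
) -> OWSAResult:
    """One-way ±span sensitivity analysis with tornado ranking.

    Each parameter is set in turn to base*(1-span) and base*(1+span) (utilities
    are capped at their logical bounds) and the full model re-run; entries are
    sorted by descending |INMB(high) - INMB(low)|.
    """
    if parameters is None:
        parameters = list(config.owsa.parameters)
    if not parameters:
        raise ValidationError("OWSA parameter list is empty")
    if span is None:
        span = config.owsa.span
    if span < 0:
        raise ValidationError("span must be >= 0")
    base = evaluate_population(config, population)
    entries = []
    for path in parameters:
        lo = evaluate_population(_apply_parameter(config, path, 1.0 - span), population)
        hi = evaluate_population(_apply_parameter(config, path, 1.0 + span), population)
        entries.append(
            OWSAEntry(
                name=path,
                icer_at_low=lo.icer,
                icer_at_high=hi.icer,
                inmb_at_low=lo.inmb,
                inmb_at_high=hi.inmb,
            )
        )
    entries.sort(key=lambda e: e.range_width, reverse=True)
    return OWSAResult(
        population=population,
        span=span,
        base_icer=base.icer,
        base_inmb=base.inmb,
        entries=tuple(entries),
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def sample_gamma(mean: float, se: float, rng: np.random.Generator, size: int | None = None):
    """Moment-matched gamma draws: shape = mean^2/se^2, scale = se^2/mean."""
    if mean <= 0:
        raise ValidationError("gamma mean must be > 0")
    if se < 0:
        raise ValidationError("se must be >= 0")
    if se == 0:
        return mean if size is None else np.full(size, mean)
    shape = mean**2 / se**2
    scale = se**2 / mean
    return rng.gamma(shape, scale, size=size)


def sample_beta(mean: float, se: float, rng: np.random.Generator, size: int | None = None):
    """Moment-matched beta draws: alpha = mean*nu, beta = (1-mean)*nu, nu = mean(1-mean)/se^2 - 1."""
    if not (0 < mean < 1):
        raise ValidationError("beta mean must be in (0, 1)")
    if se < 0:
        raise ValidationError("se must be >= 0")
    if se == 0:
        return mean if size is None else np.full(size, mean)
    if se**2 >= mean * (1 - mean):
        raise ValidationError(
            f"infeasible beta moments: se^2={se**2:.4g} >= mean(1-mean)={mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / se**2 - 1
    return rng.beta(mean * nu, (1 - mean) * nu, size=size)


@dataclass(frozen=True)
class PSAResult:
    """Draw-level PSA output for one population."""

    population: str
    n_iterations: int
    seed: int
    wtp: float
    draws: pd.DataFrame  # columns: cost_a, qalys_a, cost_b, qalys_b, delta_cost, delta_qalys, inmb

    @property
    def probability_cost_effective(self) -> float:
        return float((self.draws["inmb"] > 0).mean())


def psa(
    config: AnalysisConfig,
    population: str,
    n_iter: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Per draw, every cost component (gamma) and both utilities (beta, shared
    across arms) are resampled with se = se_fraction * mean; Weibull survival
    parameters stay fixed, so each arm's trace is computed once.  Reproducible
    for a given seed.
    """
    n_iter = config.psa.iterations if n_iter is None else n_iter
    seed = config.psa.seed if seed is None else seed
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    f = config.psa.se_fraction
    settings = config.settings

    traces = {
        arm: build_trace(
            config.populations[population][arm]["pfs"],
            config.populations[population][arm]["os"],
            settings,
        )
        for arm in ARMS
    }

    rows = []
    for _ in range(n_iter):
        u_pfs = float(sample_beta(config.utilities.u_pfs, f * config.utilities.u_pfs, rng))
        u_pd = float(sample_beta(config.utilities.u_pd, f * config.utilities.u_pd, rng))
        utilities = UtilitySet(u_pfs=u_pfs, u_pd=min(u_pd, u_pfs))
        outcome = {}
        for arm in ARMS:
            prof = config.costs[arm]
            comps = {
                k: float(sample_gamma(v, f * v, rng)) if v > 0 else 0.0
                for k, v in prof.pfs_components.items()
            }
            pd_cost = (
                float(sample_gamma(prof.pd_per_cycle, f * prof.pd_per_cycle, rng))
                if prof.pd_per_cycle > 0
                else 0.0
            )
            outcome[arm] = economics.accrue(
                traces[arm], CostProfile(comps, pd_cost), utilities, settings
            )
        (ca, ea), (cb, eb) = outcome["intervention"], outcome["comparator"]
        rows.append(
            {
                "cost_a": ca,
                "qalys_a": ea,
                "cost_b": cb,
                "qalys_b": eb,
                "delta_cost": ca - cb,
                "delta_qalys": ea - eb,
                "inmb": (ea - eb) * settings.wtp_per_qaly - (ca - cb),
            }
        )
    return PSAResult(
        population=population,
        n_iterations=n_iter,
        seed=seed,
        wtp=settings.wtp_per_qaly,
        draws=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability_cost_effective": self.probability})


def ceac(result: PSAResult, wtp_grid: list[float] | np.ndarray) -> CEACCurve:
    """For each WTP value, the fraction of draws with delta_qalys*WTP - delta_cost > 0."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("wtp_grid must be non-empty")
    dq = result.draws["delta_qalys"].to_numpy()
    dc = result.draws["delta_cost"].to_numpy()
    prob = np.array([(dq * w - dc > 0).mean() for w in grid])
    return CEACCurve(wtp=grid, probability=prob)
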