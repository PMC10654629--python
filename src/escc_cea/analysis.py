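"""High-level analysis runners producing the standard CSV reports.

Each runner takes a validated :class:`AnalysisConfig` and a population key,
executes the corresponding analysis, and (optionally) writes CSV outputs plus a
run-metadata JSON recording the seed, a configuration hash and the package
version, so that runs are traceable and re-runnable.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from . import __version__
from .config import AnalysisConfig, config_hash
from .economics import CEResult
from .model import evaluate_population
from .sensitivity import CEACCurve, OWSAResult, PSAResult, ceac, owsa, psa

__all__ = ["run_base_case", "run_owsa", "run_psa", "base_case_frame"]

logger = logging.getLogger(__name__)


def _write_metadata(outdir: Path, population: str, seed: int | None, config: AnalysisConfig) -> None:
    meta = {
        "package_version": __version__,
        "population": population,
        "seed": seed,
        "config_hash": config_hash(config),
        "wtp_per_qaly": config.settings.wtp_per_qaly,
        "horizon_cycles": config.settings.horizon_cycles,
    }
    (outdir / f"run_metadata_{population}.json").write_text(json.dumps(meta, indent=2))


def base_case_frame(result: CEResult, population: str) -> pd.DataFrame:
    """Base-case results as a two-column table (one column per strategy)."""
    fmt_icer = round(result.icer, 2) if result.icer_defined else math.nan
    return pd.DataFrame(
        {
            "result": [
                "cost_usd",
                "incremental_cost_usd",
                "effectiveness_qalys",
                "incremental_effectiveness_qalys",
                "icer_usd_per_qaly",
                "inmb_usd",
            ],
            "intervention": [
                round(result.arm_a.cost, 2),
                round(result.delta_cost, 2),
                round(result.arm_a.qalys, 4),
                round(result.delta_qalys, 4),
                fmt_icer,
                round(result.inmb, 2),
            ],
            "comparator": [
                round(result.arm_b.cost, 2),
                math.nan,
                round(result.arm_b.qalys, 4),
                math.nan,
                math.nan,
                math.nan,
            ],
        }
    ).assign(population=population)


def run_base_case(
    config: AnalysisConfig, population: str, outdir: str | Path | None = None
) -> CEResult:
    """Deterministic base-case run; optionally writes the results CSV."""
    result = evaluate_population(config, population)
    logger.info(
        "base case %s: dC=%.2f dE=%.4f ICER=%.2f INMB=%.2f",
        population,
        result.delta_cost,
        result.delta_qalys,
        result.icer,
        result.inmb,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base_case_frame(result, population).to_csv(
            outdir / f"base_case_{population}.csv", index=False
        )
        _write_metadata(outdir, population, None, config)
    return result


def run_owsa(
    config: AnalysisConfig,
    population: str,
    outdir: str | Path | None = None,
    plot: bool = False,
) -> OWSAResult:
    """One-way sensitivity analysis; optionally writes the ranked tornado CSV."""
    result = owsa(config, population)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(outdir / f"tornado_{population}.csv", index=False)
        _write_metadata(outdir, population, None, config)
        if plot:
            from .plots import tornado_plot

            tornado_plot(result, outdir / f"tornado_{population}.png")
    return result


def run_psa(
    config: AnalysisConfig,
    population: str,
    outdir: str | Path | None = None,
    seed: int | None = None,
    plot: bool = False,
) -> tuple[PSAResult, CEACCurve]:
    """Probabilistic sensitivity analysis plus CEAC; optionally writes CSVs."""
    result = psa(config, population, seed=seed)
    curve = ceac(result, config.psa.wtp_grid)
    logger.info(
        "PSA %s: P(cost-effective at WTP %.2f) = %.3f",
        population,
        result.wtp,
        result.probability_cost_effective,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        draws = result.draws.round(6)
        draws.to_csv(outdir / f"psa_draws_{population}.csv", index=False)
        curve.to_frame().to_csv(outdir / f"ceac_{population}.csv", index=False)
        _write_metadata(outdir, population, result.seed, config)
        if plot:
            from .plots import ceac_plot, ce_plane_plot

            ceac_plot(curve, result.wtp, outdir / f"ceac_{population}.png")
            ce_plane_plot(result, outdir / f"ce_plane_{population}.png")
    return result, curve
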