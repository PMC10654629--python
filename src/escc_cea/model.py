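"""Core model evaluation: from a configuration to comparative results."""

from __future__ import annotations

from .config import AnalysisConfig, StrategyDefinition
from .economics import CEResult, UtilitySet, accrue, compare
from .markov import ModelSettings, build_trace

__all__ = ["evaluate_arm", "evaluate_population"]


def evaluate_arm(
    strategy: StrategyDefinition, utilities: UtilitySet, settings: ModelSettings
) -> tuple[float, float]:
    """Discounted (cost, QALYs) for one strategy over the model horizon."""
    trace = build_trace(strategy.pfs, strategy.os, settings)
    return accrue(trace, strategy.costs, utilities, settings)


def evaluate_population(config: AnalysisConfig, population: str) -> CEResult:
    """Full deterministic model run for one population: intervention vs comparator."""
    a = evaluate_arm(config.strategy(population, "intervention"), config.utilities, config.settings)
    b = evaluate_arm(config.strategy(population, "comparator"), config.utilities, config.settings)
    return compare(a, b, config.settings.wtp_per_qaly)
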