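"""Three-state cohort model: progression-free (PFS), progressed (PD), death.

State occupancy over monthly cycles is obtained by the partitioned-survival
identity: the PFS curve gives the progression-free fraction, the OS curve gives
the fraction alive, and the progressed fraction is their difference.  This is
the unique occupancy consistent with both fitted curves and with the per-cycle
Weibull exit probability P(t, u) = 1 - exp{lambda*(t-u)**gamma - lambda*t**gamma};
the split of PFS exits between PD and death is thereby defined residually.
Independently fitted curves can cross (S_PFS > S_OS); the implied negative PD
occupancy is clamped to zero with the mass assigned to death so that every row
still sums to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .survival import WeibullParams, transition_probability, weibull_survival

__all__ = ["ModelSettings", "CohortTrace", "TransitionCheckReport", "build_trace", "trace_transition_check"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings.

    cycle_length_months is fixed at 1; horizon_cycles defaults to 120 (10 years);
    costs and utilities are discounted at 5% per year; the willingness-to-pay
    threshold defaults to $37,663.26/QALY (three times China's per-capita GDP).
    half_cycle_correction applies trapezoid weights (half weight on the first and
    last cycle boundary), the convention under which the model reproduces the
    published base-case totals.
    """

    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    discount_rate_annual: float = 0.05
    wtp_per_qaly: float = 37_663.26
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if not (0 <= self.discount_rate_annual < 1):
            raise ValidationError("discount_rate_annual must be in [0, 1)")
        if not (self.wtp_per_qaly > 0):
            raise ValidationError("wtp_per_qaly must be positive")
        if self.cycle_length_months != 1.0:
            raise ValidationError("cycle length is fixed at 1 month")


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle state occupancy; rows indexed by cycle 0..horizon."""

    pfs: np.ndarray
    pd_state: np.ndarray
    death: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pfs)
        if not (len(self.pd_state) == len(self.death) == n):
            raise ValidationError("trace columns must have equal length")
        total = self.pfs + self.pd_state + self.death
        if np.max(np.abs(total - 1.0)) > 1e-10:
            raise ValidationError("state occupancy must sum to 1 at every cycle")
        for name, col in (("pfs", self.pfs), ("pd", self.pd_state), ("death", self.death)):
            if np.any(col < -1e-12) or np.any(col > 1 + 1e-12):
                raise ValidationError(f"{name} occupancy outside [0, 1]")
        if abs(self.pfs[0] - 1.0) > 1e-12:
            raise ValidationError("cohort must start fully progression-free")

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.pfs)),
                "pfs": self.pfs,
                "pd": self.pd_state,
                "death": self.death,
            }
        )


def build_trace(
    pfs: WeibullParams, os: WeibullParams, settings: ModelSettings
) -> CohortTrace:
    """Build the partitioned-survival cohort trace over the model horizon.

    At cycle t: pfs(t) = S_PFS(t); death(t) = 1 - S_OS(t);
    pd(t) = max(0, S_OS(t) - S_PFS(t)).
    """
    cycles = np.arange(settings.horizon_cycles + 1, dtype=float)
    s_pfs = weibull_survival(pfs, cycles)
    s_os = weibull_survival(os, cycles)
    pd_occ = s_os - s_pfs
    n_clamped = int(np.sum(pd_occ < 0))
    if n_clamped:
        logger.info(
            "PFS curve exceeds OS curve at %d cycle(s); clamping PD occupancy to 0",
            n_clamped,
        )
    pd_occ = np.maximum(pd_occ, 0.0)
    pfs_occ = np.minimum(s_pfs, s_os)  # keep conservation when curves cross
    return CohortTrace(pfs=pfs_occ, pd_state=pd_occ, death=1.0 - s_os)


@dataclass(frozen=True)
class TransitionCheckReport:
    """Diagnostic comparing the trace against the Weibull exit-probability recursion."""

    max_pfs_discrepancy: float
    min_death_increment: float

    @property
    def consistent(self) -> bool:
        return self.max_pfs_discrepancy < 1e-10 and self.min_death_increment >= -1e-12


def trace_transition_check(
    trace: CohortTrace, pfs: WeibullParams, os: WeibullParams
) -> TransitionCheckReport:
    """Verify the trace against the per-cycle transition-probability recursion.

    The fraction leaving PFS during cycle t must equal
    transition_probability(pfs, t, 1) * pfs(t-1), and death increments must be
    non-negative; returns the worst discrepancies found.
    """
    max_disc = 0.0
    for t in range(1, trace.n_cycles + 1):
        p_exit = transition_probability(pfs, float(t), 1.0)
        expected_pfs = trace.pfs[t - 1] * (1.0 - p_exit)
        max_disc = max(max_disc, abs(trace.pfs[t] - expected_pfs))
    death_inc = np.diff(trace.death)
    return TransitionCheckReport(
        max_pfs_discrepancy=float(max_disc),
        min_death_increment=float(death_inc.min()) if len(death_inc) else 0.0,
    )
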