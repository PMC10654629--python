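"""Discounted cost/QALY accrual and comparative cost-effectiveness statistics.

Costs follow the per-cycle convention of the source cost table: every
treatment-phase component (drug, chemotherapy backbone, antiemetics, tests,
adverse-event management, hospitalization) accrues while the patient occupies
the progression-free state, and the subsequent-therapy cost accrues while in
the progressed state.  Utilities are annual-scale, so each monthly cycle
contributes occupancy x utility / 12 QALYs.  Both streams are discounted at an
annual rate by elapsed months, d(t) = (1 + r)**(-t/12).

Decision statistics for intervention (arm A) versus comparator (arm B):

    ICER = (C_A - C_B) / (E_A - E_B)        [$ per QALY]
    INMB = (E_A - E_B) * WTP - (C_A - C_B)  [$]

The intervention is deemed cost-effective at the threshold when INMB > 0
(equivalently, when ICER < WTP for a positive QALY gain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .exceptions import ValidationError
from .markov import CohortTrace, ModelSettings

__all__ = [
    "CostProfile",
    "UtilitySet",
    "ArmOutcome",
    "CEResult",
    "discount_factor",
    "accrue",
    "compare",
    "donation_schedule_cost",
]


@dataclass(frozen=True)
class CostProfile:
    """Per-cycle costs (USD) for one strategy.

    ``pfs_components`` maps component names (drug, chemotherapy, antiemetics,
    tests, adverse_events, hospitalization, ...) to USD per cycle accrued in the
    progression-free state; ``pd_per_cycle`` is the subsequent-therapy cost
    accrued per cycle in the progressed state.  ``drug_multiplier`` optionally
    rescales one named component per cycle (used for donation schedules).
    """

    pfs_components: Mapping[str, float]
    pd_per_cycle: float
    drug_multiplier: tuple[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        for name, v in self.pfs_components.items():
            if v < 0:
                raise ValidationError(f"cost component {name!r} is negative: {v}")
        if self.pd_per_cycle < 0:
            raise ValidationError("pd_per_cycle must be >= 0")
        if self.drug_multiplier is not None:
            comp, mults = self.drug_multiplier
            if comp not in self.pfs_components:
                raise ValidationError(f"unknown component {comp!r} in drug_multiplier")
            if any(m < 0 or m > 1 for m in mults):
                raise ValidationError("multipliers must lie in [0, 1]")

    @property
    def pfs_total(self) -> float:
        return float(sum(self.pfs_components.values()))

    def pfs_cost_at_cycle(self, cycle: int) -> float:
        """Treatment-phase cost at a given cycle, honouring any schedule."""
        if self.drug_multiplier is None:
            return self.pfs_total
        comp, mults = self.drug_multiplier
        m = mults[cycle] if cycle < len(mults) else 0.0
        return self.pfs_total - self.pfs_components[comp] * (1.0 - m)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities: progression-free, progressed; death is fixed at 0."""

    u_pfs: float = 0.68
    u_pd: float = 0.42

    def __post_init__(self) -> None:
        if not (0 <= self.u_pd <= self.u_pfs <= 1):
            raise ValidationError(
                f"need 0 <= u_pd <= u_pfs <= 1, got u_pfs={self.u_pfs}, u_pd={self.u_pd}"
            )


def discount_factor(cycle: int | np.ndarray, annual_rate: float) -> float | np.ndarray:
    """Discount factor (1 + r)**(-cycle/12) for a monthly cycle index."""
    if annual_rate < 0:
        raise ValidationError("annual_rate must be >= 0")
    c = np.asarray(cycle, dtype=float)
    if np.any(c < 0):
        raise ValidationError("cycle must be >= 0")
    out = (1.0 + annual_rate) ** (-c / 12.0)
    return float(out) if out.ndim == 0 else out


def accrue(
    trace: CohortTrace,
    costs: CostProfile,
    utilities: UtilitySet,
    settings: ModelSettings,
) -> tuple[float, float]:
    """Accrue discounted total cost (USD) and QALYs over the trace.

    With half-cycle correction (the default) cycle boundaries get trapezoid
    weights (0.5 at cycles 0 and H, 1 elsewhere); otherwise accrual runs over
    cycle ends 1..H only.
    """
    if trace.n_cycles != settings.horizon_cycles:
        raise ValidationError(
            f"trace horizon {trace.n_cycles} != settings horizon {settings.horizon_cycles}"
        )
    cycles = np.arange(trace.n_cycles + 1)
    d = discount_factor(cycles, settings.discount_rate_annual)
    pfs_cost = np.array([costs.pfs_cost_at_cycle(int(t)) for t in cycles])
    cost_flow = d * (trace.pfs * pfs_cost + trace.pd_state * costs.pd_per_cycle)
    qaly_flow = d * (trace.pfs * utilities.u_pfs + trace.pd_state * utilities.u_pd) / 12.0
    if settings.half_cycle_correction:
        w = np.ones_like(d)
        w[0] = w[-1] = 0.5
        return float(np.sum(w * cost_flow)), float(np.sum(w * qaly_flow))
    return float(np.sum(cost_flow[1:])), float(np.sum(qaly_flow[1:]))


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for a single strategy."""

    cost: float
    qalys: float


@dataclass(frozen=True)
class CEResult:
    """Comparative cost-effectiveness result: intervention (A) vs comparator (B)."""

    arm_a: ArmOutcome
    arm_b: ArmOutcome
    wtp: float
    delta_cost: float
    delta_qalys: float
    icer: float  # NaN when delta_qalys == 0
    icer_defined: bool
    inmb: float
    cost_effective: bool
    dominance: str  # "", "a_dominates", "b_dominates"


def compare(
    arm_a: tuple[float, float], arm_b: tuple[float, float], wtp: float
) -> CEResult:
    """Compute ICER/INMB for arm A (intervention) versus arm B (comparator).

    Deltas are A - B.  A zero QALY difference leaves the ICER undefined (NaN)
    while the INMB is still reported.  Dominance (one arm cheaper AND more
    effective) is labelled; the ICER is then not a decision quantity.
    """
    ca, ea = arm_a
    cb, eb = arm_b
    dc, de = ca - cb, ea - eb
    if de != 0:
        icer = dc / de
        icer_defined = True
    else:
        icer = math.nan
        icer_defined = False
    inmb = de * wtp - dc
    if dc < 0 and de > 0:
        dom = "a_dominates"
    elif dc > 0 and de < 0:
        dom = "b_dominates"
    else:
        dom = ""
    return CEResult(
        arm_a=ArmOutcome(ca, ea),
        arm_b=ArmOutcome(cb, eb),
        wtp=wtp,
        delta_cost=dc,
        delta_qalys=de,
        icer=icer,
        icer_defined=icer_defined,
        inmb=inmb,
        cost_effective=inmb > 0,
        dominance=dom,
    )


def donation_schedule_cost(
    base: CostProfile,
    schedule: Callable[[int], float],
    cap_cycles: int,
    drug_component: str = "serplulimab",
) -> CostProfile:
    """Apply a patient-assistance cost schedule to the drug component.

    ``schedule(cycle)`` returns the fraction of the list price paid at that
    cycle (in [0, 1]); after ``cap_cycles`` the drug contributes no cost.  This
    expresses pay/free block programmes (e.g. self-fund 600 mg, receive 600 mg
    free, self-fund another 600 mg, then free until progression, capped at two
    years) as explicit per-cycle multipliers.
    """
    if cap_cycles < 0:
        raise ValidationError("cap_cycles must be >= 0")
    mults = []
    for t in range(cap_cycles):
        m = float(schedule(t))
        if m < 0 or m > 1:
            raise ValidationError(f"multiplier at cycle {t} outside [0, 1]: {m}")
        mults.append(m)
    return CostProfile(
        pfs_components=dict(base.pfs_components),
        pd_per_cycle=base.pd_per_cycle,
        drug_multiplier=(drug_component, tuple(mults)),
    )
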