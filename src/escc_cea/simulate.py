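"""Synthetic two-arm trial data and digitized-KM fixtures.

Emulates a first-line phase III trial with 2:1 allocation, Weibull PFS/OS event
times and administrative censoring at roughly the reported median follow-up
(~15 months), so that the reconstruction-and-fitting front end can be exercised
end to end without any external data.

PFS and OS per subject are comonotone: a single uniform draw drives the inverse
transform of both curves, and PFS is additionally clamped to min(PFS, OS).
Wherever the PFS curve lies below the OS curve (true over any realistic horizon
for the parameter sets shipped here) the clamp is inactive and both marginals
are exactly the specified Weibulls, which is what parameter-recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .exceptions import ValidationError
from .survival import DigitizedKM, PseudoIPD, WeibullParams

__all__ = ["TrialSimSpec", "TrialData", "simulate_trial", "km_estimate", "make_digitized_fixture"]


@dataclass(frozen=True)
class TrialSimSpec:
    """Specification of a simulated two-arm trial (2:1 allocation by default)."""

    n_intervention: int = 368
    n_comparator: int = 184
    pfs_intervention: WeibullParams = WeibullParams(0.0594, 1.275)
    os_intervention: WeibullParams = WeibullParams(0.0119, 1.478)
    pfs_comparator: WeibullParams = WeibullParams(0.0595, 1.532)
    os_comparator: WeibullParams = WeibullParams(0.0158, 1.482)
    admin_censor_time: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention < 2 or self.n_comparator < 2:
            raise ValidationError("need at least 2 subjects per arm")
        if self.admin_censor_time <= 0:
            raise ValidationError("admin_censor_time must be > 0")


@dataclass(frozen=True)
class TrialData:
    """Per-arm pseudo-IPD for both endpoints."""

    pfs_intervention: PseudoIPD
    os_intervention: PseudoIPD
    pfs_comparator: PseudoIPD
    os_comparator: PseudoIPD


def _inverse_transform(u: np.ndarray, params: WeibullParams) -> np.ndarray:
    # S(t) = u  =>  t = (-ln u / lambda)**(1/gamma)
    return (-np.log(u) / params.scale_lambda) ** (1.0 / params.shape_gamma)


def _arm(
    rng: np.random.Generator,
    n: int,
    pfs: WeibullParams,
    os: WeibullParams,
    censor_time: float,
) -> tuple[PseudoIPD, PseudoIPD]:
    u = rng.uniform(size=n)
    t_os = _inverse_transform(u, os)
    t_pfs = np.minimum(_inverse_transform(u, pfs), t_os)
    out = []
    for t_event in (t_pfs, t_os):
        obs = np.minimum(t_event, censor_time)
        event = (t_event <= censor_time).astype(int)
        obs = np.maximum(obs, 1e-9)
        out.append(PseudoIPD(tuple(float(x) for x in obs), tuple(int(x) for x in event)))
    return out[0], out[1]


def simulate_trial(spec: TrialSimSpec) -> TrialData:
    """Simulate coupled PFS/OS event times with administrative censoring.

    Event times come from the specified Weibulls by inverse transform; times
    beyond ``admin_censor_time`` are recorded as censored at that time.  For
    every subject PFS time <= OS time.  Reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    pfs_i, os_i = _arm(
        rng, spec.n_intervention, spec.pfs_intervention, spec.os_intervention, spec.admin_censor_time
    )
    pfs_c, os_c = _arm(
        rng, spec.n_comparator, spec.pfs_comparator, spec.os_comparator, spec.admin_censor_time
    )
    return TrialData(pfs_i, os_i, pfs_c, os_c)


def km_estimate(ipd: PseudoIPD, risk_times: list[float] | None = None) -> DigitizedKM:
    """Kaplan-Meier product-limit curve of a pseudo-IPD set.

    The curve is reported at the distinct event times (survival steps only at
    events); a numbers-at-risk table is attached at ``risk_times`` when given,
    otherwise at integer months across follow-up.
    """
    if len(ipd) == 0:
        raise ValidationError("km_estimate needs at least one record")
    t = np.asarray(ipd.times, dtype=float)
    e = np.asarray(ipd.events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        # flat curve: a single point at the longest follow-up
        points = ((float(t.max()), 1.0),)
    else:
        surv = kmf.survival_function_at_times(event_times).to_numpy()
        points = tuple((float(tt), float(ss)) for tt, ss in zip(event_times, surv))
        t_max = float(t.max())
        if t_max > event_times[-1]:
            points = points + ((t_max, float(points[-1][1])),)
    if risk_times is None:
        risk_times = list(np.arange(0.0, float(t.max()) + 1.0, 1.0))
    risk = tuple(
        (float(rt), int(np.sum(t >= rt))) for rt in risk_times if np.sum(t >= rt) > 0
    )
    return DigitizedKM(points=points, n_total=len(ipd), risk_table=risk)


def make_digitized_fixture(
    km: DigitizedKM, n_points: int, noise_sd: float = 0.005, seed: int = 0
) -> DigitizedKM:
    """Emulate graphical digitization of a KM plot.

    Samples ``n_points`` time points evenly across follow-up, reads the step
    function there, perturbs survival with truncated Gaussian noise of the
    given standard deviation and restores monotonicity by a running minimum.
    """
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = km.times
    survs = km.survival
    grid = np.linspace(times[0], times[-1], n_points)
    # step-function lookup: survival of the last point at or before each grid time
    idx = np.searchsorted(times, grid, side="right") - 1
    s = np.where(idx >= 0, survs[np.clip(idx, 0, None)], 1.0)
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=len(s))
    s = np.clip(s, 0.0, 1.0)
    s = np.minimum.accumulate(s)
    # strictly increasing times are guaranteed by linspace for distinct endpoints
    return DigitizedKM(
        points=tuple((float(tt), float(ss)) for tt, ss in zip(grid, s)),
        n_total=km.n_total,
        risk_table=km.risk_table,
    )
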