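"""Parametric Weibull survival machinery.

The economic model extrapolates progression-free and overall survival with the
two-parameter Weibull model

    S(t) = exp(-lambda * t**gamma),        lambda > 0, gamma > 0,

with ``t`` in months, so ``lambda`` carries units of month**-gamma.  gamma > 1
corresponds to an increasing hazard, as is typical for advanced-cancer cohorts.

Besides curve evaluation, this module implements the front end that turns a
digitized Kaplan-Meier curve (coordinates read off a published figure, plus an
optional numbers-at-risk table) into pseudo individual-patient data (pseudo-IPD)
and fits the Weibull by right-censored maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import (
    FittingError,
    InfeasibleReconstructionError,
    ValidationError,
)

__all__ = [
    "WeibullParams",
    "DigitizedKM",
    "PseudoIPD",
    "WeibullFit",
    "weibull_survival",
    "transition_probability",
    "median_survival",
    "mean_survival",
    "reconstruct_ipd",
    "fit_weibull_mle",
]


@dataclass(frozen=True)
class WeibullParams:
    """Scale (lambda, month**-gamma) and shape (gamma) of a Weibull survival curve."""

    scale_lambda: float
    shape_gamma: float

    def __post_init__(self) -> None:
        if not (self.scale_lambda > 0):
            raise ValidationError(f"scale_lambda must be > 0, got {self.scale_lambda}")
        if not (self.shape_gamma > 0):
            raise ValidationError(f"shape_gamma must be > 0, got {self.shape_gamma}")


@dataclass(frozen=True)
class DigitizedKM:
    """A Kaplan-Meier curve as digitized coordinates.

    ``points`` are (time in months, survival probability) pairs with strictly
    increasing times and non-increasing survival.  ``risk_table`` optionally
    gives (time, number at risk) pairs as printed under a published figure.
    """

    points: tuple[tuple[float, float], ...]
    n_total: int
    risk_table: tuple[tuple[float, int], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValidationError("DigitizedKM needs at least one point")
        times = [t for t, _ in self.points]
        survs = [s for _, s in self.points]
        if any(t < 0 for t in times):
            raise ValidationError("times must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")
        if survs[0] > 1 + 1e-12:
            raise ValidationError("first survival value exceeds 1")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(survs, survs[1:])):
            raise ValidationError("survival must be non-increasing")
        if any(s < -1e-12 for s in survs):
            raise ValidationError("survival must be >= 0")
        if self.n_total <= 0:
            raise ValidationError("n_total must be positive")
        if self.risk_table is not None and any(n < 0 for _, n in self.risk_table):
            raise ValidationError("numbers at risk must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)

    def to_csv(self, path: str | Path, risk_path: str | Path | None = None) -> None:
        pd.DataFrame(self.points, columns=["time", "survival"]).to_csv(path, index=False)
        if risk_path is not None and self.risk_table is not None:
            pd.DataFrame(self.risk_table, columns=["time", "n_risk"]).to_csv(
                risk_path, index=False
            )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_total: int,
        risk_path: str | Path | None = None,
    ) -> "DigitizedKM":
        df = pd.read_csv(path)
        risk = None
        if risk_path is not None:
            rdf = pd.read_csv(risk_path)
            risk = tuple((float(t), int(n)) for t, n in zip(rdf["time"], rdf["n_risk"]))
        return cls(
            points=tuple((float(t), float(s)) for t, s in zip(df["time"], df["survival"])),
            n_total=n_total,
            risk_table=risk,
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed individual patient data: (time, event) with event=1, censored=0."""

    times: tuple[float, ...]
    events: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.events):
            raise ValidationError("times and events must have equal length")
        if any(t <= 0 for t in self.times):
            raise ValidationError("every time must be > 0")
        if any(e not in (0, 1) for e in self.events):
            raise ValidationError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(sum(self.events))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(tuple(float(t) for t in df["time"]), tuple(int(e) for e in df["event"]))


def weibull_survival(params: WeibullParams, t: float | np.ndarray) -> float | np.ndarray:
    """Survival function S(t) = exp(-lambda * t**gamma) at time ``t`` months."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    out = np.exp(-params.scale_lambda * t_arr**params.shape_gamma)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def transition_probability(params: WeibullParams, t: float, u: float) -> float:
    """Probability of leaving the state during the ``u``-cycle interval ending at ``t``.

    P(t, u) = 1 - exp{lambda*(t-u)**gamma - lambda*t**gamma}; for u=1 this is the
    per-cycle conditional exit probability 1 - S(t)/S(t-1).
    """
    if u < 0 or t < u:
        raise ValidationError(f"need t >= u >= 0, got t={t}, u={u}")
    lam, gam = params.scale_lambda, params.shape_gamma
    return -math.expm1(lam * (t - u) ** gam - lam * t**gam)


def median_survival(params: WeibullParams) -> float:
    """Closed-form median: (ln 2 / lambda)**(1/gamma) months."""
    return (math.log(2.0) / params.scale_lambda) ** (1.0 / params.shape_gamma)


def mean_survival(params: WeibullParams) -> float:
    """Closed-form mean: lambda**(-1/gamma) * Gamma(1 + 1/gamma) months."""
    g = params.shape_gamma
    return params.scale_lambda ** (-1.0 / g) * float(special.gamma(1.0 + 1.0 / g))


# ---------------------------------------------------------------------------
# Pseudo-IPD reconstruction from a digitized Kaplan-Meier curve
# ---------------------------------------------------------------------------


def _reconstruct_no_risk_table(km: DigitizedKM, n: int) -> tuple[list[float], list[int]]:
    # Censoring only at the final follow-up time: alive counts follow the curve
    # directly and the terminal plateau maps to administratively censored subjects.
    times = km.times
    survs = km.survival
    alive_prev = n
    rec_t: list[float] = []
    rec_e: list[int] = []
    for t, s in zip(times, survs):
        alive = int(round(n * s))
        d = alive_prev - alive
        if d > 0:
            rec_t.extend([float(t)] * d)
            rec_e.extend([1] * d)
        alive_prev = min(alive_prev, alive) if d > 0 else alive_prev
    if alive_prev > 0:
        t_end = float(times[-1])
        rec_t.extend([t_end] * alive_prev)
        rec_e.extend([0] * alive_prev)
    return rec_t, rec_e


def _reconstruct_with_risk_table(km: DigitizedKM, n: int) -> tuple[list[float], list[int]]:
    # Interval form: between consecutive risk-table times, events reproduce the
    # digitized survival drops and censorings are spread uniformly so the at-risk
    # count at the next risk-table time matches the published number.
    times = km.times
    survs = km.survival
    risk = list(km.risk_table or [])
    if not risk:
        return _reconstruct_no_risk_table(km, n)
    # Interval boundaries; extend past the last digitized time so every point falls
    # in exactly one interval.
    bounds = [t for t, _ in risk] + [float(times[-1]) + 1e-9]
    n_at = [nr for _, nr in risk]

    rec_t: list[float] = []
    rec_e: list[int] = []
    at_risk = n
    s_hat = 1.0  # reconstructed KM value
    for k in range(len(risk)):
        lo, hi = bounds[k], bounds[k + 1]
        idx = [i for i in range(len(times)) if lo < times[i] <= hi or (k == 0 and times[i] == lo)]
        pts = [(float(times[i]), float(survs[i])) for i in idx]
        target_next = n_at[k + 1] if k + 1 < len(n_at) else None

        # Pass 1: events assuming no censoring inside the interval.
        r = at_risk
        s = s_hat
        d_total = 0
        for t, sv in pts:
            if r <= 0 or s <= 0:
                break
            d = int(round(r * max(0.0, 1.0 - sv / s)))
            d = min(d, r)
            if d > 0:
                s *= 1.0 - d / r
                r -= d
                d_total += d
        # Censor count that reconciles the published next at-risk number.
        if target_next is not None:
            c = max(0, at_risk - d_total - target_next)
        else:
            c = 0
        # Pass 2: interleave uniformly spread censor times with the events.
        censor_times = list(np.linspace(lo, hi, c + 2)[1:-1]) if c > 0 else []
        censor_times = [max(ct, 1e-9) for ct in censor_times]
        merged = sorted(
            [(t, "event_pt", sv) for t, sv in pts] + [(ct, "censor", None) for ct in censor_times]
        )
        r = at_risk
        s = s_hat
        for t, kind, sv in merged:
            if kind == "censor":
                if r > 0:
                    rec_t.append(float(t))
                    rec_e.append(0)
                    r -= 1
            else:
                if r <= 0 or s <= 0:
                    continue
                d = int(round(r * max(0.0, 1.0 - sv / s)))
                d = min(d, r)
                if d > 0:
                    rec_t.extend([float(t)] * d)
                    rec_e.extend([1] * d)
                    s *= 1.0 - d / r
                    r -= d
        at_risk = r
        s_hat = s
    # Any subjects still at risk after the last interval are censored at follow-up end.
    if at_risk > 0:
        t_end = float(times[-1])
        rec_t.extend([t_end] * at_risk)
        rec_e.extend([0] * at_risk)
    return rec_t, rec_e


def reconstruct_ipd(km: DigitizedKM, target_n: int) -> PseudoIPD:
    """Reconstruct pseudo individual-patient data from a digitized KM curve.

    Survival drops are inverted to event counts; the optional numbers-at-risk
    table apportions censoring across intervals (spread uniformly within each),
    otherwise censoring is assumed to occur only at the final follow-up time.
    The KM estimate recomputed from the output matches the input curve to within
    rounding (~1/(2 n)) at the digitized time points.
    """
    if target_n <= 0:
        raise ValidationError("target_n must be positive")
    survs = km.survival
    n_drops = int(np.sum(np.diff(np.concatenate([[1.0], survs])) < -1e-12))
    if target_n < n_drops:
        raise InfeasibleReconstructionError(
            f"target_n={target_n} cannot represent {n_drops} distinct survival drops"
        )
    if km.risk_table is not None:
        rec_t, rec_e = _reconstruct_with_risk_table(km, target_n)
    else:
        rec_t, rec_e = _reconstruct_no_risk_table(km, target_n)
    # Top up with censored records if integer rounding lost subjects.
    if len(rec_t) < target_n:
        t_end = float(km.times[-1])
        deficit = target_n - len(rec_t)
        rec_t.extend([t_end] * deficit)
        rec_e.extend([0] * deficit)
    order = np.argsort(rec_t, kind="stable")
    return PseudoIPD(
        tuple(float(rec_t[i]) for i in order),
        tuple(int(rec_e[i]) for i in order),
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood Weibull fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeibullFit:
    """MLE result: parameters, standard errors, and fit metadata."""

    params: WeibullParams
    se_lambda: float
    se_gamma: float
    loglik: float
    n: int
    n_events: int


def _neg_loglik(log_params: Sequence[float], t: np.ndarray, e: np.ndarray) -> float:
    lam = math.exp(log_params[0])
    gam = math.exp(log_params[1])
    # log hazard for events + log survival for everyone
    with np.errstate(divide="ignore"):
        ll = np.sum(e * (math.log(lam) + math.log(gam) + (gam - 1.0) * np.log(t)))
    ll -= lam * np.sum(t**gam)
    return -float(ll)


def _km_init(t: np.ndarray, e: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of log(-log S_km) vs log t at event times."""
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    n = len(ts)
    at_risk = n
    s = 1.0
    xs, ys = [], []
    i = 0
    while i < n:
        j = i
        d = 0
        c = 0
        while j < n and ts[j] == ts[i]:
            d += es[j]
            c += 1 - es[j]
            j += 1
        if d > 0 and at_risk > 0:
            s *= 1.0 - d / at_risk
            if 0.0 < s < 1.0 and ts[i] > 0:
                xs.append(math.log(ts[i]))
                ys.append(math.log(-math.log(s)))
        at_risk -= d + c
        i = j
    if len(xs) >= 2:
        slope, intercept = np.polyfit(xs, ys, 1)
        gam0 = float(np.clip(slope, 0.05, 20.0))
        lam0 = float(np.clip(math.exp(intercept), 1e-10, 1e6))
        return lam0, gam0
    # exponential fallback
    lam0 = max(e.sum(), 1) / t.sum()
    return float(lam0), 1.0


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def fit_weibull_mle(ipd: PseudoIPD, fix_gamma: float | None = None) -> WeibullFit:
    """Fit Weibull scale/shape by right-censored maximum likelihood.

    Optimizes the log-likelihood

        sum_events [log lambda + log gamma + (gamma-1) log t] - lambda sum_all t**gamma

    in (log lambda, log gamma) space, initialized from a least-squares fit of
    log(-log S_KM) against log t; deterministic for a given input.  With
    ``fix_gamma`` the shape is held fixed and only the scale is estimated
    (``fix_gamma=1`` gives the closed-form exponential MLE events/total time).
    """
    t = np.asarray(ipd.times, dtype=float)
    e = np.asarray(ipd.events, dtype=float)
    n_events = int(e.sum())
    if n_events == 0:
        raise FittingError("all observations censored; Weibull MLE undefined")
    if fix_gamma is None and n_events < 2:
        raise FittingError("need >= 2 events to estimate both scale and shape")

    if fix_gamma is not None:
        if fix_gamma <= 0:
            raise ValidationError("fix_gamma must be > 0")
        gam = float(fix_gamma)
        lam = n_events / float(np.sum(t**gam))  # closed-form profile MLE
        x = np.array([math.log(lam)])
        H = _numeric_hessian(lambda z: _neg_loglik([z[0], math.log(gam)], t, e), x)
        var_loglam = 1.0 / H[0, 0] if H[0, 0] > 0 else math.nan
        se_lam = lam * math.sqrt(var_loglam) if var_loglam == var_loglam else math.nan
        ll = -_neg_loglik([math.log(lam), math.log(gam)], t, e)
        return WeibullFit(WeibullParams(lam, gam), se_lam, 0.0, ll, len(ipd), n_events)

    lam0, gam0 = _km_init(t, e)
    x0 = np.array([math.log(lam0), math.log(gam0)])
    res = optimize.minimize(
        _neg_loglik,
        x0,
        args=(t, e),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    res = optimize.minimize(
        _neg_loglik, res.x, args=(t, e), method="BFGS", options={"gtol": 1e-9}
    )
    lam, gam = math.exp(res.x[0]), math.exp(res.x[1])
    # Delta method from the observed information in log space.
    H = _numeric_hessian(lambda z: _neg_loglik(z, t, e), res.x)
    try:
        cov_log = np.linalg.inv(H)
        se_lam = lam * math.sqrt(max(cov_log[0, 0], 0.0))
        se_gam = gam * math.sqrt(max(cov_log[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_lam = se_gam = math.nan
    return WeibullFit(
        WeibullParams(lam, gam), se_lam, se_gam, -float(res.fun), len(ipd), n_events
    )
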