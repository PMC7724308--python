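"""Parametric survival models on a monthly time axis.

Four candidate families are supported for refitting digitized Kaplan-Meier
curves: Weibull ``S(t) = exp(-lam * t**gamma)``, exponential
``S(t) = exp(-lam * t)``, log-logistic ``S(t) = 1 / (1 + a * t**b)`` and
log-normal ``S(t) = 1 - Phi((ln t - mu) / sigma)``.  The same objects supply
the time-dependent per-cycle transition probabilities
``p_t = 1 - S(t+1) / S(t)`` used by the Markov engine (cycle length is one
month throughout).

Because digitized curves carry no individual-level data, fitting is weighted
nonlinear least squares on the survival probabilities, and the log-likelihood
reported for AIC/BIC is the Gaussian profile likelihood of the residuals --
the standard curve-refit surrogate, comparable across families because every
family sees the same points and weights.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "SurvivalModel",
    "DigitizedCurve",
    "FitResult",
    "survival",
    "cycle_transition_prob",
    "fit_parametric",
    "select_model",
    "read_curve_csv",
    "write_curve_csv",
    "write_fit_table",
]


class Family(str, Enum):
    """Parametric survival family."""

    WEIBULL = "weibull"
    EXPONENTIAL = "exponential"
    LOGLOGISTIC = "loglogistic"
    LOGNORMAL = "lognormal"


#: number of free parameters per family
_N_PARAMS = {
    Family.WEIBULL: 2,
    Family.EXPONENTIAL: 1,
    Family.LOGLOGISTIC: 2,
    Family.LOGNORMAL: 2,
}

#: deterministic tie-break order for model selection
_FAMILY_ORDER = {
    Family.WEIBULL: 0,
    Family.EXPONENTIAL: 1,
    Family.LOGLOGISTIC: 2,
    Family.LOGNORMAL: 3,
}


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric survival function, time in months.

    Parameters by family: weibull ``(lam, gamma)``; exponential ``(lam,)``;
    loglogistic ``(a, b)``; lognormal ``(mu, sigma)``.  All but the
    log-normal ``mu`` must be strictly positive.
    """

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        p = tuple(float(x) for x in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != _N_PARAMS[fam]:
            raise ValueError(
                f"{fam.value} expects {_N_PARAMS[fam]} parameters, got {len(p)}"
            )
        if fam is Family.LOGNORMAL:
            if p[1] <= 0:
                raise ValueError("lognormal sigma must be > 0")
        elif any(x <= 0 for x in p):
            raise ValueError(f"{fam.value} parameters must be > 0, got {p}")

    def survival(self, t):
        """S(t) for scalar or array t >= 0."""
        return survival(self, t)

    def cycle_transition_prob(self, cycle_index: int) -> float:
        return cycle_transition_prob(self, cycle_index)


def survival(model: SurvivalModel, t):
    """Survival probability S(t) of ``model`` at time ``t`` months.

    Accepts scalars or arrays; raises for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival time must be >= 0")
    fam, p = model.family, model.params
    if fam is Family.WEIBULL:
        lam, gamma = p
        s = np.exp(-lam * t_arr**gamma)
    elif fam is Family.EXPONENTIAL:
        (lam,) = p
        s = np.exp(-lam * t_arr)
    elif fam is Family.LOGLOGISTIC:
        a, b = p
        s = 1.0 / (1.0 + a * t_arr**b)
    else:  # lognormal; S(0) = 1 as the limit of the closed form
        mu, sigma = p
        with np.errstate(divide="ignore"):
            z = (np.log(t_arr, where=t_arr > 0, out=np.full_like(t_arr, -np.inf)) - mu) / sigma
        s = 1.0 - ndtr(z)
    return s if np.ndim(t) else float(s)


def cycle_transition_prob(model: SurvivalModel, cycle_index: int) -> float:
    """Per-cycle transition probability ``1 - S(t+1)/S(t)`` at t = cycle_index.

    Saturates at 1 (with a log warning) when S(t) underflows to zero, which
    only happens far beyond the horizons used here.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    s_t = survival(model, float(cycle_index))
    s_t1 = survival(model, float(cycle_index) + 1.0)
    if s_t <= 0.0:
        logger.warning(
            "S(t)=0 at cycle %d for %s%s; saturating transition probability at 1",
            cycle_index, model.family.value, model.params,
        )
        return 1.0
    return min(max(1.0 - s_t1 / s_t, 0.0), 1.0)


def cycle_transition_probs(model: SurvivalModel, n_cycles: int) -> np.ndarray:
    """Vectorized ``1 - S(t+1)/S(t)`` for t = 0..n_cycles-1."""
    t = np.arange(n_cycles + 1, dtype=float)
    s = np.asarray(survival(model, t))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - s[1:] / s[:-1]
    p = np.where(s[:-1] <= 0.0, 1.0, p)
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized (time, survival) points from a published Kaplan-Meier plot.

    ``n_risk_hint`` is an optional initial at-risk count used as a
    pseudo-likelihood weight.
    """

    points: tuple[tuple[float, float], ...]
    n_risk_hint: int | None = None

    def __post_init__(self) -> None:
        pts = tuple((float(t), float(s)) for t, s in self.points)
        object.__setattr__(self, "points", pts)
        t = self.t
        s = self.s
        if np.any(t < 0):
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 0):
            raise ValueError("survival probabilities must be non-increasing")

    @property
    def t(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def s(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FitResult:
    """One family's weighted least-squares refit of a digitized curve."""

    model: SurvivalModel
    loglik: float
    aic: float
    bic: float
    n_points: int
    converged: bool


def _initial_guess(curve: DigitizedCurve, family: Family) -> list[float]:
    """Deterministic optimizer seeds (closed forms from the curve itself)."""
    t, s = curve.t, curve.s
    t_last = t[-1]
    s_last = max(s[-1], 1e-10)
    lam0 = max(-math.log(s_last) / t_last, 1e-8)
    # first crossing of S = 0.5, falling back to the last point
    below = np.nonzero(s <= 0.5)[0]
    t_med = t[below[0]] if below.size else t_last
    t_med = max(t_med, 1e-6)
    if family is Family.EXPONENTIAL:
        return [lam0]
    if family is Family.WEIBULL:
        return [lam0, 1.0]
    if family is Family.LOGLOGISTIC:
        return [1.0 / t_med, 1.0]
    return [math.log(t_med), 1.0]  # lognormal


def fit_parametric(curve: DigitizedCurve, family: Family | str) -> FitResult:
    """Fit one parametric family to a digitized curve.

    Weighted nonlinear least squares on the survival scale; weights are
    proportional to ``n_risk_hint`` (uniform when absent).  ``loglik`` is the
    Gaussian profile log-likelihood of the weighted residuals, from which
    ``aic = 2k - 2 loglik`` and ``bic = k ln(n) - 2 loglik`` with k the
    number of free family parameters.
    """
    family = Family(family)
    n = len(curve)
    if n < 4:
        raise ValueError("need at least 4 digitized points to fit")
    s = curve.s
    if np.all(s == s[0]):
        raise ValueError("degenerate curve: all survival values equal")
    t = curve.t
    w = np.full(n, float(curve.n_risk_hint) if curve.n_risk_hint else 1.0)
    w_norm = w / w.sum()
    sqrt_w = np.sqrt(w_norm * n)  # unit mean weight

    if family is Family.LOGNORMAL:
        lower = [-np.inf, 1e-8]
    else:
        lower = [1e-10] * _N_PARAMS[family]
    upper = [np.inf] * _N_PARAMS[family]

    def resid(theta):
        m = SurvivalModel(family, tuple(theta))
        return sqrt_w * (np.asarray(survival(m, t)) - s)

    x0 = _initial_guess(curve, family)
    try:
        res = optimize.least_squares(
            resid, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
        )
        converged = bool(res.success and np.all(np.isfinite(res.x)))
        theta = tuple(float(x) for x in res.x)
        r = res.fun
    except Exception:  # optimizer failure is reported, not raised
        converged = False
        theta = tuple(x0)
        r = resid(np.array(x0))
    sigma2 = max(float(np.sum(r**2)) / n, 1e-300)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    k = _N_PARAMS[family]
    return FitResult(
        model=SurvivalModel(family, theta),
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * math.log(n) - 2.0 * loglik,
        n_points=n,
        converged=converged,
    )


def fit_all_families(curve: DigitizedCurve) -> list[FitResult]:
    """Fit all four candidate families to the same curve."""
    return [fit_parametric(curve, fam) for fam in Family]


def select_model(fits: Iterable[FitResult]) -> FitResult:
    """Lowest-BIC converged fit; ties by AIC, then fixed family order."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fit to select from")
    return min(
        converged, key=lambda f: (f.bic, f.aic, _FAMILY_ORDER[f.model.family])
    )


# ---------------------------------------------------------------------------
# interchange formats


def read_curve_csv(path) -> DigitizedCurve:
    """Read a digitized curve (`t_months,survival[,n_risk]`)."""
    df = pd.read_csv(path)
    if not {"t_months", "survival"} <= set(df.columns):
        raise ValueError("curve CSV must have columns t_months,survival[,n_risk]")
    hint = int(df["n_risk"].iloc[0]) if "n_risk" in df.columns else None
    return DigitizedCurve(
        points=tuple(zip(df["t_months"].astype(float), df["survival"].astype(float))),
        n_risk_hint=hint,
    )


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    df = pd.DataFrame({"t_months": curve.t, "survival": curve.s})
    if curve.n_risk_hint is not None:
        df["n_risk"] = curve.n_risk_hint
    df.to_csv(path, index=False)


def write_fit_table(fits: Sequence[FitResult], path, selected: FitResult | None = None) -> None:
    """JSON table of fits, one row per family, flagging the selected one."""
    rows = []
    for f in fits:
        rows.append(
            {
                "family": f.model.family.value,
                "params": list(f.model.params),
                "loglik": f.loglik,
                "aic": f.aic,
                "bic": f.bic,
                "n_points": f.n_points,
                "converged": f.converged,
                "selected": selected is not None and f is selected,
            }
        )
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2)
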