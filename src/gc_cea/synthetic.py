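"""Synthetic inputs: pseudo-digitized Kaplan-Meier curves and life tables.

Published trial curves reach the model only as digitized (time, survival)
points, so the generator here produces exactly that artefact from known
parametric ground truth: individual event times drawn by inverse-CDF
sampling, independent exponential censoring, a Kaplan-Meier step estimate,
and additive truncated Gaussian "digitization" noise on an equally spaced
reading grid.  The life-table generator is a Gompertz-Makeham hazard
approximating Chinese all-cause mortality; any real table can be supplied
as an ``age,qx`` CSV instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.special import ndtri

from .survival import DigitizedCurve, Family, SurvivalModel

__all__ = ["KmSimConfig", "simulate_km", "make_life_table"]


@dataclass(frozen=True)
class KmSimConfig:
    """Ground truth and sampling design for one pseudo-digitized curve.

    ``censor_rate`` is the monthly probability of independent censoring
    (0 disables censoring); ``noise_sd`` is the digitization error SD.
    """

    family: Family
    params: tuple[float, ...]
    n_subjects: int = 1000
    censor_rate: float = 0.0
    n_points: int = 60
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_points < 4:
            raise ValueError("need at least 4 grid points")


def _inverse_cdf(model: SurvivalModel, u: np.ndarray) -> np.ndarray:
    """Event times with survival quantile ``u`` (S(t) = u)."""
    fam, p = model.family, model.params
    if fam is Family.WEIBULL:
        lam, gamma = p
        return (-np.log(u) / lam) ** (1.0 / gamma)
    if fam is Family.EXPONENTIAL:
        (lam,) = p
        return -np.log(u) / lam
    if fam is Family.LOGLOGISTIC:
        a, b = p
        return ((1.0 / u - 1.0) / a) ** (1.0 / b)
    mu, sigma = p  # lognormal
    return np.exp(mu + sigma * ndtri(1.0 - u))


def simulate_km(config: KmSimConfig) -> DigitizedCurve:
    """Generate one pseudo-digitized KM curve; deterministic per seed.

    The reading grid is ``n_points`` equally spaced times over (0, T] where
    T is the time at which the true survival function reaches 5% (or the
    last observed time if smaller).  Noise is clipped to [0, 1] and
    monotonicity restored by a running minimum, mimicking how a digitizer
    operator reads a non-increasing step plot.
    """
    rng = np.random.default_rng(config.seed)
    model = SurvivalModel(config.family, config.params)
    u = rng.uniform(size=config.n_subjects)
    event_times = _inverse_cdf(model, np.clip(u, 1e-12, 1.0 - 1e-12))
    if config.censor_rate > 0:
        # exponential censoring with the given monthly probability
        rate = -math.log(1.0 - config.censor_rate)
        censor_times = rng.exponential(scale=1.0 / rate, size=config.n_subjects)
    else:
        censor_times = np.full(config.n_subjects, np.inf)
    observed = np.minimum(event_times, censor_times)
    event_flag = event_times <= censor_times

    kmf = KaplanMeierFitter()
    kmf.fit(observed, event_observed=event_flag)

    # time at which the ground-truth survival falls to 5%
    t_end = float(_inverse_cdf(model, np.array([0.05]))[0])
    t_end = min(t_end, float(observed.max()))
    grid = np.linspace(0.0, t_end, config.n_points + 1)[1:]
    if float(observed.min()) > grid[0]:
        # the KM estimate is still 1 there, which is fine; only a fully
        # censored-out cohort is unusable
        pass
    if not np.any(event_flag):
        raise ValueError("all subjects censored; no events to estimate from")
    s = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    if config.noise_sd > 0:
        s = s + rng.normal(0.0, config.noise_sd, size=s.shape)
    s = np.clip(s, 0.0, 1.0)
    s = np.minimum.accumulate(s)
    return DigitizedCurve(points=tuple(zip(grid, s)), n_risk_hint=config.n_subjects)


def make_life_table(A: float = 5e-5, B: float = 3.5e-5, c: float = 1.094):
    """Gompertz-Makeham life table: qx(age) = 1 - exp(-(A + B c^age)).

    Defaults give qx(56) ~ 0.005 and qx(80) ~ 0.045, a smooth stand-in for
    all-cause mortality of the modelled cohort; ages 0-100 with qx(100)
    forced to 1.  Raises for invalid parameters; hazards that would exceed
    1 before age 100 are clamped.
    """
    from .markov import LifeTable  # local import to avoid a cycle

    if A < 0 or B < 0:
        raise ValueError("A and B must be >= 0")
    if c <= 1:
        raise ValueError("c must be > 1")
    ages = np.arange(101)
    qx = 1.0 - np.exp(-(A + B * np.power(c, ages.astype(float))))
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)
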