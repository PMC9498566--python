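"""Synthetic survival data with known sparse truth.

Replicates are drawn from a Cox model with a Weibull baseline hazard
lambda_0(t) = s r^s t^{s-1} (defaults r=0.1, s=2) and a scenario-specific
log relative risk built from multivariate normal covariates:

* Setting 1 — unit linear effects on the first ``up`` variables.
* Setting 2 — strong linear effects (beta1, default 1) on the first
  up/2 variables and weak ones (beta2, default 0.3) on the next up/2.
* Setting 3 — unit linear effects (total dimension fixed, ``up`` varied).

On top of the linear part, scenarios add nonlinearities: scenario 2 the
quadratics z_{up+1}^2 + z_{up+2}^2, scenario 3 the interactions
5 (z_up z_{up-1} + z_{up-1} z_{up-2}), scenario 4 both.  Setting 3 has a
single hazard form with both quadratics and interactions.  Covariates
are MVN(0, Sigma) with either Sigma_lk = e^{-|l-k|} (an AR(1) structure,
sampled exactly via its Markov representation) or the identity.

Event times come from the inverse-transform of the cumulative hazard
Lambda(t | lp) = (r t)^s e^{lp}:  T = (1/r) (-log U e^{-lp})^{1/s}.
Censoring times are independent exponentials whose rate is calibrated
once per design, by root-finding on a large fixed Monte-Carlo sample, to
hit a target censoring fraction (default 30%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .survival import SurvivalDataset

__all__ = [
    "SimulationDesign",
    "SimulatedReplicate",
    "simulate_covariates",
    "linear_predictor",
    "truth_mask",
    "simulate_survival",
    "calibrate_censoring",
    "generate_replicate",
]

# Dedicated seed for the censoring-rate calibration sample, so every
# replicate of a design shares one calibrated rate.
_CALIBRATION_SEED = 202209
_CALIBRATION_DRAWS = 200_000


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to generate one replicate of a simulation scenario."""

    setting: int = 1
    scenario: int = 1
    p: int = 100
    N: int = 500
    up: int = 10
    corr: str = "ar1"  # "ar1" or "identity"
    beta1: float = 1.0
    beta2: float = 0.3
    r: float = 0.1
    s: float = 2.0
    censor_target: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in (1, 2, 3):
            raise ValueError("setting must be 1, 2 or 3")
        if self.setting == 3:
            if self.scenario != 1:
                raise ValueError("setting 3 has a single hazard form; use scenario=1")
        elif self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be in {1, 2, 3, 4}")
        if self.corr not in ("ar1", "identity"):
            raise ValueError("corr must be 'ar1' or 'identity'")
        if self.up < 1 or self.up > self.p:
            raise ValueError("need 1 <= up <= p")
        if self.has_interactions and self.up < 3:
            raise ValueError("interaction terms reference up-2..up; need up >= 3")
        if self.has_quadratics and self.up + 2 > self.p:
            raise ValueError("quadratic terms reference up+1, up+2; need up + 2 <= p")
        if self.setting == 2 and self.up % 2 != 0:
            raise ValueError("setting 2 splits the linear effects; up must be even")
        if not 0.0 < self.censor_target < 1.0:
            raise ValueError("censor_target must be in (0, 1)")
        if self.r <= 0 or self.s <= 0:
            raise ValueError("Weibull parameters r, s must be > 0")

    @property
    def has_quadratics(self) -> bool:
        return self.setting == 3 or self.scenario in (2, 4)

    @property
    def has_interactions(self) -> bool:
        return self.setting == 3 or self.scenario in (3, 4)

    @property
    def n_important(self) -> int:
        return self.up + (2 if self.has_quadratics else 0)


@dataclass
class SimulatedReplicate:
    """One generated dataset plus its latent ground truth."""

    data: SurvivalDataset
    true_lp: np.ndarray
    truth: np.ndarray  # boolean mask over the p variables
    T: np.ndarray  # latent event times
    C: np.ndarray  # latent censoring times
    censor_rate: float  # the calibrated exponential rate
    design: SimulationDesign


def simulate_covariates(
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    n_cols: int | None = None,
) -> np.ndarray:
    """i.i.d. rows from MVN(0, Sigma) per the design's correlation structure.

    Sigma_lk = e^{-|l-k|} is sampled exactly by the stationary AR(1)
    recursion z_k = rho z_{k-1} + sqrt(1 - rho^2) eps_k with rho = e^{-1}.
    ``n_cols`` restricts generation to the leading columns (their joint
    law is unaffected); used to keep the calibration sample cheap.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.N if n is None else n
    p = design.p if n_cols is None else n_cols
    if design.corr == "identity":
        return rng.standard_normal((n, p))
    rho = np.exp(-1.0)
    sd = np.sqrt(1.0 - rho * rho)
    Z = np.empty((n, p))
    eps = rng.standard_normal((n, p))
    Z[:, 0] = eps[:, 0]
    for k in range(1, p):
        Z[:, k] = rho * Z[:, k - 1] + sd * eps[:, k]
    return Z


def linear_predictor(Z: np.ndarray, design: SimulationDesign) -> np.ndarray:
    """The log relative risk of each sample under the design's hazard."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    up = design.up
    if Z.shape[1] < design.up + (2 if design.has_quadratics else 0):
        raise ValueError("covariate matrix has too few columns for this design")
    if design.setting == 2:
        half = up // 2
        lp = design.beta1 * Z[:, :half].sum(axis=1) + design.beta2 * Z[
            :, half:up
        ].sum(axis=1)
    else:
        lp = Z[:, :up].sum(axis=1)
    if design.has_quadratics:
        lp = lp + Z[:, up] ** 2 + Z[:, up + 1] ** 2
    if design.has_interactions:
        # 1-based indices up-2, up-1, up -> 0-based up-3, up-2, up-1
        lp = lp + 5.0 * (
            Z[:, up - 1] * Z[:, up - 2] + Z[:, up - 2] * Z[:, up - 3]
        )
    return lp


def truth_mask(design: SimulationDesign) -> np.ndarray:
    """Boolean mask of the variables whose index appears in the hazard."""
    mask = np.zeros(design.p, dtype=bool)
    mask[: design.up] = True
    if design.has_quadratics:
        mask[design.up : design.up + 2] = True
    return mask


def _draw_event_times(lp: np.ndarray, design: SimulationDesign,
                      rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=lp.shape)
    return (1.0 / design.r) * (-np.log(u) * np.exp(-lp)) ** (1.0 / design.s)


def calibrate_censoring(design: SimulationDesign) -> float:
    """Exponential censoring rate hitting the design's target censoring fraction.

    Uses the closed form P(C < T | T) = 1 - e^{-rate * T} averaged over a
    fixed 200,000-draw Monte-Carlo sample of event times, and solves for
    the rate by bracketing root-finding.  The calibration sample has its
    own dedicated seed, so the rate is shared by all replicates of a
    design regardless of their seeds.
    """
    return _calibrate_cached(
        design.setting, design.scenario, design.up, design.corr,
        design.beta1, design.beta2, design.r, design.s, design.censor_target,
        # quadratics reference columns up+1, up+2 even when p is larger
        design.up + (2 if design.has_quadratics else 0),
    )


@lru_cache(maxsize=64)
def _calibrate_cached(setting, scenario, up, corr, beta1, beta2, r, s,
                      target, n_cols) -> float:
    design = SimulationDesign(
        setting=setting, scenario=scenario, p=max(n_cols, up + 2), N=1,
        up=up, corr=corr, beta1=beta1, beta2=beta2, r=r, s=s,
        censor_target=target,
    )
    rng = np.random.default_rng(_CALIBRATION_SEED)
    Z = simulate_covariates(design, rng, n=_CALIBRATION_DRAWS, n_cols=n_cols)
    lp = linear_predictor(Z, design)
    T = _draw_event_times(lp, design, rng)

    def censored_fraction_gap(rate: float) -> float:
        return float(np.mean(-np.expm1(-rate * T))) - target

    lo, hi = 1e-12, 1.0
    while censored_fraction_gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError(
                "failed to bracket the censoring rate: target fraction "
                f"{target} unreachable for this design"
            )
    return float(brentq(censored_fraction_gap, lo, hi, xtol=1e-12))


def simulate_survival(
    lp: np.ndarray,
    design: SimulationDesign,
    rng: np.random.Generator,
    censor_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (Y, delta, T, C) given linear predictors.

    T by inverse transform of the Weibull-baseline cumulative hazard,
    C independent exponential with the calibrated rate.
    """
    lp = np.asarray(lp, dtype=float).ravel()
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if censor_rate is None:
        censor_rate = calibrate_censoring(design)
    T = _draw_event_times(lp, design, rng)
    C = rng.exponential(scale=1.0 / censor_rate, size=lp.shape)
    Y = np.minimum(T, C)
    delta = (T <= C).astype(np.int64)
    return Y, delta, T, C


def generate_replicate(design: SimulationDesign) -> SimulatedReplicate:
    """One full replicate: covariates, hazard, event/censoring times, truth."""
    rng = np.random.default_rng(design.seed)
    Z = simulate_covariates(design, rng)
    lp = linear_predictor(Z, design)
    rate = calibrate_censoring(design)
    Y, delta, T, C = simulate_survival(lp, design, rng, censor_rate=rate)
    data = SurvivalDataset(Z=Z, time=Y, event=delta)
    return SimulatedReplicate(
        data=data, true_lp=lp, truth=truth_mask(design), T=T, C=C,
        censor_rate=rate, design=design,
    )


def with_seed(design: SimulationDesign, seed: int) -> SimulationDesign:
    """A copy of the design with a different seed."""
    return replace(design, seed=int(seed))
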