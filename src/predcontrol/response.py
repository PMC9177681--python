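"""Beta-density response model and MAP estimation.

The response (observation) model maps a belief ``theta`` in (0, 1) to
the probability of the observed binary intrusion rating through a beta
density with shape ``a = theta * nu`` and ``b = nu - a``; ``nu`` is a
participant-specific inverse decision noise.  Model accuracy is the
summed negative log-likelihood of the ratings under this density
(lower = better).  Binary outcomes are evaluated at ``clip(y, eps,
1 - eps)`` because the density degenerates at exactly 0/1.

:func:`fit_model` performs MAP estimation of the perceptual parameters
plus ``log nu`` with Gaussian priors in the estimation space, using a
multi-start quasi-Newton (L-BFGS-B) optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, gammaln

from .perceptual import (
    BELIEF_EPS,
    BeliefTrajectory,
    HGFParams,
    KFParams,
    RWParams,
    model_trajectory,
    split_model_id,
    theta_builder,
)
from .sequences import TrialSequence

__all__ = [
    "ObsParams",
    "ModelFit",
    "beta_logpdf",
    "model_accuracy",
    "fit_model",
    "MODEL_IDS",
    "GaussPrior",
    "default_priors",
]

MODEL_IDS = tuple(
    f"{family}-{source}"
    for family in ("rw", "kf", "hgf2")
    for source in ("state", "item", "combined")
)


@dataclass(frozen=True)
class ObsParams:
    """Inverse decision noise of the beta response model."""

    nu: float = 1.0

    def __post_init__(self):
        if self.nu <= 0:
            raise ValueError("nu must be positive")


def beta_logpdf(theta, y, nu):
    """Log beta density of outcome ``y`` given belief ``theta``.

    ``theta`` is clamped to ``[eps, 1-eps]`` and binary outcomes are
    mapped to ``clip(y, eps, 1-eps)`` with ``eps = 1e-4``.  At
    ``theta = 0.5, nu = 2`` the density is uniform and the log-density
    zero for any outcome.
    """
    nu = float(nu)
    if nu <= 0:
        raise ValueError("nu must be positive")
    th = np.clip(np.asarray(theta, dtype=float), BELIEF_EPS, 1 - BELIEF_EPS)
    yh = np.clip(np.asarray(y, dtype=float), BELIEF_EPS, 1 - BELIEF_EPS)
    a = th * nu
    b = nu - a
    return (gammaln(nu) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(yh) + (b - 1.0) * np.log1p(-yh))


def model_accuracy(trajectory, outcomes, nu):
    """Summed negative log-likelihood of the ratings (lower = better).

    ``trajectory`` may be a :class:`BeliefTrajectory` (its validity
    mask is honoured) or a bare belief array.
    """
    if isinstance(trajectory, BeliefTrajectory):
        theta = trajectory.mu1_hat
        valid = trajectory.valid
    else:
        theta = np.asarray(trajectory, dtype=float)
        valid = np.ones(theta.shape, dtype=bool)
    y = np.asarray(outcomes, dtype=float)
    if y.shape != theta.shape:
        raise ValueError("trajectory and outcomes must be aligned")
    return float(-beta_logpdf(theta[valid], y[valid], nu).sum())


@dataclass(frozen=True)
class GaussPrior:
    mean: float
    var: float

    def logpdf(self, x: float) -> float:
        return -0.5 * ((x - self.mean) ** 2 / self.var
                       + np.log(2 * np.pi * self.var))

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))


# estimation-space parameterisation per filter family:
# (name, prior, bounds, to_native)
_IDENT = lambda x: x
_FAMILY_SPACE = {
    "hgf2": (
        ("omega", GaussPrior(-3.0, 16.0), (-20.0, 10.0), _IDENT),
    ),
    "kf": (
        ("log_pi", GaussPrior(0.0, 4.0), (-8.0, 8.0), np.exp),
        ("log_omega", GaussPrior(0.0, 4.0), (-8.0, 8.0), np.exp),
    ),
    "rw": (
        ("logit_alpha", GaussPrior(0.0, 1.0), (-8.0, 8.0), expit),
    ),
}
_NU_PRIOR = GaussPrior(0.0, 4.0)  # on log nu
# nu < 1 makes the clamped beta density U-shaped: both extreme outcomes
# get enormous density regardless of the belief, a degenerate likelihood
# sink -- estimation is therefore bounded at nu >= 1 (log nu >= 0)
_NU_BOUNDS = (0.0, 5.0)


def default_priors(family: str):
    """(name, prior, bounds, to_native) tuples for the family's
    perceptual parameters in estimation space."""
    return _FAMILY_SPACE[family]


def _native_params(family: str, x: np.ndarray):
    space = _FAMILY_SPACE[family]
    native = [spec[3](xi) for spec, xi in zip(space, x)]
    if family == "hgf2":
        return HGFParams(omega=float(native[0]))
    if family == "kf":
        return KFParams(pi=float(native[0]), omega=float(native[1]))
    return RWParams(alpha=float(native[0]))


@dataclass
class ModelFit:
    """MAP fit of one subject under one model.

    ``accuracy`` is the summed negative log-likelihood of the ratings
    under the fitted trajectory (the quantity fed to model comparison);
    ``objective`` additionally includes the negative log-prior.
    ``prior_stuck`` flags fits whose perceptual parameter never left
    the prior mean -- the signature of a stochastic ~50/50 rating
    sequence that carries no learnable structure.
    """

    model_id: str
    params: object
    nu: float
    accuracy: float
    objective: float
    converged: bool
    prior_stuck: bool
    trajectory: Optional[BeliefTrajectory] = None
    x: Optional[np.ndarray] = None

    @property
    def log_evidence(self) -> float:
        """Log-evidence proxy used by random-effects model selection:
        the negative of the MAP objective (likelihood plus prior
        shrinkage, i.e. an accuracy-with-complexity-penalty score)."""
        return -self.objective

    def params_dict(self) -> Dict[str, float]:
        out = {k: float(v) for k, v in vars(self.params).items()}
        out["nu"] = self.nu
        return out


_PRIOR_STUCK_TOL = 0.05


def fit_model(sequence: TrialSequence, model_id: str, *,
              n_starts: int = 5, seed: int = 0,
              fixed_nu: Optional[float] = None,
              keep_trajectory: bool = True) -> ModelFit:
    """MAP-fit a perceptual + response model to one rating sequence.

    Maximises ``log-likelihood + log-prior`` over the family's
    parameters in estimation space (``omega`` native with prior
    N(-3, 16) for the HGF; ``log pi``/``log omega`` N(0, 4) for the
    KF; ``logit alpha`` N(0, 1) for RW; ``log nu`` N(0, 4) unless
    ``fixed_nu`` is given).  ``n_starts`` jittered initialisations
    (jitter sd = prior sd / 4, the first start exactly at the prior
    mean) guard against local optima; the best objective is kept.  If
    every start fails, the prior-mean parameters are returned with
    ``converged=False`` (trajectories are still produced).
    """
    family, _ = split_model_id(model_id)
    y = sequence.outcomes
    if y is None:
        raise ValueError("sequence has no outcomes")
    space = list(_FAMILY_SPACE[family])
    fit_nu = fixed_nu is None
    if fit_nu:
        space.append(("log_nu", _NU_PRIOR, _NU_BOUNDS, np.exp))
    means = np.array([s[1].mean for s in space])
    sds = np.array([s[1].sd for s in space])
    bounds = [s[2] for s in space]
    n_perc = len(_FAMILY_SPACE[family])

    build, valid = theta_builder(sequence, model_id)
    yv = y.astype(float)[valid]

    def objective(x):
        if not np.isfinite(x).all():
            return 1e10
        try:
            params = _native_params(family, x[:n_perc])
            nu = float(np.exp(x[n_perc])) if fit_nu else float(fixed_nu)
            theta = build(params)[valid]
            nll = float(-beta_logpdf(theta, yv, nu).sum())
        except (FloatingPointError, ValueError, OverflowError):
            return 1e10
        if not np.isfinite(nll):
            return 1e10
        logprior = sum(s[1].logpdf(xi) for s, xi in zip(space, x))
        return nll - logprior

    rng = np.random.default_rng(seed)
    best_x, best_obj = None, np.inf
    any_success = False
    import warnings as _warnings
    for start in range(max(1, n_starts)):
        x0 = means.copy()
        if start > 0:
            x0 = x0 + rng.normal(0.0, sds / 4.0)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                        bounds=bounds)
        except (ValueError, FloatingPointError):
            continue  # optimizer stepped out of domain; drop this start
        if np.isfinite(res.fun) and res.fun < best_obj:
            best_x, best_obj = res.x, float(res.fun)
            any_success = any_success or bool(res.success)

    if best_x is None or best_obj >= 1e10:  # total failure: prior-mean fallback
        best_x = means
        best_obj = float(objective(means))
        any_success = False
    # MAP must never be worse than the prior mean
    obj_at_prior = float(objective(means))
    if obj_at_prior < best_obj:
        best_x, best_obj = means, obj_at_prior

    params = _native_params(family, best_x[:n_perc])
    nu = float(np.exp(best_x[n_perc])) if fit_nu else float(fixed_nu)
    traj = model_trajectory(sequence, model_id, params)
    accuracy = model_accuracy(traj, y, nu)
    stuck = bool(abs(best_x[0] - means[0]) < _PRIOR_STUCK_TOL)
    return ModelFit(
        model_id=model_id,
        params=params,
        nu=nu,
        accuracy=accuracy,
        objective=best_obj,
        converged=any_success,
        prior_stuck=stuck,
        trajectory=traj if keep_trajectory else None,
        x=best_x,
    )
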