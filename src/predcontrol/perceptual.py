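"""Perceptual learning filters and belief sources.

Three filters estimate, before every no-think trial, the probability
that the upcoming suppression cue will trigger a memory intrusion:

* :func:`simulate_rw` -- Rescorla-Wagner delta rule with a fixed,
  participant-specific learning rate ``alpha``;
* :func:`simulate_kf` -- Kalman filter whose gain evolves with two
  parameters, belief reliability ``pi`` and process uncertainty
  ``omega``;
* :func:`simulate_hgf2` -- two-level binary hierarchical Gaussian
  filter whose second level performs a Gaussian random walk with step
  variance ``exp(omega)``; belief updates are first-level prediction
  errors weighted by second-level uncertainty.

Each filter can be driven by three *sources* of evidence: the whole
chronological trial history (``state``), each item's own repetition
history (``item``, see :func:`build_item_trajectories`), or a
precision-weighted fusion of the two (``combined``,
:func:`combine_sources`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _filters
from .sequences import TrialSequence

__all__ = [
    "HGFParams",
    "KFParams",
    "RWParams",
    "BeliefTrajectory",
    "simulate_rw",
    "simulate_kf",
    "simulate_hgf2",
    "build_item_trajectories",
    "combine_sources",
    "combine_beliefs",
    "compute_pe",
    "model_trajectory",
]

#: clamp applied to beliefs before computing Bernoulli precisions or
#: beta densities (the density degenerates at 0/1)
BELIEF_EPS = 1e-4


class ParameterError(ValueError):
    """Raised when a filter parameter is outside its domain."""


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner: learning rate in [0, 1] and initial prediction."""

    alpha: float
    v0: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha={self.alpha} outside [0, 1]")
        if not 0.0 <= self.v0 <= 1.0:
            raise ParameterError("v0 outside [0, 1]")


@dataclass(frozen=True)
class KFParams:
    """Kalman filter: belief reliability pi, process uncertainty omega,
    initial gain k0."""

    pi: float
    omega: float
    k0: float = 0.5
    mu0: float = 0.5

    def __post_init__(self):
        if self.pi <= 0 or self.omega <= 0:
            raise ParameterError("pi and omega must be positive")
        if not 0.0 <= self.k0 <= 1.0:
            raise ParameterError("k0 outside [0, 1]")


@dataclass(frozen=True)
class HGFParams:
    """Two-level HGF: log-volatility step size omega and the initial
    second-level Gaussian (mean mu2_0, variance sigma2_0)."""

    omega: float
    mu2_0: float = 0.0
    sigma2_0: float = 1.0

    def __post_init__(self):
        if self.sigma2_0 <= 0:
            raise ParameterError("sigma2_0 must be positive")


@dataclass
class BeliefTrajectory:
    """Per-trial belief quantities for one subject under one model.

    ``mu1_hat`` is the predicted intrusion probability before each
    outcome, ``pe`` the signed outcome prediction error
    ``y - mu1_hat``.  Second-level quantities (``mu2``, ``sigma2``,
    ``psi``) and the first-level prediction precision ``pi1_hat`` are
    populated for the HGF only.  ``valid`` masks trials usable for the
    response model (item-source trajectories exclude items with fewer
    than two repetitions).
    """

    mu1_hat: np.ndarray
    source: str
    model: str
    pe: Optional[np.ndarray] = None
    mu2: Optional[np.ndarray] = None
    sigma2: Optional[np.ndarray] = None
    pi1_hat: Optional[np.ndarray] = None
    psi: Optional[np.ndarray] = None
    gain: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self):
        self.mu1_hat = np.asarray(self.mu1_hat, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.mu1_hat.shape, dtype=bool)

    def __len__(self):
        return self.mu1_hat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        data = {"trial": np.arange(len(self)), "mu1_hat": self.mu1_hat}
        for name in ("pe", "mu2", "sigma2", "pi1_hat", "psi", "gain"):
            val = getattr(self, name)
            if val is not None:
                data[name] = val
        data["valid"] = self.valid.astype(int)
        frame = pd.DataFrame(data)
        frame.attrs["source"] = self.source
        frame.attrs["model"] = self.model
        return frame

    def to_tsv(self, path) -> None:
        # 15 significant digits round-trips float64 belief values
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.15g")


def compute_pe(mu1_hat, y):
    """Signed outcome prediction error ``PE = y - mu1_hat``.

    ``PE+`` (the reactive-control demand) is this quantity restricted
    to intrusion trials (y = 1); mask with ``y == 1`` downstream.
    """
    return np.asarray(y, dtype=float) - np.asarray(mu1_hat, dtype=float)


def _outcomes(seq_or_y) -> np.ndarray:
    if isinstance(seq_or_y, TrialSequence):
        if seq_or_y.outcomes is None:
            raise ValueError("sequence has no outcomes")
        return seq_or_y.outcomes.astype(float)
    return np.asarray(seq_or_y, dtype=float)


def simulate_rw(sequence, params: RWParams) -> BeliefTrajectory:
    """Run the Rescorla-Wagner filter over a binary outcome sequence."""
    y = _outcomes(sequence)
    pred, _ = _filters.rw_filter(y, params.alpha, params.v0)
    return BeliefTrajectory(mu1_hat=pred, pe=y - pred,
                            source="state", model="rw")


def simulate_kf(sequence, params: KFParams) -> BeliefTrajectory:
    """Run the Kalman filter; the returned trajectory carries the gain
    trace."""
    y = _outcomes(sequence)
    pred, gain = _filters.kf_filter(y, params.pi, params.omega,
                                    params.k0, params.mu0)
    return BeliefTrajectory(mu1_hat=pred, pe=y - pred, gain=gain,
                            source="state", model="kf")


def simulate_hgf2(sequence, params: HGFParams) -> BeliefTrajectory:
    """Run the two-level binary HGF."""
    y = _outcomes(sequence)
    mu1hat, mu2, sigma2, pi1hat, psi, delta = _filters.hgf2_filter(
        y, params.omega, params.mu2_0, params.sigma2_0
    )
    if not (sigma2 > 0).all():
        raise FloatingPointError("second-level variance left (0, inf)")
    return BeliefTrajectory(
        mu1_hat=mu1hat, pe=delta, mu2=mu2, sigma2=sigma2,
        pi1_hat=pi1hat, psi=psi, source="state", model="hgf2",
    )


_STATE_RUNNERS = {
    "rw": simulate_rw,
    "kf": simulate_kf,
    "hgf2": simulate_hgf2,
}


def build_item_trajectories(sequence: TrialSequence, model: str,
                            params) -> BeliefTrajectory:
    """Item-source beliefs: run the filter independently on each item's
    own repetition history, then reassemble chronologically.

    For each item the filter's time index is the item's repetition
    count, not the global trial count.  Items with fewer than two
    repetitions carry no usable item history; their trials are marked
    invalid (with a warning) and keep the filter's initial prediction.
    """
    runner = _STATE_RUNNERS[model]
    y = _outcomes(sequence)
    n = len(sequence)
    mu1_hat = np.empty(n)
    fields = {k: np.full(n, np.nan) for k in
              ("mu2", "sigma2", "pi1_hat", "psi", "gain")}
    valid = np.ones(n, dtype=bool)
    items = pd.unique(sequence.item_id)
    for item in items:
        idx = np.flatnonzero(sequence.item_id == item)
        if idx.size < 2:
            warnings.warn(
                f"item {item!r} has {idx.size} repetition(s); excluded "
                "from the item-source trajectory"
            )
            valid[idx] = False
        sub = runner(y[idx], params)
        mu1_hat[idx] = sub.mu1_hat
        for k in fields:
            val = getattr(sub, k)
            if val is not None:
                fields[k][idx] = val
    kw = {k: (v if np.isfinite(v).any() else None)
          for k, v in fields.items()}
    return BeliefTrajectory(mu1_hat=mu1_hat, pe=y - mu1_hat,
                            source="item", model=model, valid=valid, **kw)


def combine_beliefs(mu_state, mu_item, pi_state=None, pi_item=None):
    """Precision-weighted fusion of state and item beliefs.

    With explicit precisions:  ``(ms ps + mi pi) / (ps + pi)``.
    Without, Bernoulli prediction precisions ``1 / (m (1 - m))`` are
    used (beliefs clamped away from 0/1 first).
    """
    ms = np.clip(np.asarray(mu_state, float), BELIEF_EPS, 1 - BELIEF_EPS)
    mi = np.clip(np.asarray(mu_item, float), BELIEF_EPS, 1 - BELIEF_EPS)
    if pi_state is None:
        pi_state = 1.0 / (ms * (1.0 - ms))
    if pi_item is None:
        pi_item = 1.0 / (mi * (1.0 - mi))
    return (ms * pi_state + mi * pi_item) / (pi_state + pi_item)


def combine_sources(state_traj: BeliefTrajectory,
                    item_traj: BeliefTrajectory,
                    sequence: TrialSequence,
                    outcomes=None) -> BeliefTrajectory:
    """Fuse state- and item-source beliefs into the combined source.

    HGF beliefs are merged with their Bernoulli prediction precisions;
    RW and KF beliefs are averaged.  The fusion is defined only from
    each item's second repetition onward -- before that, the trial
    carries the state belief unchanged.
    """
    if len(state_traj) != len(item_traj) or len(state_traj) != len(sequence):
        raise ValueError("trajectories and sequence must be aligned")
    if state_traj.model != item_traj.model:
        raise ValueError("state and item trajectories use different models")
    rep = sequence.repetition_index()
    fuse = rep >= 1
    fuse &= item_traj.valid
    if state_traj.model == "hgf2":
        merged = combine_beliefs(state_traj.mu1_hat, item_traj.mu1_hat)
    else:
        merged = 0.5 * (state_traj.mu1_hat + item_traj.mu1_hat)
    mu = np.where(fuse, merged, state_traj.mu1_hat)
    if outcomes is None and sequence.outcomes is not None:
        outcomes = sequence.outcomes
    pe = None if outcomes is None else compute_pe(mu, outcomes)
    muc = np.clip(mu, BELIEF_EPS, 1 - BELIEF_EPS)
    return BeliefTrajectory(
        mu1_hat=mu, pe=pe, pi1_hat=1.0 / (muc * (1.0 - muc)),
        source="combined", model=state_traj.model,
    )


def model_trajectory(sequence: TrialSequence, model_id: str,
                     params) -> BeliefTrajectory:
    """Dispatch on a ``<family>-<source>`` model id, e.g. ``hgf2-item``.

    ``params`` is the family's parameter dataclass; for the combined
    source the same parameters drive both the state and the item
    filter.
    """
    family, source = split_model_id(model_id)
    if source == "state":
        return _STATE_RUNNERS[family](sequence, params)
    if source == "item":
        return build_item_trajectories(sequence, family, params)
    state = _STATE_RUNNERS[family](sequence, params)
    item = build_item_trajectories(sequence, family, params)
    return combine_sources(state, item, sequence)


def split_model_id(model_id: str):
    family, _, source = model_id.partition("-")
    if family not in _STATE_RUNNERS or source not in ("state", "item",
                                                      "combined"):
        raise ValueError(f"unknown model id {model_id!r}")
    return family, source


# -- fast path for the optimizer ------------------------------------------

def _raw_pred(family: str, y: np.ndarray, params) -> np.ndarray:
    if family == "rw":
        return _filters.rw_filter(y, params.alpha, params.v0)[0]
    if family == "kf":
        return _filters.kf_filter(y, params.pi, params.omega,
                                  params.k0, params.mu0)[0]
    return _filters.hgf2_filter(y, params.omega, params.mu2_0,
                                params.sigma2_0)[0]


def theta_builder(sequence: TrialSequence, model_id: str):
    """Return ``(build, valid)`` where ``build(params)`` yields the
    belief vector for ``model_id`` on this sequence.

    Pre-indexes the per-item trial groups and repetition structure so
    repeated calls inside an optimizer avoid container overhead; the
    result is identical to ``model_trajectory(...).mu1_hat``.
    """
    family, source = split_model_id(model_id)
    y = _outcomes(sequence)
    n = y.shape[0]
    if source == "state":
        def build(params):
            return _raw_pred(family, y, params)
        return build, np.ones(n, dtype=bool)

    groups = [np.flatnonzero(sequence.item_id == item)
              for item in pd.unique(sequence.item_id)]
    valid = np.ones(n, dtype=bool)
    for idx in groups:
        if idx.size < 2:
            valid[idx] = False

    def build_item(params):
        mu = np.empty(n)
        for idx in groups:
            mu[idx] = _raw_pred(family, y[idx], params)
        return mu

    if source == "item":
        return build_item, valid

    fuse = (sequence.repetition_index() >= 1) & valid

    def build_combined(params):
        ms = _raw_pred(family, y, params)
        mi = build_item(params)
        if family == "hgf2":
            merged = combine_beliefs(ms, mi)
        else:
            merged = 0.5 * (ms + mi)
        return np.where(fuse, merged, ms)

    return build_combined, np.ones(n, dtype=bool)
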