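"""Virtual TNT experiments: generative agents, cohorts and fixtures.

The generative procedure mirrors the falsification logic used to probe
the models: an agent carries one of the nine perceptual x source
models, starts from a 0.5 belief, and on every suppression trial

1. produces its model's predicted intrusion belief,
2. subtracts a *suppression factor* (memory suppression keeps belief
   trajectories from tilting toward 1) and adds Gaussian noise,
3. emits a binary rating from the suppressed belief, and
4. updates its filter with the emitted rating.

Two response rules are available.  Under the default ``"argmax"``
rule the agent emits the rating that best improves the cumulative
beta-model log-accuracy of its responses; the single-trial log-density
difference between the candidate ratings is ``nu (2 theta - 1)
log((1-eps)/eps)``, so for every ``nu`` the rule reduces exactly to a
threshold -- rate "intrusion" iff the noisy suppressed belief exceeds
0.5 (ties resolve to 0).  The response stochasticity therefore lives
entirely in the Gaussian belief noise; its scale (default sd 0.2) is
calibrated once so that the tuned HGF sources reproduce the canonical
declining intrusion profile rather than locking at the extremes (see
the methods note).  The alternative ``"sample"`` rule instead draws
the rating Bernoulli from the suppressed belief, which makes the
expected prediction error ``-suppression_factor`` on every trial and
yields steady downward drift for every model family.

The suppression factor is tuned per model by grid search against a
session-wise target intrusion profile (default: a linear decline from
0.5 to 0.3 over four sessions, emulating the canonical behavioural
pattern).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .perceptual import (
    BELIEF_EPS,
    HGFParams,
    KFParams,
    RWParams,
    combine_beliefs,
    split_model_id,
)
from .sequences import DesignSpec, TrialSequence, generate_design

__all__ = [
    "AgentSpec",
    "simulate_agent",
    "tune_suppression",
    "generate_cohort",
    "generate_coupling_fixtures",
    "sample_params",
    "DEFAULT_TARGET_PROFILE",
]

#: packaged synthetic reference profile: session-wise intrusion
#: proportion declining linearly from 0.5 to 0.3
DEFAULT_TARGET_PROFILE = np.linspace(0.5, 0.3, 4)


# ---------------------------------------------------------------------------
# incremental filter steppers (online counterparts of predcontrol._filters)

class _RWStepper:
    def __init__(self, p: RWParams):
        self.v = p.v0
        self.alpha = p.alpha

    def predict(self) -> float:
        return self.v

    def update(self, y: float) -> None:
        self.v += self.alpha * (y - self.v)


class _KFStepper:
    def __init__(self, p: KFParams):
        self.mu = p.mu0
        self.k = p.k0
        self.po = p.pi * p.omega

    def predict(self) -> float:
        return self.mu

    def update(self, y: float) -> None:
        self.k = (self.k + self.po) / (self.k + self.po + 1.0)
        self.mu += self.k * (y - self.mu)


class _HGFStepper:
    def __init__(self, p: HGFParams):
        self.mu2 = p.mu2_0
        self.sigma2 = p.sigma2_0
        self.w = float(np.exp(p.omega))

    def predict(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.mu2)))

    def update(self, y: float) -> None:
        m1 = self.predict()
        var1 = m1 * (1.0 - m1)
        pi2 = 1.0 / (self.sigma2 + self.w) + var1
        self.sigma2 = 1.0 / pi2
        self.mu2 = float(np.clip(self.mu2 + self.sigma2 * (y - m1),
                                 -36.0, 36.0))


_STEPPERS = {"rw": _RWStepper, "kf": _KFStepper, "hgf2": _HGFStepper}


class _SourceAgent:
    """Online belief source combining a state filter and/or per-item
    filters according to the model's source."""

    def __init__(self, family: str, source: str, params):
        self.family = family
        self.source = source
        self.params = params
        self.state = _STEPPERS[family](params)
        self.items: Dict = {}
        self.seen: Dict = {}

    def _item(self, item):
        if item not in self.items:
            self.items[item] = _STEPPERS[self.family](self.params)
        return self.items[item]

    def predict(self, item) -> float:
        if self.source == "state":
            return self.state.predict()
        if self.source == "item":
            return self._item(item).predict()
        # combined: state belief until the item's second repetition
        if self.seen.get(item, 0) < 1:
            return self.state.predict()
        ms = self.state.predict()
        mi = self._item(item).predict()
        if self.family == "hgf2":
            return float(combine_beliefs(ms, mi))
        return 0.5 * (ms + mi)

    def update(self, item, y: float) -> None:
        if self.source in ("state", "combined"):
            self.state.update(y)
        if self.source in ("item", "combined"):
            self._item(item).update(y)
        self.seen[item] = self.seen.get(item, 0) + 1


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentSpec:
    """One virtual participant.

    ``suppression_factor`` is the downward bias applied to the
    generated belief before the response; ``noise_sd`` the sd of the
    Gaussian perturbation added with it; ``nu`` the (fixed) inverse
    decision noise of the response rule.
    """

    model_id: str
    params: object
    suppression_factor: float = 0.0
    noise_sd: float = 0.2
    nu: float = 1.0
    seed: int = 0
    response_rule: str = "argmax"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.response_rule not in ("sample", "argmax"):
            raise ValueError("response_rule must be 'sample' or 'argmax'")
        split_model_id(self.model_id)  # validates


def simulate_agent(design, agent: AgentSpec) -> TrialSequence:
    """Simulate one virtual participant over a design.

    ``design`` may be a :class:`DesignSpec` or a pre-built trial
    skeleton.  Returns the sequence with binary outcomes and the latent
    (suppressed, noisy, clamped) belief trace in ``beliefs``.
    """
    if isinstance(design, DesignSpec):
        design = generate_design(design)
    family, source = split_model_id(agent.model_id)
    src = _SourceAgent(family, source, agent.params)
    rng = np.random.default_rng(agent.seed)
    n = len(design)
    outcomes = np.empty(n, dtype=int)
    beliefs = np.empty(n)
    noise = (rng.normal(0.0, agent.noise_sd, size=n)
             if agent.noise_sd > 0 else np.zeros(n))
    unif = rng.random(n) if agent.response_rule == "sample" else None
    for t in range(n):
        item = design.item_id[t]
        theta = src.predict(item) - agent.suppression_factor + noise[t]
        theta = min(max(theta, BELIEF_EPS), 1.0 - BELIEF_EPS)
        beliefs[t] = theta
        if agent.response_rule == "sample":
            y = 1 if unif[t] < theta else 0
        else:
            # accuracy-greedy response == threshold at 0.5 (ties -> 0)
            y = 1 if theta > 0.5 else 0
        outcomes[t] = y
        src.update(item, float(y))
    return TrialSequence(item_id=design.item_id, session=design.session,
                         outcomes=outcomes, beliefs=beliefs,
                         subject=design.subject)


def sample_params(family: str, rng: np.random.Generator,
                  regime: str = "empirical"):
    """Draw perceptual parameters for a virtual participant.

    ``regime="empirical"`` (default for all simulations) samples from
    Gaussians tailored to the plausible range of fitted parameters in
    this task -- agents whose learning lives on the time scale of the
    canonical session-wise intrusion decline: HGF ``omega ~ N(-3, 1)``
    (the subject-level spread implied by the task's group statistics),
    RW ``logit alpha ~ N(-2, 1)`` (median learning rate ~0.12, the
    slow regime matching a 0.5 -> 0.3 decline over 144 trials), KF
    ``log pi, log omega ~ N(-2, 1)`` (matching gain magnitudes).

    ``regime="prior"`` samples from the wide estimation priors used
    for fitting (HGF omega ~ N(-3, 16); KF log pi, log omega ~
    N(0, 4); RW logit alpha ~ N(0, 1)).
    """
    if regime == "empirical":
        scales = {"hgf2": (-3.0, 1.0), "kf": (-2.0, 1.0),
                  "rw": (-2.0, 1.0)}
    elif regime == "prior":
        scales = {"hgf2": (-3.0, 4.0), "kf": (0.0, 2.0),
                  "rw": (0.0, 1.0)}
    else:
        raise ValueError("regime must be 'empirical' or 'prior'")
    loc, sd = scales[family]
    if family == "hgf2":
        return HGFParams(omega=float(rng.normal(loc, sd)))
    if family == "kf":
        return KFParams(pi=float(np.exp(rng.normal(loc, sd))),
                        omega=float(np.exp(rng.normal(loc, sd))))
    if family == "rw":
        from scipy.special import expit
        return RWParams(alpha=float(expit(rng.normal(loc, sd))))
    raise ValueError(f"unknown family {family!r}")


def _session_profile(seq: TrialSequence, n_sessions: int) -> np.ndarray:
    return np.array([
        seq.outcomes[seq.session == s].mean() for s in range(n_sessions)
    ])


def tune_suppression(model_id: str,
                     target_profile=None,
                     grid=None,
                     design: DesignSpec = DesignSpec(),
                     n_agents: int = 40,
                     noise_sd: float = 0.2,
                     nu: float = 1.0,
                     seed: int = 0,
                     full_output: bool = False):
    """Grid-search the suppression factor for one model.

    Minimises the mean squared difference between the session-wise
    intrusion profile (averaged over ``n_agents`` agents with
    prior-sampled parameters, common random numbers across grid
    values) and ``target_profile``.  Ties go to the smallest factor.
    """
    grid = np.sort(np.asarray(
        np.linspace(0.0, 0.15, 16) if grid is None else grid, dtype=float))
    if grid.size == 0:
        raise ValueError("suppression grid is empty")
    if target_profile is None:
        # canonical 0.5 -> 0.3 decline, resampled to the design's sessions
        target_profile = np.linspace(0.5, 0.3, design.n_sessions)
    target = np.asarray(target_profile, dtype=float)
    if target.shape[0] != design.n_sessions:
        raise ValueError("target profile length must match n_sessions")
    family, _ = split_model_id(model_id)
    rng = np.random.default_rng(seed)
    skeleton = generate_design(design)
    agents = [(sample_params(family, rng), int(rng.integers(2 ** 31)))
              for _ in range(n_agents)]
    losses = np.empty(grid.shape)
    for i, s in enumerate(grid):
        profiles = np.empty((n_agents, design.n_sessions))
        for j, (params, aseed) in enumerate(agents):
            spec = AgentSpec(model_id=model_id, params=params,
                             suppression_factor=float(s),
                             noise_sd=noise_sd, nu=nu, seed=aseed)
            profiles[j] = _session_profile(simulate_agent(skeleton, spec),
                                           design.n_sessions)
        losses[i] = float(np.mean((profiles.mean(axis=0) - target) ** 2))
    best = float(grid[int(np.argmin(losses))])  # argmin takes first == smallest
    if full_output:
        return best, grid, losses
    return best


def generate_cohort(n_per_group: Sequence[int],
                    omega_means: Sequence[float],
                    omega_sd: float,
                    design: DesignSpec = DesignSpec(),
                    seed: int = 0,
                    model_id: str = "hgf2-item",
                    suppression_factor: float = 0.05,
                    noise_sd: float = 0.2):
    """Simulate groups of HGF agents with group-specific drift means.

    Per subject ``omega ~ N(group mean, omega_sd)``.  Returns a list of
    rating sequences and a DataFrame of the true parameters (subject,
    group, omega).
    """
    if len(n_per_group) != len(omega_means):
        raise ValueError("one omega mean per group is required")
    if min(n_per_group) < 2:
        raise ValueError("need at least 2 subjects per group")
    family, _ = split_model_id(model_id)
    if family != "hgf2":
        raise ValueError("cohort generation varies the HGF drift omega")
    rng = np.random.default_rng(seed)
    skeleton = generate_design(design)
    sequences: List[TrialSequence] = []
    rows = []
    sub = 0
    for g, (n, mean) in enumerate(zip(n_per_group, omega_means)):
        for _ in range(n):
            omega = float(rng.normal(mean, omega_sd))
            spec = AgentSpec(model_id=model_id,
                             params=HGFParams(omega=omega),
                             suppression_factor=suppression_factor,
                             noise_sd=noise_sd,
                             seed=int(rng.integers(2 ** 31)))
            seq = simulate_agent(skeleton, spec)
            seq.subject = f"sub-{sub:03d}"
            sequences.append(seq)
            rows.append({"subject": seq.subject, "group": g, "omega": omega})
            sub += 1
    return sequences, pd.DataFrame(rows)


# unit vectors of the imbalance frame: 0 deg points down the y-axis,
# positive angles run anticlockwise; +45 deg carries negative
# predictive coupling, -45 deg negative reactive coupling
_SQ2 = np.sqrt(2.0) / 2.0


def generate_coupling_fixtures(n_per_group: Sequence[int],
                               group_angle_means: Sequence[float],
                               spread: float,
                               seed: int = 0,
                               region: str = "wHIP",
                               group_labels: Optional[Sequence[str]] = None,
                               magnitude: float = 0.5,
                               magnitude_sd: float = 0.1) -> pd.DataFrame:
    """Synthetic predictive/reactive coupling pairs with known angular
    structure, for exercising the imbalance statistics.

    Per subject an imbalance angle is drawn ``N(group mean, spread)``
    (degrees) and a resultant magnitude ``|N(magnitude,
    magnitude_sd)|``; the pair of coupling parameters is the unique
    decomposition of that resultant onto the predictive (+45 deg for
    negative coupling) and reactive (-45 deg) axes.
    """
    means = np.asarray(group_angle_means, dtype=float)
    if np.any(means <= -180.0) or np.any(means > 180.0):
        raise ValueError("group angle means must lie in (-180, 180]")
    if len(n_per_group) != means.size:
        raise ValueError("one angle mean per group is required")
    if group_labels is None:
        group_labels = [f"group{g}" for g in range(len(n_per_group))]
    rng = np.random.default_rng(seed)
    rows = []
    sub = 0
    for label, n, mean in zip(group_labels, n_per_group, means):
        for _ in range(n):
            theta = np.deg2rad(rng.normal(mean, spread) if spread > 0
                               else mean)
            r = abs(rng.normal(magnitude, magnitude_sd)) + 1e-12
            vx, vy = r * np.sin(theta), -r * np.cos(theta)
            a = _SQ2 * (vx - vy)   # magnitude along +45 deg
            b = -_SQ2 * (vx + vy)  # magnitude along -45 deg
            rows.append({
                "subject": f"sub-{sub:03d}",
                "group": label,
                "region": region,
                "predictive": -a,
                "reactive": -b,
                "true_angle": float(np.rad2deg(theta)),
            })
            sub += 1
    return pd.DataFrame(rows)
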