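"""Random-effects Bayesian model selection, family inference and BMA.

Given a subjects x models matrix of log model evidence, the
random-effects scheme treats the model identity as a random effect:
subjects are multinomial draws from population model frequencies
``r ~ Dirichlet(alpha)``.  A variational update iterates subject-level
model posteriors against the Dirichlet concentrations.  From the
posterior we report

* expected model frequencies,
* exceedance probabilities (XP) -- P(model k is the most frequent),
  estimated by seeded Monte-Carlo sampling of the posterior Dirichlet,
* the Bayesian omnibus risk (BOR) -- posterior probability that model
  frequencies are all equal (chance), from the free-energy comparison
  of the null and the random-effects model, and
* protected exceedance probabilities ``PXP = XP (1 - BOR) + BOR / K``.

Families are compared by pooling member evidences with a uniform
within-family prior (log-sum-exp minus log family size); groups are
compared by the free-energy contrast of a pooled versus group-specific
frequency profile; Bayesian model averaging weights each subject's
parameters by their subject-level model posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "EvidenceSet",
    "BMSResult",
    "rfx_bms",
    "family_bms",
    "between_group_bms",
    "bma",
    "subject_model_posteriors",
]


@dataclass
class EvidenceSet:
    """Subjects x models log-evidence matrix with labels and an
    optional model -> family map."""

    L: np.ndarray
    model_labels: List[str]
    family_partition: Optional[Dict[str, str]] = None

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("L must be subjects x models")
        if self.L.shape[1] != len(self.model_labels):
            raise ValueError("one label per model column is required")
        if not np.isfinite(self.L).all():
            raise ValueError("log evidences must be finite")
        if self.family_partition is not None:
            missing = set(self.model_labels) - set(self.family_partition)
            if missing:
                raise ValueError(f"family partition misses {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return self.L.shape[0]

    @property
    def n_models(self) -> int:
        return self.L.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.L, columns=self.model_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.15g")

    @classmethod
    def from_tsv(cls, path, family_tsv=None) -> "EvidenceSet":
        frame = pd.read_csv(path, sep="\t")
        partition = None
        if family_tsv is not None:
            fam = pd.read_csv(family_tsv, sep="\t")
            partition = dict(zip(fam.iloc[:, 0], fam.iloc[:, 1]))
        return cls(L=frame.to_numpy(), model_labels=list(frame.columns),
                   family_partition=partition)


@dataclass
class BMSResult:
    labels: List[str]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    subject_posteriors: np.ndarray  # subjects x models, rows sum to 1
    free_energy: float
    free_energy_null: float
    n_iter: int
    converged: bool


def _as_matrix(evidence) -> np.ndarray:
    if isinstance(evidence, EvidenceSet):
        return evidence.L
    L = np.asarray(evidence, dtype=float)
    if L.ndim != 2:
        raise ValueError("evidence must be a subjects x models matrix")
    if not np.isfinite(L).all():
        raise ValueError("log evidences must be finite")
    return L


def _labels(evidence, K: int) -> List[str]:
    if isinstance(evidence, EvidenceSet):
        return list(evidence.model_labels)
    return [f"m{k}" for k in range(K)]


def _vb_dirichlet(L: np.ndarray, alpha0: float, tol: float,
                  max_iter: int):
    """Variational update; returns (alpha, g, F, n_iter, converged)."""
    n, K = L.shape
    a0 = np.full(K, alpha0)
    alpha = a0.copy()
    g = np.full((n, K), 1.0 / K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        raise RuntimeError("RFX-BMS did not converge")
    elogr = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(g > 0, g * np.log(g), 0.0).sum()
    F = float(
        (g * L).sum() + (g * elogr[None, :]).sum() + ent
        + gammaln(a0.sum()) - gammaln(a0).sum()
        + ((a0 - 1.0) * elogr).sum()
        - (gammaln(alpha.sum()) - gammaln(alpha).sum()
           + ((alpha - 1.0) * elogr).sum())
    )
    return alpha, g, F, it, converged


def _null_free_energy(L: np.ndarray) -> float:
    """Evidence of the null model: every subject draws from fixed
    equal model frequencies."""
    K = L.shape[1]
    return float(np.sum(logsumexp(L, axis=1) - np.log(K)))


def _exceedance(alpha: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior."""
    K = alpha.size
    rng = np.random.default_rng(seed)
    counts = np.zeros(K)
    remaining = int(n_samples)
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=K)
        remaining -= m
    return counts / n_samples


def rfx_bms(evidence, alpha0: float = 1.0, n_samples: int = 1_000_000,
            seed: int = 0, tol: float = 1e-6,
            max_iter: int = 10_000) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix."""
    L = _as_matrix(evidence)
    n, K = L.shape
    if K < 2:
        raise ValueError("need at least two models to compare")
    if n < 1:
        raise ValueError("need at least one subject")
    alpha, g, F, it, conv = _vb_dirichlet(L, alpha0, tol, max_iter)
    F0 = _null_free_energy(L)
    # BOR: posterior probability of the null (equal frequencies)
    bor = float(1.0 / (1.0 + np.exp(F - F0)))
    xp = _exceedance(alpha, n_samples, seed)
    pxp = xp * (1.0 - bor) + bor / K
    return BMSResult(
        labels=_labels(evidence, K),
        dirichlet_alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        xp=xp,
        bor=bor,
        pxp=pxp,
        subject_posteriors=g,
        free_energy=F,
        free_energy_null=F0,
        n_iter=it,
        converged=conv,
    )


def family_evidence(evidence: EvidenceSet,
                    partition: Optional[Dict[str, str]] = None
                    ) -> EvidenceSet:
    """Per-subject log family evidence with a uniform within-family
    prior: log-sum-exp over member models minus log family size."""
    partition = partition or evidence.family_partition
    if partition is None:
        raise ValueError("no family partition supplied")
    families = sorted(set(partition.values()))
    if len(families) < 2:
        raise ValueError("family comparison needs at least two families")
    cols = []
    for fam in families:
        members = [i for i, m in enumerate(evidence.model_labels)
                   if partition[m] == fam]
        if not members:
            raise ValueError(f"family {fam!r} has no members")
        cols.append(logsumexp(evidence.L[:, members], axis=1)
                    - np.log(len(members)))
    return EvidenceSet(L=np.column_stack(cols), model_labels=families)


def family_bms(evidence: EvidenceSet,
               partition: Optional[Dict[str, str]] = None,
               **kwargs) -> BMSResult:
    """Random-effects BMS at the family level."""
    return rfx_bms(family_evidence(evidence, partition), **kwargs)


def between_group_bms(evidence_groups: Sequence, alpha0: float = 1.0,
                      tol: float = 1e-6, max_iter: int = 10_000) -> float:
    """Posterior probability that all groups share one frequency
    profile (the same models explain every group).

    Free-energy comparison, at equal prior odds, of the pooled
    random-effects model (one Dirichlet for everybody) against the
    split model (group-specific Dirichlets).
    """
    mats = [_as_matrix(g) for g in evidence_groups]
    if len(mats) < 2:
        raise ValueError("need at least two groups")
    K = mats[0].shape[1]
    if any(m.shape[1] != K for m in mats):
        raise ValueError("groups must share the same model set")
    labels = [tuple(_labels(g, K)) for g in evidence_groups]
    if any(lab != labels[0] for lab in labels):
        raise ValueError("groups must share the same model labels")
    _, _, f_pooled, _, _ = _vb_dirichlet(np.vstack(mats), alpha0, tol,
                                         max_iter)
    f_split = sum(_vb_dirichlet(m, alpha0, tol, max_iter)[2] for m in mats)
    return float(1.0 / (1.0 + np.exp(f_split - f_pooled)))


def subject_model_posteriors(evidence, **kwargs) -> np.ndarray:
    """Subject-level model posterior probabilities under RFX-BMS."""
    return rfx_bms(evidence, **kwargs).subject_posteriors


def bma(posterior_params, model_post) -> np.ndarray:
    """Bayesian model averaging of subject-level parameters.

    ``posterior_params[s, m]`` is subject ``s``'s posterior parameter
    mean under model ``m``; ``model_post[s, m]`` the posterior
    probability that subject ``s`` uses model ``m`` (rows must sum
    to 1; compute them within each group separately).  Returns the
    per-subject weighted average.
    """
    params = np.asarray(posterior_params, dtype=float)
    post = np.asarray(model_post, dtype=float)
    if params.shape != post.shape:
        raise ValueError("parameter and posterior matrices must be aligned")
    if np.any(np.abs(post.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("model posteriors must sum to 1 per subject")
    return (params * post).sum(axis=1)
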