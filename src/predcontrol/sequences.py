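"""Trial sequences and experimental designs for TNT suppression blocks.

A no-think (suppression) run is described by a :class:`DesignSpec` --
how many word-object pairs (items) there are, how often each is cued,
and over how many scanning sessions the cues are spread.  The default
design is 18 items cued 8 times each, i.e. 144 suppression trials over
4 sessions with each item appearing twice per session.

:class:`TrialSequence` holds the chronological trial table: item and
session labels plus (optionally) the binary intrusion outcomes
``y`` (1 = the suppressed memory intruded, 0 = it did not).  The model
input at trial ``t`` is the previous outcome, ``u(t) = y(t-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "TrialSequence", "generate_design"]


class DesignError(ValueError):
    """Raised when item/repetition/session counts are inconsistent."""


@dataclass(frozen=True)
class DesignSpec:
    """Layout of a virtual TNT suppression experiment.

    Parameters
    ----------
    n_items:
        Number of distinct no-think word-object pairs.
    reps_per_item:
        How many times each item is cued over the whole experiment.
    n_sessions:
        Number of scanning sessions; ``reps_per_item`` must divide
        evenly across them so every session shows each item equally
        often.
    ordering_seed:
        Seed for the pseudo-random within-session ordering.
    """

    n_items: int = 18
    reps_per_item: int = 8
    n_sessions: int = 4
    ordering_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.reps_per_item < 1 or self.n_sessions < 1:
            raise DesignError("counts must be positive")
        if self.reps_per_item % self.n_sessions != 0:
            raise DesignError(
                f"reps_per_item={self.reps_per_item} does not divide into "
                f"{self.n_sessions} sessions"
            )

    @property
    def n_trials(self) -> int:
        return self.n_items * self.reps_per_item

    @property
    def reps_per_session(self) -> int:
        return self.reps_per_item // self.n_sessions


@dataclass
class TrialSequence:
    """Chronologically ordered no-think trials for one subject.

    ``outcomes`` may be ``None`` for a design skeleton that has not yet
    been simulated or observed.
    """

    item_id: np.ndarray
    session: np.ndarray
    outcomes: Optional[np.ndarray] = None
    beliefs: Optional[np.ndarray] = None  # latent generative beliefs, if simulated
    subject: str = "sub-01"

    def __post_init__(self) -> None:
        self.item_id = np.asarray(self.item_id)
        self.session = np.asarray(self.session, dtype=int)
        if self.item_id.shape != self.session.shape:
            raise ValueError("item_id and session must be aligned")
        if self.outcomes is not None:
            self.outcomes = np.asarray(self.outcomes, dtype=int)
            if self.outcomes.shape != self.item_id.shape:
                raise ValueError("outcomes must be aligned with trials")
            if not np.isin(self.outcomes, (0, 1)).all():
                raise ValueError("outcomes must be binary")

    def __len__(self) -> int:
        return self.item_id.shape[0]

    @property
    def inputs(self) -> np.ndarray:
        """Model inputs ``u(t) = y(t-1)``; the first input is undefined
        (the filters start from a 0.5 prior belief instead) and is
        reported as -1."""
        if self.outcomes is None:
            raise ValueError("sequence has no outcomes")
        u = np.empty(len(self), dtype=int)
        u[0] = -1
        u[1:] = self.outcomes[:-1]
        return u

    def repetition_index(self) -> np.ndarray:
        """0-based count of how often each trial's item has appeared so far."""
        counts: dict = {}
        rep = np.empty(len(self), dtype=int)
        for t, item in enumerate(self.item_id):
            rep[t] = counts.get(item, 0)
            counts[item] = rep[t] + 1
        return rep

    def session_proportions(self) -> np.ndarray:
        """Mean intrusion rate per session, in session order."""
        if self.outcomes is None:
            raise ValueError("sequence has no outcomes")
        sessions = np.unique(self.session)
        return np.array(
            [self.outcomes[self.session == s].mean() for s in sessions]
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "subject": self.subject,
            "session": self.session,
            "trial": np.arange(len(self)),
            "item_id": self.item_id,
        }
        if self.outcomes is not None:
            data["outcome"] = self.outcomes
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSequence":
        frame = frame.sort_values("trial")
        subject = str(frame["subject"].iloc[0]) if "subject" in frame else "sub-01"
        outcomes = frame["outcome"].to_numpy() if "outcome" in frame else None
        return cls(
            item_id=frame["item_id"].to_numpy(),
            session=frame["session"].to_numpy(),
            outcomes=outcomes,
            subject=subject,
        )

    @classmethod
    def from_tsv(cls, path) -> "TrialSequence":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def _order_session(items: np.ndarray, rng: np.random.Generator,
                   max_tries: int = 50) -> np.ndarray:
    """Permute one session's item list avoiding back-to-back repeats
    of the same item when possible."""
    for _ in range(max_tries):
        perm = rng.permutation(items)
        if len(perm) < 2 or (perm[1:] != perm[:-1]).all():
            return perm
    return perm  # degenerate designs (e.g. one item) cannot avoid repeats


def generate_design(spec: DesignSpec) -> TrialSequence:
    """Build the trial skeleton (item and session labels, no outcomes).

    Every session contains each item exactly ``reps_per_session`` times;
    the within-session order is a seeded pseudo-random permutation with
    no immediate item repetition whenever the design permits one.
    """
    rng = np.random.default_rng(spec.ordering_seed)
    items_all = []
    sessions_all = []
    base = np.repeat(np.arange(spec.n_items), spec.reps_per_session)
    for sess in range(spec.n_sessions):
        items_all.append(_order_session(base, rng))
        sessions_all.append(np.full(base.shape, sess, dtype=int))
    return TrialSequence(
        item_id=np.concatenate(items_all),
        session=np.concatenate(sessions_all),
    )
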