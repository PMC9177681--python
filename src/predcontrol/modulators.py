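"""Parametric-modulator construction for connectivity backends.

Two modulatory input functions are built from the winning belief
model's trajectory:

* a boxcar over *all* no-think trials whose height is the predicted
  intrusion belief (predictive-control input), and
* a boxcar restricted to intrusion trials (y = 1) whose height is the
  positive prediction error ``PE+ = 1 - belief`` (reactive-control
  input).

Heights are the raw computational quantities -- they are neither
orthogonalised nor mean-centred by default.  Export is a BIDS-style
events table (onset, duration, trial_type, modulator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .perceptual import BeliefTrajectory, compute_pe
from .sequences import TrialSequence

__all__ = ["TrialTiming", "ModulatorSet", "build_modulators"]

#: events-table column schema, version-tagged for downstream readers
EVENTS_SCHEMA = ("onset", "duration", "trial_type", "modulator")
EVENTS_SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class TrialTiming:
    """Onset (s) and duration (s) of every no-think trial.

    The cue duration defaults to 3 s; pass ``durations=0`` for stick
    (event) inputs.
    """

    onsets: np.ndarray
    durations: object = 3.0

    def resolved(self, n: int):
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.shape[0] != n:
            raise ValueError("one onset per trial is required")
        durations = np.broadcast_to(
            np.asarray(self.durations, dtype=float), (n,)).copy()
        return onsets, durations


@dataclass
class ModulatorSet:
    """The two modulator regressors for one subject/session block."""

    onsets: np.ndarray
    durations: np.ndarray
    nothink_heights: np.ndarray     # belief per no-think trial
    intrusion_onsets: np.ndarray    # subset of onsets with y = 1
    intrusion_durations: np.ndarray
    pe_heights: np.ndarray          # PE+ per intrusion trial
    mean_centering: bool = False

    def to_frame(self) -> pd.DataFrame:
        belief = pd.DataFrame({
            "onset": self.onsets,
            "duration": self.durations,
            "trial_type": "nothink_belief",
            "modulator": self.nothink_heights,
        })
        pe = pd.DataFrame({
            "onset": self.intrusion_onsets,
            "duration": self.intrusion_durations,
            "trial_type": "intrusion_pe",
            "modulator": self.pe_heights,
        })
        frame = pd.concat([belief, pe], ignore_index=True)
        frame = frame.sort_values(["onset", "trial_type"],
                                  ignore_index=True)
        frame.attrs["schema_version"] = EVENTS_SCHEMA_VERSION
        return frame

    def to_tsv(self, path) -> None:
        # 15 significant digits round-trips the float64 heights
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.15g")

    @classmethod
    def from_tsv(cls, path) -> "ModulatorSet":
        frame = pd.read_csv(path, sep="\t")
        belief = frame[frame["trial_type"] == "nothink_belief"]
        pe = frame[frame["trial_type"] == "intrusion_pe"]
        return cls(
            onsets=belief["onset"].to_numpy(),
            durations=belief["duration"].to_numpy(),
            nothink_heights=belief["modulator"].to_numpy(),
            intrusion_onsets=pe["onset"].to_numpy(),
            intrusion_durations=pe["duration"].to_numpy(),
            pe_heights=pe["modulator"].to_numpy(),
        )


def build_modulators(trajectory: BeliefTrajectory,
                     sequence: TrialSequence,
                     timing: TrialTiming,
                     mean_centering: bool = False) -> ModulatorSet:
    """Build the belief and PE+ modulators from a fitted trajectory.

    Every no-think trial contributes a belief height in (0, 1); only
    trials with an experienced intrusion contribute a PE+ height
    ``y - belief`` (strictly positive).  A sequence without intrusions
    yields an empty PE+ regressor.
    """
    if sequence.outcomes is None:
        raise ValueError("sequence has no outcomes")
    n = len(sequence)
    if len(trajectory) != n:
        raise ValueError("trajectory and sequence must be aligned")
    onsets, durations = timing.resolved(n)
    beliefs = np.asarray(trajectory.mu1_hat, dtype=float)
    if np.any((beliefs <= 0) | (beliefs >= 1)):
        raise ValueError("belief heights must lie strictly in (0, 1)")
    heights = beliefs.copy()
    intruded = sequence.outcomes == 1
    pe = compute_pe(beliefs[intruded], sequence.outcomes[intruded])
    if mean_centering:
        heights = heights - heights.mean()
        if pe.size:
            pe = pe - pe.mean()
    return ModulatorSet(
        onsets=onsets,
        durations=durations,
        nothink_heights=heights,
        intrusion_onsets=onsets[intruded],
        intrusion_durations=durations[intruded],
        pe_heights=pe,
        mean_centering=mean_centering,
    )
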