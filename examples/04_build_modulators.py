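"""Export belief and PE+ parametric modulators for connectivity models.

The winning combined-source HGF trajectory supplies two modulatory
inputs: every no-think trial carries its predicted intrusion belief
(predictive control), and every experienced intrusion carries the
positive prediction error 1 - belief (reactive control demand).  The
events table is written as a BIDS-style TSV.
"""

import numpy as np

from predcontrol import (
    AgentSpec,
    DesignSpec,
    HGFParams,
    TrialTiming,
    build_modulators,
    fit_model,
    generate_design,
    simulate_agent,
)

skeleton = generate_design(DesignSpec(ordering_seed=4))
agent = AgentSpec("hgf2-combined", HGFParams(omega=-3.0),
                  suppression_factor=0.02, seed=11)
sequence = simulate_agent(skeleton, agent)
assert sequence.outcomes.sum() > 0, "re-seed: no intrusions simulated"

fit = fit_model(sequence, "hgf2-combined", seed=0)
timing = TrialTiming(onsets=np.arange(len(sequence)) * 8.0,
                     durations=3.0)
mods = build_modulators(fit.trajectory, sequence, timing)
mods.to_tsv("modulators_events.tsv")

n_intr = mods.pe_heights.size
print(f"belief regressor: {mods.nothink_heights.size} no-think trials, "
      f"heights in [{mods.nothink_heights.min():.3f}, "
      f"{mods.nothink_heights.max():.3f}]")
print(f"PE+ regressor:    {n_intr} intrusion trials, "
      f"mean reactive demand {mods.pe_heights.mean():.3f}")
print("wrote modulators_events.tsv (onset, duration, trial_type, "
      "modulator)")
print("heights are raw computational quantities: not orthogonalised, "
      "not mean-centred")
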