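"""Circular imbalance analysis of predictive versus reactive control.

Predictive (belief-modulated) and reactive (PE+-modulated) coupling
parameters are projected onto orthogonal axes; the direction of their
resultant is the per-subject imbalance angle (0 deg = balanced,
positive = predictive dominance).  Synthetic cohorts with known group
angles exercise the circular means, the Watson two-sample test and the
contrast battery.
"""

from predcontrol import (
    circular_mean_ci,
    coupling_contrasts,
    generate_coupling_fixtures,
    resultant_angles,
    watson_two_sample,
)

cohort = generate_coupling_fixtures(
    n_per_group=(40, 30, 35),
    group_angle_means=(15.0, 5.0, 33.0),
    spread=20.0,
    group_labels=("nonexposed", "trauma_resilient", "trauma_affected"),
    seed=5,
)

angles = {}
for group, sub in cohort.groupby("group", sort=False):
    theta = resultant_angles(sub.predictive, sub.reactive)
    mean, (lo, hi) = circular_mean_ci(theta, seed=0)
    angles[group] = theta
    print(f"{group:17s} circular mean {mean:6.2f} deg  "
          f"95% CI [{lo:6.2f}, {hi:6.2f}]  (n={len(sub)})")
print("a CI excluding 0 deg marks a significant imbalance toward "
      "predictive control\n")

u2, p = watson_two_sample(angles["trauma_affected"],
                          angles["trauma_resilient"], seed=1)
print(f"Watson two-sample test, affected vs resilient: "
      f"U2={u2:.3f}, p={p:.4f}\n")

table = coupling_contrasts(cohort, focal_group="trauma_affected", seed=2)
ctrl = table[table.family == "control"][
    ["group", "t", "p_fdr", "ci_low", "ci_high", "bf"]]
print("within-group control effect (predictive - reactive coupling):")
print(ctrl.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("negative t with small FDR p: predictive coupling more negative "
      "than reactive, i.e. anticipatory suppression dominates")
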