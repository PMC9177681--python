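"""Imbalance geometry, circular statistics and the contrast battery."""

import numpy as np
import pandas as pd
import pytest

from predcontrol import (
    add_whole_hippocampus,
    circular_mean_ci,
    coupling_contrasts,
    generate_coupling_fixtures,
    load_coupling_table,
    residualize_symptoms,
    resultant_angle,
    resultant_angles,
    symptom_correlations,
    watson_two_sample,
)
from predcontrol.groupstats import circular_mean, rope_bayes_factor


def _brute_force_angle(pred, react):
    """Oracle: explicit 2-D vector summation in standard Cartesian
    coordinates, then read the angle off the 0-deg-down frame."""
    axes = {
        "pred_neg": np.deg2rad(45.0),
        "pred_pos": np.deg2rad(-135.0),
        "react_neg": np.deg2rad(-45.0),
        "react_pos": np.deg2rad(135.0),
    }

    def unit(phi):
        # frame direction phi (0 = down, anticlockwise) in standard xy
        return np.array([np.sin(phi), -np.cos(phi)])

    v = np.zeros(2)
    v += abs(pred) * unit(axes["pred_neg" if pred < 0 else "pred_pos"])
    v += abs(react) * unit(axes["react_neg" if react < 0 else "react_pos"])
    if np.hypot(*v) == 0:
        return np.nan
    return np.degrees(np.arctan2(v[0], -v[1]))


class TestResultantAngle:
    def test_balance_is_zero(self):
        assert resultant_angle(-1.0, -1.0) == pytest.approx(0.0)

    def test_pure_predictive_is_plus_45(self):
        assert resultant_angle(-1.0, 0.0) == pytest.approx(45.0)

    def test_worked_vector_sum(self):
        assert resultant_angle(-1.0, -0.5) == pytest.approx(18.434948822922)

    def test_positive_couplings_flip_axes(self):
        assert resultant_angle(1.0, 0.0) == pytest.approx(-135.0)
        assert resultant_angle(0.0, 1.0) == pytest.approx(135.0)

    def test_zero_resultant_flagged(self):
        assert np.isnan(resultant_angle(0.0, 0.0))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(0, 1, size=10_000)
        react = rng.normal(0, 1, size=10_000)
        fast = resultant_angles(pred, react)
        slow = np.array([_brute_force_angle(p, r)
                         for p, r in zip(pred, react)])
        assert np.nanmax(np.abs(fast - slow)) < 1e-9

    def test_predictive_dominance_positive_angle(self):
        rng = np.random.default_rng(1)
        pred = -np.abs(rng.normal(1, 0.1, 500))
        react = -np.abs(rng.normal(0.3, 0.1, 500))
        assert (resultant_angles(pred, react) > 0).all()


class TestCircularMean:
    def test_constant_sample(self):
        mean, (lo, hi) = circular_mean_ci([33.0] * 10, seed=0)
        assert mean == pytest.approx(33.0)
        assert lo == pytest.approx(33.0)
        assert hi == pytest.approx(33.0)

    def test_wraparound(self):
        assert abs(circular_mean([170.0, -170.0])) == pytest.approx(180.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(20, 30, 40)
        c = 75.0
        m1 = circular_mean(a + c)
        m0 = circular_mean(a)
        diff = (m1 - m0 - c + 180) % 360 - 180
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_ci_covers_true_mean(self):
        rng = np.random.default_rng(3)
        a = rng.normal(25.0, 15.0, 60)
        mean, (lo, hi) = circular_mean_ci(a, seed=4)
        assert lo < mean < hi
        assert lo <= 25.0 <= hi

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            circular_mean_ci([1.0, 2.0])


class TestWatson:
    def test_identical_samples_high_p(self):
        a = np.linspace(-40, 40, 12)
        u2, p = watson_two_sample(a, a.copy(), n_perm=500, seed=0)
        assert p > 0.5

    def test_offset_concentrated_samples_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 10, 30)
        b = rng.normal(90, 10, 30)
        u2, p = watson_two_sample(a, b, n_perm=2000, seed=1)
        assert p < 0.01

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 25, 20)
        b = rng.normal(40, 25, 20)
        u2a, _ = watson_two_sample(a, b, n_perm=10, seed=2)
        u2b, _ = watson_two_sample(a + 111.0, b + 111.0, n_perm=10, seed=2)
        assert u2a == pytest.approx(u2b, abs=1e-12)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            watson_two_sample([1] * 5, [2] * 20)


class TestContrasts:
    @pytest.fixture()
    def cohort(self):
        # three groups; the focal group has stronger predictive than
        # reactive negative coupling
        rng = np.random.default_rng(7)
        rows = []
        for g, (mp, mr, n) in {
            "nonexposed": (-0.3, -0.25, 40),
            "ptsd_minus": (-0.3, -0.25, 30),
            "ptsd_plus": (-0.6, -0.05, 35),
        }.items():
            for i in range(n):
                for region in ("rHIP", "cHIP", "PC"):
                    rows.append(dict(
                        subject=f"{g}-{i}", group=g, region=region,
                        predictive=rng.normal(mp, 0.3),
                        reactive=rng.normal(mr, 0.3)))
        return pd.DataFrame(rows)

    def test_interaction_detected_in_focal_group(self, cohort):
        table = coupling_contrasts(cohort, focal_group="ptsd_plus", seed=0)
        inter = table[(table.family == "interaction")
                      & (table.region == "rHIP")]
        assert (inter.p_fdr < 0.05).all()
        assert (inter.t < 0).all()

    def test_null_groups_uncalibrated_fraction(self):
        # equal predictive/reactive means: one-tailed interaction
        # p-values should not be systematically significant
        rng = np.random.default_rng(8)
        rows = []
        for g in ("a", "b"):
            for i in range(40):
                rows.append(dict(subject=f"{g}{i}", group=g, region="wHIP",
                                 predictive=rng.normal(-0.3, 0.3),
                                 reactive=rng.normal(-0.3, 0.3)))
        table = coupling_contrasts(pd.DataFrame(rows), focal_group="b",
                                   seed=1)
        inter = table[table.family == "interaction"]
        assert (inter.p > 0.05).all()

    def test_bh_adjustment_matches_hand_oracle(self):
        # BH on p = [.01,.02,.04,.05] over 4 tests -> [.04,.04,.05,.05]
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04, 0.05], method="fdr_bh")[1]
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])

    def test_fdr_monotone_in_raw_p(self, cohort):
        table = coupling_contrasts(cohort, focal_group="ptsd_plus", seed=2)
        for fam, sub in table.groupby("family"):
            s = sub.sort_values("p")
            assert (np.diff(s.p_fdr) >= -1e-12).all()

    def test_negative_coupling_tests_one_tailed(self, cohort):
        table = coupling_contrasts(cohort, focal_group="ptsd_plus", seed=3)
        pred = table[(table.family == "predictive")
                     & (table.group == "ptsd_plus")]
        assert (pred.p_fdr < 0.05).all()
        assert (pred.pp > 0.95).all()
        assert (pred.bf > 3).all()

    def test_small_group_skipped(self):
        frame = pd.DataFrame(dict(
            subject=["a", "b", "s1", "s2"], group=["g1"] * 2 + ["g2"] * 2,
            region="wHIP", predictive=[-0.1, -0.2, -0.3, -0.2],
            reactive=[-0.1, -0.15, -0.1, -0.2]))
        table = coupling_contrasts(frame, focal_group="g2", seed=4)
        assert table.empty or (table.n >= 3).all()


def test_rope_bf_scales_with_evidence():
    rng = np.random.default_rng(9)
    strong = rng.normal(-0.8, 1.0, 60)
    null = rng.normal(0.0, 1.0, 60)
    bf_strong = rope_bayes_factor(strong, seed=0)
    bf_null = rope_bayes_factor(null, seed=0)
    assert bf_strong > 3.0
    assert bf_null < bf_strong


class TestWholeHippocampus:
    def test_sum_combination(self):
        frame = pd.DataFrame(dict(
            subject=["s1", "s1"], group=["g", "g"],
            region=["rHIP", "cHIP"],
            predictive=[-0.2, -0.3], reactive=[-0.1, -0.1]))
        out = add_whole_hippocampus(frame)
        w = out[out.region == "wHIP"].iloc[0]
        assert w.predictive == pytest.approx(-0.5)
        assert w.reactive == pytest.approx(-0.2)

    def test_mean_combination(self):
        frame = pd.DataFrame(dict(
            subject=["s1", "s1"], group=["g", "g"],
            region=["rHIP", "cHIP"],
            predictive=[-0.2, -0.4], reactive=[0.0, -0.2]))
        out = add_whole_hippocampus(frame, how="mean")
        w = out[out.region == "wHIP"].iloc[0]
        assert w.predictive == pytest.approx(-0.3)
        assert w.reactive == pytest.approx(-0.1)


class TestSymptoms:
    @pytest.fixture()
    def clinical(self):
        rng = np.random.default_rng(10)
        n = 60
        groups = np.repeat(["ptsd_plus", "ptsd_minus"], n // 2)
        value = rng.normal(0, 1, n)
        avoid = -0.5 * value + rng.normal(0, 0.8, n)
        anx = rng.normal(0, 1, n)
        imb = pd.DataFrame(dict(subject=[f"s{i}" for i in range(n)],
                                group=groups, value=value))
        sym = pd.DataFrame(dict(subject=[f"s{i}" for i in range(n)],
                                avoidance=avoid, anxiety=anx))
        return imb, sym

    def test_negative_correlation_detected(self, clinical):
        imb, sym = clinical
        corr, _ = symptom_correlations(imb, sym, ["avoidance", "anxiety"],
                                       seed=0, n_boot=300)
        row = corr[(corr.group == "ptsd_plus")
                   & (corr.symptom == "avoidance")].iloc[0]
        assert row.rho < -0.2
        assert row.ci_low < row.rho < row.ci_high

    def test_dependent_difference_flags_contrast(self, clinical):
        imb, sym = clinical
        _, diffs = symptom_correlations(
            imb, sym, ["avoidance", "anxiety"],
            compare_pairs=[("avoidance", "anxiety")], seed=1, n_boot=300)
        row = diffs[(diffs.kind == "dependent")
                    & (diffs.group == "ptsd_plus")].iloc[0]
        assert row["diff"] < 0
        assert row["p"] < 0.1

    def test_independent_difference_bootstrap_coverage(self):
        # two groups with a known rho difference ~0.66: the bootstrap
        # CI of the difference should cover it
        rng = np.random.default_rng(11)
        n = 80
        x1 = rng.normal(0, 1, n)
        y1 = 0.8 * x1 + rng.normal(0, 0.6, n)   # rho ~ 0.8
        x2 = rng.normal(0, 1, n)
        y2 = 0.15 * x2 + rng.normal(0, 1, n)    # rho ~ 0.15
        imb = pd.DataFrame(dict(
            subject=[f"s{i}" for i in range(2 * n)],
            group=np.repeat(["g1", "g2"], n),
            value=np.concatenate([x1, x2])))
        sym = pd.DataFrame(dict(subject=[f"s{i}" for i in range(2 * n)],
                                scale=np.concatenate([y1, y2])))
        _, diffs = symptom_correlations(
            imb, sym, ["scale"], compare_between=["scale"],
            between_groups=("g1", "g2"), seed=2, n_boot=400)
        row = diffs[diffs.kind == "independent"].iloc[0]
        assert row.ci_low <= row["diff"] <= row.ci_high
        assert row["diff"] > 0.3

    def test_residualization_decorrelates_total(self):
        rng = np.random.default_rng(12)
        n = 50
        total = rng.normal(30, 8, n)
        sub = 0.6 * total + rng.normal(0, 3, n)
        frame = pd.DataFrame(dict(group=["g"] * n, total=total,
                                  avoidance=sub))
        out = residualize_symptoms(frame, ["avoidance"], "total")
        r = np.corrcoef(out.avoidance, out.total)[0, 1]
        assert abs(r) < 1e-8


def test_coupling_loader_with_column_map(tmp_path):
    frame = pd.DataFrame(dict(
        subj=["a", "b"], grp=["g1", "g2"], roi=["rHIP", "rHIP"],
        belief_mod=[-0.2, -0.4], pe_mod=[-0.1, 0.05]))
    path = tmp_path / "coupling.tsv"
    frame.to_csv(path, sep="\t", index=False)
    out = load_coupling_table(path, column_map={
        "subj": "subject", "grp": "group", "roi": "region",
        "belief_mod": "predictive", "pe_mod": "reactive"})
    assert set(out.columns) >= {"subject", "group", "region",
                                "predictive", "reactive"}
    with pytest.raises(ValueError):
        load_coupling_table(path)
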