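"""Group statistics on coupling parameters and the circular imbalance.

Predictive control (belief-modulated top-down coupling) and reactive
control (PE+-modulated coupling) are treated as two orthogonal,
downward-pointing forces.  In the polar frame used here 0 deg sits at
the bottom of the y-axis, angles run anticlockwise in (-180, 180],
negative *predictive* couplings project onto the +45 deg direction
(positive ones onto -135 deg) and negative *reactive* couplings onto
-45 deg (positive onto +135 deg).  The imbalance angle theta of a
subject is the direction of the resultant force: theta = 0 means the
two control modes balance, theta > 0 predictive dominance, theta < 0
reactive dominance.

The module also provides the frequentist/Bayesian contrast battery on
model-averaged coupling parameters (one-tailed t contrasts with BH-FDR
per effect family, bootstrap CIs, posterior probabilities, ROPE Bayes
factors) and bootstrap Spearman comparisons against clinical symptom
dimensions.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "resultant_angle",
    "resultant_angles",
    "circular_mean",
    "circular_mean_ci",
    "watson_two_sample",
    "coupling_contrasts",
    "symptom_correlations",
    "residualize_symptoms",
    "load_coupling_table",
    "add_whole_hippocampus",
]

_SQ2 = np.sqrt(2.0) / 2.0
# axis unit vectors in standard Cartesian coordinates (x right, y up):
# the frame's 0 deg direction is (0, -1)
_DIR_PRED_NEG = np.array([_SQ2, -_SQ2])    # +45 deg
_DIR_REACT_NEG = np.array([-_SQ2, -_SQ2])  # -45 deg


def _resultant_xy(predictive, reactive):
    p = np.asarray(predictive, dtype=float)
    r = np.asarray(reactive, dtype=float)
    # negative coupling -> magnitude |b| along the negative-coupling
    # axis; positive coupling flips to the opposite direction
    fx = -p * _DIR_PRED_NEG[0] + -r * _DIR_REACT_NEG[0]
    fy = -p * _DIR_PRED_NEG[1] + -r * _DIR_REACT_NEG[1]
    return fx, fy


def resultant_angles(predictive, reactive) -> np.ndarray:
    """Imbalance angle(s) in degrees for coupling pairs.

    Computed with the two-argument arctangent in the 0-deg-down,
    anticlockwise-positive frame; a zero resultant is undefined and
    returned as NaN.
    """
    fx, fy = _resultant_xy(predictive, reactive)
    theta = np.degrees(np.arctan2(fx, -fy))
    zero = np.hypot(fx, fy) == 0.0
    return np.where(zero, np.nan, theta)


def resultant_angle(predictive: float, reactive: float) -> float:
    """Scalar convenience wrapper around :func:`resultant_angles`."""
    return float(resultant_angles(predictive, reactive))


def circular_mean(angles_deg) -> float:
    """Circular mean in degrees, from the resultant of unit vectors."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    return float(np.degrees(np.arctan2(s, c)))


def _wrap(deg):
    """Wrap to (-180, 180]."""
    out = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def circular_mean_ci(angles_deg, n_boot: int = 2000, seed: int = 0,
                     ci: float = 95.0) -> Tuple[float, Tuple[float, float]]:
    """Circular mean with a percentile bootstrap confidence interval.

    The CI is formed on wrapped deviations from the point estimate so
    that intervals straddling +-180 deg behave correctly.  Requires at
    least three non-missing angles; a near-zero mean resultant length
    triggers a warning (the mean direction is then unstable).
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 3:
        raise ValueError("need at least 3 angles")
    rad = np.radians(a)
    rbar = float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))
    if rbar < 1e-3:
        warnings.warn("mean resultant length ~ 0; circular mean CI is "
                      "unstable")
    mean = circular_mean(a)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = circular_mean(rng.choice(a, size=a.size, replace=True))
    dev = _wrap(boots - mean)
    lo, hi = np.percentile(dev, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return mean, (float(_wrap(mean + lo)), float(_wrap(mean + hi)))


def _watson_u2(x_frac: np.ndarray, y_frac: np.ndarray) -> float:
    """Watson's two-sample U^2 from circle-fraction samples."""
    n, m = x_frac.size, y_frac.size
    N = n + m
    vals = np.concatenate([x_frac, y_frac])
    which = np.concatenate([np.zeros(n, dtype=int), np.ones(m, dtype=int)])
    order = np.argsort(vals, kind="mergesort")
    w = which[order]
    cum_x = np.cumsum(w == 0) / n
    cum_y = np.cumsum(w == 1) / m
    d = cum_x - cum_y
    return float(n * m / N ** 2 * (np.sum(d ** 2) - np.sum(d) ** 2 / N))


def watson_two_sample(angles_a, angles_b, n_perm: int = 10_000,
                      seed: int = 0) -> Tuple[float, float]:
    """Watson's two-sample U^2 test for circular data.

    A nonparametric, rotation-invariant analogue of the two-sample
    t-test; the p-value comes from ``n_perm`` seeded label
    permutations.  Both samples need at least 8 observations.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 8 or b.size < 8:
        raise ValueError("both samples need >= 8 angles")
    fa = (a % 360.0) / 360.0
    fb = (b % 360.0) / 360.0
    u2 = _watson_u2(fa, fb)
    pooled = np.concatenate([fa, fb])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _watson_u2(perm[:fa.size], perm[fa.size:]) >= u2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return u2, float(p)


# ---------------------------------------------------------------------------
# coupling-parameter IO helpers

_CANONICAL_COLS = ("subject", "group", "region", "predictive", "reactive")


def load_coupling_table(path, column_map: Optional[Dict[str, str]] = None,
                        sep: str = "\t") -> pd.DataFrame:
    """Load a subject-level coupling-parameter table.

    The canonical schema has columns subject, group, region,
    predictive, reactive; ``column_map`` renames deposited columns
    onto it (``{"file column": "canonical name"}``).
    """
    frame = pd.read_csv(path, sep=sep)
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = set(_CANONICAL_COLS) - set(frame.columns)
    if missing:
        raise ValueError(f"coupling table misses columns {sorted(missing)}")
    if not np.isfinite(frame[["predictive", "reactive"]].to_numpy()).all():
        raise ValueError("coupling parameters must be finite")
    return frame


def add_whole_hippocampus(frame: pd.DataFrame, how: str = "sum",
                          rostral: str = "rHIP", caudal: str = "cHIP",
                          name: str = "wHIP") -> pd.DataFrame:
    """Append a whole-hippocampus region combining the rostral and
    caudal couplings (``how`` = 'sum' (default) or 'mean')."""
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    parts = frame[frame["region"].isin([rostral, caudal])]
    agg = (parts.groupby(["subject", "group"], as_index=False)
           [["predictive", "reactive"]].agg("sum" if how == "sum" else "mean"))
    agg["region"] = name
    return pd.concat([frame, agg], ignore_index=True)


# ---------------------------------------------------------------------------
# contrast battery

def _boot_means(rng, z, n_boot):
    idx = rng.integers(0, z.size, size=(n_boot, z.size))
    return z[idx].mean(axis=1)


def _pp_and_ci(rng, z, n_boot, ci=95.0):
    means = _boot_means(rng, z, n_boot)
    lo, hi = np.percentile(means, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    side = np.sign(z.mean()) or 1.0
    pp = float(np.mean(np.sign(means) == side))
    return pp, float(lo), float(hi)


def rope_bayes_factor(z, rope_d: float = 0.1, n_draws: int = 90_000,
                      seed: int = 0) -> float:
    """ROPE-based Bayes factor for a one-sample effect.

    The standardised effect d = mean/sd is given a unit-information
    Normal(0, 1) prior; with d_hat the sample effect size the
    approximate posterior is Normal(d_hat * n / (n + 1), 1 / (n + 1)).
    ``n_draws`` Monte-Carlo draws estimate the prior and posterior mass
    inside the region of practical equivalence |d| < ``rope_d``; the
    BF is their ratio (prior/posterior), so BF > 1 means the posterior
    vacated the ROPE, i.e. evidence for a non-negligible effect.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    sd = z.std(ddof=1)
    if sd == 0:
        return np.nan
    d_hat = z.mean() / sd
    rng = np.random.default_rng(seed)
    prior = rng.normal(0.0, 1.0, size=n_draws)
    post = rng.normal(d_hat * n / (n + 1.0), np.sqrt(1.0 / (n + 1.0)),
                      size=n_draws)
    p_prior = np.mean(np.abs(prior) < rope_d)
    p_post = np.mean(np.abs(post) < rope_d)
    if p_post == 0:
        return np.inf
    return float(p_prior / p_post)


def coupling_contrasts(frame: pd.DataFrame,
                       focal_group: Optional[str] = None,
                       regions: Optional[Sequence[str]] = None,
                       n_boot: int = 2000,
                       rope_d: float = 0.1,
                       n_mcmc: int = 90_000,
                       seed: int = 0) -> pd.DataFrame:
    """One-tailed contrast battery on subject-level coupling parameters.

    Four effect families, each BH-FDR-corrected internally:

    * ``interaction`` -- the control effect (predictive - reactive)
      compared between the focal group and every other group
      (directional: focal more negative);
    * ``control`` -- predictive - reactive within each group (more
      negative predictive coupling);
    * ``reactive`` / ``predictive`` -- negative-coupling tests per
      group.

    Every row carries the t statistic, its df, raw and FDR-adjusted
    one-tailed p, a ``n_boot``-resample percentile CI of the mean, the
    bootstrap posterior probability (Pp) that the mean lies on its
    observed side of zero, and (for within-group effects) a ROPE Bayes
    factor.  Groups with fewer than 3 subjects are skipped.
    """
    required = {"subject", "group", "region", "predictive", "reactive"}
    if not required <= set(frame.columns):
        raise ValueError(f"need columns {sorted(required)}")
    groups = list(pd.unique(frame["group"]))
    if focal_group is None:
        focal_group = groups[-1]
    if regions is None:
        regions = list(pd.unique(frame["region"]))
    rng = np.random.default_rng(seed)
    rows = []

    def pull(group, region):
        sub = frame[(frame["group"] == group) & (frame["region"] == region)]
        return (sub["predictive"].to_numpy(), sub["reactive"].to_numpy())

    # (a) Control x Group interactions
    for region in regions:
        pf, rf = pull(focal_group, region)
        if pf.size < 3:
            continue
        for other in groups:
            if other == focal_group:
                continue
            po, ro = pull(other, region)
            if po.size < 3:
                continue
            df_, do = pf - rf, po - ro
            t, p = stats.ttest_ind(df_, do, alternative="less")
            mf = _boot_means(rng, df_, n_boot)
            mo = _boot_means(rng, do, n_boot)
            diff = mf - mo
            lo, hi = np.percentile(diff, [2.5, 97.5])
            obs = df_.mean() - do.mean()
            side = np.sign(obs) or 1.0
            rows.append(dict(
                family="interaction", region=region, group=focal_group,
                versus=other, t=float(t), df=df_.size + do.size - 2,
                p=float(p), ci_low=float(lo), ci_high=float(hi),
                pp=float(np.mean(np.sign(diff) == side)), bf=np.nan,
                mean=float(obs), n=int(df_.size + do.size)))

    # (b) within-group control effect, (c) reactive, (d) predictive
    for family, extractor, paired in (
        ("control", lambda p, r: p - r, True),
        ("reactive", lambda p, r: r, False),
        ("predictive", lambda p, r: p, False),
    ):
        for region in regions:
            for group in groups:
                p_, r_ = pull(group, region)
                if p_.size < 3:
                    continue
                z = extractor(p_, r_)
                t, pval = stats.ttest_1samp(z, 0.0, alternative="less")
                pp, lo, hi = _pp_and_ci(rng, z, n_boot)
                bf = rope_bayes_factor(z, rope_d=rope_d, n_draws=n_mcmc,
                                       seed=int(rng.integers(2 ** 31)))
                rows.append(dict(
                    family=family, region=region, group=group, versus="",
                    t=float(t), df=z.size - 1, p=float(pval),
                    ci_low=lo, ci_high=hi, pp=pp, bf=bf,
                    mean=float(z.mean()), n=int(z.size)))

    cols = ["family", "region", "group", "versus", "t", "df", "p",
            "ci_low", "ci_high", "pp", "bf", "mean", "n"]
    if not rows:
        return pd.DataFrame(columns=cols + ["p_fdr"])
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for family in table["family"].unique():
        mask = table["family"] == family
        table.loc[mask, "p_fdr"] = multipletests(
            table.loc[mask, "p"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# symptom correlations

def residualize_symptoms(symptoms: pd.DataFrame,
                         subscale_cols: Sequence[str],
                         total_col: str,
                         group_col: str = "group") -> pd.DataFrame:
    """Adjust subscale severities for total symptom severity.

    Each subscale is replaced by its residual from a within-group
    linear regression on the total score, so the adjusted scores are
    uncorrelated with overall severity inside each group.
    """
    out = symptoms.copy()
    for _, idx in out.groupby(group_col).groups.items():
        x = out.loc[idx, total_col].to_numpy(dtype=float)
        design = np.column_stack([np.ones(x.size), x])
        for col in subscale_cols:
            yv = out.loc[idx, col].to_numpy(dtype=float)
            ok = np.isfinite(yv) & np.isfinite(x)
            if ok.sum() < 3:
                continue
            beta, *_ = np.linalg.lstsq(design[ok], yv[ok], rcond=None)
            out.loc[idx, col] = yv - design @ beta
    return out


def _spearman_boot(rng, x, y, n_boot):
    n = x.size
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out[b] = stats.spearmanr(x[idx], y[idx]).statistic
    return out


def symptom_correlations(imbalance: pd.DataFrame,
                         symptoms: pd.DataFrame,
                         symptom_cols: Sequence[str],
                         value_col: str = "value",
                         group_col: str = "group",
                         compare_pairs: Optional[Sequence[Tuple[str, str]]] = None,
                         compare_between: Optional[Sequence[str]] = None,
                         between_groups: Optional[Tuple[str, str]] = None,
                         n_boot: int = 2000,
                         ci_diff: float = 90.0,
                         seed: int = 0):
    """Spearman correlations between a control-imbalance measure and
    symptom dimensions, with bootstrap comparisons.

    Returns ``(correlations, differences)``:

    * per group and symptom, rho with a 95% percentile bootstrap CI
      (subjects resampled jointly; missing scores pairwise-deleted
      with the used n reported), BH-FDR within group;
    * for each ``compare_pairs`` entry, the within-group dependent
      difference rho_a - rho_b, and for each ``compare_between``
      symptom the difference between the two ``between_groups``
      groups, both with percentile bootstrap CIs (default 90%), a
      bootstrap Z and its two-sided normal p, BH-FDR over the
      difference family.
    """
    merged = imbalance.merge(symptoms, on="subject", suffixes=("", "_sym"))
    rng = np.random.default_rng(seed)
    corr_rows = []
    boot_cache: Dict[Tuple[str, str], np.ndarray] = {}
    rho_cache: Dict[Tuple[str, str], float] = {}
    for group, gdf in merged.groupby(group_col):
        for col in symptom_cols:
            x = gdf[value_col].to_numpy(dtype=float)
            y = gdf[col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            res = stats.spearmanr(x, y)
            boots = _spearman_boot(rng, x, y, n_boot)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            corr_rows.append(dict(group=group, symptom=col,
                                  rho=float(res.statistic),
                                  p=float(res.pvalue),
                                  ci_low=float(lo), ci_high=float(hi),
                                  n=int(x.size)))
            boot_cache[(group, col)] = boots
            rho_cache[(group, col)] = float(res.statistic)
    corr = pd.DataFrame(corr_rows)
    corr["p_fdr"] = np.nan
    for group in corr["group"].unique():
        mask = corr["group"] == group
        corr.loc[mask, "p_fdr"] = multipletests(corr.loc[mask, "p"],
                                                method="fdr_bh")[1]

    diff_rows = []
    alpha_lo = (100 - ci_diff) / 2
    # dependent differences: same group, two symptom dimensions, the
    # subjects resampled jointly so the pair of rhos co-varies
    for group, gdf in merged.groupby(group_col):
        for a, b in (compare_pairs or []):
            x = gdf[value_col].to_numpy(dtype=float)
            ya = gdf[a].to_numpy(dtype=float)
            yb = gdf[b].to_numpy(dtype=float)
            obs = (stats.spearmanr(x, ya, nan_policy="omit").statistic
                   - stats.spearmanr(x, yb, nan_policy="omit").statistic)
            boots = np.empty(n_boot)
            n = x.size
            for bb in range(n_boot):
                idx = rng.integers(0, n, size=n)
                boots[bb] = (stats.spearmanr(x[idx], ya[idx],
                                             nan_policy="omit").statistic
                             - stats.spearmanr(x[idx], yb[idx],
                                               nan_policy="omit").statistic)
            lo, hi = np.percentile(boots, [alpha_lo, 100 - alpha_lo])
            z = abs(obs) / boots.std(ddof=1)
            diff_rows.append(dict(kind="dependent", group=group,
                                  a=a, b=b, diff=float(obs),
                                  ci_low=float(lo), ci_high=float(hi),
                                  z=float(z),
                                  p=float(2 * stats.norm.sf(z))))
    # independent differences: one symptom, two groups
    if compare_between:
        if between_groups is None:
            gs = list(merged[group_col].unique())
            between_groups = (gs[0], gs[1])
        ga, gb = between_groups
        for col in compare_between:
            ba = boot_cache[(ga, col)]
            bb_ = boot_cache[(gb, col)]
            obs = rho_cache[(ga, col)] - rho_cache[(gb, col)]
            boots = ba - bb_
            lo, hi = np.percentile(boots, [alpha_lo, 100 - alpha_lo])
            z = abs(obs) / boots.std(ddof=1)
            diff_rows.append(dict(kind="independent", group=f"{ga}-{gb}",
                                  a=col, b=col, diff=float(obs),
                                  ci_low=float(lo), ci_high=float(hi),
                                  z=float(z),
                                  p=float(2 * stats.norm.sf(z))))
    diffs = pd.DataFrame(diff_rows)
    if not diffs.empty:
        diffs["p_fdr"] = multipletests(diffs["p"], method="fdr_bh")[1]
    return corr, diffs
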