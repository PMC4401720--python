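"""ANOVA/LSD statistics against independent oracles, fold-change algebra,
selection gating, clustering and comparative-CT arithmetic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from saemir import diffexp as de
from saemir import io as sio
from saemir.exceptions import DegenerateFitError, DesignError, FormatError

from conftest import make_meta


def _fit(values, groups, genders=None, include_gender="auto"):
    meta = sio.SampleMeta(make_meta(groups, genders))
    return de.fit_group_gender_anova(np.asarray(values, float), meta,
                                     include_gender)


def _normal_equations_rss(y, x):
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# two-factor ANOVA
# ---------------------------------------------------------------------------

def test_anova_matches_statsmodels_type2():
    """Group/gender F, p and MSE agree with statsmodels anova_lm(typ=2)."""
    rng = np.random.default_rng(5)
    groups = ["nonsmoker"] * 9 + ["smoker_baseline"] * 10 + ["quitter"] * 10
    genders = ["F", "M"] * 14 + ["F"]
    y = rng.normal(8, 1, size=29) + 0.8 * (np.array(groups) == "quitter")
    fit = _fit(y, groups, genders)

    frame = pd.DataFrame({"y": y, "group": groups, "gender": genders})
    ols = smf.ols("y ~ C(group) + C(gender)", data=frame).fit()
    table = sm.stats.anova_lm(ols, typ=2)
    assert fit.df_resid == int(ols.df_resid)
    assert fit.mse == pytest.approx(ols.ssr / ols.df_resid, rel=1e-10)
    assert fit.group_f == pytest.approx(table.loc["C(group)", "F"], rel=1e-9)
    assert fit.group_p == pytest.approx(table.loc["C(group)", "PR(>F)"],
                                        rel=1e-9)
    assert fit.gender_f == pytest.approx(table.loc["C(gender)", "F"], rel=1e-9)
    assert fit.gender_p == pytest.approx(table.loc["C(gender)", "PR(>F)"],
                                         rel=1e-9)


def test_anova_matches_normal_equations_oracle():
    """Type-II sums of squares recomputed from scratch via normal equations."""
    rng = np.random.default_rng(12)
    groups = ["nonsmoker"] * 5 + ["smoker_baseline"] * 6 + ["quitter"] * 4
    genders = list("FMFMF" "MFMFMF" "FMFM")
    y = rng.normal(0, 1, size=15)
    fit = _fit(y, groups, genders)

    g = np.array(groups)
    x_group = np.column_stack([np.ones(15),
                               (g == "smoker_baseline").astype(float),
                               (g == "quitter").astype(float)])
    x_gender = np.column_stack([np.ones(15),
                                (np.array(genders) == "M").astype(float)])
    x_full = np.column_stack([x_group, x_gender[:, 1:]])
    rss_full = _normal_equations_rss(y, x_full)
    rss_nogroup = _normal_equations_rss(y, x_gender)
    df_resid = 15 - 4
    mse = rss_full / df_resid
    f_group = ((rss_nogroup - rss_full) / 2) / mse
    assert fit.mse == pytest.approx(mse, rel=1e-10)
    assert fit.group_f == pytest.approx(f_group, rel=1e-10)
    assert fit.group_p == pytest.approx(stats.f.sf(f_group, 2, df_resid),
                                        rel=1e-10)
    assert fit.df_resid == df_resid


def test_single_gender_reduces_to_one_way_anova():
    """With the gender term dropped, group p equals the one-way ANOVA p."""
    y = [4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
    groups = ["nonsmoker"] * 3 + ["smoker_baseline"] * 3
    fit = _fit(y, groups, genders=["F"] * 6)
    f, p = stats.f_oneway(y[:3], y[3:])
    assert fit.group_p == pytest.approx(p, rel=1e-12)
    assert fit.group_f == pytest.approx(f, rel=1e-12)
    assert np.isnan(fit.gender_f) and np.isnan(fit.gender_p)


def test_gender_p_large_when_no_gender_signal():
    rng = np.random.default_rng(3)
    groups = ["nonsmoker"] * 8 + ["smoker_baseline"] * 8
    genders = ["F", "M"] * 8
    ps = [
        _fit(rng.normal(0, 1, 16), groups, genders).gender_p
        for _ in range(40)
    ]
    assert np.mean(ps) > 0.3  # roughly uniform p under the null


def test_constant_values_degenerate():
    groups = ["nonsmoker"] * 3 + ["smoker_baseline"] * 3
    with pytest.raises(DegenerateFitError, match="residual"):
        _fit([5.0] * 6, groups, genders=["F"] * 6)


def test_small_group_rejected():
    with pytest.raises(DesignError, match="fewer than 2"):
        _fit([1.0, 2.0, 3.0], ["nonsmoker", "nonsmoker", "smoker_baseline"],
             genders=["F"] * 3)


# ---------------------------------------------------------------------------
# LSD contrasts
# ---------------------------------------------------------------------------

def test_lsd_reduces_to_pooled_t_two_groups():
    rng = np.random.default_rng(9)
    y = rng.normal(0, 1, 14)
    y[7:] += 0.9
    groups = ["nonsmoker"] * 7 + ["smoker_baseline"] * 7
    fit = _fit(y, groups, genders=["F"] * 14)
    diff, p = de.lsd_contrast(fit, "smoker_baseline", "nonsmoker")
    t, p_ref = stats.ttest_ind(y[7:], y[:7], equal_var=True)
    assert p == pytest.approx(p_ref, rel=1e-12)
    assert diff == pytest.approx(y[7:].mean() - y[:7].mean(), rel=1e-12)


def test_lsd_antisymmetry_and_identity():
    rng = np.random.default_rng(2)
    groups = ["nonsmoker"] * 5 + ["smoker_baseline"] * 5 + ["quitter"] * 5
    y = rng.normal(0, 1, 15)
    fit = _fit(y, groups)
    d_ab, p_ab = de.lsd_contrast(fit, "smoker_baseline", "nonsmoker")
    d_ba, p_ba = de.lsd_contrast(fit, "nonsmoker", "smoker_baseline")
    assert d_ab == pytest.approx(-d_ba) and p_ab == pytest.approx(p_ba)

    y_eq = np.concatenate([y[:5], y[:5], rng.normal(0, 1, 5)])
    fit_eq = _fit(y_eq, groups, genders=["F"] * 15)
    _, p_eq = de.lsd_contrast(fit_eq, "smoker_baseline", "nonsmoker")
    assert p_eq == pytest.approx(1.0)

    with pytest.raises(DesignError, match="never_smoked"):
        de.lsd_contrast(fit, "never_smoked", "nonsmoker")


# ---------------------------------------------------------------------------
# fold-change algebra
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("log2_diff,expected",
                         [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0),
                          (np.log2(3.8), 3.8), (-np.log2(3.8), -3.8)])
def test_signed_fold_change_values(log2_diff, expected):
    assert de.signed_fold_change(log2_diff) == pytest.approx(expected)


@given(st.floats(min_value=-20, max_value=20,
                 allow_nan=False).filter(lambda d: abs(d) > 1e-9))
def test_signed_fold_change_odd_and_magnitude(d):
    fc = de.signed_fold_change(d)
    assert fc == pytest.approx(-de.signed_fold_change(-d), rel=1e-12)
    assert abs(fc) == pytest.approx(2.0 ** abs(d), rel=1e-12)
    assert abs(fc) >= 1.0


def test_signed_fold_change_rejects_nonfinite():
    with pytest.raises(FormatError):
        de.signed_fold_change(np.nan)


# ---------------------------------------------------------------------------
# selection gate
# ---------------------------------------------------------------------------

def test_selection_gate_and_ordering(paper_cfg):
    records = pd.DataFrame({
        "mirna_id": ["keep_up", "p_fail", "fc_fail", "keep_down", "big_up"],
        "direction": ["up", "up", "up", "down", "up"],
        "fold_change": [1.6, 3.0, 1.4, -2.5, 4.0],
        "p_value": [0.009, 0.02, 0.001, 0.005, 0.0001],
    })
    out = de.select_smoking_dependent(records, paper_cfg)
    assert list(out["mirna_id"]) == ["big_up", "keep_up", "keep_down"]


def test_gate_boundaries_strict_vs_inclusive():
    records = pd.DataFrame({
        "mirna_id": ["at_fc", "at_p"],
        "direction": ["up", "up"],
        "fold_change": [1.5, 2.0],
        "p_value": [0.005, 0.01],
    })
    strict = de.apply_gate(records, 0.01, 1.5)
    assert list(strict["mirna_id"]) == []  # ties excluded under strict gates
    inclusive = de.apply_gate(records, 0.01, 1.5, fc_inclusive=True)
    assert list(inclusive["mirna_id"]) == ["at_fc"]  # p stays strict


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def _expr(values, mirnas, samples):
    return sio.ExpressionMatrix(pd.DataFrame(values, index=mirnas,
                                             columns=samples))


def test_anticorrelated_blocks_split_at_root():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    mat = np.column_stack([v, v + 0.01, -v, -v + 0.01])
    expr = _expr(mat, [f"m{i}" for i in range(4)], ["a1", "a2", "b1", "b2"])
    res = de.cluster_signature(expr)
    labels = fcluster(res.sample_linkage, t=2, criterion="maxclust")
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert labels[0] != labels[2]


def test_duplicate_columns_merge_first_at_zero():
    rng = np.random.default_rng(4)
    mat = rng.normal(size=(6, 4))
    mat[:, 3] = mat[:, 0]
    expr = _expr(mat, [f"m{i}" for i in range(6)], ["s0", "s1", "s2", "s3"])
    res = de.cluster_signature(expr)
    first = res.sample_linkage[0]
    assert sorted(first[:2]) == [0, 3]
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def _brute_force_average_linkage(dist):
    """Exhaustive UPGMA on the original pairwise distances."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = np.mean([dist[x, y] for x in clusters[a]
                             for y in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        new = clusters.pop(a) | clusters.pop(b)
        merges.append((new, d))
        clusters[next_id] = new
        next_id += 1
    return merges


def test_linkage_matches_exhaustive_agglomeration():
    rng = np.random.default_rng(17)
    mat = rng.normal(size=(4, 6))  # 4 miRNAs clustered over 6 samples
    dist = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(dist, 0.0)
    expr = _expr(mat, [f"m{i}" for i in range(4)],
                 [f"s{i}" for i in range(6)])
    res = de.cluster_signature(expr)

    oracle = _brute_force_average_linkage(dist)
    # decode scipy linkage into merged leaf sets
    members = {i: frozenset([i]) for i in range(4)}
    for step, row in enumerate(res.mirna_linkage):
        merged = members[int(row[0])] | members[int(row[1])]
        members[4 + step] = merged
        assert merged == oracle[step][0]
        assert row[2] == pytest.approx(oracle[step][1], rel=1e-9)


def test_zero_variance_row_named():
    mat = np.random.default_rng(0).normal(size=(3, 5))
    mat[1] = 2.0
    expr = _expr(mat, ["m0", "flatline", "m2"], [f"s{i}" for i in range(5)])
    with pytest.raises(DegenerateFitError, match="flatline"):
        de.cluster_signature(expr)


# ---------------------------------------------------------------------------
# comparative CT
# ---------------------------------------------------------------------------

def test_ddct_reference_and_doubling():
    samples = ["r1", "r2", "x1", "x2", "x3"]
    groups = pd.Series(["nonsmoker"] * 2 + ["smoker_baseline"] * 3,
                       index=samples)
    ct_control = pd.Series(20.0, index=samples)
    # dCT of reference = 5; targets at ddCT -1, 0, +1
    ct_target = pd.Series([25.0, 25.0, 24.0, 25.0, 26.0], index=samples)
    rq = de.ddct_fold_change(ct_target, ct_control, groups, "nonsmoker")
    assert rq["x1"] == pytest.approx(2.0)
    assert rq["x2"] == pytest.approx(1.0)
    assert rq["x3"] == pytest.approx(0.5)
    assert rq[["r1", "r2"]].to_numpy() == pytest.approx([1.0, 1.0])

    with pytest.raises(DesignError, match="quitter"):
        de.ddct_fold_change(ct_target, ct_control, groups, "quitter")
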