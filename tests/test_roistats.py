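"""Volumetry, group tests, effect sizes, and the FDR procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mouseconn.roistats import (
    fdr_critical_value,
    fdr_filter,
    fdr_two_stage,
    ir_ttest,
    kruskal_wallis,
    mann_whitney,
    normalize_volumes,
    omega_squared,
    one_way_anova,
    paired_t,
    percent_pair,
    region_table,
    roi_volumes,
    two_way_anova,
)
from mouseconn.synth import AtlasSpec, EffectSpec, SynthConfig, gen_atlas, gen_measure_table
from mouseconn.types import InsufficientDataError, ValidationError


# --------------------------------------------------------------- volumetry

def test_roi_volume_unit_arithmetic():
    spec = AtlasSpec(grid_shape=(10, 10, 5), voxel_dims=(0.2, 0.2, 0.5),
                     label_voxel_counts={5: 100},
                     label_names={5: "accumbens"})
    image, names = gen_atlas(spec, seed=0)
    table = roi_volumes(image, spec.voxel_dims, names)
    assert table.loc[0, "volume_mm3"] == pytest.approx(2.0)


def test_roi_volume_missing_label_warns():
    image = np.zeros((4, 4, 4), dtype=np.int32)
    image[0, 0, 0] = 1
    names = pd.DataFrame({"label": [1, 2], "roi_name": ["a", "b"]})
    with pytest.warns(UserWarning, match="label 2"):
        table = roi_volumes(image, (1, 1, 1), names)
    assert table.loc[table.roi_name == "b", "volume_mm3"].item() == 0.0


def test_roi_volume_conservation(rng):
    counts = {k: int(c) for k, c in
              zip(range(1, 8), rng.integers(5, 40, size=7))}
    spec = AtlasSpec(grid_shape=(12, 12, 6), voxel_dims=(0.25, 0.25, 0.4),
                     label_voxel_counts=counts,
                     label_names={k: f"roi{k}" for k in counts})
    image, names = gen_atlas(spec, seed=2)
    table = roi_volumes(image, spec.voxel_dims, names)
    assert table["volume_mm3"].sum() == pytest.approx(
        table.attrs["total_brain_mm3"], abs=1e-12)


def measure_rows(values, measure="volume_mm3"):
    rows = []
    for (subj, sess, roi), v in values.items():
        rows.append({"subject_id": subj, "group": "placebo",
                     "session": sess, "roi_name": roi,
                     "measure": measure, "value": v})
    return pd.DataFrame(rows)


def test_normalize_volumes_fractions():
    tab = measure_rows({("s1", "chronic", "a"): 3.0,
                        ("s1", "chronic", "b"): 1.0,
                        ("s2", "chronic", "a"): 5.0})
    out = normalize_volumes(tab)
    frac = out[out.measure == "volume_fraction"]
    s1 = frac[frac.subject_id == "s1"].set_index("roi_name")["value"]
    assert s1["a"] == pytest.approx(0.75) and s1["b"] == pytest.approx(0.25)
    assert frac[frac.subject_id == "s2"]["value"].item() == pytest.approx(1.0)


def test_normalize_volumes_random_tables_sum_to_one(rng):
    rows = {("s%d" % s, "chronic", "r%d" % r): float(rng.uniform(0.1, 5))
            for s in range(4) for r in range(10)}
    out = normalize_volumes(measure_rows(rows))
    frac = out[out.measure == "volume_fraction"]
    sums = frac.groupby("subject_id")["value"].sum()
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_normalize_volumes_zero_total_raises():
    with pytest.raises(ValidationError, match="total brain volume"):
        normalize_volumes(measure_rows({("s1", "chronic", "a"): 0.0}))


def test_percent_pair_cases():
    assert percent_pair(2.0, 2.0) == (50.0, 50.0)
    assert percent_pair(3.0, 1.0) == (75.0, 25.0)
    with pytest.raises(ValidationError):
        percent_pair(0.0, 0.0)


@given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
@settings(max_examples=50, deadline=None)
def test_percent_pair_sums_to_100(a, b):
    pa, pb = percent_pair(a, b)
    assert pa + pb == pytest.approx(100.0, abs=1e-9)


# ------------------------------------------------------------- basic tests

def test_paired_t_cases(rng):
    x = rng.standard_normal(10)
    t, p, md = paired_t(x, x)
    assert (t, p, md) == (0.0, 1.0, 0.0)
    base = np.arange(6, dtype=float)
    with pytest.raises(ValidationError):
        paired_t(base + 1.0, base)  # constant nonzero differences
    y = x + rng.standard_normal(10)
    t, p, md = paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)
    assert md == pytest.approx(np.mean(x - y), abs=1e-12)


def test_kruskal_wallis_cases():
    assert kruskal_wallis([np.ones(3), np.ones(4)]) == (0.0, 1.0)
    h, p = kruskal_wallis([np.array([1, 2, 3.0]),
                           np.array([10, 11, 12.0]),
                           np.array([20, 21, 22.0])])
    assert h == pytest.approx(7.2, abs=1e-10)  # hand-ranked H
    # order invariance
    h2, _ = kruskal_wallis([np.array([20, 21, 22.0]),
                            np.array([1, 2, 3.0]),
                            np.array([10, 11, 12.0])])
    assert h2 == pytest.approx(h, abs=1e-12)


def test_mann_whitney_extremes():
    u, _ = mann_whitney(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
    assert u == 0.0
    x = np.array([1.0, 2, 3, 4])
    u, _ = mann_whitney(x, x)
    assert u == len(x) ** 2 / 2


def test_mann_whitney_exact_matches_scipy(rng):
    for _ in range(10):
        x = rng.standard_normal(5)
        y = rng.standard_normal(6) + 0.5
        u, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_one_way_anova_two_groups_is_squared_t(rng):
    x, y = rng.standard_normal((2, 8))
    f, p, _ = one_way_anova([x, y])
    t = sps.ttest_ind(x, y)
    assert f == pytest.approx(t.statistic**2, abs=1e-10)
    assert p == pytest.approx(t.pvalue, abs=1e-10)


def test_one_way_anova_worked_dataset():
    """3 groups x 5 values with hand-computed sums of squares."""
    g1 = np.array([4.0, 5, 6, 5, 4])   # mean 4.8
    g2 = np.array([6.0, 7, 8, 7, 7])   # mean 7.0
    g3 = np.array([9.0, 10, 11, 10, 10])  # mean 10.0
    grand = 7.2666666666666666
    ss_b = 5 * ((4.8 - grand) ** 2 + (7.0 - grand) ** 2 + (10.0 - grand) ** 2)
    ss_w = (np.sum((g1 - 4.8) ** 2) + np.sum((g2 - 7.0) ** 2)
            + np.sum((g3 - 10.0) ** 2))
    f_hand = (ss_b / 2) / (ss_w / 12)
    f, p, w2 = one_way_anova([g1, g2, g3])
    assert f == pytest.approx(f_hand, abs=1e-10)
    ref = sps.f_oneway(g1, g2, g3)
    assert f == pytest.approx(ref.statistic, abs=1e-10)
    w2_hand = (ss_b - 2 * (ss_w / 12)) / (ss_b + ss_w + ss_w / 12)
    assert w2 == pytest.approx(w2_hand, abs=1e-12)


def test_omega_squared_nonpositive_under_null(rng):
    vals = [omega_squared([rng.standard_normal(6) for _ in range(3)])
            for _ in range(300)]
    # unbiasedness: centred near zero, often negative under the null
    assert abs(np.mean(vals)) < 0.02
    assert np.mean(np.array(vals) < 0) > 0.3


def test_two_way_anova_pure_a_effect(rng):
    a = np.repeat(["a1", "a2"], 20)
    b = np.tile(np.repeat(["b1", "b2"], 10), 2)
    y = (a == "a2") * 3.0 + rng.standard_normal(40) * 0.5
    table = two_way_anova(y, a, b)
    assert table.loc["A", "p"] < 1e-6
    assert table.loc["B", "p"] > 0.01
    assert table.loc["A:B", "p"] > 0.01


def test_two_way_anova_balanced_matches_classical_ss(rng):
    a = np.repeat(["a1", "a2"], 12)
    b = np.tile(np.repeat(["b1", "b2"], 6), 2)
    y = rng.standard_normal(24) + (a == "a2") * 1.0 + (b == "b2") * 0.5
    table = two_way_anova(y, a, b)
    # balanced design: Type-II SS equal textbook factor SS
    ya1, ya2 = y[a == "a1"], y[a == "a2"]
    ss_a = 12 * ((ya1.mean() - y.mean()) ** 2 + (ya2.mean() - y.mean()) ** 2)
    yb1, yb2 = y[b == "b1"], y[b == "b2"]
    ss_b = 12 * ((yb1.mean() - y.mean()) ** 2 + (yb2.mean() - y.mean()) ** 2)
    assert table.loc["A", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
    assert table.loc["B", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)


def test_two_way_anova_all_equal():
    a = np.repeat(["a1", "a2"], 4)
    b = np.tile(["b1", "b2"], 4)
    table = two_way_anova(np.ones(8), a, b)
    assert (table.loc[["A", "B"], "F"] == 0).all()


def test_ir_ttest_contracts(rng):
    sym = 0.5 + np.array([-0.1, 0.1, -0.2, 0.2])
    t, p = ir_ttest(sym)
    assert t == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValidationError):
        ir_ttest(np.full(5, 0.5))
    ir = rng.uniform(0.3, 0.9, size=12)
    t, p = ir_ttest(ir)
    ref = sps.ttest_1samp(ir, 0.5)
    assert (t, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))


# --------------------------------------------------------------------- FDR

def test_fdr_critical_values_at_reference_ranks():
    assert round(fdr_critical_value(29, 139, q=0.2), 3) == 0.042
    assert round(fdr_critical_value(7, 139, q=0.2), 3) == 0.010
    assert round(fdr_critical_value(39, 139, q=0.2), 3) == 0.056
    assert fdr_critical_value(139, 139, q=0.2) == pytest.approx(0.2)


def test_fdr_filter_basic(rng):
    p = np.array([0.001, 0.5, 0.01, 0.9])
    out = fdr_filter(p, v=139, q=0.2)
    assert list(out["fdr_rank"]) == [1, 3, 2, 4]
    np.testing.assert_allclose(out["fdr_critical"],
                               out["fdr_rank"] * 0.2 / 139)
    assert out.loc[0, "passes_fdr"] and not out.loc[3, "passes_fdr"]
    with pytest.raises(ValidationError):
        fdr_filter(np.array([1.5]))


@given(st.lists(st.floats(0, 1), min_size=3, max_size=30))
@settings(max_examples=50, deadline=None)
def test_fdr_filter_order_invariant(pvals):
    p = np.array(pvals)
    a = fdr_filter(p, q=0.2)
    perm = np.random.default_rng(0).permutation(len(p))
    b = fdr_filter(p[perm], q=0.2)
    # each p-value keeps its decision regardless of input order (ties may
    # swap ranks but identical p-values share a decision only when their
    # critical values agree; compare via sorted views)
    np.testing.assert_array_equal(np.sort(a["fdr_critical"]),
                                  np.sort(b["fdr_critical"]))
    sa = a.sort_values(["p", "fdr_rank"]).reset_index(drop=True)
    sb = b.sort_values(["p", "fdr_rank"]).reset_index(drop=True)
    np.testing.assert_array_equal(sa["passes_fdr"], sb["passes_fdr"])


def test_fdr_filter_null_calibration(rng):
    """Under a global null the discovery fraction stays controlled."""
    hits = []
    for _ in range(200):
        p = rng.uniform(size=139)
        hits.append(fdr_filter(p, q=0.2)["passes_fdr"].mean())
    assert np.mean(hits) < 0.2


def test_fdr_two_stage_extremes():
    assert not fdr_two_stage(np.ones(10)).any()
    assert fdr_two_stage(np.full(10, 1e-6)).all()


def test_fdr_two_stage_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(20):
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(size=20)])
        rng.shuffle(p)
        mine = fdr_two_stage(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        np.testing.assert_array_equal(mine, ref)


def test_fdr_two_stage_monotone_in_p(rng):
    p = rng.uniform(size=40)
    dec = fdr_two_stage(p, q=0.1)
    if dec.any():
        assert p[dec].max() <= p[~dec].min() or not (~dec).any()


# ----------------------------------------------------------- region tables

def test_region_table_recovers_planted_effect():
    cfg = SynthConfig(seed=3, n_nodes=20, n_timepoints=10,
                      groups=(("placebo", 8), ("CBD", 8), ("THC", 8)),
                      module_sizes=[5, 5, 5, 5])
    spec = EffectSpec(rois=cfg.node_names()[:4],
                      shifts={("THC", "washout"): -0.2}, noise_cv=0.03)
    table = gen_measure_table(cfg, seed=3, effect_spec=spec, measure="FA")
    out = region_table(table, measure="FA", session="washout", q=0.2)
    top = set(out.nsmallest(4, "p")["roi_name"])
    assert top == set(spec.rois)
    assert out.nsmallest(4, "p")["passes_fdr"].all()
    assert set(out.columns) >= {"pattern", "omega_sq", "critical_3dp"}


def test_percent_difference_chain_recovers_sign():
    """Generated DA-system tables show the planted chronic THC shrinkage in
    nearly every seed."""
    from mouseconn.synth import default_da_rois
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = SynthConfig(seed=seed, n_nodes=16, n_timepoints=10,
                          groups=(("placebo", 1), ("THC", 1)),
                          sessions=("chronic",),
                          module_sizes=[8, 8])
        table = gen_measure_table(cfg, seed=seed, measure="volume_mm3")
        table = normalize_volumes(table)
        frac = table[table.measure == "volume_fraction"]
        da = default_da_rois(cfg)
        diffs = []
        for roi in da:
            a = frac[(frac.group == "placebo")
                     & (frac.roi_name == roi)]["value"].item()
            b = frac[(frac.group == "THC")
                     & (frac.roi_name == roi)]["value"].item()
            pa, pb = percent_pair(a, b)
            diffs.append(pb - pa)
        hits += np.mean(diffs) < 0
    assert hits >= 0.95 * n_seeds
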