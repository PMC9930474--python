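"""Synthetic cohort, atlas and measure-table generators."""

import numpy as np
import pytest

from mouseconn.connectome import correlate, density_threshold, graph_from_matrix
from mouseconn.modularity import consensus_partition
from mouseconn.sweep import metric_sweep
from mouseconn.synth import (
    AtlasSpec,
    EffectSpec,
    SynthConfig,
    default_module_sizes,
    gen_atlas,
    gen_cohort,
    gen_measure_table,
)
from mouseconn.types import ValidationError


def tiny_config(**kw):
    defaults = dict(seed=1, n_nodes=20, n_timepoints=60,
                    groups=(("placebo", 2), ("THC", 2)),
                    sessions=("chronic",),
                    module_sizes=[5, 5, 5, 5],
                    drift_amplitude=0.0, spike_rate=0.0, noise_sd=0.0)
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.mark.parametrize("bad, fieldname", [
    (dict(n_timepoints=2), "n_timepoints"),
    (dict(module_sizes=[10, 5]), "module_sizes"),
    (dict(within_module_corr=0.1, between_module_corr=0.3),
     "within_module_corr"),
    (dict(effect_multipliers={("THC", "chronic"): -1.0}),
     "effect_multipliers"),
    (dict(sample_interval=0.0), "sample_interval"),
])
def test_invalid_config_names_field(bad, fieldname):
    with pytest.raises(ValidationError, match=fieldname):
        tiny_config(**bad)


def test_cohort_shape_and_determinism():
    cfg = tiny_config(spike_rate=1.0, noise_sd=0.2)
    cohort = gen_cohort(cfg)
    assert len(cohort) == 4  # 2 groups x 2 subjects x 1 session
    for s in cohort:
        assert s.data.shape == (20, 60)
    again = gen_cohort(tiny_config(spike_rate=1.0, noise_sd=0.2))
    for a, b in zip(cohort, again):
        assert a.subject_id == b.subject_id
        assert a.censored_frames == b.censored_frames
        np.testing.assert_array_equal(a.data, b.data)


def test_planted_correlation_recovered_at_long_t():
    """Empirical within/between-block correlations approach their targets."""
    cfg = tiny_config(n_timepoints=1000, within_module_corr=0.6,
                      between_module_corr=0.0,
                      groups=(("placebo", 3),))
    cohort = gen_cohort(cfg)
    aff = cfg.module_affiliation()
    within = (aff[:, None] == aff[None, :]) & ~np.eye(20, dtype=bool)
    between = aff[:, None] != aff[None, :]
    r = np.mean([np.corrcoef(s.data) for s in cohort], axis=0)
    assert r[within].mean() == pytest.approx(0.6, abs=0.05)
    assert abs(r[between].mean()) < 0.05
    assert r[between].std() < 0.1  # sampling noise only


def test_unit_multipliers_make_sessions_exchangeable():
    cfg = tiny_config(sessions=("chronic", "washout"), effect_multipliers={})
    cohort = gen_cohort(cfg)
    aff = cfg.module_affiliation()
    within = (aff[:, None] == aff[None, :]) & ~np.eye(20, dtype=bool)
    by_session = {}
    for s in cohort:
        by_session.setdefault(s.session, []).append(
            np.corrcoef(s.data)[within].mean())
    diff = abs(np.mean(by_session["chronic"]) - np.mean(by_session["washout"]))
    assert diff < 0.1  # same generative law, different draws


def test_spikes_recorded_and_bounded():
    cfg = tiny_config(spike_rate=3.0, noise_sd=0.5)
    for s in gen_cohort(cfg):
        assert all(0 <= f < 60 for f in s.censored_frames)


def test_multiplier_cannot_invert_block_structure():
    with pytest.raises(ValidationError, match="effect_multipliers"):
        gen_cohort(tiny_config(within_module_corr=0.3,
                               between_module_corr=0.25,
                               effect_multipliers={("THC", "chronic"): 0.5}))


# ---------------------------------------------------------------- atlas

def atlas_spec(counts):
    return AtlasSpec(grid_shape=(10, 10, 5), voxel_dims=(0.2, 0.2, 0.5),
                     label_voxel_counts=counts,
                     label_names={k: f"roi{k}" for k in counts})


def test_atlas_counts_exact_and_conserved():
    spec = atlas_spec({1: 100, 2: 37, 5: 60})
    image, names = gen_atlas(spec, seed=3)
    assert image.shape == (10, 10, 5)
    for label, count in spec.label_voxel_counts.items():
        assert (image == label).sum() == count
    assert (image > 0).sum() == 197
    assert set(names["label"]) == {1, 2, 5}


def test_atlas_empty_and_overfull():
    image, _ = gen_atlas(atlas_spec({}), seed=0)
    assert (image == 0).all()
    with pytest.raises(ValidationError, match="capacity"):
        atlas_spec({1: 600})


def test_atlas_deterministic():
    spec = atlas_spec({1: 50, 2: 50})
    a, _ = gen_atlas(spec, seed=11)
    b, _ = gen_atlas(spec, seed=11)
    np.testing.assert_array_equal(a, b)


# -------------------------------------------------------- measure tables

def test_measure_table_exact_shift_no_noise():
    cfg = tiny_config()
    spec = EffectSpec(rois=cfg.node_names()[:3],
                      shifts={("THC", "chronic"): -0.1217}, noise_cv=0.0)
    table = gen_measure_table(cfg, seed=5, effect_spec=spec)
    pl = table[(table.group == "placebo") & table.roi_name.isin(spec.rois)]
    th = table[(table.group == "THC") & table.roi_name.isin(spec.rois)]
    ratio = (th.groupby("roi_name")["value"].mean()
             / pl.groupby("roi_name")["value"].mean())
    np.testing.assert_allclose(ratio, 0.8783, rtol=1e-12)


def test_measure_table_unknown_roi_raises():
    cfg = tiny_config()
    with pytest.raises(KeyError, match="nonexistent"):
        gen_measure_table(cfg, seed=0, effect_spec=EffectSpec(
            rois=["nonexistent"], shifts={}))


def test_measure_table_mean_recovery_with_noise():
    """Group means recover the planted shift within 2 SE over replicates."""
    cfg = tiny_config()
    spec = EffectSpec(rois=cfg.node_names()[:3],
                      shifts={("THC", "chronic"): -0.1}, noise_cv=0.05)
    ratios = []
    for rep in range(60):
        table = gen_measure_table(cfg, seed=100 + rep, effect_spec=spec)
        pl = table[(table.group == "placebo") & table.roi_name.isin(spec.rois)]
        th = table[(table.group == "THC") & table.roi_name.isin(spec.rois)]
        ratios.append(th["value"].mean() / pl["value"].mean())
    se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(np.mean(ratios) - 0.9) <= 2 * se + 1e-3


def test_measure_table_deterministic():
    cfg = tiny_config()
    a = gen_measure_table(cfg, seed=9)
    b = gen_measure_table(cfg, seed=9)
    assert a.equals(b)


# ------------------------------------------- downstream recoverability

def test_consensus_recovers_planted_modules():
    """At within 0.6 / between 0.1, the downstream consensus partition
    finds the planted modules (mean NMI >= 0.9 across seeds)."""
    from sklearn.metrics import normalized_mutual_info_score
    nmis = []
    for seed in range(20):
        cfg = SynthConfig(seed=seed, n_nodes=60, n_timepoints=200,
                          groups=(("placebo", 1),), sessions=("chronic",),
                          module_sizes=default_module_sizes(60, 4),
                          within_module_corr=0.6, between_module_corr=0.1,
                          spike_rate=0.0)
        series = gen_cohort(cfg)[0]
        g = density_threshold(graph_from_matrix(correlate(series)), 0.16)
        part = consensus_partition(g, n_iter=25, seed=seed)
        nmis.append(normalized_mutual_info_score(cfg.module_affiliation(),
                                                 part.affiliation))
    assert np.mean(nmis) >= 0.9


def test_modularity_auc_monotone_in_effect_multiplier():
    """Raising the (CBD, washout) multiplier raises mean modularity AUC."""
    mults = (1.0, 1.3, 1.6)
    means = []
    for mult in mults:
        aucs = []
        for seed in range(20):
            cfg = SynthConfig(seed=seed, n_nodes=60, n_timepoints=200,
                              groups=(("CBD", 1),), sessions=("washout",),
                              module_sizes=default_module_sizes(60, 4),
                              effect_multipliers={("CBD", "washout"): mult},
                              spike_rate=0.0)
            series = gen_cohort(cfg)[0]
            sw = metric_sweep(correlate(series), metrics=("modularity",),
                              seed=seed)
            aucs.append(sw.auc["modularity"])
        means.append(np.mean(aucs))
    assert means[0] < means[1] < means[2]
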