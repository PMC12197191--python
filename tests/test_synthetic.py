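import numpy as np
import pytest
from scipy.integrate import quad

from nirsda.core_data import DomainKey, ExperimentDesign, tuberlin_design, tufts_design
from nirsda.da_losses import KernelSpec, mmd
from nirsda.synthetic_fnirs import (
    GeneratorConfig,
    HRFModel,
    generate_dataset,
    hrf_response,
    sample_domain_effects,
)


def small_design(**overrides) -> ExperimentDesign:
    kwargs = dict(
        name="custom", n_subjects=2, sessions_per_subject=2, blocks_per_session=4,
        trials_per_block=6, block_condition_order=(0, 1, 1, 0), window_seconds=2.0,
        sampling_rate=10.0, n_spatial_channels=8, n_hemoglobin_types=2,
        n_optical_types=1, class_set=(0, 1),
    )
    kwargs.update(overrides)
    return ExperimentDesign(**kwargs)


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

def test_hrf_onset_and_peak():
    model = HRFModel()
    assert hrf_response(np.array([0.0]), model)[0] == 0.0
    assert hrf_response(np.array([model.peak_seconds]), model)[0] == pytest.approx(1.0)


def test_hrf_max_on_dense_grid_is_one():
    t = np.linspace(0, 40, 8001)
    h = hrf_response(t, HRFModel())
    assert h.max() == pytest.approx(1.0, abs=1e-9)


def test_hrf_has_undershoot():
    t = np.linspace(0, 40, 2001)
    h = hrf_response(t, HRFModel())
    assert h.min() < -0.01  # the tail dips below zero


def test_hrf_integral_matches_quadrature():
    """Sampled-sum integral agrees with adaptive quadrature of the curve."""
    model = HRFModel()
    t = np.linspace(0, 60, 60_001)
    riemann = np.trapezoid(hrf_response(t, model), t)
    exact, _ = quad(lambda s: float(hrf_response(np.array([s]), model)[0]), 0, 60,
                    limit=200)
    assert riemann == pytest.approx(exact, abs=1e-4)


def test_hrf_rejects_negative_time():
    with pytest.raises(ValueError):
        hrf_response(np.array([-1.0]), HRFModel())


# ---------------------------------------------------------------------------
# corpus structure
# ---------------------------------------------------------------------------

def test_published_trial_counts_per_condition():
    """One subject of the three-session n-back preset: 180 epochs per
    condition (20 trials x 3 blocks x 3 sessions)."""
    es = generate_dataset(GeneratorConfig(design=tuberlin_design(1), seed=0))
    labels, counts = np.unique(es.labels, return_counts=True)
    assert dict(zip(labels.tolist(), counts.tolist())) == {0: 180, 2: 180, 3: 180}


def test_published_single_session_total():
    """One participant of the 16-block single-session preset: 640 epochs."""
    es = generate_dataset(GeneratorConfig(design=tufts_design(1), seed=0))
    assert len(es) == 640


def test_same_seed_identical_corpora():
    cfg = GeneratorConfig(design=small_design(), seed=11)
    a = generate_dataset(cfg)
    b = generate_dataset(GeneratorConfig(design=small_design(), seed=11))
    np.testing.assert_array_equal(a.X, b.X)
    assert a.meta.equals(b.meta)


def test_different_seed_differs():
    a = generate_dataset(GeneratorConfig(design=small_design(), seed=1))
    b = generate_dataset(GeneratorConfig(design=small_design(), seed=2))
    assert not np.array_equal(a.X, b.X)


def test_structure_follows_design():
    design = small_design()
    es = generate_dataset(GeneratorConfig(design=design, seed=0))
    meta = es.meta
    assert meta.subject_id.nunique() == design.n_subjects
    per_block = meta.groupby(["subject_id", "session_idx", "block_idx"]).size()
    assert (per_block == design.trials_per_block).all()
    for (_, sess, blk), grp in meta.groupby(["subject_id", "session_idx", "block_idx"]):
        assert (grp.label == design.block_condition(sess, blk)).all()


# ---------------------------------------------------------------------------
# signal structure
# ---------------------------------------------------------------------------

def _noise_free_config(design, **overrides):
    kwargs = dict(
        design=design, subject_gain_sd=0.0, subject_offset_sd=0.0,
        session_offset_sd=0.0, block_drift_sd=0.0, measurement_noise_sd=1e-12,
        physio_oscillation_amplitude=0.0, seed=0,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def test_zero_shift_same_class_epochs_identical():
    """No domain effects and vanishing noise: same-class epochs coincide
    across subjects, sessions and blocks."""
    es = generate_dataset(_noise_free_config(small_design()))
    for label in (0, 1):
        idx = np.flatnonzero(es.labels == label)
        ref = es[int(idx[0])].data
        for i in idx[1:]:
            np.testing.assert_allclose(es[int(i)].data, ref, atol=1e-6)


def test_hbr_is_negated_scaled_hbo():
    design = small_design()
    cfg = _noise_free_config(design, informative_channel_fraction=1.0)
    es = generate_dataset(cfg)
    ep = es[0].data.astype(float)
    hbo = ep[:, design.hbo_columns()]
    hbr = ep[:, design.hbr_columns()]
    np.testing.assert_allclose(hbr, -cfg.hbr_ratio * hbo, atol=1e-6)


def test_class_mean_amplitude_monotone():
    """Mean informative-channel HbO amplitude follows the class gain order."""
    design = small_design(class_set=(0, 1), block_condition_order=(0, 1, 1, 0))
    cfg = GeneratorConfig(design=design, seed=4,
                          class_amplitudes={0: 0.4, 1: 1.4})
    es = generate_dataset(cfg)
    info_cols = np.concatenate(
        [design.feature_columns(c) for c in cfg.informative_channels()]
    )
    hbo_info = np.intersect1d(design.hbo_columns(), info_cols)
    means = {}
    for label in (0, 1):
        X = es.X[es.labels == label].astype(float)
        means[label] = X[:, :, hbo_info].mean()
    assert means[1] > means[0]


def test_uninformative_channels_carry_no_class_signal():
    design = small_design()
    cfg = _noise_free_config(design, informative_channel_fraction=0.25)
    es = generate_dataset(cfg)
    quiet = [c for c in range(design.n_spatial_channels)
             if c not in cfg.informative_channels()]
    quiet_cols = np.concatenate([design.feature_columns(c) for c in quiet])
    m0 = es.X[es.labels == 0][:, :, quiet_cols].mean()
    m1 = es.X[es.labels == 1][:, :, quiet_cols].mean()
    assert abs(m0 - m1) < 1e-6


# ---------------------------------------------------------------------------
# domain effects
# ---------------------------------------------------------------------------

def test_zero_sds_give_zero_effects():
    design = small_design()
    cfg = _noise_free_config(design)
    effects = sample_domain_effects(cfg)
    for table in effects.values():
        for eff in table.values():
            for v in eff.values():
                assert np.allclose(v, 0.0)


def test_effect_tables_keyed_uniquely():
    cfg = GeneratorConfig(design=small_design(), seed=0)
    effects = sample_domain_effects(cfg)
    assert len(effects["subject"]) == 2
    assert len(effects["session"]) == 4
    assert len(effects["block"]) == 16
    key = DomainKey("S000", 1, 2, "block")
    assert key in effects["block"]


def test_block_effect_sample_sd_matches_config():
    """Law of large numbers: ~10000 blocks reproduce the configured SD."""
    design = small_design(
        n_subjects=4, sessions_per_subject=5, blocks_per_session=500,
        trials_per_block=1,
        block_condition_order=tuple([0, 1] * 250),
    )
    cfg = GeneratorConfig(design=design, block_drift_sd=1.0, seed=8)
    effects = sample_domain_effects(cfg)
    offsets = np.array([e["offset"] for e in effects["block"].values()])
    assert len(offsets) == 10_000
    assert abs(offsets.std() - 1.0) < 0.05


def test_effects_match_generated_corpus():
    """sample_domain_effects returns exactly the effects generate_dataset
    applies: a pure block offset shifts that block's epochs by it."""
    design = small_design()
    cfg = _noise_free_config(design, block_drift_sd=0.5)
    cfg2 = GeneratorConfig(**{**cfg.__dict__, "block_drift_sd": 0.0})
    shifted = generate_dataset(cfg)
    flat = generate_dataset(cfg2)
    effects = sample_domain_effects(cfg)
    ep_s, ep_f = shifted[0], flat[0]
    be = effects["block"][DomainKey(ep_s.subject_id, ep_s.session_idx,
                                    ep_s.block_idx, "block")]
    # remove the known ramp component at the first sample of the block
    T = design.n_timesteps
    block_len = design.trials_per_block * T
    frac = (ep_s.trial_idx * T + np.arange(T)) / (block_len - 1)
    drift = be["offset"][None, :] + be["ramp"] * (frac - 0.5)[:, None]
    diff = ep_s.data.astype(float) - ep_f.data.astype(float) - drift
    np.testing.assert_allclose(diff, be["gain_jitter"] * ep_f.data.astype(float),
                               atol=1e-5)


def test_block_drift_increases_between_block_mmd():
    """Empirical MMD between two blocks' same-class epochs grows with the
    configured block drift (averaged over seeds)."""
    design = small_design()
    spec = KernelSpec(bandwidths=(5.0,))

    def mean_mmd(drift_sd):
        vals = []
        for seed in range(10):
            cfg = GeneratorConfig(design=design, block_drift_sd=drift_sd, seed=seed)
            es = generate_dataset(cfg)
            meta = es.meta
            a = meta[(meta.subject_id == "S000") & (meta.session_idx == 0)
                     & (meta.block_idx == 0)].epoch_idx.to_numpy()
            b = meta[(meta.subject_id == "S000") & (meta.session_idx == 0)
                     & (meta.block_idx == 3)].epoch_idx.to_numpy()  # same condition 0
            Xa = es.X[a].reshape(len(a), -1).astype(float)
            Xb = es.X[b].reshape(len(b), -1).astype(float)
            vals.append(float(mmd(Xa, Xb, spec)))
        return np.mean(vals)

    assert mean_mmd(1.0) > mean_mmd(0.0)


def test_invalid_config_rejected():
    design = small_design()
    with pytest.raises(ValueError):
        GeneratorConfig(design=design, ar1_coefficient=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(design=design, informative_channel_fraction=0.0)
    with pytest.raises(ValueError):
        GeneratorConfig(design=design, measurement_noise_sd=-0.1)
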