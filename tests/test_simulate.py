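import numpy as np
import pytest

import avcond as av
from avcond.simulate import attenuation_factor, injection_gain


@pytest.fixture(scope="module")
def small_config():
    return av.DesignConfig(n_blocks=2, trials_per_block=22, targets_per_block=2,
                           seed=4)


@pytest.fixture(scope="module")
def small_schedule(small_config):
    return av.generate_schedule(small_config)


def test_noiseless_average_recovers_auditory_template(layout, small_schedule,
                                                      small_config):
    effects = av.default_effects(layout, srate=500.0, noise_sd=0.0,
                                 white_sd=0.0, attenuation_rate=0.0,
                                 similarity_gain=0.0)
    ep = av.simulate_session(small_schedule, layout, effects, seed=0,
                             config=small_config)
    a1 = (ep.meta["trial_type"] == "A1-trial").to_numpy()
    avg = ep.data[a1].mean(axis=0)
    audio = ep.time_mask(0.0, 600.0)
    assert np.allclose(avg[:, audio], effects.auditory_template, atol=1e-12)


def test_full_injection_places_visual_template_in_audio_period(
        layout, small_config):
    # pick a schedule seed whose last non-target trial is an A1 trial
    cfg = small_config
    schedule = None
    for seed in range(20):
        cand = av.generate_schedule(av.DesignConfig(
            n_blocks=cfg.n_blocks, trials_per_block=cfg.trials_per_block,
            targets_per_block=cfg.targets_per_block, seed=seed))
        nt = cand["trial_type"].isin(["A1-trial", "A2-trial"])
        if cand.loc[nt[nt].index.max(), "trial_type"] == "A1-trial":
            schedule = cand
            break
    assert schedule is not None
    kwargs = dict(srate=500.0, noise_sd=0.0, white_sd=0.0,
                  attenuation_rate=0.0)
    with_inj = av.default_effects(layout, similarity_gain=1.0, **kwargs)
    without = av.default_effects(layout, similarity_gain=0.0, **kwargs)
    ep1 = av.simulate_session(schedule, layout, with_inj, seed=0, config=cfg)
    ep0 = av.simulate_session(schedule, layout, without, seed=0, config=cfg)
    nt = ep1.meta["trial_type"].isin(["A1-trial", "A2-trial"]).to_numpy()
    last = int(np.nonzero(nt)[0].max())
    diff = ep1.data[last] - ep0.data[last]
    window = ep1.time_mask(200.0, 650.0)
    n_in = int(window.sum())
    # injection gain is exactly 1 on the final non-target trial, truncated
    # at the end of the tone+gap
    assert np.allclose(diff[:, window], with_inj.visual_template[:, :n_in],
                       atol=1e-12)
    assert np.allclose(diff[:, ~window], 0.0, atol=1e-12)


def test_pwpe_coupling_slope_recovered_by_regression(layout, small_schedule,
                                                     small_config):
    effects = av.default_effects(layout, srate=500.0, noise_sd=0.0,
                                 white_sd=0.0, similarity_gain=0.0,
                                 pwpe_coupling=2.0)
    # zero the evoked templates so the coupling is the only signal
    effects.auditory_template = np.zeros_like(effects.auditory_template)
    effects.visual_template = np.zeros_like(effects.visual_template)
    a1 = (small_schedule["trial_type"] == "A1-trial").to_numpy()
    rng = np.random.default_rng(0)
    pwpe = rng.uniform(0.05, 0.5, a1.sum())
    ep = av.simulate_session(small_schedule, layout, effects,
                             pwpe={"A1": pwpe}, seed=0, config=small_config)
    oz = layout.names.index("Oz")  # coupling profile peaks at 1 there
    window = ep.time_mask(900.0, 1200.0)
    amp = ep.data[a1][:, oz, window].mean(axis=-1)
    slope = np.polyfit(pwpe, amp, 1)[0]
    assert slope == pytest.approx(2.0, abs=1e-8)


def test_pwpe_shape_mismatch_rejected(layout, small_schedule, small_config):
    effects = av.default_effects(layout, srate=500.0)
    with pytest.raises(ValueError, match="pwpe"):
        av.simulate_session(small_schedule, layout, effects,
                            pwpe={"A1": np.ones(3)}, seed=0,
                            config=small_config)


def test_simulation_deterministic_given_seed(layout, small_schedule,
                                             small_config):
    effects = av.default_effects(layout, srate=500.0)
    a = av.simulate_session(small_schedule, layout, effects, seed=7,
                            config=small_config)
    b = av.simulate_session(small_schedule, layout, effects, seed=7,
                            config=small_config)
    assert np.array_equal(a.data, b.data)


def test_zero_effects_make_conditions_exchangeable(layout, small_config):
    """With no planted effects the tones are undecodable (AUC ~ 0.5)."""
    cfg = av.DesignConfig(n_blocks=4, trials_per_block=32, targets_per_block=2,
                          seed=8)
    schedule = av.generate_schedule(cfg)
    effects = av.default_effects(layout, srate=500.0, attenuation_rate=0.0,
                                 similarity_gain=0.0, pwpe_coupling=0.0)
    ep = av.simulate_session(schedule, layout, effects, seed=1, config=cfg)
    nt = ep.meta["trial_type"].isin(["A1-trial", "A2-trial"]).to_numpy()
    # a handful of audio-period timepoints is enough for a null check
    t_idx = np.nonzero(ep.time_mask(100.0, 600.0))[0][::50]
    data = ep.data[np.ix_(np.nonzero(nt)[0], np.arange(27), t_idx)]
    labels = ep.meta.loc[nt, "trial_type"].to_numpy()
    res = av.decode_timecourse(data, labels, seed=0)
    assert abs(res.auc.mean() - 0.5) < 0.08


def test_attenuation_factor_phase_means():
    # averages 1 over the first third of positions and 1-rate over the last
    pos = np.linspace(0, 1, 3001)
    f = attenuation_factor(pos, 0.4)
    assert f[pos <= 1 / 3].mean() == pytest.approx(1.0, abs=1e-3)
    assert f[pos >= 2 / 3].mean() == pytest.approx(0.6, abs=1e-3)
    assert injection_gain(1.0, 0.7) == pytest.approx(0.7)


def test_epochset_hdf5_round_trip(layout, small_schedule, small_config,
                                  tmp_path):
    effects = av.default_effects(layout, srate=500.0)
    ep = av.simulate_session(small_schedule, layout, effects, seed=2,
                             config=small_config)
    path = tmp_path / "session.h5"
    ep.save(path)
    back = av.EpochSet.load(path)
    assert np.allclose(back.data, ep.data)
    assert back.srate == ep.srate
    assert back.layout.names == ep.layout.names
    assert (back.meta["trial_type"] == ep.meta["trial_type"]).all()
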