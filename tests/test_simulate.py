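import numpy as np
import pytest
from scipy import stats as sps

from gvscreen import features as F
from gvscreen.session import read_session, write_session
from gvscreen.simulate import (CohortConfig, HC_MEAN, PD_MEAN, SubjectProfile,
                               default_profiles, generate_source,
                               hc_mean_params, simulate_cohort,
                               simulate_segment, simulate_trial)
from gvscreen.features import CENTRAL_CHANNELS

FS = 1000


def _params(**over):
    p = dict(HC_MEAN)
    p.update(over)
    return p


class TestSegment:
    def test_shape_and_determinism(self):
        prof = default_profiles(CohortConfig())[0]
        a = simulate_segment(prof, 2000, FS, 42, ("Cz", "C3"))
        b = simulate_segment(prof, 2000, FS, 42, ("Cz", "C3"))
        assert a.shape == (2, 2000)
        assert np.array_equal(a, b)

    def test_channel_subset_bit_identical(self):
        prof = default_profiles(CohortConfig())[3]
        full = simulate_segment(prof, 2000, FS, 1, CENTRAL_CHANNELS)
        sub = simulate_segment(prof, 2000, FS, 1, ("Cz", "CP5"))
        assert np.array_equal(full[CENTRAL_CHANNELS.index("Cz")], sub[0])
        assert np.array_equal(full[CENTRAL_CHANNELS.index("CP5")], sub[1])

    def test_minimum_length_enforced(self):
        prof = default_profiles(CohortConfig())[0]
        with pytest.raises(ValueError, match="1 s"):
            simulate_segment(prof, 500, FS, 0, ("Cz",))

    def test_no_oscillation_beta_fraction_matches_background(self):
        # with beta_amp=0 and pac_depth=0 the beta-band power fraction should
        # match the pure 1/f expectation over many seeds
        p = _params(beta_amp=0.0, pac_depth=0.0, noise_sd=0.0,
                    aperiodic_exponent=1.0, aperiodic_offset=0.5)
        fracs = []
        for s in range(100):
            src = generate_source(p, 2000, FS, np.random.default_rng(s))
            _, rel = F.band_powers(src, FS)
            fracs.append(rel)
        # expectation for PSD ~ 1/f: int(13..30 df/f) / int(1..45 df/f)
        expected = np.log(30 / 13) / np.log(45 / 1)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)

    def test_exponent_recovery(self):
        p = _params(beta_amp=0.0, pac_depth=0.0, noise_sd=0.0,
                    aperiodic_exponent=2.0, aperiodic_offset=0.5)
        est = [F.aperiodic_fit(generate_source(p, 2000, FS,
                                               np.random.default_rng(s)), FS)[0]
               for s in range(50)]
        assert np.mean(est) == pytest.approx(2.0, abs=0.2)

    def test_pac_depth_increases_mi(self):
        means = {}
        for depth in (0.0, 0.8):
            p = _params(pac_depth=depth, beta_amp=2.0, noise_sd=0.5)
            vals = [F.tort_mi(generate_source(p, 2000, FS,
                                              np.random.default_rng(s)), FS)
                    for s in range(50)]
            means[depth] = np.mean(vals)
        assert means[0.8] > means[0.0]

    def test_positive_shape_asym_gives_positive_pt_asym(self):
        p = _params(shape_asym=0.5, beta_amp=5.0, noise_sd=0.3,
                    aperiodic_offset=0.3)
        pts = [F.waveform_shape(generate_source(p, 2000, FS,
                                                np.random.default_rng(s)),
                                FS)[0] for s in range(50)]
        assert int(np.sum(np.array(pts) > 0)) >= 45


@pytest.fixture(scope="module")
def setup(library):
    cfg = CohortConfig(n_hc=2, n_pd=2, channel_names=CENTRAL_CHANNELS,
                       master_seed=3)
    profiles = default_profiles(cfg)
    pd_prof = [p for p in profiles if p.group == "PD"][0]
    return cfg, profiles, pd_prof, hc_mean_params(profiles)


class TestTrial:

    def test_delta_zero_equals_baseline_stim(self, setup, library):
        cfg, _, prof, hc_mean = setup
        t0 = simulate_trial(prof, library[5], 0.0, hc_mean, (3, 0, 0), cfg)
        assert t0.data.shape == (13, 9000)
        # delta=0 trial equals a trial generated with delta implicitly 0
        t1 = simulate_trial(prof, library[5], 0.0, hc_mean, (3, 0, 0), cfg)
        assert np.array_equal(t0.data, t1.data)

    def test_effect_confined_to_stim_interval(self, setup, library):
        cfg, _, prof, hc_mean = setup
        t0 = simulate_trial(prof, library[5], 0.0, hc_mean, (3, 0, 1), cfg)
        t1 = simulate_trial(prof, library[5], 0.8, hc_mean, (3, 0, 1), cfg)
        fs = cfg.fs
        assert np.array_equal(t0.data[:, :2 * fs], t1.data[:, :2 * fs])
        assert np.array_equal(t0.data[:, 4 * fs:], t1.data[:, 4 * fs:])
        assert not np.array_equal(t0.data[:, 2 * fs:4 * fs],
                                  t1.data[:, 2 * fs:4 * fs])

    def test_delta_one_stim_equals_hc_mean_generator(self, setup, library):
        cfg, _, prof, hc_mean = setup
        t1 = simulate_trial(prof, library[5], 1.0, hc_mean, (3, 1, 2), cfg)
        hc_prof = SubjectProfile(subject_id="X", group="PD", **hc_mean)
        t2 = simulate_trial(hc_prof, library[5], 0.0, hc_mean, (3, 1, 2), cfg)
        fs = cfg.fs
        assert np.array_equal(t1.data[:, 2 * fs:4 * fs],
                              t2.data[:, 2 * fs:4 * fs])

    def test_sham_forces_delta_zero(self, setup, library):
        cfg, _, prof, hc_mean = setup
        sham = [s for s in library if s.family == "sham"][0]
        t1 = simulate_trial(prof, sham, 0.9, hc_mean, (3, 2, 3), cfg)
        t0 = simulate_trial(prof, sham, 0.0, hc_mean, (3, 2, 3), cfg)
        assert np.array_equal(t0.data, t1.data)

    def test_hc_never_shifted(self, setup, library):
        cfg, profiles, _, hc_mean = setup
        hc = [p for p in profiles if p.group == "HC"][0]
        t1 = simulate_trial(hc, library[5], 0.9, hc_mean, (3, 3, 4), cfg)
        t0 = simulate_trial(hc, library[5], 0.0, hc_mean, (3, 3, 4), cfg)
        assert np.array_equal(t0.data, t1.data)

    def test_bad_delta_rejected(self, setup, library):
        cfg, _, prof, hc_mean = setup
        with pytest.raises(ValueError, match="delta"):
            simulate_trial(prof, library[5], 1.5, hc_mean, (3, 0, 0), cfg)


class TestCohort:
    def test_shapes_and_schema(self, mini_cohort):
        assert len(mini_cohort.subject_ids) == 4
        trials = list(mini_cohort.iter_trials("PD01"))
        assert len(trials) == 12
        assert all(t.data.shape == (13, 9000) for t in trials)
        truth = mini_cohort.ground_truth()
        assert list(truth.columns) == ["subject_id", "group", "stim_id",
                                       "category_id", "delta"]
        assert len(truth) == 4 * 12

    def test_same_seed_identical(self, library):
        cfg = CohortConfig(n_hc=1, n_pd=1, n_trials=3,
                           channel_names=CENTRAL_CHANNELS, master_seed=11)
        a = next(simulate_cohort(cfg, library).iter_trials("PD01"))
        b = next(simulate_cohort(cfg, library).iter_trials("PD01"))
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self, library):
        cfg1 = CohortConfig(n_hc=1, n_pd=1, n_trials=3,
                            channel_names=CENTRAL_CHANNELS, master_seed=1)
        cfg2 = CohortConfig(n_hc=1, n_pd=1, n_trials=3,
                            channel_names=CENTRAL_CHANNELS, master_seed=2)
        a = next(simulate_cohort(cfg1, library).iter_trials("PD01"))
        b = next(simulate_cohort(cfg2, library).iter_trials("PD01"))
        assert a.data.shape == b.data.shape
        assert not np.array_equal(a.data, b.data)

    def test_trial_order_is_permutation(self, mini_cohort):
        order = mini_cohort.trial_order("HC01")
        assert sorted(order) == sorted(s.stim_id for s in
                                       mini_cohort.library[:12])

    def test_pre_window_matches_full_trial(self, mini_cohort):
        trial = next(mini_cohort.iter_trials("HC02"))
        pw = mini_cohort.pre_window("HC02", 0, ("Cz",))
        idx = trial.channel_names.index("Cz")
        assert np.array_equal(trial.data[idx, :2000], pw[0])

    def test_planted_group_contrast(self, library):
        # PD pre-stim beta power, PAC, burst-ish envelope exceed HC means;
        # HC sample entropy exceeds PD
        vals = {"HC": [], "PD": []}
        for grp, mean in (("HC", HC_MEAN), ("PD", PD_MEAN)):
            for s in range(25):
                src = generate_source(dict(mean), 2000, FS,
                                      np.random.default_rng(s))
                bp, _ = F.band_powers(src, FS)
                mi = F.tort_mi(src, FS)
                se = F.sample_entropy(F._entropy_signal(src, FS,
                                                        F.DEFAULT_CONFIG))
                vals[grp].append((bp, mi, se))
        hc, pd_ = np.mean(vals["HC"], axis=0), np.mean(vals["PD"], axis=0)
        assert pd_[0] > hc[0]  # beta power
        assert pd_[1] > hc[1]  # PAC
        assert hc[2] > pd_[2]  # entropy

    def test_null_effect_stim_matches_pre_distribution(self, library):
        # with all deltas zero, stim-interval biomarkers are distributed like
        # pre-interval biomarkers (KS test at a scaled-down cohort size)
        cfg = CohortConfig(n_hc=0, n_pd=1, n_trials=60, effect_map={},
                           channel_names=CENTRAL_CHANNELS, master_seed=5)
        cohort = simulate_cohort(cfg, library)
        pre_v, stim_v = [], []
        for trial in cohort.iter_trials("PD01"):
            idx = trial.channel_names.index("Cz")
            wins = F.segment_trial(trial.data, trial.fs)
            pre_v.append(F.band_powers(wins["pre"][0][idx], FS)[1])
            stim_v.append(F.band_powers(wins["stim"][0][idx], FS)[1])
        assert sps.ks_2samp(pre_v, stim_v).pvalue > 0.01

    def test_too_many_trials_rejected(self, library):
        cfg = CohortConfig(n_trials=305, channel_names=CENTRAL_CHANNELS)
        with pytest.raises(ValueError, match="library"):
            simulate_cohort(cfg, library)


@pytest.fixture(scope="module")
def session_dir(library, tmp_path_factory):
    cfg = CohortConfig(n_hc=1, n_pd=1, n_trials=2,
                       channel_names=CENTRAL_CHANNELS, master_seed=9)
    cohort = simulate_cohort(cfg, library)
    d = tmp_path_factory.mktemp("session")
    write_session(cohort, d)
    return d, cohort


class TestSessionIO:

    def test_round_trip_within_quantization(self, session_dir):
        d, cohort = session_dir
        sess = read_session(d)
        orig = list(cohort.iter_trials("PD01"))
        back = list(sess.iter_trials("PD01"))
        assert len(back) == len(orig)
        from gvscreen.edfio import quantization_step
        for a, b in zip(orig, back):
            assert a.stim_id == b.stim_id
            assert np.max(np.abs(a.data - b.data)) <= quantization_step()

    def test_events_row_count(self, session_dir):
        d, cohort = session_dir
        sess = read_session(d)
        ev = sess.events("HC01")
        assert list(ev.columns) == ["trial_index", "stim_id", "onset_sample"]
        assert len(ev) == 2
        assert list(ev["onset_sample"]) == [2000, 11000]

    def test_missing_events_file_raises(self, session_dir):
        d, _ = session_dir
        sess = read_session(d)
        with pytest.raises(FileNotFoundError, match="events"):
            sess.events("PD99")

    def test_missing_edf_named_in_error(self, session_dir, tmp_path):
        d, _ = session_dir
        sess = read_session(d)
        (d / "PD01_events.csv").rename(tmp_path / "stash.csv")
        try:
            (tmp_path / "stash.csv").rename(d / "PD02_events.csv")
            with pytest.raises(FileNotFoundError, match="PD02"):
                list(sess.iter_trials("PD02"))
        finally:
            (d / "PD02_events.csv").rename(d / "PD01_events.csv")

    def test_missing_library_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="library"):
            read_session(tmp_path)
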