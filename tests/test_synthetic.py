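"""The synthetic cohort generator: determinism, anchors, embedded effects."""
import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from fcrkit import (GeneratorConfig, generate_behavior, generate_cohort,
                    generate_emg_session, generate_fa_volume,
                    read_emg_session, roi_mean, subject_fcr, subject_fits,
                    write_emg_session)
from fcrkit.emg import session_curve_points


def cfg_with(**kw) -> GeneratorConfig:
    return dataclasses.replace(GeneratorConfig(), **kw)


class TestConfig:
    def test_defaults_valid(self):
        GeneratorConfig()

    @pytest.mark.parametrize("kw", [
        {"paretic_fcr_mean": 5.0},                      # mean outside range
        {"intensity_grid": (100.0, 110.0)},             # too few points
        {"intensity_grid": (100.0, 100.0, 120.0)},      # not increasing
        {"severity_range": (0.5, 0.1)},                 # unordered
        {"severity_range": (-0.2, 0.8)},                # outside [0,1]
        {"emg_noise_sd": -1.0},
        {"fa_lesioned_mean": 0.6, "fa_intact_mean": 0.5},
    ])
    def test_invalid_configs_refused(self, kw):
        with pytest.raises(ValueError):
            cfg_with(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = cfg_with(n_subjects=7, seed=3, emg_noise_sd=0.001)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert GeneratorConfig.from_yaml(p) == cfg


class TestCohort:
    def test_same_seed_identical_cohorts(self):
        cfg = cfg_with(n_subjects=8, seed=123)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_different_seeds_differ(self):
        a = generate_cohort(cfg_with(n_subjects=8, seed=1))
        b = generate_cohort(cfg_with(n_subjects=8, seed=2))
        assert a != b

    def test_too_small_cohort_refused(self):
        with pytest.raises(ValueError, match=">= 3"):
            generate_cohort(cfg_with(n_subjects=2))

    def test_degenerate_severity_collapses_variance(self):
        cohort = generate_cohort(cfg_with(n_subjects=6,
                                          severity_range=(0.0, 0.0)))
        fcrs = [s.true_fcr["paretic"] for s in cohort]
        asyms = [s.true_fa["contralesional"] - s.true_fa["lesioned"]
                 for s in cohort]
        assert np.ptp(fcrs) == 0.0
        assert np.ptp(asyms) == 0.0
        assert asyms[0] == 0.0     # severity 0 = undamaged tract

    def test_nonparetic_fcr_population_mean(self):
        """Large low-noise cohort: mean non-paretic FCR sits at 0.55."""
        cohort = generate_cohort(cfg_with(n_subjects=200, seed=17))
        mean = np.mean([s.true_fcr["non-paretic"] for s in cohort])
        assert mean == pytest.approx(0.55, abs=0.02)

    def test_paretic_fcr_monotone_in_severity(self):
        cohort = generate_cohort(cfg_with(n_subjects=30, seed=5))
        sev = [s.severity for s in cohort]
        fcr = [s.true_fcr["paretic"] for s in cohort]
        order = np.argsort(sev)
        assert np.all(np.diff(np.asarray(fcr)[order]) >= 0)

    def test_ranges_respected(self):
        cfg = cfg_with(n_subjects=100, seed=9)
        for s in generate_cohort(cfg):
            assert cfg.paretic_fcr_range[0] <= s.true_fcr["paretic"] \
                <= cfg.paretic_fcr_range[1]
            assert 0 <= s.true_fm <= 34
            assert s.true_walk_time_s > 0
            assert all(v > 0 for v in s.true_slopes.values())


class TestEmgSession:
    def test_at_threshold_mep_is_zero_without_noise(self, noiseless_config,
                                                    noiseless_cohort):
        from fcrkit import window_area
        state = noiseless_cohort[0]
        trials = generate_emg_session(state, noiseless_config)
        at_mt = [t for t in trials if t.intensity == 100.0]
        assert at_mt
        for t in at_mt:
            assert window_area(t, noiseless_config.mep_window) == 0.0

    def test_pretrigger_contains_baseline_only(self, noiseless_config,
                                               noiseless_cohort):
        cfg = noiseless_config
        t = generate_emg_session(noiseless_cohort[0], cfg)[-1]
        pre = t.samples[t.times_ms < 0]
        assert np.allclose(pre, cfg.tonic_emg_mv)

    def test_doubling_slope_doubles_block_means(self, noiseless_config,
                                                noiseless_cohort):
        cfg = noiseless_config
        state = noiseless_cohort[0]
        doubled = dataclasses.replace(
            state, true_slopes={k: 2 * v for k, v in state.true_slopes.items()})
        pts = session_curve_points(generate_emg_session(state, cfg),
                                   cfg.mep_window, cfg.pre_trigger_window)
        pts2 = session_curve_points(generate_emg_session(doubled, cfg),
                                    cfg.mep_window, cfg.pre_trigger_window)
        for key in pts:
            for a, b in zip(pts[key], pts2[key]):
                assert b.response == pytest.approx(2 * a.response, abs=1e-12)

    def test_same_seed_identical_traces(self, default_config):
        cfg = dataclasses.replace(default_config, n_subjects=3, seed=44)
        s = generate_cohort(cfg)[0]
        t1 = generate_emg_session(s, cfg)
        t2 = generate_emg_session(s, cfg)
        assert all(np.array_equal(a.samples, b.samples)
                   for a, b in zip(t1, t2))

    def test_columnar_roundtrip(self, tmp_path, noiseless_config,
                                noiseless_cohort):
        trials = generate_emg_session(noiseless_cohort[0], noiseless_config)[:6]
        meta = write_emg_session(trials, tmp_path)
        back = read_emg_session(meta)
        assert len(back) == 6
        for a, b in zip(trials, back):
            assert np.allclose(a.samples, b.samples)
            assert a.intensity == b.intensity
            assert a.stimulated_hemisphere == b.stimulated_hemisphere


class TestFaVolume:
    def test_zero_noise_roi_mean_exact(self, noiseless_config,
                                       noiseless_cohort):
        state = noiseless_cohort[0]
        v = generate_fa_volume(state, noiseless_config)
        assert roi_mean(v["fa"], v["plic_lesioned"]) \
            == pytest.approx(state.true_fa["lesioned"], abs=1e-12)
        assert roi_mean(v["fa"], v["plic_intact"]) \
            == pytest.approx(state.true_fa["contralesional"], abs=1e-12)

    def test_alic_symmetric(self, noiseless_config, noiseless_cohort):
        v = generate_fa_volume(noiseless_cohort[0], noiseless_config)
        assert roi_mean(v["fa"], v["alic_lesioned"]) \
            == pytest.approx(roi_mean(v["fa"], v["alic_intact"]))

    def test_severity_zero_empty_lesion(self):
        cfg = cfg_with(n_subjects=3, severity_range=(0.0, 0.0))
        v = generate_fa_volume(generate_cohort(cfg)[0], cfg)
        assert v["lesion"].data.sum() == 0.0

    def test_cst_descends_through_plic(self, noiseless_config,
                                       noiseless_cohort):
        v = generate_fa_volume(noiseless_cohort[0], noiseless_config)
        assert 0 <= v["cst"].data.min() and v["cst"].data.max() <= 1
        in_plic = v["cst"].data[v["plic_lesioned"].data.astype(bool)]
        out = v["cst"].data[~(v["plic_lesioned"].data.astype(bool)
                              | v["plic_intact"].data.astype(bool))]
        assert in_plic.mean() > out.mean()

    def test_too_small_volume_refused(self):
        cfg = cfg_with(n_subjects=3, volume_shape=(4, 4, 4))
        with pytest.raises(ValueError, match="fit the ROIs"):
            generate_fa_volume(generate_cohort(cfg)[0], cfg)


class TestBehavior:
    def _state_with_walk_time(self, t_s):
        cohort = generate_cohort(cfg_with(n_subjects=3))
        return dataclasses.replace(cohort[0], true_walk_time_s=t_s)

    def test_unit_conversion(self):
        fm, speed = generate_behavior(self._state_with_walk_time(60.0))
        assert speed == pytest.approx(10.0)

    def test_table_row_inversion(self):
        # 10 m in 6.685 s -> 89.75 m/min at 2 dp
        _, speed = generate_behavior(self._state_with_walk_time(6.685))
        assert round(speed, 2) == 89.75

    def test_fm_clipped_to_scale_maximum(self):
        state = self._state_with_walk_time(10.0)
        assert 0 <= generate_behavior(state)[0] <= 34
        with pytest.raises(ValueError):
            dataclasses.replace(state, true_fm=40)


class TestEmbeddedEffects:
    """Generative structure the downstream battery is meant to detect."""

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_paretic_fcr_tracks_walking_speed(self, seed):
        cfg = cfg_with(n_subjects=50, seed=seed)
        cohort = generate_cohort(cfg)
        est = []
        for s in cohort:
            fits = subject_fits(generate_emg_session(s, cfg), cfg)
            est.append(subject_fcr(fits)["paretic"].fcr)
        speed = [generate_behavior(s)[1] for s in cohort]
        assert sps.spearmanr(est, speed)[0] < 0

    def test_nonparetic_fcr_null_centered_on_zero(self):
        rhos = []
        for seed in (7, 17, 27, 37, 47, 57):
            cfg = cfg_with(n_subjects=50, seed=seed)
            cohort = generate_cohort(cfg)
            fcr_np = [s.true_fcr["non-paretic"] for s in cohort]
            speed = [generate_behavior(s)[1] for s in cohort]
            rhos.append(sps.spearmanr(fcr_np, speed)[0])
        assert abs(np.mean(rhos)) < 0.2

    def test_control_roi_null_but_plic_signal(self):
        """ALIC asymmetry carries no severity signal; PLIC asymmetry does."""
        from fcrkit import fa_asymmetry, roi_stats
        cfg = cfg_with(n_subjects=50, seed=13)
        cohort = generate_cohort(cfg)
        alic, plic, sev = [], [], []
        for s in cohort:
            v = generate_fa_volume(s, cfg)
            plic.append(roi_stats(v["fa"], v["plic_lesioned"],
                                  v["plic_intact"], "PLIC").fa_asymmetry)
            alic.append(roi_stats(v["fa"], v["alic_lesioned"],
                                  v["alic_intact"], "ALIC").fa_asymmetry)
            sev.append(s.severity)
        assert abs(sps.spearmanr(alic, sev)[0]) < 0.3
        assert sps.spearmanr(plic, sev)[0] > 0.9
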