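"""Generator self-consistency: the synthetic cohorts must carry the
structure the analysis assumes, and the pipeline must recover it."""

import numpy as np
import pandas as pd
import pytest

from betalock.behavior import apomorphine_classify, openfield_features, segment_states
from betalock.core_io import (
    ChannelMeta,
    Episode,
    SessionConfig,
    StateIntervals,
    read_session,
)
from betalock.spectral import band_power, spectrogram, state_locked_psd
from betalock.core_io import BANDS, LOW_BETA
from betalock.synthetic_data import (
    CohortConfig,
    EffectConfig,
    gen_behavior_sequence,
    gen_cohort,
    gen_lfp,
    gen_rotation_record,
    gen_tracking,
)


def _episodes(dur=60.0):
    return [Episode(0.0, dur, False)]


def _config(dur=60.0, group="sham", subject="SH01", assignment="sham"):
    return SessionConfig(paradigm="cylinder", episodes=_episodes(dur), group=group,
                         subject_id=subject, assignment=assignment)


class TestBehaviorGenerator:
    def test_fixed_seed_reproducible(self):
        out1 = gen_behavior_sequence(60.0, "sham", _episodes(), np.random.default_rng(3))
        out2 = gen_behavior_sequence(60.0, "sham", _episodes(), np.random.default_rng(3))
        assert out1[0].intervals == out2[0].intervals
        np.testing.assert_array_equal(out1[1].codes, out2[1].codes)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_segmentation_recovers_generating_states(self, seed):
        rng = np.random.default_rng(seed)
        states, codes, rot = gen_behavior_sequence(120.0, "PD", _episodes(120.0), rng)
        recovered = segment_states(codes, rot)
        # time-weighted agreement on a fine grid
        grid = np.arange(0.0, 120.0, 0.05) + 0.025
        truth = np.array([states.state_at(t) for t in grid])
        est = np.array([recovered.state_at(t) for t in grid])
        assert (truth == est).mean() >= 0.95

    def test_lesioned_subjects_more_inactive_than_sham(self):
        diffs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            pd_states, *_ = gen_behavior_sequence(120.0, "PD", _episodes(120.0), rng)
            rng = np.random.default_rng(100 + seed)
            sh_states, *_ = gen_behavior_sequence(120.0, "sham", _episodes(120.0), rng)

            def frac_inactive(st):
                return sum(b - a for a, b, s in st.intervals if s == "inactive") / 120.0

            diffs.append(frac_inactive(pd_states) > frac_inactive(sh_states))
        assert np.mean(diffs) >= 0.9


class TestLfpGenerator:
    def test_pink_background_slope(self):
        """With all oscillations off, the log-log PSD slope matches -1."""
        effects = EffectConfig(theta_base=0.0, theta_gain=0.0, beta_amp_intact=0.0)
        states = StateIntervals([(0.0, 60.0, "inactive")])
        ch = [ChannelMeta("M1", "left", False, "SH01", "sham")]
        rec = gen_lfp(states, _config(), ch, effects, np.random.default_rng(0))
        psd = state_locked_psd(rec, states, "inactive")
        mask = (psd.freqs >= 5) & (psd.freqs <= 100)
        slope = np.polyfit(np.log(psd.freqs[mask]), np.log(psd.power[mask]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_injected_lesion_effect_recovered(self):
        """Doubled low-beta burst amplitude on the lesioned side shows up as a
        raw band-power ratio above 1.5 in a rearing-rich session."""
        effects = EffectConfig(
            lesion_gain={("rearing", "low_beta"): 2.0, ("rearing", "high_beta"): 1.0,
                         ("stepping", "low_beta"): 1.0}
        )
        states = StateIntervals([(0.0, 60.0, "rearing")])
        cfg = _config(group="PD", subject="PD01", assignment="PD-DBS OFF")
        chans = [
            ChannelMeta("M1", "left", False, "PD01", "PD"),
            ChannelMeta("M1", "right", True, "PD01", "PD"),
        ]
        rec = gen_lfp(states, cfg, chans, effects, np.random.default_rng(1))
        powers = {}
        for hemi in ("left", "right"):
            psd = state_locked_psd(rec.select(hemisphere=hemi), states, "rearing")
            powers[hemi] = band_power(psd, LOW_BETA, "raw")
        assert powers["right"] / powers["left"] > 1.5

    def test_dbs_artifact_only_during_on_episodes(self):
        effects = EffectConfig(dbs_artifact_amp=20.0)
        states = StateIntervals([(0.0, 20.0, "inactive")])
        cfg = SessionConfig(
            paradigm="cylinder",
            episodes=[Episode(0.0, 10.0, False), Episode(10.0, 20.0, True)],
            group="PD", subject_id="PD01", assignment="PD-DBS ON",
        )
        ch = [ChannelMeta("M1", "right", True, "PD01", "PD")]
        rec = gen_lfp(states, cfg, ch, effects, np.random.default_rng(2))
        spg = spectrogram(rec, window_len=1.0, overlap=0.0)
        fi = np.argmin(np.abs(spg.freqs - 130.0))
        on_cols = spg.times > 11.0
        off_cols = spg.times < 9.0
        assert spg.power[fi, on_cols].min() > 50 * spg.power[fi, off_cols].max()
        peak_f = spg.freqs[np.argmax(spg.power[:, on_cols].mean(axis=1))]
        assert peak_f == pytest.approx(130.0, abs=1.0)

    def test_missing_effect_key_is_configuration_error(self):
        effects = EffectConfig()
        from betalock.core_io import ValidationError

        with pytest.raises(ValidationError, match="effect"):
            effects.beta_amp(True, "rearing", "gamma", False)

    def test_fixed_seed_bit_identical(self):
        states = StateIntervals([(0.0, 10.0, "inactive")])
        ch = [ChannelMeta("M1", "left", False, "SH01", "sham")]
        a = gen_lfp(states, _config(10.0), ch, EffectConfig(), np.random.default_rng(5))
        b = gen_lfp(states, _config(10.0), ch, EffectConfig(), np.random.default_rng(5))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestTrackingGenerator:
    def test_positions_confined_to_arena(self):
        rng = np.random.default_rng(0)
        states, *_ = gen_behavior_sequence(120.0, "sham", _episodes(120.0), rng)
        tr = gen_tracking(states, rng)
        assert tr.x.min() >= 0 and tr.x.max() <= 74
        assert tr.y.min() >= 0 and tr.y.max() <= 74
        assert tr.n_frames == int(120 * 25)

    def test_all_inactive_states_give_full_immobility(self):
        states = StateIntervals([(0.0, 60.0, "inactive")])
        tr = gen_tracking(states, np.random.default_rng(1))
        from betalock.behavior import compute_speed

        speed = compute_speed(tr)
        f = openfield_features(speed, tr.fps, [(0.0, 60.0, False)])
        assert f.immobility_time >= 55.0

    def test_fixed_seed_reproducible(self):
        states = StateIntervals([(0.0, 20.0, "stepping")])
        a = gen_tracking(states, np.random.default_rng(9))
        b = gen_tracking(states, np.random.default_rng(9))
        np.testing.assert_array_equal(a.x, b.x)


class TestRotationRecord:
    def test_zero_rate_all_zero(self):
        counts = gen_rotation_record(0.0, np.random.default_rng(0))
        assert counts.shape == (30,)
        assert np.all(counts == 0)

    def test_poisson_mean_within_ci(self):
        means = [gen_rotation_record(5.0, np.random.default_rng(s)).mean()
                 for s in range(20)]
        assert np.mean(np.abs(np.array(means) - 5.0) <= 1.0) >= 0.95

    def test_rate_six_classified_lesioned(self):
        hits = [apomorphine_classify(gen_rotation_record(6.0, np.random.default_rng(s)))
                for s in range(20)]
        assert all(hits)


class TestCohort:
    def test_small_cohort_layout_and_manifest(self, tmp_path):
        cfg = CohortConfig(n_pd=3, n_sham=2, n_dbs_on=2, n_dbs_off=1,
                           paradigms=("cylinder",), regions=("M1",))
        manifest = gen_cohort(cfg, tmp_path / "coh", seed=11)
        assert len(manifest) == 5
        assert (manifest["assignment"] == "PD-DBS ON").sum() == 2
        assert manifest["seed"].nunique() == 5
        for sid in manifest["subject_id"]:
            bundle = read_session(tmp_path / "coh" / sid / "cylinder")
            assert bundle.lfp.n_channels == 2  # M1 left + right
            assert bundle.codes is not None and bundle.rotation is not None
        assert (tmp_path / "coh" / "manifest.csv").exists()

    def test_default_composition_is_13_pd_7on_6off_12_sham(self):
        cfg = CohortConfig()
        assert (cfg.n_pd, cfg.n_sham, cfg.n_dbs_on, cfg.n_dbs_off) == (13, 12, 7, 6)

    def test_inconsistent_split_rejected(self):
        from betalock.core_io import ValidationError

        with pytest.raises(ValidationError):
            CohortConfig(n_pd=13, n_dbs_on=7, n_dbs_off=7)
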