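"""Preprocessing chain: masking, discarding, scrubbing, filtering, regression."""

import numpy as np
import pytest

from conftest import make_ts
from igtnet.preprocess import (
    apply_mask,
    bandpass,
    build_gray_matter_mask,
    discard_initial,
    extract_confounds,
    framewise_displacement,
    nuisance_regress,
    preprocess_block,
    scrub_volumes,
)
from igtnet.synthetic import rest_params, simulate_timeseries
from igtnet.timeseries import ConfoundSet
from igtnet.volumes import LabeledVolume, LabelInfo


def tiny_atlas():
    labels = np.zeros((4, 4, 4), dtype=int)
    labels[:2] = 1  # gray
    labels[2] = 91  # white
    labels[3] = 92  # csf
    table = {
        1: LabelInfo("gray", "gray"),
        91: LabelInfo("wm", "white"),
        92: LabelInfo("csf", "csf"),
    }
    return LabeledVolume(labels=labels, affine=np.eye(4), label_table=table)


class TestGrayMatterMask:
    def test_hand_enumerated_rule(self):
        atlas = tiny_atlas()
        gm = atlas.tissue_mask("gray").astype(float)
        wm = np.zeros(atlas.shape)
        csf = np.zeros(atlas.shape)
        wm[0, 0, 0] = 1.0  # pure WM inside an atlas-gray voxel -> excluded
        wm[1, 0, 0] = 0.5  # partial WM -> kept
        csf[3] = 1.0
        mask = build_gray_matter_mask(gm, wm, csf, atlas)
        # brute-force per-voxel rule
        expected = np.zeros(atlas.shape, dtype=bool)
        for idx in np.ndindex(atlas.shape):
            whole = (gm[idx] + wm[idx] + csf[idx]) > 0
            expected[idx] = whole and atlas.labels[idx] == 1 and wm[idx] < 0.99
        assert np.array_equal(mask, expected)
        assert not mask[0, 0, 0]
        assert mask[1, 0, 0]

    def test_shape_mismatch_rejected(self):
        atlas = tiny_atlas()
        with pytest.raises(ValueError, match="shape"):
            build_gray_matter_mask(
                np.zeros((3, 3, 3)), np.zeros(atlas.shape),
                np.zeros(atlas.shape), atlas,
            )


class TestDiscard:
    def test_120_minus_10(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((5, 120)))
        out = discard_initial(ts, 10)
        assert out.n_timepoints == 110
        assert out.kept_volume_index[0] == 10

    def test_zero_is_identity(self):
        ts = make_ts(np.arange(20, dtype=float).reshape(2, 10))
        out = discard_initial(ts, 0)
        assert np.array_equal(out.data, ts.data)

    def test_discarding_everything_rejected(self):
        ts = make_ts(np.ones((2, 5)) * np.arange(5))
        with pytest.raises(ValueError):
            discard_initial(ts, 5)


class TestScrub:
    def test_framewise_displacement_hand_computed(self):
        motion = np.zeros((4, 6))
        motion[2, 0] = 1.0  # 1 mm translation step at volume 2
        motion[3, 4] = 0.01  # 0.01 rad rotation step at volume 3
        fd = framewise_displacement(motion)
        np.testing.assert_allclose(fd, [0.0, 0.0, 1.0, 1.0 + 50 * 0.01])

    def test_zero_motion_removes_nothing(self):
        ts = make_ts(np.random.default_rng(1).standard_normal((3, 20)))
        out, removed = scrub_volumes(ts, np.zeros((20, 6)), 0.5)
        assert len(removed) == 0
        assert out.n_timepoints == 20

    def test_injected_step_removes_exactly_that_volume(self):
        ts = make_ts(np.random.default_rng(2).standard_normal((3, 30)))
        motion = np.zeros((30, 6))
        motion[12:, 1] = 2.0  # sustained 2 mm step at volume 12
        out, removed = scrub_volumes(ts, motion, 0.5)
        assert list(removed) == [12]
        assert 12 not in out.kept_volume_index

    def test_infinite_threshold_is_identity(self):
        ts = make_ts(np.random.default_rng(3).standard_normal((3, 10)))
        motion = np.random.default_rng(4).normal(size=(10, 6))
        out, removed = scrub_volumes(ts, motion, np.inf)
        assert len(removed) == 0

    def test_scrubbing_composes_with_discard(self):
        ts = make_ts(np.random.default_rng(5).standard_normal((3, 30)))
        motion = np.zeros((30, 6))
        motion[20:, 0] = 3.0
        out = discard_initial(ts, 10)
        out, removed = scrub_volumes(out, motion, 0.5)
        assert 20 not in out.kept_volume_index
        assert out.n_timepoints == 19

    def test_all_removed_rejected(self):
        ts = make_ts(np.random.default_rng(6).standard_normal((3, 6)))
        # FD of the first volume is 0 by convention, so only a negative
        # threshold can flag every volume; the guard must still reject it
        with pytest.raises(ValueError, match="every volume"):
            scrub_volumes(ts, np.zeros((6, 6)), -1.0)


class TestBandpass:
    def _sine(self, freq, tr=2.0, n=400):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq * t)

    def test_passband_sine_retained(self):
        ts = make_ts(self._sine(0.04)[None, :])
        out = bandpass(ts)
        # compare amplitude at 0.04 Hz via FFT
        f = np.fft.rfftfreq(ts.n_timepoints, d=2.0)
        bin04 = np.argmin(np.abs(f - 0.04))
        a_in = np.abs(np.fft.rfft(ts.data[0]))[bin04]
        a_out = np.abs(np.fft.rfft(out.data[0]))[bin04]
        assert a_out / a_in > 0.95

    def test_stopband_sine_attenuated(self):
        ts = make_ts(self._sine(0.2)[None, :])
        out = bandpass(ts)
        assert out.data.std() < 0.1 * ts.data.std()

    def test_dc_removed(self):
        ts = make_ts(np.full((2, 200), 7.0) + 0.0)
        out = bandpass(ts)
        assert np.abs(out.data).max() < 0.5

    def test_zero_phase(self):
        # forward-backward filtering: a pass-band sine comes out unshifted
        # and at unit gain, so away from the edges it matches the input
        x = self._sine(0.04)
        out = bandpass(make_ts(x[None, :])).data[0]
        np.testing.assert_allclose(out[50:-50], x[50:-50], atol=0.05)

    def test_high_edge_above_nyquist_rejected(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((2, 50)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, high=0.3)  # Nyquist at TR=2 s is 0.25 Hz


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_confounds(self, rng):
        ts = make_ts(rng.standard_normal((6, 80)))
        conf = ConfoundSet(rng.standard_normal((80, 3)), ["a", "b", "c"])
        out = nuisance_regress(ts, conf)
        inner = out.data @ conf.columns
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)

    def test_intercept_only_demeans(self, rng):
        ts = make_ts(rng.standard_normal((4, 50)) + 5.0)
        conf = ConfoundSet(np.empty((50, 0)), [])
        out = nuisance_regress(ts, conf)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            out.data, ts.data - ts.data.mean(axis=1, keepdims=True)
        )

    def test_planted_global_component_removed(self, rng):
        g = rng.standard_normal(100)
        noise = rng.standard_normal((5, 100))
        ts = make_ts(2.0 * g[None, :] + noise)
        conf = ConfoundSet(g[:, None], ["global_mean"])
        out = nuisance_regress(ts, conf)
        for row in out.data:
            assert abs(np.corrcoef(row, g)[0, 1]) < 1e-10

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.standard_normal(40)
        conf = ConfoundSet(np.column_stack([x, 2 * x]), ["wm_mean", "wm_double"])
        ts = make_ts(rng.standard_normal((3, 40)))
        with pytest.raises(ValueError, match="wm_double"):
            nuisance_regress(ts, conf)

    def test_mismatched_length_rejected(self, rng):
        ts = make_ts(rng.standard_normal((3, 40)))
        conf = ConfoundSet(rng.standard_normal((30, 2)), ["a", "b"])
        with pytest.raises(ValueError, match="timepoints"):
            nuisance_regress(ts, conf)


class TestFullChain:
    def test_voxel_count_equals_mask_count(self, small_atlas):
        blk = simulate_timeseries(small_atlas, "rest", rest_params(seed=9))
        gm_mask = small_atlas.tissue_mask("gray")
        clean, report = preprocess_block(blk.ts, blk.motion, gm_mask)
        assert clean.n_voxels == int(gm_mask.sum()) == 120
        assert report["n_voxels"] == 120

    def test_mask_application_idempotent(self, small_atlas):
        blk = simulate_timeseries(small_atlas, "rest", rest_params(seed=9, n_timepoints=30))
        gm_mask = small_atlas.tissue_mask("gray")
        once = apply_mask(blk.ts, gm_mask)
        twice = apply_mask(once, gm_mask)
        assert np.array_equal(once.data, twice.data)

    def test_global_regression_removes_global_signal(self, small_atlas):
        p = rest_params(seed=10, global_signal_sd=2.0, n_timepoints=80)
        blk = simulate_timeseries(small_atlas, "rest", p)
        gm_mask = small_atlas.tissue_mask("gray")
        conf = extract_confounds(blk.ts, blk.motion, gm_mask=gm_mask)
        assert "global_mean" in conf.names
        out = nuisance_regress(blk.ts, conf)
        g = conf.columns[:, conf.names.index("global_mean")]
        corr = out.data @ g  # residuals orthogonal to the regressed global
        np.testing.assert_allclose(corr, 0.0, atol=1e-8)

    def test_regress_then_filter_order_supported(self, small_atlas):
        blk = simulate_timeseries(small_atlas, "rest", rest_params(seed=11))
        gm_mask = small_atlas.tissue_mask("gray")
        clean, _ = preprocess_block(
            blk.ts, blk.motion, gm_mask, filter_before_regression=False
        )
        assert clean.n_voxels == int(gm_mask.sum())
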