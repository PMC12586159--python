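"""Masking rules, ridge filters, distance rims, statistics, group tests."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import csfmobility as cm
from csfmobility.errors import ConfigurationError
from csfmobility.roitools import (MaskConfig, RidgeConfig, csf_mask,
                                  dilation_rims, nonparam_tests, ridge_filter,
                                  roi_stats, stim_response)


class TestCsfMask:
    def _volumes(self):
        rng = np.random.default_rng(0)
        ref = np.abs(rng.normal(0, 20, (12, 12, 12)))
        ref[3:7, 3:7, 3:7] = 1000.0
        structure = np.zeros_like(ref, dtype=bool)
        structure[3:7, 3:7, 3:7] = True
        return ref, structure

    def test_threshold_selects_structure(self):
        ref, structure = self._volumes()
        mask = csf_mask(ref, None, MaskConfig())
        assert np.array_equal(mask, structure)

    def test_excessive_change_excluded(self):
        ref, structure = self._volumes()
        change = np.zeros_like(ref)
        change[4, 4, 4] = 60.0  # > 50% change in the random dataset
        mask = csf_mask(ref, [change], MaskConfig())
        assert not mask[4, 4, 4]
        assert mask.sum() == structure.sum() - 1

    def test_lonely_voxel_removed(self):
        ref, structure = self._volumes()
        ref[10, 10, 10] = 1000.0  # isolated voxel
        mask = csf_mask(ref, None, MaskConfig())
        assert not mask[10, 10, 10]
        assert np.array_equal(mask, structure)

    def test_rule_order_independence(self):
        ref, _ = self._volumes()
        rng = np.random.default_rng(1)
        changes = [rng.normal(0, 40, ref.shape) for _ in range(3)]
        expected = csf_mask(ref, changes, MaskConfig())
        for perm in itertools.permutations(changes):
            assert np.array_equal(csf_mask(ref, list(perm), MaskConfig()),
                                  expected)


class TestRidgeFilter:
    def _tube_and_sphere(self, n=24):
        vol_t = np.zeros((n, n, n))
        vol_s = np.zeros((n, n, n))
        c = n // 2
        ij = np.arange(n)
        Y, Z = np.meshgrid(ij, ij, indexing="ij")
        tube = (Y - c) ** 2 + (Z - c) ** 2 <= 1.5**2
        vol_t[4:-4, tube] = 100.0
        X, Y, Z = np.meshgrid(ij, ij, ij, indexing="ij")
        sphere = (X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= 4**2
        vol_s[sphere] = 100.0
        return vol_t, vol_s, c

    def test_uniform_volume_gives_zero(self):
        resp, _ = ridge_filter(np.ones((16, 16, 16)), RidgeConfig(),
                               voxel_size=1.0)
        assert np.allclose(resp, 0.0)

    def test_tube_beats_sphere(self):
        vol_t, vol_s, c = self._tube_and_sphere()
        cfg = RidgeConfig(sigmas=(0.6, 0.8, 1.0))
        rt, _ = ridge_filter(vol_t, cfg, voxel_size=0.5)
        rs, _ = ridge_filter(vol_s, cfg, voxel_size=0.5)
        centerline = rt[8:-8, c, c]
        assert np.median(centerline) > rs[c, c, c]

    def test_thin_tube_centerline_recall(self):
        n = 24
        vol = np.zeros((n, n, n))
        c = n // 2
        vol[3:-3, c, c] = 100.0  # radius ~1 voxel tube
        cfg = RidgeConfig(sigmas=(0.6, 0.8, 1.0), threshold=1e-4)
        resp, mask = ridge_filter(vol, cfg, voxel_size=1.0)
        recall = mask[3:-3, c, c].mean()
        assert recall >= 0.9

    def test_anisotropic_voxels_rejected(self):
        with pytest.raises(ConfigurationError):
            ridge_filter(np.zeros((8, 8, 8)), RidgeConfig(),
                         voxel_size=np.array([0.5, 0.5, 1.0]))


class TestRims:
    def test_rim_count_and_partition(self):
        n = 40
        vessel = np.zeros((n, n, n), dtype=bool)
        vessel[:, n // 2, n // 2] = True
        csf = np.ones((n, n, n), dtype=bool)
        mob = np.full((n, n, n), 0.04)
        prof = dilation_rims(vessel, voxel_size=0.17, csf=csf, mobility=mob,
                             step=0.17, max_dist=3.00)
        assert len(prof.distances) == 17
        union = np.zeros((n, n, n), dtype=bool)
        for a, b in itertools.combinations(range(17), 2):
            assert not (prof.rims[a] & prof.rims[b]).any()
        for r in prof.rims:
            union |= r
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~vessel, sampling=[0.17] * 3)
        shell = (dist > 0) & (dist <= 17 * 0.17) & csf
        assert np.array_equal(union, shell)

    def test_uniform_field_uniform_rims(self):
        n = 40
        vessel = np.zeros((n, n, n), dtype=bool)
        vessel[:, n // 2, n // 2] = True
        csf = np.ones((n, n, n), dtype=bool)
        mob = np.full((n, n, n), 0.035)
        prof = dilation_rims(vessel, voxel_size=0.17, csf=csf, mobility=mob)
        got = prof.mobility_mean[prof.voxel_count > 0]
        assert np.allclose(got, 0.035)

    def test_empty_vessel_raises(self):
        with pytest.raises(ConfigurationError):
            dilation_rims(np.zeros((8, 8, 8), bool), 0.17,
                          np.ones((8, 8, 8), bool), np.ones((8, 8, 8)))


class TestRoiStats:
    def test_constant_map(self):
        s = roi_stats(np.full(10, 3.0))
        assert s["sd"] == 0.0 and s["ci_half_width"] == 0.0

    def test_arithmetic_example(self):
        s = roi_stats(np.arange(1.0, 9.0))
        assert s["mean"] == pytest.approx(4.5)
        assert s["sd"] == pytest.approx(2.449, abs=1e-3)
        assert s["ci_half_width"] == pytest.approx(1.697, abs=1e-3)

    def test_single_observation_flagged(self):
        s = roi_stats(np.array([1.0]))
        assert s["degenerate"] and np.isnan(s["ci_half_width"])


class TestNonparamTests:
    def test_separated_groups_exact_mann_whitney(self):
        a = np.arange(10.0, 18.0)
        b = np.arange(0.0, 8.0)
        r = nonparam_tests([a, b], "independent_two")
        assert r["p_value"] == pytest.approx(2 / 12870, rel=1e-12)

    def test_mann_whitney_matches_enumeration_small_n(self):
        # brute-force null enumeration of all C(8,4) group assignments
        from itertools import combinations

        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        a, b = x[:4], x[4:]
        r = nonparam_tests([a, b], "independent_two")
        ranks = rankdata(x)
        u_obs = ranks[:4].sum() - 4 * 5 / 2
        us = []
        for comb in combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(comb)] = True
            us.append(ranks[sel].sum() - 4 * 5 / 2)
        us = np.array(us)
        # two-sided: double the smaller tail (U has a symmetric null)
        tail = min((us <= u_obs).mean(), (us >= u_obs).mean())
        assert r["p_value"] == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    def test_wilcoxon_all_positive_differences(self):
        a = np.arange(1.0, 10.0) + 5
        b = np.arange(1.0, 10.0)
        r = nonparam_tests([a, b], "paired_two")
        assert r["p_value"] == pytest.approx(2 / 2**9, rel=1e-12)

    def test_wilcoxon_matches_signflip_enumeration(self):
        from itertools import product

        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, 7)
        r = nonparam_tests([d + np.arange(7.0), np.arange(7.0)], "paired_two")
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [np.sum(ranks[np.array(signs, bool)])
              for signs in product([0, 1], repeat=7)]
        ws = np.array(ws)
        tail = min((ws <= w_obs).mean(), (ws >= w_obs).mean())
        assert r["p_value"] == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    def test_bonferroni(self):
        a = np.arange(10.0, 18.0)
        b = np.arange(0.0, 8.0)
        r = nonparam_tests([a, b], "independent_two", correction=3)
        assert r["p_corrected"] == pytest.approx(3 * r["p_value"])
        r2 = nonparam_tests([a, b], "independent_two", correction=10**9)
        assert r2["p_corrected"] == 1.0

    def test_friedman_runs(self):
        rng = np.random.default_rng(4)
        g = [rng.normal(i * 0.5, 1.0, 12) for i in range(3)]
        r = nonparam_tests(g, "paired_multi")
        assert 0 <= r["p_value"] <= 1

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            r = nonparam_tests([np.ones(5), np.ones(5)], "paired_two")
        assert r["p_value"] == 1.0


class TestStimResponse:
    def _rois(self):
        active = np.zeros((8, 8, 8), bool)
        active[:4] = True
        return active, ~active

    def test_identical_maps_zero_change(self):
        m = np.full((8, 8, 8), 0.02)
        active, control = self._rois()
        r = stim_response(m, m, active, control)
        assert r["active_change_pct"] == 0.0
        assert r["control_change_pct"] == 0.0

    def test_printed_stimulation_effect(self):
        # +1.2% mobility in the activated region only
        off = np.full((8, 8, 8), 0.02)
        on = off.copy()
        active, control = self._rois()
        on[active] *= 1.012
        r = stim_response(on, off, active, control)
        assert r["active_change_pct"] == pytest.approx(1.2, abs=1e-9)
        assert r["control_change_pct"] == pytest.approx(0.0, abs=1e-12)

    def test_bold_amplitude_block_arithmetic(self):
        block = np.full(20, 100.0)
        block[14:20] = 102.0
        ts = np.tile(block, 3)
        active, control = self._rois()
        m = np.full((8, 8, 8), 0.02)
        r = stim_response(m, m, active, control, bold_timeseries=ts)
        assert r["bold_amplitude_pct"] == pytest.approx(2.0)

    def test_wrong_timeseries_length(self):
        active, control = self._rois()
        m = np.full((8, 8, 8), 0.02)
        with pytest.raises(ConfigurationError):
            stim_response(m, m, active, control, bold_timeseries=np.ones(50))


def test_group_difference_recovery_power():
    """Cohorts at the observed patient/control effect sizes are separable
    in a majority of repetitions (power at n = 8 + 8 is ~0.6, see docs)."""
    rng = np.random.default_rng(0)
    hits = 0
    reps = 100
    for _ in range(reps):
        caa = rng.normal(0.042, 0.006, 8)
        ctl = rng.normal(0.035, 0.005, 8)
        r = nonparam_tests([caa, ctl], "independent_two")
        hits += r["p_value"] < 0.05
    assert hits / reps > 0.5
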