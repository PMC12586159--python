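"""Encoding directions, sampling patterns, shot scheduling, forward model."""

import numpy as np
import pytest

import csfmobility as cm
from csfmobility.errors import ConfigurationError
from csfmobility.sampling import (AcquisitionConfig, centered_fftn,
                                  centered_ifftn, make_pattern,
                                  make_shot_schedule, simulate_subscan)
from csfmobility.tensorfit import design_matrix
from tests.conftest import small_phantom


class TestDirections:
    def test_design_full_rank(self):
        dirs, _ = cm.encoding_directions()
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0)
        assert np.linalg.matrix_rank(design_matrix(dirs)) == 6

    @pytest.mark.parametrize("venc_axis,effective", [(5.0, 3.5), (5.6, 4.0)])
    def test_dual_axis_effective_venc(self, venc_axis, effective):
        _, eff = cm.encoding_directions(venc_axis)
        assert eff == effective


class TestPattern:
    def test_full_sampling(self):
        cfg = AcquisitionConfig(grid=(16, 16), accel_target=1.0, acs_size=9)
        p = make_pattern(cfg)
        assert p.n_profiles == 256
        assert p.acceleration == 1.0

    def test_acs_fully_sampled(self):
        cfg = AcquisitionConfig(grid=(64, 64), acs_size=29, accel_target=4.0,
                                seed=1)
        m = make_pattern(cfg).mask()
        c = 32
        assert m[c - 14:c + 15, c - 14:c + 15].all()
        assert m[c - 14:c + 15, c - 14:c + 15].sum() == 841

    def test_pseudoradial_acceleration_and_determinism(self):
        cfg = AcquisitionConfig(grid=(96, 96), acs_size=13, accel_target=6.0,
                                seed=2)
        p1, p2 = make_pattern(cfg), make_pattern(cfg)
        assert np.array_equal(p1.profiles, p2.profiles)
        assert abs(p1.acceleration - 6.0) / 6.0 < 0.05
        p3 = make_pattern(AcquisitionConfig(grid=(96, 96), acs_size=13,
                                            accel_target=6.0, seed=3))
        assert abs(p3.acceleration - 6.0) / 6.0 < 0.05
        assert not np.array_equal(p1.profiles, p3.profiles)

    def test_pseudoradial_density_decreases_radially(self):
        cfg = AcquisitionConfig(grid=(96, 96), acs_size=13, accel_target=6.0,
                                seed=2)
        m = make_pattern(cfg).mask()
        ky, kz = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        r = np.hypot((ky - 48) / 48, (kz - 48) / 48)
        edges = np.linspace(0.22, 1.0, 6)  # annuli outside the ACS
        dens = [m[(r >= a) & (r < b)].mean()
                for a, b in zip(edges[:-1], edges[1:])]
        assert all(d1 > d2 for d1, d2 in zip(dens[:-1], dens[1:]))

    def test_poisson_acceleration_and_spacing(self):
        cfg = AcquisitionConfig(grid=(128, 96), acs_size=9, accel_target=12.0,
                                pattern_mode="poisson", seed=1)
        p = make_pattern(cfg)
        assert 11.4 <= p.acceleration <= 12.6
        from scipy.spatial import cKDTree

        pts = p.profiles.astype(float)
        d, _ = cKDTree(pts).query(pts, k=2)
        assert d[:, 1].min() > 0

    def test_infeasible_acceleration_raises(self):
        with pytest.raises(ConfigurationError):
            make_pattern(AcquisitionConfig(grid=(32, 32), acs_size=29,
                                           accel_target=4.0))


class TestSchedule:
    def test_single_shot(self):
        cfg = AcquisitionConfig(grid=(16, 16), accel_target=1.0, acs_size=9,
                                tse_factor=8)
        p = make_pattern(cfg)
        from csfmobility.sampling import SamplingPattern

        small = SamplingPattern(profiles=p.profiles[:4], grid=p.grid,
                                acs_size=p.acs_size)
        s = make_shot_schedule(small, cfg)
        assert s.n_shots == 1 and len(s.shot_profiles[0]) == 4

    def test_protocol_shot_arithmetic(self):
        # 14,162 profiles at 146 per shot -> 97 shots spanning 0..326.4 s
        n_prof = 14_162
        assert int(np.ceil(n_prof / 146)) == 97
        start_times = np.arange(97) * 3.4
        assert start_times[-1] == pytest.approx(326.4)

    def test_chunking_and_times(self):
        cfg = AcquisitionConfig(grid=(32, 32), accel_target=1.0, acs_size=9,
                                tse_factor=100, TR=3.4)
        sched = make_shot_schedule(make_pattern(cfg), cfg)
        assert sched.n_shots == int(np.ceil(1024 / 100))
        assert np.allclose(np.diff(sched.start_times), 3.4)
        total = sum(len(s) for s in sched.shot_profiles)
        assert total == 1024
        assert all(len(s) <= 100 for s in sched.shot_profiles)

    def test_repeats_extend_schedule(self):
        cfg = AcquisitionConfig(grid=(16, 16), accel_target=1.0, acs_size=9,
                                tse_factor=64)
        sched = make_shot_schedule(make_pattern(cfg), cfg, repeats=3)
        assert sched.n_shots == 3 * 4
        assert np.array_equal(sched.shot_profiles[0], sched.shot_profiles[4])


class TestForwardModel:
    def _setup(self, noise_sd=0.0, **tube_kwargs):
        truth = small_phantom(noise_sd=noise_sd, **tube_kwargs)
        cfg = AcquisitionConfig(grid=(16, 16), accel_target=1.0, acs_size=9,
                                tse_factor=64)
        sched = make_shot_schedule(make_pattern(cfg), cfg)
        traces = cm.make_physio_traces(sched.duration + 10, jitter=0.0, seed=1)
        return truth, cfg, sched, traces

    def test_zero_tensor_matches_reference(self):
        truth, cfg, sched, traces = self._setup()
        truth.tensor0[:] = 0.0
        ref = simulate_subscan(truth, traces, sched, 0, cfg)
        enc = simulate_subscan(truth, traces, sched, 3, cfg)
        for a, b in zip(ref.samples, enc.samples):
            assert np.allclose(a, b, atol=1e-12)

    def test_isotropic_attenuation_closed_form(self):
        truth, cfg, sched, traces = self._setup()
        iso = 0.04 * np.array([1, 0, 0, 1, 0, 1.0])
        truth.tensor0[truth.mask] = iso
        enc = simulate_subscan(truth, traces, sched, 1, cfg)
        full = np.zeros(truth.signal.shape, dtype=complex)
        for k in range(sched.n_shots):
            p = sched.shot_profiles[k]
            full[:, p[:, 0], p[:, 1]] = enc.samples[k]
        img = centered_ifftn(full).real
        m = truth.mask
        expected = truth.spec.csf_signal * np.exp(-cfg.b_value * 0.04)
        assert np.allclose(img[m], expected, rtol=1e-10)

    def test_fourier_identity_full_sampling(self):
        truth, cfg, sched, traces = self._setup()
        ref = simulate_subscan(truth, traces, sched, 0, cfg)
        full = np.zeros(truth.signal.shape, dtype=complex)
        for k in range(sched.n_shots):
            p = sched.shot_profiles[k]
            full[:, p[:, 0], p[:, 1]] = ref.samples[k]
        img = np.abs(centered_ifftn(full))
        assert np.max(np.abs(img - truth.signal)) <= 1e-10 * truth.signal.max()

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 8, 8))
        k = centered_fftn(x)
        assert np.sum(np.abs(k) ** 2) == pytest.approx(np.sum(x**2), rel=1e-12)

    def test_attenuation_bounds(self):
        truth, cfg, sched, traces = self._setup()
        ref = simulate_subscan(truth, traces, sched, 0, cfg)
        enc = simulate_subscan(truth, traces, sched, 2, cfg)

        def image(sub):
            full = np.zeros(truth.signal.shape, dtype=complex)
            for k in range(sched.n_shots):
                p = sched.shot_profiles[k]
                full[:, p[:, 0], p[:, 1]] = sub.samples[k]
            return centered_ifftn(full).real

        m = truth.mask
        ratio = image(enc)[m] / image(ref)[m]
        assert np.all(ratio > 0) and np.all(ratio <= 1 + 1e-12)

    def test_bad_direction_index(self):
        truth, cfg, sched, traces = self._setup()
        with pytest.raises(ConfigurationError):
            simulate_subscan(truth, traces, sched, 7, cfg)
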