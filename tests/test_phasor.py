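import numpy as np
import pytest

from flimlite.core import DecayCurve, FLIDataset, TimeAxis, ValidityMask
from flimlite.errors import (
    DegenerateAxisError,
    DegenerateCalibrationError,
    EmptyDecayError,
    NotOnCircleError,
    TangencyError,
    ValidationError,
)
from flimlite.phasor import (
    Phasor,
    PhasorCalibration,
    PhasorROI,
    ReferencePair,
    amplitude_avg_lifetime,
    calibrate,
    decay_phasor,
    decompose,
    phase_mod_lifetimes,
    phasor_image,
    phasor_select,
    principal_axis_uc_references,
    uc_lifetime,
    uc_phasor,
)
from flimlite.synthetic import make_irf, simulate_decay, simulate_scene


class TestDecayPhasor:
    def test_delta_at_time_zero(self):
        axis = TimeAxis(4, 12.8, np.array([0.0, 3.2, 6.4, 9.6]))
        d = DecayCurve(axis.bin_centers_ns, np.array([100.0, 0, 0, 0]))
        p = decay_phasor(d, axis)
        assert (p.g, p.s) == (1.0, 0.0)

    def test_uniform_counts_average_to_origin(self, axis256):
        d = DecayCurve(axis256.bin_centers_ns, np.full(256, 7.0))
        p = decay_phasor(d, axis256)
        assert abs(p.g) < 1e-12 and abs(p.s) < 1e-12

    def test_omega_tau_one_lands_near_half_half(self, axis4096, delta_irf):
        """Continuous-limit closed form g = s = 1/2 at omega*tau = 1."""
        w = axis4096.omega()
        tau = 1.0 / w
        irf = delta_irf(axis4096)
        d = simulate_decay((1.0,), (tau,), 0.0, irf, axis4096, 1e6, noiseless=True)
        cal = PhasorCalibration("single", decay_phasor(irf, axis4096), 0.0)
        p = calibrate(decay_phasor(d, axis4096), cal, omega=w)
        # midpoint sampling leaves a ~half-bin phase residual (~4e-4 at
        # 4096 bins); the calibration contract bounds it at 1e-3
        assert abs(p.g - 0.5) < 1e-3 and abs(p.s - 0.5) < 1e-3

    def test_empty_decay_rejected(self, axis256):
        with pytest.raises(EmptyDecayError):
            decay_phasor(DecayCurve(axis256.bin_centers_ns, np.zeros(256)), axis256)

    def test_linearity_over_summed_decays(self, axis256, gauss_irf):
        irf = gauss_irf(axis256)
        a = simulate_decay((1.0,), (1.0,), 0.0, irf, axis256, 5e4, seed=1)
        b = simulate_decay((1.0,), (3.5,), 0.0, irf, axis256, 2e4, seed=2)
        pa, pb = decay_phasor(a, axis256), decay_phasor(b, axis256)
        summed = DecayCurve(axis256.bin_centers_ns, a.counts + b.counts)
        ps = decay_phasor(summed, axis256)
        na, nb = a.total, b.total
        assert abs(ps.g - (na * pa.g + nb * pb.g) / (na + nb)) < 1e-12
        assert abs(ps.s - (na * pa.s + nb * pb.s) / (na + nb)) < 1e-12


class TestPhasorImage:
    def test_matches_per_pixel_loop(self, random_cube):
        ds = random_cube(seed=13)
        pi = phasor_image(ds)
        for r in range(ds.frame_shape[0]):
            for c in range(ds.frame_shape[1]):
                if pi.valid.valid[r, c]:
                    p = decay_phasor(ds.pixel_decay(r, c), ds.time_axis)
                    assert abs(pi.g[r, c] - p.g) < 1e-12
                    assert abs(pi.s[r, c] - p.s) < 1e-12

    def test_homogeneous_cube_constant_maps(self, axis256, gauss_irf):
        d = simulate_decay((1.0,), (2.0,), 0.0, gauss_irf(axis256), axis256, 1e5,
                           noiseless=True)
        cube = np.repeat(d.counts[:, None], 6, axis=1).reshape(256, 2, 3)
        pi = phasor_image(FLIDataset(cube, axis256))
        assert np.ptp(pi.g) < 1e-12 and np.ptp(pi.s) < 1e-12


class TestCalibration:
    def test_identity_and_self_calibration(self):
        cal = PhasorCalibration("single", Phasor(1.0, 0.0), 0.0)
        p = calibrate(Phasor(0.3, 0.4), cal, omega=0.49)
        assert (p.g, p.s) == (0.3, 0.4)
        cal2 = PhasorCalibration("single", Phasor(0.3, 0.4), 0.0)
        p2 = calibrate(Phasor(0.3, 0.4), cal2, omega=0.49)
        assert abs(p2.g - 1.0) < 1e-12 and abs(p2.s) < 1e-12

    def test_self_calibration_with_lifetime_lands_on_uc(self, axis256, gauss_irf):
        """Calibrating a decay by itself with tau_ref = tau gives uc(tau)."""
        w = axis256.omega()
        d = simulate_decay((1.0,), (2.7,), 0.0, gauss_irf(axis256), axis256, 1e5,
                           noiseless=True)
        raw = decay_phasor(d, axis256)
        cal = PhasorCalibration("single", raw, reference_lifetime_ns=2.7)
        p = calibrate(raw, cal, omega=w)
        ideal = uc_phasor(2.7, w)
        assert abs(p.g - ideal.g) < 1e-12 and abs(p.s - ideal.s) < 1e-12

    def test_irf_calibration_convolution_theorem(self, axis4096, gauss_irf):
        """IRF-convolved decay calibrated by the IRF phasor lands on the UC."""
        w = axis4096.omega()
        irf = gauss_irf(axis4096)
        d = simulate_decay((1.0,), (3.0,), 0.0, irf, axis4096, 1e6, noiseless=True)
        cal = PhasorCalibration("single", decay_phasor(irf, axis4096), 0.0)
        p = calibrate(decay_phasor(d, axis4096), cal, omega=w)
        ideal = uc_phasor(3.0, w)
        assert np.hypot(p.g - ideal.g, p.s - ideal.s) < 1e-3

    def test_zero_modulus_calibration_rejected(self):
        with pytest.raises(DegenerateCalibrationError):
            calibrate(Phasor(0.3, 0.4), PhasorCalibration("single", Phasor(0.0, 0.0), 0.0),
                      omega=0.49)

    def test_per_pixel_mode_flattens_irf_shift_gradient(self, axis256):
        """Pixels with different IRF arrival times calibrate to one point."""
        w = axis256.omega()
        shifts = np.linspace(0.0, 0.8, 6).reshape(2, 3)
        g = np.empty((2, 3))
        s = np.empty((2, 3))
        ig = np.empty((2, 3))
        is_ = np.empty((2, 3))
        for idx, shift in np.ndenumerate(shifts):
            irf = make_irf(axis256, 2.0 + shift, 0.3)
            d = simulate_decay((1.0,), (2.0,), 0.0, irf, axis256, 1e5, noiseless=True)
            p = decay_phasor(d, axis256)
            q = decay_phasor(irf, axis256)
            g[idx], s[idx] = p.g, p.s
            ig[idx], is_[idx] = q.g, q.s
        valid = ValidityMask(np.ones((2, 3), bool))
        from flimlite.phasor import PhasorImage

        pi = PhasorImage(g, s, valid, frequency_MHz=axis256.frequency_MHz)
        irf_pi = PhasorImage(ig, is_, valid, frequency_MHz=axis256.frequency_MHz)
        out = calibrate(pi, PhasorCalibration("per_pixel", irf_pi, 0.0))
        assert np.ptp(out.g) < 1e-9 and np.ptp(out.s) < 1e-9


class TestUniversalCircle:
    def test_closed_forms(self):
        w = 0.49
        p = uc_phasor(0.0, w)
        assert (p.g, p.s) == (1.0, 0.0)
        p = uc_phasor(1.0 / w, w)
        assert abs(p.g - 0.5) < 1e-15 and abs(p.s - 0.5) < 1e-15

    def test_round_trip_at_paper_frequency(self):
        w = TimeAxis.regular(16, 1000.0 / 78.02).omega()
        assert abs(uc_lifetime(uc_phasor(3.7, w), w) - 3.7) < 1e-12

    def test_off_circle_point_rejected(self):
        with pytest.raises(NotOnCircleError):
            uc_lifetime(Phasor(0.5, 0.1), omega=0.49)

    def test_phase_mod_lifetimes(self):
        w = 0.49
        tp, tm = phase_mod_lifetimes(Phasor(0.5, 0.5), w)
        assert abs(tp - 1 / w) < 1e-12 and abs(tm - 1 / w) < 1e-12
        tp, tm = phase_mod_lifetimes(Phasor(1.0, 0.0), w)
        assert tp == 0 and tm == 0
        tp, tm = phase_mod_lifetimes(Phasor(0.55, 0.35), w)
        assert abs(tp - (0.35 / 0.55) / w) < 1e-12
        assert abs(tm - np.sqrt(1 / 0.4250 - 1) / w) < 1e-12
        assert tm > tp  # strict inequality inside the UC
        assert phase_mod_lifetimes(Phasor(0.8, 0.65), w)[1] is None  # modulus > 1
        with pytest.raises(ValidationError):
            phase_mod_lifetimes(Phasor(-0.1, 0.5), w)


class TestPrincipalAxisReferences:
    W = TimeAxis.regular(16, 1000.0 / 78.02).omega()

    def test_two_clusters_recover_chord_exactly(self):
        p1, p2 = uc_phasor(1.0, self.W), uc_phasor(4.0, self.W)
        pts = np.array([[p1.g, p1.s]] * 8 + [[p2.g, p2.s]] * 8)
        refs = principal_axis_uc_references(pts, self.W)
        assert abs(refs.tau1_ns - 1.0) < 1e-6
        assert abs(refs.tau2_ns - 4.0) < 1e-6
        assert refs.p1.g > refs.p2.g  # short lifetime first

    def test_jittered_chord_within_5_percent(self):
        rng = np.random.default_rng(0)
        a, b = uc_phasor(0.8, self.W), uc_phasor(3.5, self.W)
        t = rng.uniform(0, 1, 500)
        pts = (
            np.array([a.g, a.s]) * t[:, None]
            + np.array([b.g, b.s]) * (1 - t[:, None])
            + rng.normal(0, 0.003, (500, 2))
        )
        refs = principal_axis_uc_references(pts, self.W)
        assert abs(refs.tau1_ns / 0.8 - 1) < 0.05
        assert abs(refs.tau2_ns / 3.5 - 1) < 0.05

    def test_minor_axis_is_perpendicular(self):
        """For an anisotropic cloud the minor axis crosses the UC elsewhere."""
        rng = np.random.default_rng(1)
        center = np.array([0.5, 0.25])
        direction = np.array([1.0, 0.35])
        direction /= np.hypot(*direction)
        pts = center + rng.uniform(-0.12, 0.12, (300, 1)) * direction
        pts = pts + rng.normal(0, 0.004, (300, 2))
        major = principal_axis_uc_references(pts, self.W, use_major=True)
        minor = principal_axis_uc_references(pts, self.W, use_major=False)
        chord_major = np.array([major.p1.g - major.p2.g, major.p1.s - major.p2.s])
        chord_minor = np.array([minor.p1.g - minor.p2.g, minor.p1.s - minor.p2.s])
        cosang = np.dot(chord_major, chord_minor) / (
            np.linalg.norm(chord_major) * np.linalg.norm(chord_minor)
        )
        assert abs(cosang) < 0.05

    def test_tangent_axis_flagged(self):
        # horizontal major axis along s = 0.5: touches the UC only at (0.5, 0.5)
        pts = np.array([[0.3, 0.5], [0.4, 0.5], [0.6, 0.5], [0.7, 0.5]])
        with pytest.raises(TangencyError) as err:
            principal_axis_uc_references(pts, self.W)
        assert err.value.point is not None
        assert abs(err.value.point[0] - 0.5) < 1e-9
        assert abs(err.value.point[1] - 0.5) < 1e-9

    def test_isotropic_cloud_rejected(self):
        pts = np.array([[0.4, 0.3], [0.6, 0.3], [0.5, 0.2], [0.5, 0.4]])
        with pytest.raises(DegenerateAxisError):
            principal_axis_uc_references(pts, self.W)

    def test_selection_regions_filter_the_cloud(self):
        p1, p2 = uc_phasor(1.0, self.W), uc_phasor(4.0, self.W)
        good = np.array([[p1.g, p1.s]] * 5 + [[p2.g, p2.s]] * 5)
        junk = np.tile([[0.05, 0.05]], (30, 1))  # would drag the axis away
        pts = np.vstack([good, junk])
        disc1 = PhasorROI(center=(p1.g, p1.s), radius=0.02)
        disc2 = PhasorROI(center=(p2.g, p2.s), radius=0.02)
        refs = principal_axis_uc_references(pts, self.W, selection=[disc1, disc2])
        assert abs(refs.tau1_ns - 1.0) < 1e-6
        assert abs(refs.tau2_ns - 4.0) < 1e-6
        assert "disc" in refs.message

    def test_intensity_weighting_changes_the_mean(self):
        p1, p2 = uc_phasor(1.0, self.W), uc_phasor(4.0, self.W)
        pts = np.array([[p1.g, p1.s]] * 3 + [[p2.g, p2.s]] * 3 + [[0.2, 0.1]])
        weights = np.array([1.0] * 6 + [0.0])  # zero weight silences the outlier
        refs = principal_axis_uc_references(pts, self.W, weights=weights)
        assert abs(refs.tau1_ns - 1.0) < 1e-6 and abs(refs.tau2_ns - 4.0) < 1e-6


class TestDecomposition:
    W = TimeAxis.regular(16, 1000.0 / 78.02).omega()

    def _refs(self, t1=1.0, t2=3.0):
        return ReferencePair(
            p1=uc_phasor(t1, self.W), p2=uc_phasor(t2, self.W), tau1_ns=t1, tau2_ns=t2
        )

    def test_endpoints_and_midpoint(self):
        refs = self._refs()
        d = decompose(refs.p1, refs)
        assert d.f1 == 1.0 and d.residual < 1e-15 and not d.clamped
        mid = Phasor((refs.p1.g + refs.p2.g) / 2, (refs.p1.s + refs.p2.s) / 2)
        assert abs(decompose(mid, refs).f1 - 0.5) < 1e-12

    def test_projection_beyond_endpoint_is_clamped(self):
        refs = self._refs()
        v1 = np.array([refs.p1.g, refs.p1.s])
        v2 = np.array([refs.p2.g, refs.p2.s])
        beyond = v2 + 1.2 * (v1 - v2)
        d = decompose(Phasor(*beyond), refs)
        assert d.f1 == 1.0 and d.clamped

    def test_residual_band_invalidates(self):
        refs = self._refs()
        v1 = np.array([refs.p1.g, refs.p1.s])
        v2 = np.array([refs.p2.g, refs.p2.s])
        chord = v1 - v2
        normal = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)
        off = (v1 + v2) / 2 + 0.05 * normal
        d = decompose(Phasor(*off), refs, max_residual=0.01)
        assert not d.valid and abs(d.residual - 0.05) < 1e-12
        assert decompose(Phasor(*off), refs, max_residual=0.1).valid

    def test_fractions_always_sum_to_one(self):
        refs = self._refs()
        rng = np.random.default_rng(3)
        for g, s in rng.uniform(0, 1, (50, 2)):
            d = decompose(Phasor(g, s), refs)
            assert d.f1 + d.f2 == 1.0
            assert 0.0 <= d.f1 <= 1.0

    def test_amplitude_average_closed_form(self):
        refs = self._refs(1.0, 3.0)
        from flimlite.phasor import Decomposition

        half = Decomposition(f1=0.5, f2=0.5, residual=0.0)
        assert abs(amplitude_avg_lifetime(half, refs) - 1.5) < 1e-15
        ends = Decomposition(f1=1.0, f2=0.0, residual=0.0)
        assert amplitude_avg_lifetime(ends, refs) == 1.0
        same = self._refs(2.0, 2.0 + 1e-13)
        for f1 in (0.0, 0.3, 1.0):
            d = Decomposition(f1=f1, f2=1 - f1, residual=0.0)
            assert abs(amplitude_avg_lifetime(d, same) - 2.0) < 1e-9

    def test_noiseless_mixture_recovery(self, axis4096, gauss_irf):
        """Mixture phasors decompose back to their intensity fractions."""
        w = axis4096.omega()
        t1, t2 = 1.0, 3.5
        irf = gauss_irf(axis4096)
        cal = PhasorCalibration("single", decay_phasor(irf, axis4096), 0.0)
        pure1 = calibrate(decay_phasor(
            simulate_decay((1.0,), (t1,), 0.0, irf, axis4096, 1e6, noiseless=True),
            axis4096), cal, omega=w)
        pure2 = calibrate(decay_phasor(
            simulate_decay((1.0,), (t2,), 0.0, irf, axis4096, 1e6, noiseless=True),
            axis4096), cal, omega=w)
        refs = ReferencePair(
            p1=Phasor(*_project_to_uc(pure1)), p2=Phasor(*_project_to_uc(pure2)),
            tau1_ns=uc_lifetime(Phasor(*_project_to_uc(pure1)), w),
            tau2_ns=uc_lifetime(Phasor(*_project_to_uc(pure2)), w),
        )
        for f1_true in (0.25, 0.5, 0.8):
            # intensity fractions: amplitudes a_i proportional to f_i / tau_i
            a1, a2 = f1_true / t1, (1 - f1_true) / t2
            mix = simulate_decay((a1, a2), (t1, t2), 0.0, irf, axis4096, 1e6,
                                 noiseless=True)
            p = calibrate(decay_phasor(mix, axis4096), cal, omega=w)
            d = decompose(p, refs)
            assert abs(d.f1 - f1_true) < 2e-3
            tau_avg = amplitude_avg_lifetime(d, refs)
            expected = 1.0 / (f1_true / t1 + (1 - f1_true) / t2)
            assert abs(tau_avg - expected) < 5e-3


def _project_to_uc(p: Phasor) -> tuple[float, float]:
    """Nearest universal-circle point (for building exact reference pairs)."""
    v = np.array([p.g - 0.5, p.s])
    v = 0.5 * v / np.linalg.norm(v)
    return 0.5 + v[0], v[1]


class TestPhasorSelect:
    def test_whole_plane_region_keeps_validity(self, random_cube):
        ds = random_cube()
        pi = phasor_image(ds)
        box = PhasorROI(vertices=[(-2, -2), (2, -2), (2, 2), (-2, 2)])
        sel = phasor_select(pi, box)
        np.testing.assert_array_equal(sel.valid, pi.valid.valid)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValidationError):
            PhasorROI(vertices=[(0, 0), (1, 1), (2, 2)])
        with pytest.raises(ValidationError):
            PhasorROI(center=(0.5, 0.5), radius=0.0)

    def test_two_population_scene_separated_by_disc(self):
        """A disc around one population's phasor selects its pixels."""
        from flimlite.synthetic import Population

        ds, mask, truth = simulate_scene(
            n_cells=6, shape=(40, 40), seed=5, counts_per_cell=4e5,
            lifetime_populations=[
                Population(1.0, 1.0, f1_mean=0.5, f1_sd=0.0),
                Population(3.5, 3.5, f1_mean=0.5, f1_sd=0.0),
            ],
        )
        axis = ds.time_axis
        w = axis.omega()
        irf = make_irf(axis, truth.irf_center_ns, truth.irf_fwhm_ns)
        cal = PhasorCalibration("single", decay_phasor(irf, axis), 0.0)
        from flimlite.preprocess import validity_mask

        vm = validity_mask(ds, 500)
        pi = calibrate(phasor_image(ds, 1, vm), cal)
        short_cells = {c.id for c in truth.cells if c.lifetimes[0] == 1.0}
        target = uc_phasor(1.0, w)
        sel = phasor_select(pi, PhasorROI(center=(target.g, target.s), radius=0.05))
        truth_pixels = np.zeros(ds.frame_shape, bool)
        for c in truth.cells:
            if c.id in short_cells:
                for (r, cc) in c.pixels:
                    truth_pixels[r, cc] = True
        in_cells = mask.labels > 0
        mism = np.mean(sel.valid[in_cells & vm.valid] != truth_pixels[in_cells & vm.valid])
        assert mism < 0.05
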