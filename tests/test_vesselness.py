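"""Feature-bank unit and property tests: Hessian, eigen-system, f1..f5."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from vesscade.vesselness import (FeatureComputationError, FeatureParams,
                                 ScaleBank, default_scale_bank,
                                 eigen_sorted, eigenvalues_analytic,
                                 frangi_f2, frangi_gamma, hessian_at_scale,
                                 li_f4, magnitude_view, manniesing_f5,
                                 multiscale_features, sato_f1, shikata_f3)
from vesscade.volume import Volume

from conftest import straight_tube


class TestScaleBank:
    def test_default_sigmas(self):
        bank = default_scale_bank()
        expected = [0.6, 0.8485, 1.2, 1.6971, 2.4, 3.3941]
        assert np.allclose(bank.sigmas, expected, atol=1e-3)

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            ScaleBank((1.0, 1.0))


class TestHessian:
    def test_constant_volume_zero(self):
        vol = Volume(np.full((12, 12, 12), 7.0))
        comp = hessian_at_scale(vol, 1.0)
        assert np.allclose(comp, 0.0, atol=1e-5)

    def test_quadratic_second_derivative(self):
        # I = x^2 (mm): normalized Hessian ~ diag(2 sigma^2, 0, 0) inside.
        x = np.arange(32, dtype=float)
        vol = Volume(np.broadcast_to((x**2)[:, None, None], (32, 32, 32)).copy())
        sigma = 2.0
        comp = hessian_at_scale(vol, sigma)
        c = 16
        assert comp[0][c, c, c] == pytest.approx(2.0 * sigma**2, rel=1e-3)
        for k in range(1, 6):
            # float32 filtering leaves small residues on the large-amplitude
            # quadratic; keep them well below the diagonal signal
            assert abs(comp[k][c, c, c]) < 1e-2 * 2.0 * sigma**2

    def test_gaussian_blob_isotropic_negative(self):
        # A separable Gaussian blob has three equal negative eigenvalues at
        # its center (closed-form Gaussian derivatives).
        n, s = 33, 3.0
        g = np.exp(-((np.arange(n) - n // 2) ** 2) / (2 * s * s))
        vol = Volume(g[:, None, None] * g[None, :, None] * g[None, None, :])
        comp = hessian_at_scale(vol, 1.5)
        eig = eigen_sorted(comp[:, n // 2, n // 2, n // 2])
        lam = eig.eigenvalues
        assert np.all(lam < 0)
        assert np.allclose(lam, lam[0], rtol=1e-3)

    def test_undersampled_scale_rejected(self):
        vol = Volume(np.zeros((12, 12, 12)), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(FeatureComputationError):
            hessian_at_scale(vol, 0.5)

    def test_nonfinite_rejected(self):
        data = np.zeros((12, 12, 12))
        data[0, 0, 0] = np.nan
        with pytest.raises(FeatureComputationError):
            hessian_at_scale(Volume(data), 1.0)


class TestEigenSorted:
    def test_diagonal(self):
        eig = eigen_sorted(np.diag([3.0, -1.0, -5.0]))
        assert np.allclose(eig.eigenvalues, [3.0, -1.0, -5.0])
        # eigenvectors are the coordinate axes, up to sign
        assert np.allclose(np.abs(eig.eigenvectors), np.eye(3), atol=1e-12)

    def test_zero_matrix(self):
        eig = eigen_sorted(np.zeros((3, 3)))
        assert np.allclose(eig.eigenvalues, 0.0)
        E = eig.eigenvectors
        assert np.allclose(E.T @ E, np.eye(3), atol=1e-12)

    def test_against_characteristic_polynomial(self, rng):
        """Eigenvalues match root-finding on det(H - lambda I) for >=1000
        random symmetric matrices within 1e-8."""
        n = 1200
        A = rng.normal(size=(n, 3, 3))
        H = 0.5 * (A + np.swapaxes(A, 1, 2))
        eig = eigen_sorted(H)
        analytic = eigenvalues_analytic(np.stack([
            H[:, 0, 0], H[:, 1, 1], H[:, 2, 2],
            H[:, 0, 1], H[:, 0, 2], H[:, 1, 2]]))
        for i in range(n):
            coeffs = np.poly(H[i])
            roots = np.sort(np.real(np.roots(coeffs)))[::-1]
            assert np.allclose(eig.eigenvalues[i], roots, atol=1e-8)
            assert np.allclose(analytic[i], roots, atol=1e-7)

    def test_orthonormal_eigenvectors(self, rng):
        A = rng.normal(size=(50, 3, 3))
        H = 0.5 * (A + np.swapaxes(A, 1, 2))
        eig = eigen_sorted(H)
        E = eig.eigenvectors
        gram = np.einsum("nij,nik->njk", E, E)
        assert np.allclose(gram, np.eye(3), atol=1e-6)
        # eigenvector/eigenvalue pairing
        for i in range(50):
            for k in range(3):
                v = E[i, :, k]
                assert np.allclose(H[i] @ v, eig.eigenvalues[i, k] * v,
                                   atol=1e-8)

    def test_rejects_asymmetric(self):
        M = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            eigen_sorted(M)


class TestMagnitudeView:
    @pytest.mark.parametrize("signed,expected", [
        ((3.0, -1.0, -5.0), (-1.0, 3.0, -5.0)),
        ((0.0, 0.0, -2.0), (0.0, 0.0, -2.0)),
    ])
    def test_examples(self, signed, expected):
        assert tuple(magnitude_view(np.array(signed))) == expected

    def test_tie_stability(self):
        # |a| == |b|: original signed order preserved
        out = magnitude_view(np.array([2.0, -2.0, -3.0]))
        assert tuple(out) == (2.0, -2.0, -3.0)


class TestSato:
    def test_zero_lambda2(self):
        assert sato_f1(1.0, 0.0) == 0.0

    def test_vanishing_exponent(self):
        assert sato_f1(0.0, -2.0) == pytest.approx(-2.0)

    def test_hand_evaluation(self):
        # lam1=-1, lam2=-2, alpha1=0.5 -> -2 exp(-0.5)
        assert sato_f1(-1.0, -2.0, 0.5, 2.0) == pytest.approx(
            -2.0 * np.exp(-0.5), rel=1e-12)

    def test_branch_switch(self):
        # lam1 > 0 uses the larger alpha2 -> weaker damping
        v_neg = sato_f1(-1.0, -2.0, 0.5, 2.0)
        v_pos = sato_f1(1.0, -2.0, 0.5, 2.0)
        assert abs(v_pos) > abs(v_neg)


class TestFrangi:
    def test_positive_lambda2_zero(self):
        assert frangi_f2(np.array([0.0, 1.0, -2.0])) == 0.0

    def test_ideal_tube_value(self):
        # lam = (0, -k, -k), S >> gamma: (1 - exp(-1/(2 alpha^2)))
        val = frangi_f2(np.array([0.0, -50.0, -50.0]), alpha=0.5, beta=0.5,
                        gamma=1e-3)
        assert val == pytest.approx(1.0 - np.exp(-2.0), rel=1e-4)

    def test_all_zero(self):
        assert frangi_f2(np.zeros(3)) == 0.0

    def test_range(self, rng):
        lam = np.sort(rng.normal(size=(500, 3)), axis=1)[:, ::-1]
        v = frangi_f2(lam, gamma=1.0)
        assert np.all((v >= 0) & (v <= 1))


class TestFrangiGamma:
    def test_single_matrix(self):
        assert frangi_gamma(np.diag([2.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_identity_field(self):
        field = np.broadcast_to(np.eye(3), (4, 3, 3))
        assert frangi_gamma(field) == pytest.approx(np.sqrt(3) / 2)

    def test_zero_field_errors(self):
        with pytest.raises(FeatureComputationError):
            frangi_gamma(np.zeros((5, 3, 3)))


class TestShikata:
    def test_zero_lambda(self):
        val, n = shikata_f3(np.array(2.0), np.array(0.0), 1.0)
        assert val == 0.0 and n == 0

    def test_direct_substitution(self):
        val, _ = shikata_f3(np.array(2.0), np.array(-4.0), 1.0)
        assert val == pytest.approx(-2.0)

    def test_low_intensity_guard(self):
        val, n = shikata_f3(np.array([0.0, 4.0]), np.array([-4.0, -4.0]), 1.0,
                            intensity_floor=1e-6)
        assert val[0] == 0.0 and val[1] == pytest.approx(-1.0)
        assert n == 1


class TestLi:
    @pytest.mark.parametrize("lam,expected", [
        ((1.0, -2.0, -4.0), 0.0),      # lam1 >= 0
        ((-1.0, -2.0, -2.0), 0.0),     # lam2 == lam3
        ((-1.0, -2.0, -4.0), 4.0),     # direct substitution
    ])
    def test_examples(self, lam, expected):
        assert li_f4(*lam) == pytest.approx(expected)

    def test_nonnegative_on_sorted(self, rng):
        lam = np.sort(rng.normal(size=(500, 3)), axis=1)[:, ::-1]
        assert np.all(li_f4(lam[:, 0], lam[:, 1], lam[:, 2]) >= 0)


class TestManniesing:
    def test_nonnegative_lambda2_zero(self):
        assert manniesing_f5(np.array([0.0, 0.0, -2.0])) == 0.0

    def test_default_c_inert(self):
        lam = np.array([-0.1, -5.0, -5.0])
        v5 = manniesing_f5(lam, gamma=5.0, c=1e-6)
        v2 = frangi_f2(lam, gamma=5.0)
        assert v5 == pytest.approx(v2, rel=1e-9)

    def test_range(self, rng):
        lam = np.sort(rng.normal(size=(500, 3)), axis=1)[:, ::-1]
        v = manniesing_f5(lam)
        assert np.all((v >= 0) & (v <= 1))


@given(p=hst.floats(-10, 10), q=hst.floats(-10, 0),
       r=hst.floats(-10, 0))
@settings(max_examples=200, deadline=None)
def test_feature_formulas_finite(p, q, r):
    lam = np.sort(np.array([p, q, r]))[::-1]
    assert np.isfinite(sato_f1(lam[0], lam[1]))
    assert np.isfinite(frangi_f2(lam, gamma=1.0))
    assert np.isfinite(li_f4(lam[0], lam[1], lam[2]))
    assert np.isfinite(manniesing_f5(lam))


class TestMultiscale:
    def test_constant_volume_all_zero(self):
        vol = Volume(np.full((16, 16, 16), 5.0))
        ff = multiscale_features(vol)
        assert np.allclose(ff.values, 0.0, atol=1e-4)

    def test_output_shape(self, tube_volume):
        ff = multiscale_features(tube_volume)
        assert ff.values.shape == (6, 5) + tube_volume.shape

    def test_invariant_ranges(self, tube_volume):
        ff = multiscale_features(tube_volume)
        assert np.all(np.isfinite(ff.values))
        f2, f4, f5 = ff.values[:, 1], ff.values[:, 3], ff.values[:, 4]
        assert np.all((f2 >= 0) & (f2 <= 1))
        assert np.all((f5 >= 0) & (f5 <= 1))
        assert np.all(f4 >= -1e-6)

    def test_scale_selectivity_on_tube(self):
        """On a noise-free tube the best mean on-axis Frangi response over
        scales is near the tube's profile scale.

        Cross-scale comparison needs one gamma for all scales: the default
        per-scale auto-gamma normalizes each scale by its own maximum
        response, which deliberately flattens the scale profile.
        """
        radius = 2.0
        vol, _ = straight_tube(radius=radius)
        bank = default_scale_bank()
        ff = multiscale_features(vol, bank, FeatureParams(frangi_gamma=30.0))
        on_axis = ff.values[:, 1][:, 20, 20, :].mean(axis=1)
        best = bank.sigmas[int(np.argmax(on_axis))]
        profile_sigma = 0.5 * radius
        # within one scale step (factor sqrt 2) of the profile scale
        assert 0.6 * profile_sigma <= best <= 2.1 * profile_sigma

    def test_rotation_equivariance(self):
        """Rotating a tube by 90 deg about a grid axis permutes the feature
        maps exactly."""
        vol, _ = straight_tube(shape=(24, 24, 24), axis=2)
        rot = Volume(np.rot90(vol.data, k=1, axes=(1, 2)).copy())
        bank = ScaleBank((1.0, 1.6))
        f_orig = multiscale_features(vol, bank).values
        f_rot = multiscale_features(rot, bank).values
        expected = np.rot90(f_orig, k=1, axes=(3, 4))
        assert np.allclose(f_rot, expected, atol=1e-4)

    def test_axis_response_decays_outward(self):
        """At the matched scale, f1 (magnitude), f2, f4 and f5 are maximal on
        the tube axis and decay monotonically along a ray beyond the
        boundary."""
        radius = 2.0
        vol, _ = straight_tube(radius=radius)
        bank = default_scale_bank()
        ff = multiscale_features(vol, bank)
        profile_sigma = 0.5 * radius
        si = int(np.argmin(np.abs(np.asarray(bank.sigmas) - profile_sigma)))
        mid = 20
        for fi, transform in ((0, np.abs), (1, None), (3, None), (4, None)):
            prof = ff.values[si, fi][mid:, mid, mid].astype(float)
            if transform is not None:
                prof = transform(prof)
            assert prof[0] > 0
            assert prof[0] == prof.max()  # maximal on the axis
            tail = prof[int(np.ceil(radius)) + 1:int(np.ceil(radius)) + 6]
            # tolerance relative to the axis value: float32 far-field ripple
            assert np.all(np.diff(tail) <= 1e-4 * prof[0])

    def test_roi_matches_full(self, tube_volume):
        full = multiscale_features(tube_volume)
        roi = np.zeros(tube_volume.shape, dtype=bool)
        roi[10:30, 10:30, 10:30] = True
        part = multiscale_features(tube_volume, roi=roi)
        assert np.allclose(part.values[:, :, roi], full.values[:, :, roi])
        assert np.allclose(part.values[:, :, ~roi], 0.0)
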