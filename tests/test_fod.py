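"""FOD representation: SH fits, rotational invariants, dispersion angle,
the exponential-decay family, and the Watson/Poisson references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import eval_legendre

from smval import fod
from smval.sphere import SphericalHistogram, histogram_from_directions, icosphere_mesh
from smval.shbasis import norm_factor

from conftest import gauss_legendre_01


class TestShFitAndInvariants:
    def test_uniform_density_has_zero_high_degree_coefficients(self):
        mesh = icosphere_mesh(4)
        hist = SphericalHistogram(mesh, np.ones(mesh.n_bins)).normalize()
        coeffs = fod.sh_fit(hist, lmax=8)
        inv = fod.rot_invariants(coeffs)
        # residual leakage is the mesh quadrature error of the bin model
        assert all(v < 1e-4 for v in inv.pl.values())

    def test_delta_fod_invariants_are_one(self):
        hist = histogram_from_directions(np.tile([0.0, 0.0, 1.0], (5, 1)))
        inv = fod.rot_invariants(fod.sh_fit(hist, lmax=8))
        assert all(abs(v - 1.0) < 1e-9 for v in inv.pl.values())
        # p_l0 -> N_l for a delta along z; the bin centroid sits ~1.5 deg
        # off the pole, so the offset grows as 1 - P_l(cos theta_bin)
        coeffs = fod.sh_fit(hist, lmax=8)
        assert coeffs.coeff(2, 0) == pytest.approx(norm_factor(2), rel=5e-3)
        assert coeffs.coeff(4, 0) == pytest.approx(norm_factor(4), rel=2e-2)

    def test_watson_histogram_p2_matches_quadrature(self):
        kappa = 4.0
        from smval.synthetic import sample_directions

        dirs = sample_directions("watson", {"kappa": kappa}, 200000, seed=3)
        inv = fod.rot_invariants(fod.sh_fit(dirs, lmax=8))
        assert inv.pl[2] == pytest.approx(fod.watson_invariant(kappa, 2),
                                          abs=0.01)

    def test_axisym_invariant_equals_legendre_average(self):
        """For any axially symmetric FOD, p_l = |<P_l(cos theta)>| by direct
        quadrature -- checked against the SH-fit route on the mesh."""
        kappa = 9.0
        mesh = icosphere_mesh(4)
        dens = fod.watson_density(kappa, mesh.centers[:, 2])
        hist = SphericalHistogram(mesh, dens).normalize()
        inv = fod.rot_invariants(fod.sh_fit(hist, lmax=8))
        for l in (2, 4, 6):
            oracle = fod.axisym_invariant(
                lambda t: fod.watson_density(kappa, t), l)
            # mesh level 4 quadrature: ~1e-4 at l=2, growing with degree
            assert inv.pl[l] == pytest.approx(oracle, abs=3e-4)

    def test_odd_lmax_rejected(self):
        with pytest.raises(ValueError):
            fod.sh_fit(np.array([[0.0, 0.0, 1.0]]), lmax=3)


class TestThetaFromP2:
    @pytest.mark.parametrize("p2,expected", [
        (1.0, 0.0),
        (0.0, 54.7356),
        (0.7, np.degrees(np.arccos(np.sqrt(0.8)))),
    ])
    def test_known_values(self, p2, expected):
        assert fod.theta_from_p2(p2) == pytest.approx(expected, abs=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fod.theta_from_p2(1.2)

    @given(st.floats(0.0, 0.99), st.floats(0.001, 0.01))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, p2, dp):
        assert fod.theta_from_p2(p2 + dp) < fod.theta_from_p2(p2)


class TestExpDecayFamily:
    def test_fit_recovers_exact_geometric_sequence(self):
        pl = {l: 0.9 * 0.8**l for l in (2, 4, 6, 8)}
        C, lam = fod.fit_expdecay(pl)
        assert C == pytest.approx(0.9, rel=1e-12)
        assert lam == pytest.approx(0.8, rel=1e-12)

    def test_fit_of_constant_invariants(self):
        C, lam = fod.fit_expdecay({l: 1.0 for l in (2, 4, 6)})
        assert (C, lam) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_fit_needs_two_positive_values(self):
        with pytest.raises(ValueError):
            fod.fit_expdecay({2: 0.5, 4: 0.0, 6: -0.1})

    def test_closed_form_is_isotropic_when_degenerate(self):
        t = np.linspace(-1, 1, 11)
        assert np.allclose(fod.family_eval(0.0, 0.5, t), 1.0)
        assert np.allclose(fod.family_eval(0.7, 0.0, t), 1.0)

    @pytest.mark.parametrize("C,lam", [(1.0, 0.8), (0.5, 0.5), (1.1, 0.9)])
    def test_invariants_are_exactly_geometric(self, C, lam):
        """The defining property: quadrature invariants equal C*lambda^l."""
        for l in range(2, 17, 2):
            assert fod.family_invariant(C, lam, l) == pytest.approx(
                C * lam**l, abs=1e-9)

    def test_roundtrip_through_sh_fit(self):
        """Invariants of the closed form fitted at lmax=16 recover the
        generative (C, lambda) within 1%."""
        C, lam = 0.85, 0.75
        mesh = icosphere_mesh(4)
        dens = fod.family_eval(C, lam, mesh.centers[:, 2])
        hist = SphericalHistogram(mesh, dens).normalize()
        inv = fod.rot_invariants(fod.sh_fit(hist, lmax=16))
        Chat, lamhat = fod.fit_expdecay({l: inv.pl[l] for l in (2, 4, 6, 8)})
        assert Chat == pytest.approx(C, rel=0.01)
        assert lamhat == pytest.approx(lam, rel=0.01)

    def test_nonnegativity_domain(self):
        assert fod.family_domain(0.0, 0.3)
        assert fod.family_domain(1.0, 0.8)
        assert not fod.family_domain(1.5, 0.8)
        assert fod.family_domain(1.0, 0.999)
        # analytic equator bound agrees with the numeric boundary
        lam = 0.8
        analytic = 1.0 / (1.0 - (1 - lam**2) * (1 + lam**2) ** -1.5)
        assert fod.family_cmax(lam) == pytest.approx(analytic, rel=1e-6)
        # just inside/outside the boundary
        assert fod.family_domain(analytic * 0.999, lam)
        assert not fod.family_domain(analytic * 1.01, lam)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fod.family_eval(1.0, 1.0, 0.5)


class TestReferenceFods:
    def test_watson_limits(self):
        assert fod.watson_invariant(0.0, 2) == pytest.approx(0.0, abs=1e-12)
        assert fod.watson_invariant(1e6, 2) == pytest.approx(1.0, abs=1e-4)

    def test_watson_p2_monotone_in_kappa(self):
        kappas = [0.5, 1, 2, 4, 8, 16, 32, 64]
        p2s = [fod.watson_invariant(k, 2) for k in kappas]
        assert all(0 < p < 1 for p in p2s)
        assert np.all(np.diff(p2s) > 0)

    def test_watson_density_normalized(self):
        t, w = gauss_legendre_01()
        assert np.sum(w * fod.watson_density(7.0, t)) == pytest.approx(1.0)

    def test_poisson_invariants_are_powers(self):
        lam = 0.6
        for l in (2, 4, 6):
            quad = fod.axisym_invariant(
                lambda t: fod.poisson_density(lam, t), l)
            assert quad == pytest.approx(lam**l, abs=1e-10)

    def test_watson_and_poisson_deviate_from_exponential_decay(self):
        """The discriminating property: for kappa=4, neither the Watson nor
        the matched-p2 Poisson invariants follow a C*lambda^l law (relative
        deviation > 5% at higher l)."""
        kappa = 4.0
        degrees = list(range(2, 17, 2))
        watson_pl = {l: fod.watson_invariant(kappa, l) for l in degrees}
        C, lam = fod.fit_expdecay(watson_pl)
        dev_watson = max(abs(watson_pl[l] - C * lam**l) / watson_pl[l]
                         for l in degrees)
        assert dev_watson > 0.05
        lam_poisson = np.sqrt(watson_pl[2])       # matched p2
        dev_poisson = max(
            abs(lam_poisson**l - C * lam**l) / (C * lam**l)
            for l in degrees)
        assert dev_poisson > 0.05

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fod.reference_fod_eval("bingham", 1.0, 0.5)


class TestLobeSegmentation:
    @staticmethod
    def _mixture_hist(weights, axes, kappa=16.0):
        mesh = icosphere_mesh(4)
        dens = np.zeros(mesh.n_bins)
        for w, ax in zip(weights, axes):
            dens += w * fod.watson_density(kappa, mesh.centers @ ax)
        return SphericalHistogram(mesh, dens).normalize()

    def test_single_bundle_gives_one_lobe_with_global_invariants(self):
        hist = self._mixture_hist([1.0], [np.array([0.0, 0.0, 1.0])])
        lobes = fod.lobe_invariants(hist)
        assert len(lobes) == 1
        global_inv = fod.rot_invariants(fod.sh_fit(hist, lmax=6))
        assert lobes[0].invariants.pl[2] == pytest.approx(
            global_inv.pl[2], abs=0.01)

    def test_orthogonal_bundles_recover_single_bundle_dispersion(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        hist = self._mixture_hist([0.5, 0.5], [z, x])
        lobes = fod.lobe_invariants(hist)
        assert len(lobes) == 2
        single = self._mixture_hist([1.0], [z])
        theta_single = fod.theta_from_p2(fod.rot_invariants(
            fod.sh_fit(single, lmax=6)).pl[2])
        for lobe in lobes:
            theta_lobe = fod.theta_from_p2(lobe.invariants.pl[2])
            assert abs(theta_lobe - theta_single) < 3.0

    def test_unequal_bundles_mass_ratio(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        hist = self._mixture_hist([2 / 3, 1 / 3], [z, x])
        lobes = fod.lobe_invariants(hist)
        assert len(lobes) == 2
        assert lobes[0].mass / lobes[1].mass == pytest.approx(2.0, rel=0.1)
        assert sum(lb.mass for lb in lobes) == pytest.approx(1.0, abs=1e-9)

    def test_flat_fod_returns_single_lobe(self):
        mesh = icosphere_mesh(3)
        hist = SphericalHistogram(mesh, np.ones(mesh.n_bins)).normalize()
        assert len(fod.lobe_invariants(hist)) == 1
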