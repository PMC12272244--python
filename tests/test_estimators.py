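"""Estimator self-consistency and cross-checks: DKI, WMTI, NODDI, SMT,
SMI, and FOD recovery from the fitted kernel."""

import numpy as np
import pytest

from smval import fod
from smval.estimators import (NODDIEstimator, SMTEstimator, WMTIEstimator,
                              fit_dki, fod_from_kernel, invariant_features,
                              smi_train, wmti)
from smval.forward import (KernelParams, SignalSet, kernel_projection,
                           simulate_signal)

from conftest import mixture_tensors


def cumulant_signal(protocol, tensors):
    """Exact signal of the b, b^2 cumulant expansion for given tensors."""
    Dapp, Kapp = tensors.apparent(protocol.bvecs)
    b = protocol.bvals
    return SignalSet(protocol,
                     np.exp(-b * Dapp + (b**2 / 6.0) * Kapp * Dapp**2))


class TestDKI:
    def test_single_gaussian_recovers_tensor_with_zero_kurtosis(
            self, protocol):
        D = np.diag([0.4, 0.6, 1.7])
        sig = SignalSet(protocol, np.exp(
            -protocol.bvals * np.einsum("ni,ij,nj->n", protocol.bvecs, D,
                                        protocol.bvecs)))
        t = fit_dki(sig)
        assert np.abs(t.D - D).max() < 1e-8
        assert np.abs(t.W).max() < 1e-8

    def test_two_gaussian_mixture_matches_analytic_cumulants(
            self, protocol):
        truth = mixture_tensors(
            [0.4, 0.6], [np.diag([0, 0, 1.2]), np.diag([0.5, 0.5, 1.8])])
        t = fit_dki(cumulant_signal(protocol, truth))
        assert np.abs(t.D - truth.D).max() < 1e-8
        assert np.abs(t.W - truth.W).max() < 1e-7

    def test_isotropic_signal(self, protocol):
        sig = SignalSet(protocol, np.exp(-protocol.bvals * 1.1))
        t = fit_dki(sig)
        assert t.mean_diffusivity() == pytest.approx(1.1, abs=1e-10)
        _, Kapp = t.apparent(np.eye(3))
        assert np.abs(Kapp).max() < 1e-8


class TestWMTI:
    def test_exact_moments_recover_aligned_two_compartment_truth(
            self, protocol):
        f, Da, Dep, Det = 0.4, 1.2, 1.8, 0.5
        truth = mixture_tensors(
            [f, 1 - f], [np.diag([0, 0, Da]), np.diag([Det, Det, Dep])])
        r = wmti(truth)
        assert r.xi.f == pytest.approx(f, abs=1e-6)
        assert r.xi.Da == pytest.approx(Da, abs=1e-6)
        assert r.xi.De_par == pytest.approx(Dep, abs=1e-6)
        assert r.xi.De_perp == pytest.approx(Det, abs=1e-6)
        assert r.xi.Da <= r.xi.De_par

    def test_fully_aligned_intra_tensor_gives_p2_one(self, protocol):
        truth = mixture_tensors(
            [0.4, 0.6], [np.diag([0, 0, 1.2]), np.diag([0.5, 0.5, 1.8])])
        r = wmti(truth)
        assert r.p2 == pytest.approx(1.0, abs=1e-6)

    def test_signal_route_matches_tensor_route(self, protocol):
        truth = mixture_tensors(
            [0.45, 0.55], [np.diag([0, 0, 1.0]), np.diag([0.4, 0.4, 1.7])])
        est = WMTIEstimator(protocol).fit(
            cumulant_signal(protocol, truth).values[None, :])
        r = est.results_[0]
        assert r.xi.f == pytest.approx(0.45, abs=1e-6)

    def test_p2_formula_limits(self):
        # eigenvalues (Da, 0, 0) -> p2 = 1; isotropic thirds -> p2 = 0
        for ev, expected in (((1.2, 0, 0), 1.0), ((0.4, 0.4, 0.4), 0.0)):
            ev = np.array(ev)
            Da = ev.sum()
            p2 = np.sqrt(1.5 * np.sum((ev - Da / 3) ** 2)) / Da
            assert p2 == pytest.approx(expected, abs=1e-12)


class TestNODDI:
    def test_noiseless_self_consistency(self, protocol):
        est = NODDIEstimator(protocol)
        mu = np.array([0.2, 0.3, 0.93])
        mu /= np.linalg.norm(mu)
        truth = (0.6, 0.1, 4.0)
        sig = est._model(truth, mu)
        r = est.fit(sig[None, :]).results_[0]
        assert r.diagnostics["f_intra"] == pytest.approx(0.6, rel=0.01)
        assert r.xi.fw == pytest.approx(0.1, rel=0.01)
        assert r.kappa == pytest.approx(4.0, rel=0.01)

    def test_pure_extra_axonal_data_gives_zero_f(self, protocol):
        est = NODDIEstimator(protocol)
        mu = np.array([0.0, 0.0, 1.0])
        sig = est._model((0.0, 0.0, 4.0), mu)
        r = est.fit(sig[None, :]).results_[0]
        assert r.diagnostics["f_intra"] == pytest.approx(0.0, abs=0.01)

    def test_kappa_maps_monotonically_to_p2(self):
        p2s = [fod.watson_invariant(k, 2) for k in (0.5, 2.0, 8.0, 32.0)]
        assert np.all(np.diff(p2s) > 0)
        assert all(0 <= p <= 1 for p in p2s)


class TestSMT:
    def test_noiseless_self_consistency(self, protocol):
        f, dpar = 0.5, 1.8
        xi = KernelParams(f=f, Da=dpar, De_par=dpar,
                          De_perp=dpar * (1 - f))
        pl = {l: fod.watson_invariant(8.0, l) for l in (2, 4, 6)}
        sig = simulate_signal(protocol, fod.axisym_coeffs(pl, lmax=6), xi)
        r = SMTEstimator(protocol).fit(sig.values[None, :]).results_[0]
        assert r.xi.f == pytest.approx(f, abs=0.005)
        assert r.xi.Da == pytest.approx(dpar, abs=0.01)

    def test_stick_spherical_mean_matches_kernel_projection(self, protocol):
        xi = KernelParams(f=1.0, Da=2.0, De_par=2.0, De_perp=0.0)
        sig = simulate_signal(
            protocol, fod.axisym_coeffs({l: 1.0 for l in (2, 4, 6)},
                                        lmax=6), xi)
        from smval.forward import signal_invariants

        s0 = signal_invariants(sig).s0()
        assert s0[0] == pytest.approx(0.4410, abs=1e-3)

    def test_fit_is_fod_independent(self, protocol):
        f, dpar = 0.55, 1.6
        xi = KernelParams(f=f, Da=dpar, De_par=dpar,
                          De_perp=dpar * (1 - f))
        est = SMTEstimator(protocol)
        fits = []
        for pl in ({l: 1.0 for l in (2, 4, 6)}, {2: 0.4, 4: 0.1, 6: 0.02}):
            sig = simulate_signal(protocol, fod.axisym_coeffs(pl, lmax=6),
                                  xi)
            fits.append(est.fit(sig.values[None, :]).params_[0])
        assert np.allclose(fits[0][:2], fits[1][:2], atol=1e-3)


class TestSMI:
    def test_same_seed_gives_identical_training(self, protocol):
        a, Xa, _ = smi_train(protocol, n_train=500, seed=3)
        b, Xb, _ = smi_train(protocol, n_train=500, seed=3)
        assert np.array_equal(Xa, Xb)
        ca = a.model_.named_steps["linearregression"].coef_
        cb = b.model_.named_steps["linearregression"].coef_
        assert np.array_equal(ca, cb)

    def test_noiseless_recovery_gates(self, protocol):
        """Median absolute errors on a noiseless draw from the training
        prior: f < 0.03, Da < 0.15, p2 < 0.05."""
        est, _, _ = smi_train(protocol, n_train=20000, seed=1, snr=None)
        _, Xt, yt = smi_train(protocol, n_train=2000, seed=42, snr=None)
        err = np.median(np.abs(est.predict(Xt) - yt), axis=0)
        named = dict(zip(est.target_names, err))
        assert named["f"] < 0.03
        assert named["Da"] < 0.15
        assert named["p2"] < 0.05

    def test_delta_fod_sample_maps_to_high_p2(self, protocol):
        est, _, _ = smi_train(protocol, n_train=20000, seed=1, snr=None)
        xi = KernelParams(f=0.6, Da=1.8, De_par=1.5, De_perp=0.5)
        pl = {l: 0.93**l for l in (2, 4, 6)}   # near-delta family FOD
        sig = simulate_signal(protocol, fod.axisym_coeffs(pl, lmax=6), xi)
        pred = est.predict(invariant_features(sig)[None, :])[0]
        assert pred[4] > 0.8
        # bounds respected
        assert 0.0 <= pred[0] <= 1.0 and 0.0 <= pred[4] <= 1.0

    def test_extrapolation_flagged(self, protocol):
        est, X, _ = smi_train(protocol, n_train=2000, seed=1)
        far = X[:1] + 10.0
        _, flags = est.predict(far, return_flags=True)
        assert flags[0]


class TestFodFromKernel:
    def test_noiseless_roundtrip(self, protocol):
        xi = KernelParams(f=0.55, Da=2.2, De_par=1.5, De_perp=0.6)
        pl = {l: 0.7**l for l in (2, 4, 6)}
        coeffs = fod.axisym_coeffs(pl, lmax=6,
                                   main_direction=[0.3, 0.2, 0.93])
        sig = simulate_signal(protocol, coeffs, xi)
        rec = fod_from_kernel(sig, xi, lmax=6)
        assert np.abs(rec.values - coeffs.values).max() < 1e-4

    def test_uniform_fod_recovers_zero_coefficients(self, protocol):
        xi = KernelParams(f=0.5, Da=1.8, De_par=1.4, De_perp=0.6)
        sig = simulate_signal(protocol, fod.axisym_coeffs({}, lmax=6), xi)
        rec = fod_from_kernel(sig, xi, lmax=6)
        assert np.abs(rec.values[1:]).max() < 1e-8

    def test_chained_family_parameter_recovery(self, protocol):
        """Forward family FOD -> signals -> recovered p_l -> log-linear fit
        lands near the generative (C, lambda)."""
        C, lam = 0.9, 0.75
        xi = KernelParams(f=0.55, Da=1.9, De_par=1.5, De_perp=0.6)
        pl = {l: C * lam**l for l in (2, 4, 6)}
        sig = simulate_signal(protocol, fod.axisym_coeffs(pl, lmax=6), xi)
        inv = fod.rot_invariants(fod_from_kernel(sig, xi, lmax=6))
        Chat, lamhat = fod.fit_expdecay(inv)
        assert Chat == pytest.approx(C, rel=0.02)
        assert lamhat == pytest.approx(lam, rel=0.02)


class TestEstimatorComparison:
    def test_smi_beats_constrained_estimators_off_their_constraints(
            self, protocol):
        """When the truth violates the tortuosity constraint, the
        unconstrained regression recovers f with smaller median error than
        NODDI and SMT."""
        rng = np.random.default_rng(7)
        est, _, _ = smi_train(protocol, n_train=20000, seed=1, snr=None)
        rows, feats, truth_f = [], [], []
        for _ in range(8):
            f = rng.uniform(0.3, 0.7)
            xi = KernelParams(f=f, Da=rng.uniform(1.5, 2.0),
                              De_par=rng.uniform(1.2, 1.8),
                              De_perp=rng.uniform(0.3, 1.0))
            lam = rng.uniform(0.6, 0.9)
            pl = {l: lam**l for l in (2, 4, 6)}
            sig = simulate_signal(protocol, fod.axisym_coeffs(pl, lmax=6),
                                  xi)
            rows.append(sig.values)
            feats.append(invariant_features(sig))
            truth_f.append(f)
        X = np.vstack(rows)
        truth_f = np.array(truth_f)
        err_smi = np.median(np.abs(
            est.predict(np.vstack(feats))[:, 0] - truth_f))
        err_smt = np.median(np.abs(
            SMTEstimator(protocol).fit(X).params_[:, 0] - truth_f))
        err_nod = np.median(np.abs(
            NODDIEstimator(protocol).fit(X).params_[:, 0] - truth_f))
        assert err_smi < err_smt
        assert err_smi < err_nod
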