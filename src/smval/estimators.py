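"""Standard Model estimators: WMTI, NODDI, SMT, SMI.

All four target the same fascicle parameters xi = {f, Da, De_par, De_perp}
(+ free-water fraction fw and the FOD) but differ in constraints and fitting
strategy:

* WMTI -- closed-form map from the diffusion and kurtosis tensors, valid
  for coherently aligned fibers, with the branch choice Da <= De_par.
* NODDI -- maximum-likelihood fit of (f, fw, kappa) with fixed
  Da = De_par = 0.6 um^2/ms (ex vivo), the tortuosity constraint
  De_perp = De_par (1 - f), and a Watson FOD.
* SMT -- maximum-likelihood fit of (f, D_par) to per-shell spherical means
  with D_par = Da = De_par and the tortuosity constraint.
* SMI -- machine-learning regression (cubic polynomial) from per-shell
  signal rotational invariants s_l (l <= 6) to the unconstrained kernel
  parameters and FOD invariants.

Estimators follow the scikit-learn protocol: construct with settings,
``fit(X)`` on an (n_samples, n_measurements) signal array (SMI additionally
supports supervised ``fit(X, y)`` on invariant features), fitted attributes
carry a trailing underscore, ``predict`` maps new data to parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures
from scipy.special import erf

from .fod import SHCoefficients, watson_invariant
from .forward import (KernelParams, Protocol, SignalSet, kernel_projection,
                      signal_invariants)
from .shbasis import lm_pairs, real_sh_matrix
from .sphere import icosphere_mesh

__all__ = [
    "DKITensors",
    "EstimatorResult",
    "fit_dki",
    "wmti",
    "WMTIEstimator",
    "NODDIEstimator",
    "SMTEstimator",
    "SMIEstimator",
    "smi_train",
    "invariant_features",
    "fod_from_kernel",
    "SMI_PRIOR_DEFAULT",
    "SMI_PRIOR_RICH",
]


# ---------------------------------------------------------------------------
# DKI: weighted linear least squares on the log-signal cumulant expansion
# ---------------------------------------------------------------------------

_D_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
_D_MULT = np.array([1.0, 2.0, 2.0, 1.0, 2.0, 1.0])


def _w_indices():
    idx, mult = [], []
    from itertools import combinations_with_replacement
    from math import factorial

    for comb in combinations_with_replacement(range(3), 4):
        idx.append(comb)
        counts = [comb.count(k) for k in range(3)]
        mult.append(factorial(4) // (factorial(counts[0]) *
                                     factorial(counts[1]) *
                                     factorial(counts[2])))
    return idx, np.array(mult, dtype=float)


_W_IDX, _W_MULT = _w_indices()


@dataclass
class DKITensors:
    """Diffusion tensor D (um^2/ms), kurtosis tensor W (dimensionless,
    15 unique components), and the S0 estimate."""

    D: np.ndarray            # (3, 3) symmetric
    W: np.ndarray            # (15,) unique components, _W_IDX order
    S0: float = 1.0

    def mean_diffusivity(self) -> float:
        return float(np.trace(self.D) / 3.0)

    def apparent(self, directions: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Apparent diffusivity and kurtosis along unit ``directions``."""
        u = np.atleast_2d(directions)
        Dapp = np.einsum("ni,ij,nj->n", u, self.D, u)
        quart = np.stack([u[:, i] * u[:, j] * u[:, k] * u[:, l]
                          for (i, j, k, l) in _W_IDX], axis=1)
        Wapp = quart @ (self.W * _W_MULT)
        md = self.mean_diffusivity()
        Kapp = Wapp * md**2 / np.maximum(Dapp, 1e-12) ** 2
        return Dapp, Kapp


def _dki_design(protocol: Protocol) -> np.ndarray:
    u = protocol.bvecs
    b = protocol.bvals[:, None]
    quad = np.stack([u[:, i] * u[:, j] for (i, j) in _D_IDX], axis=1)
    quart = np.stack([u[:, i] * u[:, j] * u[:, k] * u[:, l]
                      for (i, j, k, l) in _W_IDX], axis=1)
    return np.hstack([np.ones((protocol.n_meas, 1)),
                      -b * quad * _D_MULT,
                      (b**2 / 6.0) * quart * _W_MULT])


def fit_dki(signals: SignalSet) -> DKITensors:
    """Two-pass weighted linear least squares of the b, b^2 log-signal
    cumulant expansion.  Weights in the second pass are the squared
    predicted signals."""
    protocol = signals.protocol
    if len(protocol.shells) < 2:
        raise ValueError("DKI needs at least 2 non-zero shells")
    X = _dki_design(protocol)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient DKI design")
    y = np.log(np.maximum(signals.values, 1e-10))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(2):
        w = np.exp(X @ beta)
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)
    D = np.zeros((3, 3))
    for c, (i, j) in zip(beta[1:7], _D_IDX):
        D[i, j] = D[j, i] = c
    md = np.trace(D) / 3.0
    V = beta[7:]                      # = md^2 * W
    W = V / max(md**2, 1e-12)
    return DKITensors(D=D, W=W, S0=float(np.exp(beta[0])))


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class EstimatorResult:
    method: str
    xi: KernelParams
    p2: float
    kappa: float | None = None
    plm: SHCoefficients | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1e-9 <= self.p2 <= 1.0 + 1e-9:
            raise ValueError(f"p2 out of [0, 1]: {self.p2}")
        self.p2 = float(np.clip(self.p2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# WMTI
# ---------------------------------------------------------------------------

def wmti(tensors: DKITensors, directions: np.ndarray | None = None
         ) -> EstimatorResult:
    """Closed-form WMTI parameter map from the diffusion/kurtosis tensors.

    The axonal water fraction is f = K_max/(K_max + 3); per direction the
    two compartmental apparent diffusivities follow from (D_app, K_app) of a
    two-Gaussian mixture, taking the branch that assigns the smaller
    diffusivity to the intra-axonal space (hence Da <= De_par).  The
    intra-axonal tensor eigenvalues give
    p2 = sqrt(3/2 * sum_i (lam_ai - Da/3)^2) / Da.
    """
    if directions is None:
        directions = icosphere_mesh(2).centers
    Dapp, Kapp = tensors.apparent(directions)
    kmax = float(np.max(Kapp))
    valid = kmax > 0
    f = kmax / (kmax + 3.0) if valid else 0.0
    diag = {"kmax": kmax, "valid": valid, "branch": "Da<=De_par"}
    if not valid or f <= 1e-9:
        xi = KernelParams(f=0.0, Da=0.0,
                          De_par=float(np.max(Dapp)),
                          De_perp=float(np.min(Dapp)), fw=0.0)
        return EstimatorResult("wmti", xi, p2=0.0, diagnostics=diag)
    Kc = np.clip(Kapp, 0.0, None)
    if np.any(Kapp < -1e-6):
        diag["valid"] = False
        diag["negative_kurtosis"] = float(np.min(Kapp))
    De_app = Dapp * (1.0 + np.sqrt(Kc * f / (3.0 * (1.0 - f))))
    Da_app = Dapp * (1.0 - np.sqrt(Kc * (1.0 - f) / (3.0 * f)))
    Da_app = np.clip(Da_app, 0.0, None)

    def tensor_from_directional(vals):
        quad = np.stack([directions[:, i] * directions[:, j]
                         for (i, j) in _D_IDX], axis=1) * _D_MULT
        c, *_ = np.linalg.lstsq(quad, vals, rcond=None)
        T = np.zeros((3, 3))
        for cc, (i, j) in zip(c, _D_IDX):
            T[i, j] = T[j, i] = cc
        return T

    Te = tensor_from_directional(De_app)
    Ta = tensor_from_directional(Da_app)
    ev_e = np.linalg.eigvalsh(Te)
    ev_a = np.linalg.eigvalsh(Ta)
    Da = float(np.sum(ev_a))
    De_par = float(ev_e[-1])
    De_perp = float(0.5 * (ev_e[0] + ev_e[1]))
    if Da > 1e-9:
        p2 = float(np.sqrt(1.5 * np.sum((ev_a - Da / 3.0) ** 2)) / Da)
    else:
        p2 = 0.0
    xi = KernelParams(f=float(np.clip(f, 0, 1)), Da=max(Da, 0.0),
                      De_par=max(De_par, 0.0), De_perp=max(De_perp, 0.0),
                      fw=0.0)
    diag["lambda_a"] = ev_a
    return EstimatorResult("wmti", xi, p2=min(p2, 1.0), diagnostics=diag)


# ---------------------------------------------------------------------------
# sklearn-style wrappers
# ---------------------------------------------------------------------------

class _SignalFitter(BaseEstimator):
    """Shared scaffolding: fit(X) runs the per-sample solver over rows."""

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.results_ = [self._fit_one(row) for row in X]
        self.params_ = np.array([
            [r.xi.f, r.xi.Da, r.xi.De_par, r.xi.De_perp, r.xi.fw, r.p2]
            for r in self.results_])
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([
            [r.xi.f, r.xi.Da, r.xi.De_par, r.xi.De_perp, r.xi.fw, r.p2]
            for r in (self._fit_one(row) for row in X)])

    param_names = ("f", "Da", "De_par", "De_perp", "fw", "p2")


class WMTIEstimator(_SignalFitter):
    """DKI fit followed by the WMTI closed-form map."""

    def __init__(self, protocol: Protocol = None):
        self.protocol = protocol

    def _fit_one(self, row) -> EstimatorResult:
        tensors = fit_dki(SignalSet(self.protocol, row))
        return wmti(tensors)


class NODDIEstimator(_SignalFitter):
    """Watson-FOD maximum-likelihood fit of (f, fw, kappa) with fixed
    Da = De_par = ``d_fixed`` and the tortuosity constraint."""

    def __init__(self, protocol: Protocol = None, d_fixed: float = 0.6,
                 d_iso: float = 2.0, lmax: int = 8,
                 kappa_starts: tuple = (0.5, 2.0, 8.0, 32.0)):
        self.protocol = protocol
        self.d_fixed = d_fixed
        self.d_iso = d_iso
        self.lmax = lmax
        self.kappa_starts = kappa_starts

    def _principal_direction(self, row) -> np.ndarray:
        sig = SignalSet(self.protocol, row)
        tensors = fit_dki(sig)
        _, vecs = np.linalg.eigh(tensors.D)
        return vecs[:, -1]

    def _model(self, params, mu):
        f, fw, kappa = params
        prot = self.protocol
        out = np.ones(prot.n_meas)
        pl = {l: (1.0 if l == 0 else watson_invariant(kappa, l))
              for l in range(0, self.lmax + 1, 2)}
        xi = KernelParams(f=f, Da=self.d_fixed, De_par=self.d_fixed,
                          De_perp=self.d_fixed * (1.0 - f), fw=0.0)
        for b in prot.shells:
            mask = prot.shell_mask(b)
            t = prot.bvecs[mask] @ mu
            fascicle = np.zeros(mask.sum())
            for l in range(0, self.lmax + 1, 2):
                Kl = kernel_projection(xi, b, l)
                from scipy.special import eval_legendre

                fascicle += (2 * l + 1) * pl[l] * Kl * eval_legendre(l, t)
            out[mask] = ((1.0 - fw) * fascicle
                         + fw * np.exp(-b * self.d_iso))
        return out

    def _fit_one(self, row) -> EstimatorResult:
        mu0 = self._principal_direction(row)
        th0 = float(np.arccos(np.clip(mu0[2], -1.0, 1.0)))
        ph0 = float(np.arctan2(mu0[1], mu0[0]))

        def residual(p):
            f, fw, kappa, th, ph = p
            mu = np.array([np.sin(th) * np.cos(ph),
                           np.sin(th) * np.sin(ph), np.cos(th)])
            return self._model((f, fw, kappa), mu) - row

        best = None
        for k0 in self.kappa_starts:
            res = least_squares(
                residual, x0=[0.5, 0.05, k0, th0, ph0],
                bounds=([0.0, 0.0, 0.0, -np.inf, -np.inf],
                        [1.0, 1.0, 128.0, np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12)
            if best is None or res.cost < best.cost:
                best = res
        f, fw, kappa = best.x[:3]
        th, ph = best.x[3:]
        mu = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                       np.cos(th)])
        p2 = watson_invariant(kappa, 2)
        xi = KernelParams(f=float(f * (1 - fw)), Da=self.d_fixed,
                          De_par=self.d_fixed,
                          De_perp=self.d_fixed * (1.0 - f),
                          fw=float(fw), Dw=self.d_iso)
        return EstimatorResult(
            "noddi", xi, p2=p2, kappa=float(kappa),
            diagnostics={"cost": float(best.cost), "f_intra": float(f),
                         "converged": bool(best.success), "mu": mu})


def _smt_h(x: np.ndarray) -> np.ndarray:
    """h(x) = integral_0^1 exp(-x t^2) dt, stable at x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    big = x > 1e-8
    out[big] = (np.sqrt(np.pi) * erf(np.sqrt(x[big]))
                / (2.0 * np.sqrt(x[big])))
    small = ~big
    out[small] = 1.0 - x[small] / 3.0
    return out


class SMTEstimator(_SignalFitter):
    """Spherical-mean fit of (f, D_par) under D_par = Da = De_par and
    De_perp = D_par (1 - f); diffusivity bound 2 um^2/ms (room-temperature
    free water)."""

    def __init__(self, protocol: Protocol = None, d_max: float = 2.0):
        self.protocol = protocol
        self.d_max = d_max

    @staticmethod
    def mean_model(f, d_par, bvals):
        b = np.asarray(bvals, dtype=float)
        intra = f * _smt_h(b * d_par)
        de_perp = d_par * (1.0 - f)
        extra = ((1.0 - f) * np.exp(-b * de_perp)
                 * _smt_h(b * (d_par - de_perp)))
        return intra + extra

    def _fit_one(self, row) -> EstimatorResult:
        sig = SignalSet(self.protocol, row)
        # s0 from the per-shell SH fit: the design-unbiased spherical mean
        sinv = signal_invariants(sig, lmax=6)
        bs = sinv.shells
        y = sinv.s0()
        if np.any(y <= 0) or np.any(y > 1.0 + 1e-6):
            raise ValueError("spherical means must lie in (0, 1]")
        best = None
        for f0 in (0.2, 0.5, 0.8):
            for d0 in (0.8, 1.5):
                res = least_squares(
                    lambda p: self.mean_model(p[0], p[1], bs) - y,
                    x0=[f0, d0], bounds=([0.0, 0.0], [1.0, self.d_max]),
                    xtol=1e-14, ftol=1e-14)
                if best is None or res.cost < best.cost:
                    best = res
        f, d_par = best.x
        xi = KernelParams(f=float(f), Da=float(d_par), De_par=float(d_par),
                          De_perp=float(d_par * (1.0 - f)), fw=0.0)
        # p2 from the factorized system s2 = p2 K2 on the fitted kernel
        k2 = np.array([kernel_projection(xi, b, 2) for b in sinv.shells])
        s2 = sinv.sl.get(2, np.zeros_like(k2))
        num, den = float(np.sum(np.abs(k2) * s2)), float(np.sum(k2**2))
        p2 = num / den if den > 1e-12 else 0.0
        return EstimatorResult(
            "smt", xi, p2=float(np.clip(p2, 0, 1)),
            diagnostics={"cost": float(best.cost),
                         "converged": bool(best.success)})


# ---------------------------------------------------------------------------
# SMI
# ---------------------------------------------------------------------------

# Stand-in training prior (the published regression's prior is not part of
# this package): uniform kernel parameters spanning the 2 um^2/ms ex vivo
# bound, FOD from the exponential-decay family.
SMI_PRIOR_DEFAULT = {
    "f": (0.05, 0.95),
    "Da": (0.5, 2.0),
    "De_par": (0.5, 2.0),
    "De_perp": (0.05, 1.5),
    "lam": (0.0, 0.95),   # FOD exponential-decay parameter lambda, C = 1
    "C": (1.0, 1.0),
}

# Richer FOD prior: amplitude C sampled over the non-negativity domain, so
# (p2, p4, p6) vary independently; better behaved on FODs that are not
# exactly exponential-decay (e.g. Watson histograms).
SMI_PRIOR_RICH = dict(SMI_PRIOR_DEFAULT, C=(0.3, 1.25))

_SMI_TARGETS = ("f", "Da", "De_par", "De_perp", "p2", "p4", "p6")


def invariant_features(signals: SignalSet, lmax: int = 6) -> np.ndarray:
    """Flattened per-shell rotational invariants [s_l(b)] used by SMI."""
    sinv = signal_invariants(signals, lmax=lmax)
    return np.concatenate([sinv.sl[l] for l in range(0, lmax + 1, 2)])


class SMIEstimator(BaseEstimator):
    """Cubic-polynomial regression from per-shell signal invariants to the
    unconstrained kernel parameters and FOD invariants (fw fixed to 0).

    ``fit(X, y)`` is standard supervised training on invariant features;
    :func:`smi_train` builds the training set from the prior by the exact
    factorization s_l = p_l |K_l|.
    """

    def __init__(self, protocol: Protocol = None, degree: int = 3,
                 lmax: int = 6):
        self.protocol = protocol
        self.degree = degree
        self.lmax = lmax

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.model_ = make_pipeline(
            PolynomialFeatures(degree=self.degree, include_bias=True),
            LinearRegression())
        self.model_.fit(X, y)
        self.feature_min_ = X.min(axis=0)
        self.feature_max_ = X.max(axis=0)
        return self

    def predict(self, X, return_flags: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = self.model_.predict(X)
        # declared bounds
        out[:, 0] = np.clip(out[:, 0], 0.0, 1.0)        # f
        out[:, 1:4] = np.clip(out[:, 1:4], 0.0, None)   # diffusivities
        out[:, 4:7] = np.clip(out[:, 4:7], 0.0, 1.0)    # p2, p4, p6
        if return_flags:
            margin = 0.05 * (self.feature_max_ - self.feature_min_ + 1e-12)
            extrapolating = np.any(
                (X < self.feature_min_ - margin)
                | (X > self.feature_max_ + margin), axis=1)
            return out, extrapolating
        return out

    def predict_result(self, X) -> list[EstimatorResult]:
        out, flags = self.predict(X, return_flags=True)
        res = []
        for row, flag in zip(out, flags):
            xi = KernelParams(f=row[0], Da=row[1], De_par=row[2],
                              De_perp=row[3], fw=0.0)
            res.append(EstimatorResult(
                "smi", xi, p2=row[4],
                diagnostics={"p4": row[5], "p6": row[6],
                             "extrapolating": bool(flag)}))
        return res

    target_names = _SMI_TARGETS


def smi_train(protocol: Protocol, prior: dict = None, n_train: int = 50000,
              snr: float | None = 50.0, seed: int = 0,
              degree: int = 3, lmax: int = 6
              ) -> tuple[SMIEstimator, np.ndarray, np.ndarray]:
    """Build the SMI training set from the prior and fit the regression.

    FOD invariants follow the exponential-decay family p_l = C lambda^l
    with (C, lambda) sampled over the non-negative domain, so the training
    cloud spans independent (p2, p4, p6) combinations.  Noiseless
    invariants come from the factorization s_l = p_l |K_l|; training noise
    of std 1/(SNR * sqrt(n_dir)) per invariant (first-order propagation of
    direction averaging) regularizes the regression off the noiseless
    manifold -- pass ``snr=None`` for a strictly noiseless map.
    Returns (fitted estimator, features, targets).
    """
    prior = dict(SMI_PRIOR_DEFAULT if prior is None else prior)
    rng = np.random.default_rng(seed)
    shells = protocol.shells
    n_dir = int(protocol.shell_mask(shells[0]).sum())
    degs = list(range(0, lmax + 1, 2))

    f = rng.uniform(*prior["f"], n_train)
    Da = rng.uniform(*prior["Da"], n_train)
    Dep = rng.uniform(*prior["De_par"], n_train)
    Det = rng.uniform(*prior["De_perp"], n_train)
    lam = rng.uniform(*prior["lam"], n_train)
    c_lo, c_hi = prior.get("C", (1.0, 1.0))
    # analytic non-negativity bound (equator minimum of the family FOD)
    with np.errstate(divide="ignore"):
        cmax = 1.0 / (1.0 - (1.0 - lam**2) * (1.0 + lam**2) ** -1.5)
    cmax = np.minimum(np.where(lam > 0, cmax, np.inf), c_hi)
    C = rng.uniform(np.minimum(c_lo, cmax), cmax)

    # vectorized kernel projections over the whole training set
    from scipy.special import eval_legendre

    from .forward import _KW, _KX

    x2 = _KX**2
    pl_leg = {l: eval_legendre(l, _KX) for l in degs}
    X = np.empty((n_train, len(degs) * len(shells)))
    col = 0
    for l in degs:
        pl = np.ones(n_train) if l == 0 else C * lam**l
        for b in shells:
            K = (f[:, None] * np.exp(-b * Da[:, None] * x2[None, :])
                 + (1.0 - f)[:, None] * np.exp(
                     -b * Det[:, None]
                     - b * (Dep - Det)[:, None] * x2[None, :]))
            Kl = K @ (_KW * pl_leg[l])
            X[:, col] = pl * np.abs(Kl)
            col += 1
    y = np.column_stack([f, Da, Dep, Det,
                         C * lam**2, C * lam**4, C * lam**6])
    if snr is not None and np.isfinite(snr):
        X = X + rng.normal(0.0, 1.0 / (snr * np.sqrt(n_dir)), X.shape)
        X = np.clip(X, 0.0, None)
    est = SMIEstimator(protocol=protocol, degree=degree, lmax=lmax)
    est.fit(X, y)
    return est, X, y


# ---------------------------------------------------------------------------
# FOD recovery from a fitted kernel
# ---------------------------------------------------------------------------

def fod_from_kernel(signals: SignalSet, xi: KernelParams,
                    lmax: int = 6, ridge: float = 1e-8
                    ) -> SHCoefficients:
    """Invert s_lm = p_lm K_l shell by shell: each p_lm is the K_l^2-weighted
    (ridge-regularized) combination of s_lm(b)/K_l(b) across shells."""
    protocol = signals.protocol
    shells = protocol.shells
    pairs = lm_pairs(lmax)
    slm = {}
    for b in shells:
        mask = protocol.shell_mask(b)
        Y = real_sh_matrix(protocol.bvecs[mask], lmax)
        coef, *_ = np.linalg.lstsq(Y, signals.values[mask], rcond=None)
        slm[b] = coef
    values = np.zeros(len(pairs))
    for j, (l, m) in enumerate(pairs):
        if l == 0:
            values[j] = np.sqrt(4.0 * np.pi)
            continue
        kl = np.array([kernel_projection(xi, b, l) for b in shells])
        num = float(np.sum(kl * np.array([slm[b][j] for b in shells])))
        den = float(np.sum(kl**2))
        values[j] = num / (den + ridge) if den > ridge else 0.0
    return SHCoefficients(lmax=lmax, values=values)
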