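"""Fiber orientation distributions: SH decomposition, rotational invariants,
dispersion angle, and axially symmetric FOD families.

The FOD P(n) is an antipodally symmetric density on the unit sphere,
normalized under the measure dn = dOmega/(4*pi) so that <1> = 1.  Its
spherical-harmonic coefficients are p_lm = 4*pi*<Y_lm>, and the per-degree
rotational invariants

    p_l = sqrt(sum_m p_lm^2) / N_l,      N_l = sqrt(4*pi*(2l+1)),

satisfy 0 <= p_l <= 1 with p_l = |<P_l(cos theta)>| for axially symmetric
FODs.  p_2 maps to a dispersion angle via
theta_p2 = arccos(sqrt((2 p2 + 1)/3)).

Three axially symmetric families are provided:

* ``expdecay``: the two-parameter family whose invariants decay exactly
  exponentially, p_l = C * lambda^l for even l >= 2.  Its closed form is the
  even-degree resummation of the Poisson-kernel generating function: the
  potential of two symmetric point sources at +/- lambda * n0 inside the
  unit sphere, mixed with an isotropic floor 1 - C.
* ``watson``: the Watson distribution, density proportional to
  exp(kappa * t^2).
* ``poisson``: the one-parameter symmetrized Poisson kernel, invariants
  p_l = lambda^l (the C = 1 member of the family).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import eval_legendre, hyp1f1

from .shbasis import lm_pairs, norm_factor, real_sh_matrix
from .sphere import SphericalHistogram

__all__ = [
    "SHCoefficients",
    "RotInvariants",
    "sh_fit",
    "axisym_coeffs",
    "rot_invariants",
    "theta_from_p2",
    "fit_expdecay",
    "family_eval",
    "family_invariant",
    "family_domain",
    "family_cmax",
    "watson_density",
    "watson_invariant",
    "watson_cos2_mean",
    "watson_kappa_for_theta",
    "poisson_density",
    "reference_fod_eval",
    "reference_fod_invariants",
    "axisym_invariant",
    "lobe_invariants",
]

LMAX_DEFAULT = 16

# 128-point Gauss-Legendre nodes on [0, 1]; spectrally accurate for every
# smooth axially symmetric density used here.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(128)
_GL_T = 0.5 * (_GL_X + 1.0)
_GL_WT = 0.5 * _GL_W


@dataclass
class SHCoefficients:
    """Even-degree real SH coefficients of an FOD (p_00 = sqrt(4*pi))."""

    lmax: int
    values: np.ndarray  # ordered per shbasis.lm_pairs(lmax)

    def __post_init__(self):
        if self.lmax % 2 != 0:
            raise ValueError("lmax must be even")
        if self.lmax > LMAX_DEFAULT:
            raise ValueError(f"lmax must be <= {LMAX_DEFAULT}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite SH coefficients")

    def coeff(self, l: int, m: int) -> float:
        return float(self.values[lm_pairs(self.lmax).index((l, m))])

    def degree_block(self, l: int) -> np.ndarray:
        pairs = lm_pairs(self.lmax)
        idx = [i for i, (ll, _) in enumerate(pairs) if ll == l]
        return self.values[idx]


@dataclass
class RotInvariants:
    """Rotational invariants p_l per even degree l >= 2 (p_0 == 1)."""

    lmax: int
    pl: dict[int, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.pl[l] for l in sorted(self.pl)])


def sh_fit(
    data: SphericalHistogram | np.ndarray,
    lmax: int = LMAX_DEFAULT,
    weights: np.ndarray | None = None,
) -> SHCoefficients:
    """Project an orientation histogram or direction sample onto even SH.

    For a histogram, p_lm = sum_bins Y_lm(c_b) P_b Omega_b; for raw unit
    directions, p_lm = 4*pi * weighted mean of Y_lm (a Monte-Carlo estimate
    of the same projection).  Odd degrees are identically zero by basis
    construction (only even l present).
    """
    if lmax % 2 != 0:
        raise ValueError("lmax must be even")
    if isinstance(data, SphericalHistogram):
        if abs(data.mass - 1.0) > 1e-6:
            raise ValueError("histogram must be normalized before SH fit")
        Y = real_sh_matrix(data.mesh.centers, lmax)
        vals = Y.T @ (data.density * data.mesh.solid_angles)
    else:
        directions = np.atleast_2d(np.asarray(data, dtype=float))
        directions = directions / np.linalg.norm(directions, axis=1,
                                                 keepdims=True)
        if weights is None:
            weights = np.ones(len(directions))
        w = np.asarray(weights, dtype=float)
        Y = real_sh_matrix(directions, lmax)
        vals = 4.0 * np.pi * (Y.T @ w) / w.sum()
    return SHCoefficients(lmax=lmax, values=vals)


def axisym_coeffs(pl: dict[int, float], lmax: int = LMAX_DEFAULT,
                  main_direction=None) -> SHCoefficients:
    """SH coefficients of an axially symmetric FOD from its invariants:
    p_l0 = N_l p_l in the fiber frame (optionally rotated to an arbitrary
    ``main_direction`` by numerical projection)."""
    pairs = lm_pairs(lmax)
    vals = np.zeros(len(pairs))
    for i, (l, m) in enumerate(pairs):
        if m == 0:
            vals[i] = norm_factor(l) * (1.0 if l == 0 else pl.get(l, 0.0))
    coeffs = SHCoefficients(lmax=lmax, values=vals)
    if main_direction is None:
        return coeffs
    mu = np.asarray(main_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    # rotate by re-projecting P(t = n . mu) on a product quadrature grid
    ct, wt = np.polynomial.legendre.leggauss(2 * lmax + 8)
    nphi = 4 * lmax + 16
    phi = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
    st = np.sqrt(1.0 - ct**2)
    dirs = np.stack([np.outer(st, np.cos(phi)), np.outer(st, np.sin(phi)),
                     np.outer(ct, np.ones(nphi))], axis=-1).reshape(-1, 3)
    w = np.repeat(wt, nphi) * (2.0 * np.pi / nphi)
    t = dirs @ mu
    P = np.zeros_like(t)
    for l in range(0, lmax + 1, 2):
        pl_val = 1.0 if l == 0 else pl.get(l, 0.0)
        P += (2 * l + 1) * pl_val * eval_legendre(l, t)
    Y = real_sh_matrix(dirs, lmax)
    return SHCoefficients(lmax=lmax, values=(Y.T * w) @ P)


def rot_invariants(coeffs: SHCoefficients) -> RotInvariants:
    pl = {}
    for l in range(2, coeffs.lmax + 1, 2):
        block = coeffs.degree_block(l)
        val = np.sqrt(np.sum(block**2)) / norm_factor(l)
        pl[l] = float(max(val, 0.0))
    return RotInvariants(lmax=coeffs.lmax, pl=pl)


def theta_from_p2(p2: float) -> float:
    """Dispersion angle (degrees) from the l=2 invariant."""
    if not 0.0 <= p2 <= 1.0 + 1e-12:
        raise ValueError(f"p2 must be in [0, 1], got {p2}")
    p2 = min(p2, 1.0)
    return float(np.degrees(np.arccos(np.sqrt((2.0 * p2 + 1.0) / 3.0))))


def fit_expdecay(pl: dict[int, float] | RotInvariants) -> tuple[float, float]:
    """Log-linear least-squares fit p_l ~ C * lambda^l over even degrees.

    Returns (C, lambda).  Non-positive invariants are excluded; at least two
    positive values are required.
    """
    if isinstance(pl, RotInvariants):
        pl = pl.pl
    ls = np.array(sorted(pl))
    vals = np.array([pl[l] for l in ls], dtype=float)
    keep = vals > 0
    if keep.sum() < 2:
        raise ValueError("need at least two positive invariants to fit decay")
    ls, vals = ls[keep], vals[keep]
    slope, intercept = np.polyfit(ls, np.log(vals), 1)
    return float(np.exp(intercept)), float(np.exp(slope))


# ---------------------------------------------------------------------------
# Exponential-decay family (closed form and non-negativity domain)
# ---------------------------------------------------------------------------

def _source_pair(t: np.ndarray, lam: float) -> np.ndarray:
    """Symmetrized two-source 1/r^3 potential on the sphere: the generating
    function sum over even l of (2l+1) lambda^l P_l(t)."""
    t = np.asarray(t, dtype=float)
    a = (1.0 - 2.0 * lam * t + lam**2) ** -1.5
    b = (1.0 + 2.0 * lam * t + lam**2) ** -1.5
    return 0.5 * (1.0 - lam**2) * (a + b)


def family_eval(C: float, lam: float, t: np.ndarray | float) -> np.ndarray:
    """Closed-form FOD of the exponential-decay family at t = n . n0.

    P(t) = (1 - C) + C * [symmetrized Poisson kernel at lambda], whose
    rotational invariants are exactly C * lambda^l for even l >= 2.
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError(f"lambda must be in [0, 1), got {lam}")
    if C < 0:
        raise ValueError(f"C must be >= 0, got {C}")
    return (1.0 - C) + C * _source_pair(t, lam)


def axisym_invariant(density, l: int) -> float:
    """p_l = |<P_l(cos theta)>| for an axially symmetric density(t) on [0,1],
    by Gauss-Legendre quadrature (the convention-free definition)."""
    vals = density(_GL_T)
    return float(abs(np.sum(_GL_WT * vals * eval_legendre(l, _GL_T))))


def family_invariant(C: float, lam: float, l: int) -> float:
    """Quadrature invariant of the closed-form family (equals C*lambda^l)."""
    return axisym_invariant(lambda t: family_eval(C, lam, t), l)


def family_cmax(lam: float) -> float:
    """Largest C keeping the family FOD non-negative at given lambda.

    The minimum of P over t in [0,1] sits at the equator t = 0, giving the
    analytic bound C <= 1 / (1 - (1-lam^2)(1+lam^2)^{-3/2}); a numerical
    minimization cross-checks that the equator is indeed the minimum.
    """
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must be in [0, 1)")
    if lam == 0.0:
        return np.inf
    g0 = _source_pair(np.array(0.0), lam)
    c_analytic = 1.0 / (1.0 - float(g0))
    # numerical refinement of min_t of the source term
    tgrid = np.linspace(0.0, 1.0, 1001)
    g = _source_pair(tgrid, lam)
    i = int(np.argmin(g))
    lo, hi = max(0.0, tgrid[i] - 2e-3), min(1.0, tgrid[i] + 2e-3)
    res = minimize_scalar(lambda t: _source_pair(np.array(t), lam),
                          bounds=(lo, hi), method="bounded")
    gmin = min(float(res.fun), float(g[i]))
    c_numeric = 1.0 / (1.0 - gmin) if gmin < 1.0 else np.inf
    return min(c_analytic, c_numeric)


def family_domain(C: float, lam: float) -> bool:
    """True iff (C, lambda) keeps the family FOD non-negative everywhere."""
    if C < 0 or not 0.0 <= lam < 1.0:
        return False
    if C <= 1.0:
        return True  # isotropic floor covers the deficit
    return C <= family_cmax(lam) * (1.0 + 1e-12)


# ---------------------------------------------------------------------------
# Reference FODs: Watson and Poisson kernel
# ---------------------------------------------------------------------------

def watson_density(kappa: float, t: np.ndarray | float) -> np.ndarray:
    """Watson density w.r.t. dn = dOmega/(4*pi): exp(kappa t^2)/M(1/2,3/2,k)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    t = np.asarray(t, dtype=float)
    norm = hyp1f1(0.5, 1.5, kappa)
    if not np.isfinite(norm) or norm <= 0:
        raise ValueError(f"Watson normalization failed for kappa={kappa}")
    return np.exp(kappa * t**2 - np.log(norm))


def _watson_moment(kappa: float, func) -> float:
    """<func(t)> under Watson(kappa), numerically stable for large kappa."""
    logw = kappa * _GL_T**2
    logw -= logw.max()
    w = _GL_WT * np.exp(logw)
    return float(np.sum(w * func(_GL_T)) / np.sum(w))


def watson_invariant(kappa: float, l: int) -> float:
    """p_l of Watson(kappa) by quadrature; p_l in [0, 1), monotone in kappa."""
    if kappa > 1e5:  # delta limit
        return 1.0
    return abs(_watson_moment(kappa, lambda t: eval_legendre(l, t)))


def watson_cos2_mean(kappa: float) -> float:
    if kappa > 1e5:
        return 1.0
    return _watson_moment(kappa, lambda t: t**2)


def watson_kappa_for_theta(theta_deg: float) -> float:
    """Concentration kappa whose dispersion angle (Eq.-1 style,
    arccos sqrt(<cos^2>)) equals ``theta_deg``."""
    target = np.cos(np.radians(theta_deg)) ** 2
    if target <= 1.0 / 3.0:
        raise ValueError("theta beyond the isotropic limit (54.74 deg)")
    return brentq(lambda k: watson_cos2_mean(k) - target, 1e-6, 1e5)


def poisson_density(lam: float, t: np.ndarray | float) -> np.ndarray:
    """One-parameter symmetrized Poisson-kernel FOD; p_l = lambda^l."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must be in [0, 1)")
    return _source_pair(t, lam)


def reference_fod_eval(model: str, params, t):
    if model == "watson":
        return watson_density(float(params), t)
    if model == "poisson":
        return poisson_density(float(params), t)
    if model == "expdecay":
        C, lam = params
        return family_eval(C, lam, t)
    raise ValueError(f"unknown FOD model '{model}'")


def reference_fod_invariants(model: str, params, degrees) -> dict[int, float]:
    out = {}
    for l in degrees:
        if model == "watson":
            out[l] = watson_invariant(float(params), l)
        elif model == "poisson":
            out[l] = float(params) ** l
        elif model == "expdecay":
            C, lam = params
            out[l] = C * lam**l if l >= 2 else 1.0
        else:
            raise ValueError(f"unknown FOD model '{model}'")
    return out


# ---------------------------------------------------------------------------
# Lobe segmentation of multi-peak FODs
# ---------------------------------------------------------------------------

@dataclass
class Lobe:
    mass: float
    direction: np.ndarray          # principal orientation of the lobe
    invariants: RotInvariants
    bin_indices: np.ndarray


def lobe_invariants(
    hist: SphericalHistogram,
    lmax: int = 6,
    floor_factor: float = 1.5,
    n_neighbors: int = 8,
    merge_deg: float = 30.0,
) -> list[Lobe]:
    """Segment FOD lobes by gradient ascent on the sphere mesh and compute
    per-lobe rotational invariants.

    Each bin is linked to its highest-density neighbor; following the links
    partitions the mesh into ascent basins.  Peaks within ``merge_deg`` of a
    stronger peak (axially, so antipodal peaks merge too) are absorbed into
    it.  If no peak rises above ``floor_factor`` times the isotropic level,
    the whole FOD is returned as one lobe.  Each lobe is renormalized to
    unit mass before its p_l are computed (p_l is rotation invariant, so no
    explicit rotation to the lobe frame is needed).
    """
    from scipy.spatial import cKDTree

    mesh, dens = hist.mesh, hist.density
    tree = cKDTree(mesh.centers)
    _, nbrs = tree.query(mesh.centers, k=n_neighbors + 1)
    # steepest-ascent pointer (self if local max)
    best = nbrs[np.arange(mesh.n_bins)[:, None],
                np.argmax(dens[nbrs], axis=1)[:, None]].ravel()
    # pointer jumping to fixed point
    for _ in range(64):
        nxt = best[best]
        if np.array_equal(nxt, best):
            break
        best = nxt
    peaks = np.unique(best)
    # merge near-coincident / antipodal peaks into the strongest one
    order = peaks[np.argsort(-dens[peaks])]
    cos_merge = np.cos(np.radians(merge_deg))
    kept: list[int] = []
    root_of: dict[int, int] = {}
    for p in order:
        merged = False
        for q in kept:
            if abs(mesh.centers[p] @ mesh.centers[q]) > cos_merge:
                root_of[p] = q
                merged = True
                break
        if not merged:
            kept.append(int(p))
            root_of[p] = int(p)
    significant = [p for p in kept if dens[p] > floor_factor]
    if not significant:
        labels = np.zeros(mesh.n_bins, dtype=int)
        roots = np.array([int(np.argmax(dens))])
    else:
        # sub-floor peaks go to the axially nearest significant peak
        sig_dirs = mesh.centers[significant]
        for p in kept:
            if p not in significant:
                root_of[p] = significant[int(np.argmax(
                    np.abs(sig_dirs @ mesh.centers[p])))]
        mapped = np.array([root_of[root_of[p]] for p in best])
        roots = np.unique(mapped)
        labels = np.searchsorted(roots, mapped)

    lobes = []
    for i, root in enumerate(roots):
        sel = labels == i
        mass = float(np.sum(dens[sel] * mesh.solid_angles[sel]) / (4 * np.pi))
        if mass <= 0:
            continue
        sub = np.zeros_like(dens)
        sub[sel] = dens[sel] / mass
        sub_hist = SphericalHistogram(mesh, sub)
        coeffs = sh_fit(sub_hist, lmax=lmax)
        w = dens[sel] * mesh.solid_angles[sel]
        T = (mesh.centers[sel].T * w) @ mesh.centers[sel]
        evals, evecs = np.linalg.eigh(T)
        lobes.append(Lobe(mass=mass, direction=evecs[:, -1],
                          invariants=rot_invariants(coeffs),
                          bin_indices=np.where(sel)[0]))
    lobes.sort(key=lambda lb: -lb.mass)
    return lobes
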