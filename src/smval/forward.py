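"""Standard Model forward signal machinery.

The dMRI signal of a white-matter voxel is the spherical convolution of the
fiber orientation distribution P(n) with an axially symmetric fascicle
kernel

    K(b, xi, x) = f exp(-b Da x^2)
                + (1 - f - fw) exp(-b De_perp - b (De_par - De_perp) x^2)
                + fw exp(-b Dw),            x = u . n,

so that K(0) = 1 and S(b=0) = S0.  (Compartment fractions are fractions of
the total dMRI-visible water; the extra-axonal fraction is 1 - f - fw.)

In the spherical-harmonic basis the convolution factorizes:
s_lm(b) = p_lm * K_l(b) with K_l = integral_0^1 K(x) P_l(x) dx, and the
per-shell signal invariants obey s_l = p_l * |K_l| on noiseless data -- the
central identity every simulation route here is tested against.

The acquisition protocol is multi-shell PGSE: b = 2, 3, 4 ms/um^2 with
3 x 43 half-sphere directions plus 3 b=0 volumes (132 total), pulse length
delta = 6 ms and separation Delta = 11.5 ms (timing is metadata only for
Gaussian compartments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

from .fod import SHCoefficients
from .shbasis import lm_pairs, norm_factor, real_sh_matrix
from .sphere import uniform_hemisphere

# Self-diffusion coefficient of free water at 21 C (room temperature),
# um^2/ms.  Used for the free-water compartment; the idealized axoplasm
# bound D0 = 2.0 is kept separately in `synthetic.D0_AXOPLASM`.
D_WATER_21C = 2.1

DEFAULT_SHELLS = (2.0, 3.0, 4.0)     # ms/um^2
DEFAULT_NDIR = 43
DEFAULT_NB0 = 3
DEFAULT_DELTA = 6.0                  # ms
DEFAULT_DELTA_BIG = 11.5             # ms

_GLX, _GLW = np.polynomial.legendre.leggauss(64)
_KX = 0.5 * (_GLX + 1.0)             # nodes on [0, 1]
_KW = 0.5 * _GLW

__all__ = [
    "KernelParams",
    "Protocol",
    "SignalSet",
    "SignalInvariants",
    "kernel_eval",
    "kernel_projection",
    "simulate_signal",
    "simulate_signal_direct",
    "signal_invariants",
    "spherical_mean",
    "add_noise",
    "make_protocol",
    "D_WATER_21C",
]


@dataclass(frozen=True)
class KernelParams:
    """Fiber-fascicle compartment parameters (diffusivities in um^2/ms)."""

    f: float
    Da: float
    De_par: float
    De_perp: float
    fw: float = 0.0
    Dw: float = D_WATER_21C

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0 or not 0.0 <= self.fw <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
        if self.f + self.fw > 1.0 + 1e-12:
            raise ValueError("f + fw must be <= 1")
        for name in ("Da", "De_par", "De_perp", "Dw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Protocol:
    """Multi-shell PGSE acquisition: per-volume b-value and unit direction."""

    bvals: np.ndarray                  # (n_meas,), ms/um^2, 0 for b0
    bvecs: np.ndarray                  # (n_meas, 3) unit vectors
    delta: float = DEFAULT_DELTA       # ms, pulse length (metadata)
    Delta: float = DEFAULT_DELTA_BIG   # ms, pulse separation

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (n_meas, 3)")
        nrm = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(nrm[dw] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit norm")

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])

    def shell_mask(self, b: float) -> np.ndarray:
        return np.isclose(self.bvals, b)

    @property
    def n_meas(self) -> int:
        return len(self.bvals)


@dataclass
class SignalSet:
    """S/S0 per acquisition volume, matched to a protocol."""

    protocol: Protocol
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-1] != self.protocol.n_meas:
            raise ValueError("signal length does not match protocol")


@dataclass
class SignalInvariants:
    """Per-shell rotational invariants s_l of the signal, even l."""

    shells: np.ndarray
    sl: dict[int, np.ndarray]   # degree -> per-shell values

    def s0(self) -> np.ndarray:
        return self.sl[0]


def make_protocol(shells=DEFAULT_SHELLS, n_dir: int = DEFAULT_NDIR,
                  n_b0: int = DEFAULT_NB0, seed: int = 42,
                  delta: float = DEFAULT_DELTA,
                  Delta: float = DEFAULT_DELTA_BIG) -> Protocol:
    """The study's acquisition design: one b0 before each shell of
    electrostatically repelled half-sphere directions."""
    bvals, bvecs = [], []
    for i, b in enumerate(shells):
        dirs = uniform_hemisphere(n_dir, seed=seed + i)
        bvals.append(0.0)
        bvecs.append(np.array([0.0, 0.0, 1.0]))
        bvals.extend([b] * n_dir)
        bvecs.extend(dirs)
    # trailing b0s if more requested than shells
    for _ in range(max(0, n_b0 - len(shells))):
        bvals.append(0.0)
        bvecs.append(np.array([0.0, 0.0, 1.0]))
    return Protocol(bvals=np.array(bvals), bvecs=np.vstack(bvecs),
                    delta=delta, Delta=Delta)


# ---------------------------------------------------------------------------
# Kernel
# ---------------------------------------------------------------------------

def kernel_eval(xi: KernelParams, b: float, x: np.ndarray | float
                ) -> np.ndarray:
    """Fascicle response K(b, xi, x) at x = u . n."""
    x2 = np.asarray(x, dtype=float) ** 2
    intra = xi.f * np.exp(-b * xi.Da * x2)
    extra = (1.0 - xi.f - xi.fw) * np.exp(
        -b * xi.De_perp - b * (xi.De_par - xi.De_perp) * x2)
    water = xi.fw * np.exp(-b * xi.Dw)
    return intra + extra + water


def kernel_projection(xi: KernelParams, b: float, l: int) -> float:
    """K_l = integral_0^1 K(b, xi, x) P_l(x) dx (64-pt Gauss-Legendre)."""
    if l % 2 != 0:
        raise ValueError("kernel projections are defined for even l")
    vals = kernel_eval(xi, b, _KX)
    return float(np.sum(_KW * vals * eval_legendre(l, _KX)))


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _check_normalized(coeffs: SHCoefficients):
    p00 = coeffs.coeff(0, 0)
    if abs(p00 - np.sqrt(4.0 * np.pi)) > 1e-6 * np.sqrt(4.0 * np.pi):
        raise ValueError("FOD is not normalized (p00 != sqrt(4 pi))")


def simulate_signal(protocol: Protocol, coeffs: SHCoefficients,
                    xi: KernelParams) -> SignalSet:
    """SH route: s_lm(b) = p_lm K_l(b), synthesized at the protocol
    directions.  S(u) = sum_lm p_lm K_l Y_lm(u)."""
    _check_normalized(coeffs)
    pairs = lm_pairs(coeffs.lmax)
    out = np.empty(protocol.n_meas)
    b0 = protocol.bvals == 0
    out[b0] = 1.0
    for b in protocol.shells:
        mask = protocol.shell_mask(b)
        Y = real_sh_matrix(protocol.bvecs[mask], coeffs.lmax)
        Kl = {l: kernel_projection(xi, b, l)
              for l in range(0, coeffs.lmax + 1, 2)}
        slm = coeffs.values * np.array([Kl[l] for l, _ in pairs])
        out[mask] = Y @ slm
    return SignalSet(protocol=protocol, values=out)


def simulate_signal_direct(protocol: Protocol, fod_axisym,
                           main_direction, xi: KernelParams,
                           n_theta: int = 64, n_phi: int = 128) -> SignalSet:
    """Direct route: S(u) = <P(n) K(b, u.n)> by product Gauss-Legendre x
    trapezoid quadrature over the sphere, for an axially symmetric FOD
    given as a callable density(t) about ``main_direction``.

    Serves as the independent cross-check of the SH route.
    """
    mu = np.asarray(main_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    st = np.sqrt(1.0 - ct**2)
    # grid directions in the frame where mu = z
    dirs = np.stack([
        np.outer(st, np.cos(phi)),
        np.outer(st, np.sin(phi)),
        np.outer(ct, np.ones_like(phi)),
    ], axis=-1).reshape(-1, 3)
    w = np.repeat(wt, n_phi) * (2.0 * np.pi / n_phi) / (4.0 * np.pi)
    pvals = fod_axisym(dirs[:, 2])       # density depends on t = n . z
    mass = float(np.sum(w * pvals))
    if abs(mass - 1.0) > 1e-6:
        raise ValueError(f"FOD not normalized (mass {mass:.6f})")
    from .geometry import rotation_to_z

    R = rotation_to_z(mu)                # R @ mu = z
    out = np.empty(protocol.n_meas)
    out[protocol.bvals == 0] = 1.0
    for b in protocol.shells:
        mask = protocol.shell_mask(b)
        u = protocol.bvecs[mask] @ R.T   # into the mu = z frame
        x = u @ dirs.T
        K = kernel_eval(xi, b, x)
        out[mask] = K @ (w * pvals)
    return SignalSet(protocol=protocol, values=out)


# ---------------------------------------------------------------------------
# Signal invariants and spherical mean
# ---------------------------------------------------------------------------

def signal_invariants(signals: SignalSet, lmax: int = 6) -> SignalInvariants:
    """Per-shell even-degree SH fit of the signal and its invariants
    s_l = ||s_lm|| / N_l (s_0 is the spherical mean)."""
    protocol = signals.protocol
    shells = protocol.shells
    import warnings

    sl: dict[int, list[float]] = {}
    for b in shells:
        mask = protocol.shell_mask(b)
        dirs = protocol.bvecs[mask]
        n_min = (lmax + 1) * (lmax + 2) // 2
        l_eff = lmax
        while mask.sum() < (l_eff + 1) * (l_eff + 2) // 2 and l_eff > 0:
            l_eff -= 2
        if l_eff < lmax:
            warnings.warn(
                f"shell b={b}: {mask.sum()} < {n_min} directions, "
                f"reducing lmax to {l_eff}")
        Y = real_sh_matrix(dirs, l_eff)
        coef, *_ = np.linalg.lstsq(Y, signals.values[mask], rcond=None)
        pairs = lm_pairs(l_eff)
        for l in range(0, l_eff + 1, 2):
            block = coef[[i for i, (ll, _) in enumerate(pairs) if ll == l]]
            val = np.sqrt(np.sum(block**2)) / norm_factor(l)
            sl.setdefault(l, []).append(float(val))
    return SignalInvariants(shells=shells,
                            sl={l: np.array(v) for l, v in sl.items()})


def spherical_mean(signals: SignalSet) -> dict[float, float]:
    """Directional average per shell (uniform design assumed)."""
    out = {}
    for b in signals.protocol.shells:
        mask = signals.protocol.shell_mask(b)
        out[float(b)] = float(signals.values[mask].mean())
    return out


def add_noise(signals: SignalSet, snr: float, model: str = "rician",
              seed: int = 0) -> SignalSet:
    """Add measurement noise at the stated SNR (defined at S0 = 1).

    ``rician``: magnitude of the complex signal with i.i.d. Gaussian noise
    of sigma = 1/SNR on both channels; ``gaussian``: real additive noise.
    """
    if snr <= 0:
        raise ValueError("SNR must be > 0")
    if np.isinf(snr):
        return SignalSet(signals.protocol, signals.values.copy())
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    v = signals.values
    if model == "gaussian":
        noisy = v + rng.normal(0.0, sigma, v.shape)
    elif model == "rician":
        noisy = np.abs(v + rng.normal(0.0, sigma, v.shape)
                       + 1j * rng.normal(0.0, sigma, v.shape))
    else:
        raise ValueError(f"unknown noise model '{model}'")
    return SignalSet(signals.protocol, noisy)
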