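"""Real spherical-harmonic basis.

Conventions (stated once, used everywhere):

* Real SH built from the complex ones with Condon-Shortley phase,
  orthonormal under the canonical measure dOmega:
  ``integral |Y_lm|^2 dOmega = 1``.  Equivalently, with the normalized
  sphere measure dn = dOmega/(4*pi), ``4*pi * <|Y_lm|^2> = 1``.
* Only even degrees l are used for antipodally symmetric densities.
* Coefficient ordering: l ascending, m from -l to +l.
* FOD coefficients: p_lm = integral Y_lm(n) P(n) dOmega = 4*pi <Y_lm>_P.
* Y_l0(z-axis) = sqrt((2l+1)/(4*pi)), so N_l = sqrt(4*pi*(2l+1)) satisfies
  Y_l0 = (N_l/(4*pi)) P_l(cos theta) and a delta FOD has p_l0 = N_l.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y


def norm_factor(l: int | np.ndarray) -> np.ndarray:
    """N_l = sqrt(4*pi*(2l+1)), the invariant normalization for degree l."""
    return np.sqrt(4.0 * np.pi * (2.0 * np.asarray(l) + 1.0))


def even_degrees(lmax: int) -> list[int]:
    if lmax % 2 != 0 or lmax < 0:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    return list(range(0, lmax + 1, 2))


def lm_pairs(lmax: int, include_l0: bool = True) -> list[tuple[int, int]]:
    """(l, m) ordering of the even-degree coefficient vector."""
    pairs = []
    for l in even_degrees(lmax):
        if l == 0 and not include_l0:
            continue
        for m in range(-l, l + 1):
            pairs.append((l, m))
    return pairs


def n_coeffs(lmax: int) -> int:
    return len(lm_pairs(lmax))


def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    r = np.linalg.norm(d, axis=1)
    theta = np.arccos(np.clip(d[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    return theta, phi


def real_sh_matrix(directions: np.ndarray, lmax: int) -> np.ndarray:
    """Design matrix of real even-degree SH evaluated at unit ``directions``.

    Returns shape (n_directions, n_coeffs(lmax)), columns ordered by
    :func:`lm_pairs`.
    """
    theta, phi = _to_angles(directions)
    cols = []
    for l, m in lm_pairs(lmax):
        am = abs(m)
        y = sph_harm_y(l, am, theta, phi)  # complex, CS phase included
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** am * y.imag)
    return np.stack(cols, axis=1)


def legendre_even(l: int, x: np.ndarray) -> np.ndarray:
    """Legendre polynomial P_l(x)."""
    from scipy.special import eval_legendre

    return eval_legendre(l, x)
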