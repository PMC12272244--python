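"""Synthetic axon populations with known ground truth.

Emulates segmented 3d-EM myelinated axons: each axon is a centerline through
a rectangular tissue block with a transverse sinusoidal undulation, a
sinusoidally varying cross-sectional area ("beading"), and a myelin annulus
set by the g-ratio.  Orientations are drawn from a delta, Watson, or
exponential-decay-family distribution about a main direction, so every
downstream morphometry quantity has an analytic or quadrature ground truth:

* dispersion angle  theta = arccos sqrt(<cos^2 theta_i>)  from the
  generative tangents;
* axial tortuosity  Lambda_par = <A_bar/A(z)> = 1/sqrt(1-a^2)  for beading
  amplitude a;
* undulation factor <cos^2 theta_u> ~ 1/sqrt(1 + (u k)^2) for amplitude u
  and wavenumber k = 2*pi/wavelength;
* intra-axonal fraction f = V_intra / (V_box - V_myelin);
* predicted intra-axonal diffusivity
  D_a = sum_k w_k (D0/Lambda_k) <cos^2 theta_u>_k, w_k ~ axon volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fod import family_domain, family_eval
from .geometry import AxonGeometry, weighted_mean_direction

D0_AXOPLASM = 2.0  # um^2/ms, unrestricted axoplasm diffusivity at room temp

__all__ = [
    "PopulationSpec",
    "GroundTruth",
    "SyntheticPopulation",
    "sample_directions",
    "generate_axon",
    "generate_population",
    "ground_truth",
    "D0_AXOPLASM",
]


@dataclass
class PopulationSpec:
    """Generative parameters of one synthetic axon population."""

    n_axons: int = 200
    box: tuple[float, float, float] = (50.0, 50.0, 50.0)   # um extents
    fod_model: str = "watson"            # delta | watson | expdecay_family
    fod_params: dict = field(default_factory=lambda: {"kappa": 16.0})
    main_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    undulation_amplitude: float = 0.5    # um
    undulation_wavelength: float = 10.0  # um
    beading_amplitude: float = 0.2       # relative, in [0, 1)
    beading_wavelength: float = 5.0      # um
    mean_diameter: float = 1.0           # inner diameter, um
    diameter_sigma: float = 0.2          # lognormal sigma of ln(diameter)
    g_ratio: float = 0.7
    step_dz: float = 0.25                # um centerline sampling step
    min_length: float = 12.0             # um
    seed: int = 0

    def __post_init__(self):
        if self.n_axons < 1:
            raise ValueError("n_axons must be >= 1")
        if any(e <= 0 for e in self.box):
            raise ValueError("box extents must be > 0")
        if not 0.0 <= self.beading_amplitude < 1.0:
            raise ValueError("beading amplitude must be in [0, 1)")
        for name in ("undulation_wavelength", "beading_wavelength",
                     "step_dz", "mean_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.g_ratio <= 1.0:
            raise ValueError("g_ratio must be in (0, 1]")
        n0 = np.asarray(self.main_direction, dtype=float)
        nrm = np.linalg.norm(n0)
        if nrm == 0:
            raise ValueError("main_direction must be non-zero")
        self.main_direction = tuple(n0 / nrm)


@dataclass
class GroundTruth:
    """Generative truth of a population, computed independently of the
    morphometry pipeline (from the generator's own tangents and formulas)."""

    theta_deg: float
    f: float
    mean_tortuosity: float
    cos2_undulation: float
    Da_pred: float
    fod_model: str
    fod_params: dict


@dataclass
class SyntheticPopulation:
    axons: list[AxonGeometry]
    box: tuple[float, float, float]
    spec: PopulationSpec
    ground_truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------

def _rotate_frame(vecs: np.ndarray, n0: np.ndarray) -> np.ndarray:
    from .geometry import rotation_to_z

    R = rotation_to_z(n0)          # R @ n0 = z
    return vecs @ R                # rows v -> R.T @ v : z-frame -> n0-frame


def _sample_watson_t(kappa: float, n: int, rng: np.random.Generator
                     ) -> np.ndarray:
    """|cos| of Watson(kappa) by rejection from a truncated-exponential
    envelope exp(kappa*t) on [0, 1]; exact for all kappa >= 0."""
    if kappa < 1e-12:
        return rng.uniform(0.0, 1.0, n)
    out = np.empty(n)
    got = 0
    while got < n:
        m = max(n - got, 64)
        u = rng.uniform(0.0, 1.0, 2 * m)
        # inverse CDF of the envelope ~ exp(kappa t) on [0,1]
        t = np.log1p(u[:m] * np.expm1(kappa)) / kappa
        acc = np.log(u[m:]) <= kappa * (t**2 - t)
        t = t[acc][: n - got]
        out[got:got + len(t)] = t
        got += len(t)
    return out


def _sample_family_t(C: float, lam: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """|cos| of the exponential-decay family by rejection from uniform."""
    if not family_domain(C, lam):
        raise ValueError(f"(C={C}, lambda={lam}) outside the "
                         "non-negativity domain")
    grid = np.linspace(0.0, 1.0, 2001)
    pmax = float(family_eval(C, lam, grid).max()) * (1.0 + 1e-9)
    out = np.empty(n)
    got = 0
    while got < n:
        m = max(n - got, 64)
        t = rng.uniform(0.0, 1.0, m)
        acc = rng.uniform(0.0, pmax, m) <= family_eval(C, lam, t)
        t = t[acc][: n - got]
        out[got:got + len(t)] = t
        got += len(t)
    return out


def sample_directions(model: str, params: dict, n: int, seed: int,
                      main_direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Draw ``n`` antipodally symmetric unit vectors from an FOD model.

    Models: ``delta`` (all along the main direction), ``watson`` (parameter
    ``kappa``), ``expdecay_family`` (parameters ``C`` and ``lam``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    n0 = np.asarray(main_direction, dtype=float)
    n0 = n0 / np.linalg.norm(n0)
    if model == "delta":
        t = np.ones(n)
    elif model == "watson":
        kappa = float(params["kappa"])
        if kappa < 0:
            raise ValueError("kappa must be >= 0")
        t = np.ones(n) if kappa >= 1e6 else _sample_watson_t(kappa, n, rng)
    elif model == "expdecay_family":
        t = _sample_family_t(float(params["C"]), float(params["lam"]), n, rng)
    else:
        raise ValueError(f"unknown FOD model '{model}'")
    sign = rng.choice([-1.0, 1.0], n)        # antipodal symmetry
    t = t * sign
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    vecs = np.column_stack([s * np.cos(phi), s * np.sin(phi), t])
    return _rotate_frame(vecs, n0)


# ---------------------------------------------------------------------------
# Axon construction
# ---------------------------------------------------------------------------

def generate_axon(direction, length: float, undulation: tuple[float, float],
                  beading: tuple[float, float], diameter: float,
                  g_ratio: float, step_dz: float,
                  seed: int | np.random.Generator = 0,
                  origin=(0.0, 0.0, 0.0), axon_id: int = 0) -> AxonGeometry:
    """One axon: straight line along ``direction`` plus a transverse
    sinusoid (amplitude u, wavelength ell, random phase/azimuth), with
    sinusoidal area variation A(z) = A_bar (1 + a sin(2 pi z/ell_b + phi)).
    """
    u, ell = undulation
    a, ell_b = beading
    if a >= 1.0 or a < 0.0:
        raise ValueError("beading amplitude must be in [0, 1)")
    if length < 2.0 * step_dz:
        raise ValueError("length must be >= 2 * step_dz")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal transverse frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    z = np.arange(0.0, length + 0.5 * step_dz, step_dz)
    phase_u = rng.uniform(0.0, 2.0 * np.pi)
    phase_b = rng.uniform(0.0, 2.0 * np.pi)
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    trans = np.cos(azimuth) * e1 + np.sin(azimuth) * e2
    disp = u * np.sin(2.0 * np.pi * z / ell + phase_u)
    pts = (np.asarray(origin, dtype=float)[None, :] + z[:, None] * d[None, :]
           + disp[:, None] * trans[None, :])
    area_bar = np.pi * (diameter / 2.0) ** 2
    area = area_bar * (1.0 + a * np.sin(2.0 * np.pi * z / ell_b + phase_b))
    r_in = np.sqrt(area / np.pi)
    myelin = r_in * (1.0 / g_ratio - 1.0)
    return AxonGeometry(points=pts, area=area, myelin_thickness=myelin,
                        axon_id=axon_id)


def generate_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Generate, clip to the box, and annotate with ground truth.

    One master seed; per-axon streams are spawned deterministically so the
    population is bit-identical across runs for a fixed spec.
    """
    bx, by, bz = spec.box
    directions = sample_directions(spec.fod_model, spec.fod_params,
                                   spec.n_axons, spec.seed,
                                   spec.main_direction)
    # canonical +z representative so axons traverse the box upward
    flip = directions @ np.asarray(spec.main_direction) < 0
    directions[flip] *= -1

    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(spec.n_axons)
    axons: list[AxonGeometry] = []
    for i, (d, ss) in enumerate(zip(directions, streams)):
        rng = np.random.default_rng(ss)
        diam = spec.mean_diameter * np.exp(
            rng.normal(0.0, spec.diameter_sigma)
            - 0.5 * spec.diameter_sigma**2)
        along = abs(float(d @ np.asarray(spec.main_direction)))
        length = min(bz / max(along, 1e-3), 3.0 * bz)
        length = max(length, spec.min_length)
        origin = np.array([rng.uniform(0.0, bx), rng.uniform(0.0, by), 0.0])
        axon = generate_axon(
            d, length,
            (spec.undulation_amplitude, spec.undulation_wavelength),
            (spec.beading_amplitude, spec.beading_wavelength),
            diam, spec.g_ratio, spec.step_dz, seed=rng,
            origin=origin, axon_id=i)
        clipped = _clip_to_box(axon, spec.box)
        if clipped is not None:
            axons.append(clipped)
    pop = SyntheticPopulation(axons=axons, box=spec.box, spec=spec)
    pop.ground_truth = ground_truth(pop)
    return pop


def _clip_to_box(axon: AxonGeometry,
                 box: tuple[float, float, float]) -> AxonGeometry | None:
    """Keep the longest contiguous in-box run of centerline points."""
    inside = np.all((axon.points >= 0.0) & (axon.points <= np.asarray(box)),
                    axis=1)
    if not inside.any():
        return None
    # longest run of True
    idx = np.flatnonzero(np.diff(np.concatenate([[0], inside.view(np.int8),
                                                 [0]])))
    runs = idx.reshape(-1, 2)
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    if stop - start < 4:
        return None
    return AxonGeometry(points=axon.points[start:stop],
                        area=axon.area[start:stop],
                        myelin_thickness=axon.myelin_thickness[start:stop],
                        axon_id=axon.axon_id)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def ground_truth(population: SyntheticPopulation,
                 D0: float = D0_AXOPLASM) -> GroundTruth:
    """Generative-truth record computed from the generated geometry itself
    (tangent finite differences and the generative A(z)), independent of the
    morphometry pipeline under test."""
    if not population.axons:
        raise ValueError("empty population")
    spec = population.spec
    n0 = np.asarray(spec.main_direction, dtype=float)

    all_t, all_w = [], []
    lam_list, cos2u_list, vol_list = [], [], []
    v_intra = v_myelin = 0.0
    for axon in population.axons:
        t = axon.tangents()
        w = axon.segment_lengths()
        all_t.append(t)
        all_w.append(w)
        v_intra += axon.intra_volume()
        v_myelin += axon.myelin_volume()
        # per-axon tortuosity from the generative A(z)
        a_bar = axon.area.mean()
        lam_list.append(float(np.mean(a_bar / axon.area)))
        own = weighted_mean_direction(t, w)
        cos2u_list.append(float(np.sum(w * (t @ own) ** 2) / w.sum()))
        vol_list.append(axon.intra_volume())
    t = np.concatenate(all_t)
    w = np.concatenate(all_w)
    cos2 = float(np.sum(w * (t @ n0) ** 2) / w.sum())
    theta = float(np.degrees(np.arccos(np.sqrt(cos2))))

    box_vol = float(np.prod(population.box))
    if v_myelin >= box_vol:
        raise ValueError("myelin volume exceeds the box volume")
    f = v_intra / (box_vol - v_myelin)

    wk = np.asarray(vol_list) / np.sum(vol_list)
    lam = np.asarray(lam_list)
    c2u = np.asarray(cos2u_list)
    da = float(np.sum(wk * (D0 / lam) * c2u))
    return GroundTruth(theta_deg=theta, f=float(f),
                       mean_tortuosity=float(np.sum(wk * lam)),
                       cos2_undulation=float(np.sum(wk * c2u)),
                       Da_pred=da, fod_model=spec.fod_model,
                       fod_params=dict(spec.fod_params))
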