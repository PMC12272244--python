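"""Readers and writers for the exchange formats.

* Skeleton CSV: columns ``axon_id, point_index, x_um, y_um, z_um, area_um2,
  myelin_thickness_um`` with a header line; points ordered along each axon.
* FSL-style bval/bvec text files: one row of b-values; three rows of
  direction components.  b-values are ms/um^2 internally; files in s/mm^2
  (x1000) are auto-detected by magnitude and converted (logged).
* SH coefficient CSV: columns ``l, m, value`` with a metadata header
  comment stating the basis convention.
* Metric tables: plain CSV via pandas.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fod import SHCoefficients
from .forward import Protocol
from .geometry import AxonGeometry
from .shbasis import lm_pairs
from .synthetic import PopulationSpec

logger = logging.getLogger(__name__)

SKELETON_COLUMNS = ["axon_id", "point_index", "x_um", "y_um", "z_um",
                    "area_um2", "myelin_thickness_um"]

SH_HEADER = ("# real spherical harmonics, orthonormal in dOmega, "
             "Condon-Shortley phase; even l only; rows ordered l ascending, "
             "m from -l to +l; p00 = sqrt(4*pi) for a normalized FOD")


# ---------------------------------------------------------------------------
# Skeleton CSV
# ---------------------------------------------------------------------------

def write_skeletons(axons: list[AxonGeometry], path) -> None:
    rows = []
    for ax in axons:
        for i, (pt, a, mt) in enumerate(zip(ax.points, ax.area,
                                            ax.myelin_thickness)):
            rows.append((ax.axon_id, i, pt[0], pt[1], pt[2], a, mt))
    df = pd.DataFrame(rows, columns=SKELETON_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_skeletons(path) -> list[AxonGeometry]:
    df = pd.read_csv(path)
    missing = [c for c in SKELETON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"skeleton CSV missing columns: {missing}")
    axons = []
    for axon_id, grp in df.groupby("axon_id", sort=True):
        grp = grp.sort_values("point_index")
        axons.append(AxonGeometry(
            points=grp[["x_um", "y_um", "z_um"]].to_numpy(),
            area=grp["area_um2"].to_numpy(),
            myelin_thickness=grp["myelin_thickness_um"].to_numpy(),
            axon_id=int(axon_id)))
    return axons


# ---------------------------------------------------------------------------
# bval / bvec
# ---------------------------------------------------------------------------

def write_bval_bvec(protocol: Protocol, bval_path, bvec_path,
                    si_units: bool = False) -> None:
    """Write FSL-style files; ``si_units`` writes b in s/mm^2 (x1000)."""
    scale = 1000.0 if si_units else 1.0
    np.savetxt(bval_path, (protocol.bvals * scale)[None, :], fmt="%.6g")
    np.savetxt(bvec_path, protocol.bvecs.T, fmt="%.12g")


def read_bval_bvec(bval_path, bvec_path, delta: float = 6.0,
                   Delta: float = 11.5) -> Protocol:
    bvals = np.atleast_1d(np.loadtxt(bval_path)).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvals.max() > 100:            # s/mm^2 convention
        logger.info("b-values look like s/mm^2; converting to ms/um^2")
        bvals = bvals / 1000.0
    nrm = np.linalg.norm(bvecs, axis=1)
    dw = bvals > 0
    bad = dw & (np.abs(nrm - 1.0) > 1e-6)
    if bad.any():
        logger.warning("renormalizing %d non-unit bvecs", int(bad.sum()))
        bvecs[bad] /= nrm[bad, None]
    return Protocol(bvals=bvals, bvecs=bvecs, delta=delta, Delta=Delta)


# ---------------------------------------------------------------------------
# SH coefficients
# ---------------------------------------------------------------------------

def write_sh(coeffs: SHCoefficients, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SH_HEADER + "\n")
        fh.write("l,m,value\n")
        for (l, m), v in zip(lm_pairs(coeffs.lmax), coeffs.values):
            fh.write(f"{l},{m},{v:.15g}\n")


def read_sh(path) -> SHCoefficients:
    df = pd.read_csv(path, comment="#")
    lmax = int(df["l"].max())
    expected = lm_pairs(lmax)
    got = list(zip(df["l"].astype(int), df["m"].astype(int)))
    if got != expected:
        raise ValueError("SH CSV rows not in the declared (l, m) order")
    return SHCoefficients(lmax=lmax, values=df["value"].to_numpy())


# ---------------------------------------------------------------------------
# Configs and tables
# ---------------------------------------------------------------------------

def write_population_spec(spec: PopulationSpec, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in vars(spec).items()}
    Path(path).write_text(json.dumps(d, indent=2))


def read_population_spec(path) -> PopulationSpec:
    d = json.loads(Path(path).read_text())
    for k in ("box", "main_direction"):
        if k in d:
            d[k] = tuple(d[k])
    return PopulationSpec(**d)


def write_metrics_json(metrics: dict, path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, default=float))


def write_signals(values: np.ndarray, path) -> None:
    np.savetxt(path, np.atleast_2d(values), fmt="%.12g", delimiter=",")


def read_signals(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
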