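"""Synthetic surfaces and specimen tables with known ground truth.

Real tooth-row scans of the studied specimens are not publicly
deposited, so the complexity engine and the model-selection machinery
are validated on synthetic twins instead:

* analytic and randomized elevation fields (planes, faceted pyramids,
  circular cones, Gaussian cusp fields) whose orientation-patch
  structure is predictable -- an isolated Gaussian cusp contributes one
  patch per occupied compass octant, giving a tunable OPC ladder;
* specimen tables drawn from the same statistical structure the GLS
  candidate models assume, for parameter-recovery experiments.

The generator defaults for specimen simulation are frozen moments of
the packaged 34-specimen table (predictor means/SDs/correlations, the
body-size distribution, and the best-supported model's coefficients).
Everything is deterministic for a fixed spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .surface_io import GeometryError, HeightMap

__all__ = ["SurfaceSpec", "make_surface", "SimulationParams", "simulate_specimens"]


@dataclass
class SurfaceSpec:
    """Recipe for one synthetic elevation field.

    kind: "plane", "pyramid", "cone" or "cusp_field".  size is
    (rows, cols); spacing is the grid step in mm.  For planes: slope
    (dz per mm) and azimuth_deg (downhill direction, clockwise from the
    +row axis).  For pyramids/cones: n_faces radial faces (pyramid)
    meeting at a central apex, face downhill azimuths at
    azimuth_deg + k * 360/n_faces.  For cusp fields: n_cusps Gaussian
    bumps of width cusp_width_mm and heights in cusp_height_mm placed
    >= 4 widths apart by rejection sampling on a gentle base plane.
    """

    kind: str = "cusp_field"
    n_rows: int = 100
    n_cols: int = 60
    spacing: float = 0.05
    slope: float = 0.5
    azimuth_deg: float = 0.0
    n_faces: int = 4
    n_cusps: int = 5
    cusp_width_mm: float = 0.25
    cusp_height_mm: tuple[float, float] = (0.5, 1.5)
    base_slope: float = 0.02
    seed: int = 0


def _coords(spec: SurfaceSpec):
    north = (np.arange(spec.n_rows) - (spec.n_rows - 1) / 2.0) * spec.spacing
    east = (np.arange(spec.n_cols) - (spec.n_cols - 1) / 2.0) * spec.spacing
    return np.meshgrid(north, east, indexing="ij")


def make_surface(spec: SurfaceSpec) -> HeightMap:
    """Build the elevation field described by ``spec``."""
    N, E = _coords(spec)
    az = np.radians(spec.azimuth_deg)
    if spec.kind == "plane":
        # descends toward azimuth_deg: z decreases along (cos az, sin az)
        z = -spec.slope * (N * np.cos(az) + E * np.sin(az))
    elif spec.kind == "pyramid":
        if spec.n_faces < 3:
            raise GeometryError("a pyramid needs at least 3 faces")
        azs = az + 2.0 * np.pi * np.arange(spec.n_faces) / spec.n_faces
        # each face is a plane descending toward its azimuth; the surface
        # is their lower envelope, an n-faceted pyramid with apex at 0
        proj = np.stack([N * np.cos(a) + E * np.sin(a) for a in azs])
        z = -spec.slope * proj.max(axis=0)
    elif spec.kind == "cone":
        z = -spec.slope * np.hypot(N, E)
    elif spec.kind == "cusp_field":
        z = _cusp_field(spec, N, E)
    else:
        raise ValueError(f"unknown surface kind '{spec.kind}'")
    return HeightMap(values=z, spacing_row=spec.spacing, spacing_col=spec.spacing,
                     mask=np.ones_like(z, dtype=bool))


def _cusp_field(spec: SurfaceSpec, N: np.ndarray, E: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    lo_n, hi_n = N.min(), N.max()
    lo_e, hi_e = E.min(), E.max()
    min_sep = 4.0 * spec.cusp_width_mm
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n_cusps:
        c = (rng.uniform(lo_n, hi_n), rng.uniform(lo_e, hi_e))
        if all(np.hypot(c[0] - a, c[1] - b) >= min_sep for a, b in centers):
            centers.append(c)
        tries += 1
        if tries > 10_000:
            raise GeometryError(
                f"could not place {spec.n_cusps} cusps {min_sep:.3g} mm apart; "
                "reduce the cusp count or width")
    z = spec.base_slope * N  # gentle base plane so no cell is exactly flat
    h_lo, h_hi = spec.cusp_height_mm
    for cn, ce in centers:
        h = rng.uniform(h_lo, h_hi)
        z = z + h * np.exp(-((N - cn) ** 2 + (E - ce) ** 2)
                           / (2.0 * spec.cusp_width_mm ** 2))
    return z


# ---------------------------------------------------------------------------
# specimen-table simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationParams:
    """Generating model for synthetic specimen tables.

    (ln_lower, rt, rd) are multivariate normal with the given moments;
    the response is

        ln_upper = beta0 + beta1*ln_lower + beta_rt*rt + beta_rd*rd + eps

    with eps iid N(0, sigma^2) when rho == 0, else Gaussian-kernel
    correlated over predictor space with range rho.  Body size w is
    lognormal; t and d are back-formed from rt, rd and w so that the
    emitted table matches the packaged specimen schema.  Defaults are
    the packaged table's moments and its best-supported model
    (beta_rd < 0, beta_rt = 0).
    """

    n: int = 34
    beta0: float = 0.89
    beta1: float = 0.79
    beta_rt: float = 0.0
    beta_rd: float = -0.22
    sigma: float = 0.11
    rho: float = 0.0
    pred_means: tuple[float, float, float] = (4.54, -2.90, -2.21)
    pred_sds: tuple[float, float, float] = (0.59, 0.40, 0.36)
    # correlations among (ln_lower, rt), (ln_lower, rd), (rt, rd)
    pred_corr: tuple[float, float, float] = (0.46, -0.02, 0.59)
    ln_w_mean: float = 3.81
    ln_w_sd: float = 0.51
    ln_a_mean: float = 3.29
    ln_a_sd: float = 0.29
    seed: int = 0

    def covariance(self) -> np.ndarray:
        s = np.asarray(self.pred_sds)
        r12, r13, r23 = self.pred_corr
        R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
        cov = R * np.outer(s, s)
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("predictor correlation matrix is not positive definite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        return cov


def simulate_specimens(params: SimulationParams) -> pd.DataFrame:
    """Draw one synthetic specimen table in the packaged-table schema."""
    p = params
    cov = p.covariance()
    rng = np.random.default_rng(p.seed)
    pred = rng.multivariate_normal(np.asarray(p.pred_means), cov, size=p.n,
                                   method="cholesky")
    ln_lower, rt, rd = pred.T
    if p.rho > 0:
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pred))
        C = np.exp(-((D / p.rho) ** 2)) + 1e-10 * np.eye(p.n)
        eps = np.linalg.cholesky(C) @ rng.standard_normal(p.n) * p.sigma
    else:
        eps = rng.standard_normal(p.n) * p.sigma
    ln_upper = p.beta0 + p.beta1 * ln_lower + p.beta_rt * rt + p.beta_rd * rd + eps

    w = np.exp(rng.normal(p.ln_w_mean, p.ln_w_sd, size=p.n))
    a = np.clip(np.exp(rng.normal(p.ln_a_mean, p.ln_a_sd, size=p.n)), 1.0, 89.0)
    t = np.exp(rt) * w
    d = np.exp(rd) * w
    n_upper = rng.integers(1, 5, size=p.n)
    n_lower = rng.integers(1, 5, size=p.n)
    half = p.n // 2
    order = np.where(np.arange(p.n) < half, "Carnivora", "Dasyuromorphia")
    return pd.DataFrame({
        "order_name": order,
        "family": "Synthetica",
        "genus": "Simulotherium",
        "species": [f"sp{i:03d}" for i in range(p.n)],
        "collection": "SIM",
        "number": [f"S{i:04d}" for i in range(p.n)],
        "n_upper_teeth": n_upper,
        "n_lower_teeth": n_lower,
        "upper_opcr": np.exp(ln_upper),
        "lower_opcr": np.exp(ln_lower),
        "t": t, "d": d, "a": a, "w": w,
    })
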