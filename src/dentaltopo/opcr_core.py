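"""Orientation patch count (OPC) and its rotation average (OPCR).

OPC measures the complexity of an occlusal surface as the number of
contiguous patches whose steepest-descent direction (aspect) falls in
the same compass octant.  Low counts characterize faunivores (few
cutting surfaces), high counts herbivores (many grinding facets).  The
raster pipeline is

    HeightMap -> aspect field -> 8-way orientation bins -> connected
    components (patches) -> patch count,

and OPCR averages the count over eight rotations of the bin boundaries
at multiples of 5.625 degrees, removing the dependence on how the
specimen happened to be aligned.  Rotating the bin boundaries is the
exact grid analogue of rotating the specimen about the vertical axis:
a rigid rotation shifts every aspect by the same angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label

from .surface_io import HeightMap, ToothRowGrid, GeometryError

__all__ = [
    "OPCParams",
    "OrientationField",
    "BinnedField",
    "PatchMap",
    "OPCResult",
    "compute_aspect",
    "bin_orientations",
    "find_patches",
    "compute_opc",
    "compute_opcr",
    "average_tooth_opcr",
]


@dataclass
class OPCParams:
    """Tunable knobs of the patch-count pipeline.

    min_patch_size follows the standard OPC lineage default of 3 cells;
    flat_eps=None means the automatic scale-aware threshold
    1e-6 * (elevation range / mean grid spacing).
    """

    n_bins: int = 8
    connectivity: int = 4  # 4 = edge adjacency, 8 adds diagonals
    min_patch_size: int = 3
    flat_eps: float | None = None


@dataclass
class OrientationField:
    """Per-cell aspect: azimuth of steepest descent, degrees clockwise
    from grid north (+row direction).  Cells flatter than flat_eps or
    touching masked/border cells are undefined."""

    aspect: np.ndarray  # degrees in [0, 360), NaN where undefined
    defined_mask: np.ndarray  # True where aspect defined


@dataclass
class BinnedField:
    bin_index: np.ndarray  # int in 0..n_bins-1, -1 undefined
    n_bins: int = 8
    offset_deg: float = 0.0


@dataclass
class PatchMap:
    labels: np.ndarray  # int patch id, 0 = no patch
    patch_sizes: dict[int, int] = field(default_factory=dict)
    patch_bins: dict[int, int] = field(default_factory=dict)

    @property
    def n_patches(self) -> int:
        return len(self.patch_sizes)


@dataclass
class OPCResult:
    opc_per_rotation: list[int]
    opcr: float
    n_rotations: int = 8
    step_deg: float = 5.625

    def __post_init__(self) -> None:
        assert len(self.opc_per_rotation) == self.n_rotations


def compute_aspect(hm: HeightMap, flat_eps: float | None = None) -> OrientationField:
    """Central-difference aspect of each interior cell.

    Aspect is the azimuth of -grad z in degrees clockwise from grid
    north (+row axis).  Cells whose gradient magnitude is below
    ``flat_eps`` (mm elevation per mm distance), or any of whose four
    neighbours is masked or off-grid, are undefined.
    """
    if hm.n_valid() == 0:
        raise GeometryError("all cells masked: cannot compute aspect")
    z = np.where(hm.mask, hm.values, 0.0)
    m = hm.mask
    nr, nc = hm.shape
    defined = np.zeros((nr, nc), dtype=bool)
    defined[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[2:, 1:-1] & m[:-2, 1:-1] & m[1:-1, 2:] & m[1:-1, :-2]
    )
    dz_n = np.zeros((nr, nc))
    dz_e = np.zeros((nr, nc))
    dz_n[1:-1, :] = (z[2:, :] - z[:-2, :]) / (2.0 * hm.spacing_row)
    dz_e[:, 1:-1] = (z[:, 2:] - z[:, :-2]) / (2.0 * hm.spacing_col)
    grad = np.hypot(dz_n, dz_e)
    if flat_eps is None:
        valid = hm.values[m]
        zrange = float(valid.max() - valid.min()) if valid.size else 0.0
        mean_spacing = 0.5 * (hm.spacing_row + hm.spacing_col)
        flat_eps = 1e-6 * zrange / mean_spacing
    defined &= grad >= max(flat_eps, np.finfo(float).tiny)
    aspect = np.degrees(np.arctan2(-dz_e, -dz_n)) % 360.0
    aspect = np.where(defined, aspect, np.nan)
    return OrientationField(aspect=aspect, defined_mask=defined)


def bin_orientations(of: OrientationField, n_bins: int = 8,
                     offset_deg: float = 0.0) -> BinnedField:
    """Assign aspects to n_bins half-open compass sectors.

    Bin k covers [k*width - width/2 + offset, k*width + width/2 + offset)
    modulo 360, i.e. bins are centred on the compass directions when
    offset is 0; a boundary aspect belongs to the higher bin.
    """
    if 360 % n_bins != 0:
        raise ValueError("n_bins must divide 360")
    width = 360.0 / n_bins
    with np.errstate(invalid="ignore"):
        idx = np.floor(((of.aspect - offset_deg + width / 2.0) % 360.0) / width)
    idx = np.nan_to_num(idx, nan=0.0).astype(int) % n_bins
    idx = np.where(of.defined_mask, idx, -1)
    return BinnedField(bin_index=idx, n_bins=n_bins, offset_deg=offset_deg)


def find_patches(bf: BinnedField, connectivity: int = 4,
                 min_patch_size: int = 3) -> PatchMap:
    """Connected components of equal-bin cells; small components dropped.

    Components smaller than ``min_patch_size`` cells get label 0 and do
    not count as patches.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skconn = 1 if connectivity == 4 else 2
    # skimage labels connected regions of equal value; shift bins so that
    # the undefined value (-1 -> 0) becomes background.
    labels = _cc_label(bf.bin_index + 1, background=0, connectivity=skconn)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_patch_size]
    relabel = np.zeros(labels.max() + 1, dtype=int)
    relabel[keep] = np.arange(1, len(keep) + 1)
    out = relabel[labels]
    sizes = {}
    bins = {}
    for new_id, old_id, size in zip(relabel[keep], keep, counts[np.isin(ids, keep)]):
        sizes[int(new_id)] = int(size)
        cell = np.argwhere(labels == old_id)[0]
        bins[int(new_id)] = int(bf.bin_index[cell[0], cell[1]])
    return PatchMap(labels=out, patch_sizes=sizes, patch_bins=bins)


def compute_opc(trg: ToothRowGrid, offset_deg: float = 0.0,
                params: OPCParams | None = None) -> int:
    """Orientation patch count of a standardized tooth row at one bin offset."""
    p = params or OPCParams()
    of = compute_aspect(trg.heightmap, flat_eps=p.flat_eps)
    bf = bin_orientations(of, n_bins=p.n_bins, offset_deg=offset_deg)
    pm = find_patches(bf, connectivity=p.connectivity, min_patch_size=p.min_patch_size)
    return pm.n_patches


def compute_opcr(trg: ToothRowGrid, n_rotations: int = 8, step_deg: float = 5.625,
                 params: OPCParams | None = None) -> OPCResult:
    """OPC averaged over ``n_rotations`` bin-boundary rotations of
    ``step_deg`` degrees (default 8 x 5.625, spanning one bin width)."""
    counts = [compute_opc(trg, offset_deg=k * step_deg, params=params)
              for k in range(n_rotations)]
    return OPCResult(opc_per_rotation=counts, opcr=float(np.mean(counts)),
                     n_rotations=n_rotations, step_deg=step_deg)


def average_tooth_opcr(row_opcr: float, n_teeth: int) -> float:
    """Tooth-row OPCR divided by the number of teeth in the row.

    The natural-log transform used in the comparative statistics is
    applied downstream, not here.
    """
    if n_teeth < 1:
        raise ValueError("n_teeth must be >= 1")
    return row_opcr / n_teeth
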