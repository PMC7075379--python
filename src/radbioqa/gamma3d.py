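"""3D gamma-index comparison of a reference and an evaluated dose grid.

For every reference point the gamma index is

    gamma(r) = min over r' of sqrt( |r' - r|^2 / dta^2  +
                                    (D_eval(r') - D_ref(r))^2 / dD^2 )

with ``dta`` the distance-to-agreement criterion (mm) and ``dD`` the dose
criterion, a percentage of the normalization dose.  A point passes when
gamma <= 1; the pass rate over the evaluated mask is the headline QA
number, reported alongside the arithmetic mean and median gamma.

Note on naming: the *gamma index* of dose comparison is unrelated to the
dose-response slope parameter; the latter is called ``gamma_slope``
throughout this package (:mod:`radbioqa.rb_core`).

The minimisation is an exhaustive search of the evaluated distribution,
trilinearly interpolated at ``interp_step_mm`` within ``search_radius_mm``
of each reference point.  Offsets are visited in order of increasing
distance with an active-set early exit: once ``|r'-r|/dta`` alone exceeds a
point's current best gamma, no farther offset can improve it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .rb_core import ValidationError

__all__ = [
    "DoseGrid",
    "GammaCriteria",
    "GammaSummary",
    "gamma_map",
    "pass_rate",
    "gamma_summary",
    "load_dose_grid",
    "save_dose_grid",
]


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D voxel grid of absolute dose.

    ``values`` is indexed ``[iz, iy, ix]`` (z slowest); ``spacing`` is
    ``(dx, dy, dz)`` in mm and ``origin`` ``(x0, y0, z0)`` in mm is the
    physical position of voxel ``[0, 0, 0]``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValidationError("dose grid must be 3-D (z, y, x)")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("dose values must be finite and non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError("spacing must be three positive lengths (mm)")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def point_coordinates(self):
        """Physical (x, y, z) mm coordinates of every voxel, each shaped like
        ``values``."""
        nz, ny, nx = self.values.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        z, y, x = np.meshgrid(
            z0 + np.arange(nz) * dz,
            y0 + np.arange(ny) * dy,
            x0 + np.arange(nx) * dx,
            indexing="ij",
        )
        return x, y, z


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria and search controls.

    ``dose_pct``/``dta_mm`` are the headline criteria (e.g. 3%/3 mm).  The
    dose criterion is ``dose_pct`` percent of a normalization dose:
    ``norm_fraction`` x max reference dose under ``global_fraction_of_max``
    (default 0.9, i.e. "percent of 90% of the maximum dose"), a fixed
    ``norm_dose_gy`` under ``global_fixed``, or the local reference dose
    under ``local``.  Points below ``low_dose_threshold_pct`` percent of the
    normalization dose are excluded from evaluation (default 0: all points).
    """

    dose_pct: float
    dta_mm: float
    normalization: str = "global_fraction_of_max"
    norm_fraction: float = 0.9
    norm_dose_gy: float | None = None
    low_dose_threshold_pct: float = 0.0
    search_radius_mm: float | None = None  # default 3 x dta
    interp_step_mm: float | None = None    # default dta / 10

    def __post_init__(self) -> None:
        if not (self.dose_pct > 0 and self.dta_mm > 0):
            raise ValidationError("dose_pct and dta_mm must be positive")
        if not (0 < self.norm_fraction <= 1):
            raise ValidationError("norm_fraction must lie in (0, 1]")
        if self.normalization not in ("global_fraction_of_max", "global_fixed", "local"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "global_fixed" and not self.norm_dose_gy:
            raise ValidationError("global_fixed normalization requires norm_dose_gy")

    @property
    def radius(self) -> float:
        return self.search_radius_mm if self.search_radius_mm is not None else 3.0 * self.dta_mm

    @property
    def step(self) -> float:
        return self.interp_step_mm if self.interp_step_mm is not None else self.dta_mm / 10.0


@dataclass(frozen=True)
class GammaSummary:
    """Pass rate and distribution summary of a gamma map over its mask."""

    pass_rate_pct: float
    mean_gamma: float
    median_gamma: float
    min_gamma: float
    max_gamma: float
    n_evaluated: int


def _normalization_dose(reference: DoseGrid, criteria: GammaCriteria) -> float:
    if criteria.normalization == "global_fixed":
        return float(criteria.norm_dose_gy)
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise ValidationError("reference grid is all zero; normalization dose undefined")
    if criteria.normalization == "global_fraction_of_max":
        return criteria.norm_fraction * ref_max
    return ref_max  # local: only used for the low-dose threshold


def _offsets(criteria: GammaCriteria) -> np.ndarray:
    """Search offsets (mm, columns x/y/z) sorted by distance from zero."""
    step, radius = criteria.step, criteria.radius
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    r2 = np.einsum("ij,ij->i", offs, offs)
    keep = r2 <= radius**2 + 1e-9
    offs, r2 = offs[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return offs[order]


def _to_index_coords(x, y, z, grid: DoseGrid):
    dx, dy, dz = grid.spacing
    x0, y0, z0 = grid.origin
    return np.array([(z - z0) / dz, (y - y0) / dy, (x - x0) / dx])


def gamma_map(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the gamma index at every reference voxel.

    Returns ``(gamma, mask)`` where ``gamma`` has the reference shape and
    ``mask`` marks the points actually evaluated (above the low-dose
    threshold and covered by the evaluated grid).  If the two grids share
    no physical region, a :class:`ValidationError` is raised.  The search
    is capped at ``criteria.radius``; a point whose true minimum lies
    farther away reports the best value found within the cap (necessarily
    > radius/dta, i.e. already a clear failure).
    """
    norm_dose = _normalization_dose(reference, criteria)
    ref_vals = reference.values
    mask = np.ones(ref_vals.shape, dtype=bool)
    if criteria.low_dose_threshold_pct > 0:
        mask &= ref_vals >= criteria.low_dose_threshold_pct / 100.0 * norm_dose
    if not mask.any():
        raise ValidationError("low-dose threshold excluded every reference point")

    x, y, z = reference.point_coordinates()
    px, py, pz = x[mask], y[mask], z[mask]
    ref_d = ref_vals[mask]

    if criteria.normalization == "local":
        with np.errstate(divide="ignore"):
            dcrit = criteria.dose_pct / 100.0 * ref_d
    else:
        dcrit = np.full_like(ref_d, criteria.dose_pct / 100.0 * norm_dose)

    dta2 = criteria.dta_mm**2
    n_pts = ref_d.size
    gamma2 = np.full(n_pts, np.inf)
    seen_valid = np.zeros(n_pts, dtype=bool)

    for off in _offsets(criteria):
        r2n = (off @ off) / dta2
        active = gamma2 > r2n
        if not active.any():
            break
        coords = _to_index_coords(
            px[active] + off[0], py[active] + off[1], pz[active] + off[2], evaluated
        )
        ev = map_coordinates(
            evaluated.values, coords, order=1, mode="constant", cval=np.nan
        )
        valid = np.isfinite(ev)
        if not valid.any():
            continue
        dd = ev[valid] - ref_d[active][valid]
        dc = dcrit[active][valid]
        with np.errstate(divide="ignore", invalid="ignore"):
            dose_term = np.where(
                dc > 0, (dd / np.where(dc > 0, dc, 1.0)) ** 2,
                np.where(dd == 0, 0.0, np.inf),
            )
        g2 = r2n + dose_term
        idx = np.flatnonzero(active)[valid]
        np.minimum.at(gamma2, idx, g2)
        seen_valid[idx] = True

    if not seen_valid.any():
        raise ValidationError("reference and evaluated grids do not overlap")

    gamma = np.full(ref_vals.shape, np.nan)
    flat_mask = np.zeros(ref_vals.shape, dtype=bool)
    midx = np.argwhere(mask)
    covered = seen_valid
    gamma[tuple(midx[covered].T)] = np.sqrt(gamma2[covered])
    flat_mask[tuple(midx[covered].T)] = True
    return gamma, flat_mask


def pass_rate(gamma_grid: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of evaluated points with gamma <= 1."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty evaluation mask")
    g = np.asarray(gamma_grid)[mask]
    return 100.0 * np.count_nonzero(g <= 1.0) / g.size


def gamma_summary(gamma_grid: np.ndarray, mask: np.ndarray) -> GammaSummary:
    """Pass rate plus mean/median/min/max of gamma over the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty evaluation mask")
    g = np.asarray(gamma_grid)[mask]
    return GammaSummary(
        pass_rate_pct=100.0 * np.count_nonzero(g <= 1.0) / g.size,
        mean_gamma=float(np.mean(g)),
        median_gamma=float(np.median(g)),
        min_gamma=float(np.min(g)),
        max_gamma=float(np.max(g)),
        n_evaluated=int(g.size),
    )


# ---------------------------------------------------------------------------
# grid I/O
# ---------------------------------------------------------------------------

def load_dose_grid(path) -> DoseGrid:
    """Load a dose grid from DICOM RT Dose (.dcm), NPZ, or CSV+JSON sidecar.

    The CSV format stores the flattened values with a ``<name>.json``
    sidecar holding ``shape``, ``spacing`` and ``origin``; NPZ stores the
    same three arrays.  DICOM honours DoseGridScaling, PixelSpacing,
    GridFrameOffsetVector and ImagePositionPatient (axial, identity
    orientation assumed).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcm":
        return _load_dicom(path)
    if suffix == ".npz":
        with np.load(path) as npz:
            return DoseGrid(npz["values"], tuple(npz["spacing"]), tuple(npz["origin"]))
    if suffix == ".csv":
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        values = np.loadtxt(path, delimiter=",").reshape(meta["shape"])
        return DoseGrid(values, tuple(meta["spacing"]), tuple(meta.get("origin", (0, 0, 0))))
    raise ValidationError(f"unsupported dose grid format {path.suffix!r}")


def save_dose_grid(grid: DoseGrid, path) -> None:
    """Write NPZ or CSV+JSON sidecar, matching :func:`load_dose_grid`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        np.savez(path, values=grid.values, spacing=grid.spacing, origin=grid.origin)
    elif suffix == ".csv":
        np.savetxt(path, grid.values.reshape(grid.shape[0], -1), delimiter=",")
        path.with_suffix(".json").write_text(
            json.dumps(
                {"shape": grid.shape, "spacing": grid.spacing, "origin": grid.origin}
            )
        )
    else:
        raise ValidationError(f"unsupported dose grid format {path.suffix!r}")


def _load_dicom(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(path)
    values = ds.pixel_array.astype(float) * float(getattr(ds, "DoseGridScaling", 1.0))
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz_steps = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz_steps, dz_steps[0]):
        raise ValidationError("non-uniform slice spacing in RT Dose grid")
    dz = float(dz_steps[0]) if offsets.size > 1 else 1.0
    x0, y0, z0 = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, (dx, dy, abs(dz)), (x0, y0, z0 + float(offsets[0])))
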