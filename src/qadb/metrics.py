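"""Verification statistics: mean dose difference and the 3D gamma index.

The mean dose difference is

    %Δ = 100 × (D_indep − D_tps) / D_ref

where D_indep and D_tps are the mean target doses from the independent
recalculation and the local planning system, and D_ref is the maximum
point dose in the treatment plan. Positive values mean the independent
calculation is higher.

The gamma index compares two dose grids voxel by voxel: for each reference
voxel, gamma is the minimum over nearby evaluated voxels of

    sqrt(Δr²/dta² + ΔD²/ΔD_crit²)

with Δr the spatial separation, dta the distance-to-agreement criterion
and ΔD_crit the dose criterion. With *global* normalisation ΔD_crit is a
percentage of the reference-grid maximum; with *local* normalisation it is
the same percentage of each reference voxel's own dose. A voxel passes
when gamma ≤ 1. Reference voxels below a low-dose threshold (percent of
the reference maximum) are excluded from the passing rate.

Version-1 scope: both grids must share geometry (shape, spacing, origin);
the search visits evaluated voxel centres within ``search_radius_factor ×
dta_mm`` without sub-voxel interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MeanDoseInputs",
    "DoseGrid",
    "GammaCriteria",
    "mean_dose_difference",
    "gamma_map",
    "gamma_pass_rate",
    "load_dose_grid",
    "save_dose_grid",
]


@dataclass(frozen=True)
class MeanDoseInputs:
    """Mean target doses (Gy) entering the mean-dose-difference statistic.

    d_m3d : mean target dose from the independent calculation
    d_tps : mean target dose from the local planning system
    d_ref : maximum point dose in the treatment plan (normaliser)
    """

    d_m3d: float
    d_tps: float
    d_ref: float

    def __post_init__(self) -> None:
        for name in ("d_m3d", "d_tps", "d_ref"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.d_ref <= 0:
            raise ValueError("d_ref must be positive (normalisation undefined)")


def mean_dose_difference(inputs: MeanDoseInputs) -> float:
    """Mean dose difference in percent: 100 × (d_m3d − d_tps) / d_ref."""
    return 100.0 * (inputs.d_m3d - inputs.d_tps) / inputs.d_ref


@dataclass(frozen=True)
class DoseGrid:
    """A 3D dose array with regular geometry, axis order (z, y, x).

    ``spacing`` is the per-axis voxel size in mm and ``origin`` the
    position of the first voxel centre in mm, both in (z, y, x) order.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if values.ndim != 3 or values.size == 0:
            raise ValueError("dose grid must be a non-empty 3D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def same_geometry(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison criteria; defaults give the global (3%, 3 mm) test.

    dose_pct      : dose-difference criterion, percent
    dta_mm        : distance-to-agreement criterion, mm
    threshold_pct : low-dose cutoff as percent of the reference maximum
    normalization : 'global' (percent of reference max) or 'local'
    search_radius_factor : search extent as a multiple of dta_mm
    """

    dose_pct: float = 3.0
    dta_mm: float = 3.0
    threshold_pct: float = 10.0
    normalization: str = "global"
    search_radius_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dose_pct <= 0:
            raise ValueError("dose_pct must be positive")
        if self.dta_mm <= 0:
            raise ValueError("dta_mm must be positive")
        if not (0.0 <= self.threshold_pct < 100.0):
            raise ValueError("threshold_pct must lie in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if self.search_radius_factor <= 0:
            raise ValueError("search_radius_factor must be positive")


def _search_offsets(
    spacing: tuple[float, float, float], radius_mm: float
) -> list[tuple[float, tuple[int, int, int]]]:
    """Voxel offsets within the search sphere, sorted by physical distance."""
    max_vox = [int(math.floor(radius_mm / s)) for s in spacing]
    offsets = []
    for dz in range(-max_vox[0], max_vox[0] + 1):
        for dy in range(-max_vox[1], max_vox[1] + 1):
            for dx in range(-max_vox[2], max_vox[2] + 1):
                d = math.sqrt(
                    (dz * spacing[0]) ** 2
                    + (dy * spacing[1]) ** 2
                    + (dx * spacing[2]) ** 2
                )
                if d <= radius_mm:
                    offsets.append((d, (dz, dy, dx)))
    offsets.sort(key=lambda t: t[0])
    return offsets


def _overlap_slices(shape, offset):
    """Slices of the reference and the shifted evaluated array that overlap."""
    ref_sl, ev_sl = [], []
    for n, d in zip(shape, offset):
        ref_sl.append(slice(max(0, -d), min(n, n - d)))
        ev_sl.append(slice(max(0, d), min(n, n + d)))
    return tuple(ref_sl), tuple(ev_sl)


def gamma_map(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria
) -> np.ndarray:
    """Voxel-wise gamma of ``evaluated`` against ``reference``.

    Returns an array of the reference shape with the gamma value at each
    included voxel and NaN at voxels below the low-dose threshold. The
    minimisation visits evaluated voxel centres inside a sphere of radius
    ``search_radius_factor × dta_mm``; offsets are scanned in order of
    increasing distance so the search can stop once the pure-distance term
    alone exceeds every running minimum.
    """
    if not reference.same_geometry(evaluated):
        raise ValueError("reference and evaluated grids must share geometry")
    ref = reference.values
    ev = evaluated.values
    ref_max = float(ref.max())
    if ref_max <= 0:
        raise ValueError("all-zero reference grid: normalisation undefined")

    if criteria.normalization == "global":
        dcrit = criteria.dose_pct / 100.0 * ref_max
        dcrit_arr = None
    else:
        dcrit_arr = criteria.dose_pct / 100.0 * ref
        dcrit = None

    included = ref >= criteria.threshold_pct / 100.0 * ref_max
    radius = criteria.search_radius_factor * criteria.dta_mm
    gamma2 = np.full(ref.shape, np.inf)

    for dist, offset in _search_offsets(reference.spacing, radius):
        dist_term = (dist / criteria.dta_mm) ** 2
        worst = gamma2[included].max() if included.any() else 0.0
        if dist_term >= worst:
            break
        ref_sl, ev_sl = _overlap_slices(ref.shape, offset)
        dd = ev[ev_sl] - ref[ref_sl]
        if dcrit_arr is None:
            dose_term = (dd / dcrit) ** 2
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                dose_term = (dd / dcrit_arr[ref_sl]) ** 2
            # zero-dose reference voxel: exact agreement passes, else infinite
            dose_term = np.nan_to_num(dose_term, nan=0.0, posinf=np.inf)
        np.minimum(gamma2[ref_sl], dist_term + dose_term, out=gamma2[ref_sl])

    gamma = np.sqrt(gamma2)
    gamma[~included] = np.nan
    return gamma


def gamma_pass_rate(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria
) -> float:
    """Percent of included voxels with gamma ≤ 1, in [0, 100]."""
    gm = gamma_map(reference, evaluated, criteria)
    finite = np.isfinite(gm)
    n_included = int(finite.sum())
    if n_included == 0:
        raise ValueError("no voxels above the low-dose threshold")
    return 100.0 * float((gm[finite] <= 1.0).sum()) / n_included


# ---------------------------------------------------------------------------
# Grid I/O: a flat float32 binary with a JSON geometry header, plus optional
# DICOM RTDOSE ingestion via pydicom.

def save_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid as `<path>.json` (geometry) + `<path>.raw` (float32 C-order)."""
    path = Path(path)
    header = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "dtype": "float32",
        "order": "C",
        "axes": "zyx",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    grid.values.astype(np.float32).tofile(path.with_suffix(".raw"))


def _load_flat(path: Path) -> DoseGrid:
    header = json.loads(path.with_suffix(".json").read_text())
    values = np.fromfile(path.with_suffix(".raw"), dtype=np.float32)
    values = values.reshape(header["shape"]).astype(float)
    return DoseGrid(
        values=values,
        spacing=tuple(header["spacing_mm"]),
        origin=tuple(header["origin_mm"]),
    )


def _load_rtdose(path: Path) -> DoseGrid:
    import pydicom  # optional dependency

    ds = pydicom.dcmread(str(path))
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(np.diff(offsets).mean()) if offsets.size > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    ox, oy, oz = (float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values=values, spacing=(abs(dz), dy, dx), origin=(oz, oy, ox))


def load_dose_grid(path: str | Path) -> DoseGrid:
    """Load a dose grid from `.dcm` (RTDOSE) or the flat `.json`/`.raw` pair."""
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        return _load_rtdose(path)
    return _load_flat(path)
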