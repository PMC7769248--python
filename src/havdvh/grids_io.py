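"""Voxel-grid data model and imaging I/O.

One canonical container (:class:`ImageVolume`) carries every 3-D scalar
grid in the pipeline — CT in Hounsfield units, dose in Gy — together with
its physical geometry.  The frame is DICOM patient coordinates (LPS) with
axis-aligned grids: the physical position of voxel ``(i, j, k)`` is
``origin + (i*sx, j*sy, k*sz)`` and ``origin`` is the *center* of voxel
``(0, 0, 0)``.  Arrays are indexed ``(x, y, z)``.

Masks live on the geometry of a reference volume; structures arrive either
as binary NRRD volumes or as planar contour polygons (RTSTRUCT-style) that
are rasterized with a voxel-center even-odd rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "ContourSet",
    "GridIOError",
    "read_ct_series",
    "read_rtdose",
    "read_rtstruct_contours",
    "read_nrrd",
    "write_nrrd",
    "rasterize_contours",
    "resample_dose_to_ct",
]


class GridIOError(ValueError):
    """Raised for malformed or inconsistent imaging inputs."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU or Gy) with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples at voxel centers.
    spacing : (3,) float
        Per-axis voxel size in mm; all components > 0.
    origin : (3,) float
        Physical position (mm, LPS) of the center of voxel (0, 0, 0).
    axes : str
        Direction-convention identifier; only axis-aligned "LPS" is used.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: str = "LPS"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GridIOError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise GridIOError("each axis needs at least one voxel")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GridIOError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis (mm)."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_geometry(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask:
    """Boolean voxel set on the geometry of a reference :class:`ImageVolume`."""

    values: np.ndarray
    reference: ImageVolume

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.reference.shape:
            raise GridIOError(
                f"mask shape {self.values.shape} != reference {self.reference.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.reference.voxel_volume_mm3


@dataclass
class ContourSet:
    """Closed planar polygons in patient coordinates, grouped by slice.

    ``slices`` maps slice z-position (mm) to a list of polygons; each
    polygon is an (n, 2) array of (x, y) vertices, n >= 3.  All polygons
    of one entry are coplanar by construction.
    """

    name: str
    slices: dict[float, list[np.ndarray]]

    def __post_init__(self) -> None:
        for z, polys in self.slices.items():
            for p in polys:
                if np.asarray(p).shape[0] < 3:
                    raise GridIOError(
                        f"polygon on slice z={z} has fewer than 3 vertices"
                    )


# ---------------------------------------------------------------------------
# DICOM readers


def _check_axis_aligned(ds) -> None:
    """Only the identity orientation is supported; reject oblique grids."""
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is not None and not np.allclose(
            [float(v) for v in iop], [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise GridIOError(f"oblique ImageOrientationPatient {list(iop)} "
                          "is not supported (axis-aligned LPS only)")


def read_ct_series(directory_path: str | Path) -> ImageVolume:
    """Read one DICOM CT series from a directory into HU.

    Slices are sorted by position along the slice normal; pixel data are
    rescaled with slope/intercept.  Fails on mixed series, non-CT
    modality, or a non-uniform slice gap (> 1% deviation), naming the gap.
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except (pydicom.errors.InvalidDicomError, Exception):
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise GridIOError(f"no DICOM image slices found in {directory_path}")

    modalities = {getattr(ds, "Modality", "?") for ds in datasets}
    if modalities != {"CT"}:
        raise GridIOError(f"expected a CT series, found modalities {sorted(modalities)}")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise GridIOError(f"mixed series in directory: {len(uids)} SeriesInstanceUIDs")

    _check_axis_aligned(datasets[0])
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0):
            raise GridIOError("duplicate or non-monotone slice positions")
        ref = np.median(gaps)
        bad = np.nonzero(np.abs(gaps - ref) > 0.01 * ref)[0]
        if bad.size:
            z0, z1 = zs[bad[0]], zs[bad[0] + 1]
            raise GridIOError(
                f"non-uniform slice spacing: gap of {z1 - z0:.3f} mm between "
                f"z={z0:.3f} and z={z1:.3f} (expected {ref:.3f} mm) — missing slice?"
            )
        dz = float(ref)
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    vol = np.empty((cols, rows, len(datasets)), dtype=np.float64)
    for k, ds in enumerate(datasets):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        vol[:, :, k] = ds.pixel_array.T.astype(np.float64) * slope + intercept

    dy, dx = (float(v) for v in first.PixelSpacing)  # PixelSpacing is (row, col)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return ImageVolume(vol, spacing=(dx, dy, dz), origin=origin)


def read_rtdose(file_path: str | Path) -> ImageVolume:
    """Read a DICOM RTDOSE grid into absolute dose (Gy)."""
    ds = pydicom.dcmread(str(file_path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise GridIOError(f"not an RTDOSE object: modality={getattr(ds, 'Modality', '?')}")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise GridIOError("RTDOSE is missing DoseGridScaling")
    summation = getattr(ds, "DoseSummationType", "PLAN")
    if summation not in ("PLAN", "FRACTION"):
        raise GridIOError(f"unsupported DoseSummationType {summation!r}")

    _check_axis_aligned(ds)
    raw = ds.pixel_array.astype(np.float64) * float(scaling)  # (frame, row, col)
    vol = np.transpose(raw, (2, 1, 0))  # -> (x, y, z)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        dz_all = np.diff(offsets)
        if not np.allclose(dz_all, dz_all[0]):
            raise GridIOError("non-uniform GridFrameOffsetVector")
        dz = float(dz_all[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0))
    pos = np.asarray([float(v) for v in ds.ImagePositionPatient])
    origin = (pos[0], pos[1], pos[2] + offsets[0])
    return ImageVolume(vol, spacing=(dx, dy, dz), origin=origin)


def read_rtstruct_contours(file_path: str | Path, structure_name: str) -> ContourSet:
    """Extract one structure's planar contours from a DICOM RTSTRUCT.

    ``structure_name`` is matched case-insensitively against ROI names.
    """
    ds = pydicom.dcmread(str(file_path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise GridIOError("not an RTSTRUCT object")
    wanted = structure_name.strip().lower()
    number = None
    for roi in ds.StructureSetROISequence:
        if str(roi.ROIName).strip().lower() == wanted:
            number = roi.ROINumber
            break
    if number is None:
        names = [str(r.ROIName) for r in ds.StructureSetROISequence]
        raise GridIOError(f"structure {structure_name!r} not found; available: {names}")
    slices: dict[float, list[np.ndarray]] = {}
    for rc in ds.ROIContourSequence:
        if rc.ReferencedROINumber != number:
            continue
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            z = float(np.round(pts[:, 2].mean(), 6))
            slices.setdefault(z, []).append(pts[:, :2])
    return ContourSet(name=structure_name, slices=slices)


# ---------------------------------------------------------------------------
# NRRD (single-file volumes) — accepted everywhere DICOM is


def read_nrrd(file_path: str | Path) -> ImageVolume:
    """Read an axis-aligned NRRD volume (geometry in LPS)."""
    img = sitk.ReadImage(str(file_path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    vol = np.transpose(arr, (2, 1, 0)).astype(np.float64)
    return ImageVolume(vol, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_nrrd(
    volume: ImageVolume | BinaryMask,
    file_path: str | Path,
    sidecar: bool = False,
) -> None:
    """Write a volume or mask as NRRD; optionally a JSON geometry sidecar."""
    if isinstance(volume, BinaryMask):
        arr = volume.values.astype(np.uint8)
        geom = volume.reference
    else:
        arr = volume.values
        geom = volume
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
    img.SetSpacing(geom.spacing)
    img.SetOrigin(geom.origin)
    sitk.WriteImage(img, str(file_path))
    if sidecar:
        side = Path(str(file_path)).with_suffix(".geom.json")
        side.write_text(
            json.dumps(
                {"shape": list(arr.shape), "spacing": list(geom.spacing),
                 "origin": list(geom.origin), "axes": geom.axes},
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# Contour rasterization


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray,
                       edge_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Even-odd crossing test plus an on-edge indicator for many points.

    Returns ``(inside, on_edge)`` boolean arrays.  The crossing test uses
    the half-open convention (count an edge when one endpoint is strictly
    above and the other at-or-below the ray), which handles vertices
    touching the ray exactly once.
    """
    poly = np.asarray(poly, dtype=float)
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)

    px = px[:, None]
    py = py[:, None]
    cond = (y0[None, :] > py) != (y1[None, :] > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = x0 + (py - y0) * (x1 - x0) / np.where(y1 == y0, np.inf, y1 - y0)
    crossings = np.sum(cond & (px < x_int), axis=1)
    inside = (crossings % 2) == 1

    # distance from each point to each segment, for the tie rule
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    t = np.clip(((px - x0) * dx + (py - y0) * dy) / np.where(seg2 == 0, 1, seg2), 0, 1)
    d2 = (px - (x0 + t * dx)) ** 2 + (py - (y0 + t * dy)) ** 2
    on_edge = np.any(d2 <= edge_tol * edge_tol, axis=1)
    return inside, on_edge


def rasterize_contours(contours: ContourSet, geometry: ImageVolume) -> BinaryMask:
    """Rasterize planar contours onto a grid with the voxel-center rule.

    A voxel belongs to the structure iff its center lies inside an odd
    number of that slice's polygons (even-odd rule, so inner polygons cut
    holes), with centers exactly on a polygon edge counted inside.
    Contour slices must land within half a slice thickness of a grid
    slice; orphans raise an error listing their positions.
    """
    zc = geometry.voxel_centers(2)
    dz = geometry.spacing[2]
    xs = geometry.voxel_centers(0)
    ys = geometry.voxel_centers(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat_x, flat_y = gx.ravel(), gy.ravel()
    edge_tol = 1e-9 * max(1.0, float(np.max(np.abs([xs.max(), ys.max(), 1.0]))))

    mask = np.zeros(geometry.shape, dtype=bool)
    orphans = []
    for z, polys in contours.slices.items():
        k = int(np.argmin(np.abs(zc - z)))
        if abs(zc[k] - z) > dz / 2 + 1e-9:
            orphans.append(z)
            continue
        parity = np.zeros(flat_x.shape, dtype=bool)
        edge_any = np.zeros(flat_x.shape, dtype=bool)
        for poly in polys:
            inside, on_edge = _points_in_polygon(flat_x, flat_y, poly, edge_tol)
            parity ^= inside
            edge_any |= on_edge
        mask[:, :, k] |= (parity | edge_any).reshape(gx.shape)
    if orphans:
        raise GridIOError(
            f"contour slices with no matching grid slice at z={sorted(orphans)} "
            f"(grid z range {zc[0]:.3f}..{zc[-1]:.3f}, dz={dz})"
        )
    return BinaryMask(mask, reference=geometry)


# ---------------------------------------------------------------------------
# Dose resampling


def resample_dose_to_ct(dose: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Trilinearly resample a dose grid onto the target (CT) geometry.

    Target voxel centers outside the physical extent of the dose grid get
    0 Gy — lung outside the dose matrix is unirradiated — and the
    uncovered fraction is recorded in ``meta['uncovered_fraction']`` (a
    warning is emitted when it is non-zero).
    """
    if min(dose.shape) < 2:
        raise GridIOError(f"degenerate dose grid {dose.shape}: need >= 2 voxels per axis")
    coords = []
    for axis in range(3):
        c = target.voxel_centers(axis)
        coords.append((c - dose.origin[axis]) / dose.spacing[axis])
    ii, jj, kk = np.meshgrid(*coords, indexing="ij")
    outside = np.zeros(ii.shape, dtype=bool)
    for idx, axis in ((ii, 0), (jj, 1), (kk, 2)):
        outside |= (idx < -1e-9) | (idx > dose.shape[axis] - 1 + 1e-9)
    stacked = np.vstack([ii.ravel(), jj.ravel(), kk.ravel()])
    resampled = map_coordinates(dose.values, stacked, order=1, mode="constant",
                                cval=0.0).reshape(target.shape)
    resampled[outside] = 0.0
    uncovered = float(outside.mean())
    if uncovered > 0:
        warnings.warn(
            f"{uncovered:.1%} of target voxels lie outside the dose grid; set to 0 Gy",
            stacklevel=2,
        )
    out = ImageVolume(resampled, spacing=target.spacing, origin=target.origin,
                      axes=target.axes)
    out.meta["uncovered_fraction"] = uncovered
    return out


def coverage_fraction(dose: ImageVolume, mask: BinaryMask) -> float:
    """Fraction of mask voxels whose centers lie inside the dose grid extent."""
    if mask.voxel_count == 0:
        return 1.0
    geom = mask.reference
    inside = np.ones(geom.shape, dtype=bool)
    for axis in range(3):
        c = geom.voxel_centers(axis)
        idx = (c - dose.origin[axis]) / dose.spacing[axis]
        ok = (idx >= -1e-9) & (idx <= dose.shape[axis] - 1 + 1e-9)
        shape = [1, 1, 1]
        shape[axis] = -1
        inside &= ok.reshape(shape)
    return float(inside[mask.values].mean())
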