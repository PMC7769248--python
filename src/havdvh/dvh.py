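"""Dose-volume parameters, conventional and high-attenuation-restricted.

Conventional parameters score dose to the whole lung: MLD (mean lung
dose, Gy) and Vx (percentage of lung volume receiving >= x Gy).  The
emphysema-masked family restricts the *numerator* to the high
attenuation (non-emphysematous) lung while keeping the whole-lung
denominator:

    HAVx% = 100 * volume(HAV and dose >= x Gy) / TLV
    MHALD = mean dose over the HAV mask (Gy)

Both dose thresholds and the HU threshold are inclusive (>=).  All
parameters are computed by direct voxel evaluation — binning exists only
for exported cumulative curves — so no histogram bin width enters the
values.  When the HAV mask is empty, MHALD and HAVx% are undefined and
reported as NaN markers rather than zeros, which would silently corrupt
cohort statistics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids_io import BinaryMask, GridIOError, ImageVolume
from .segmentation import LungSegmentation

__all__ = [
    "DvhRecord",
    "DvhCurve",
    "DVH_COLUMNS",
    "DEFAULT_DOSE_GRID_GY",
    "v_x",
    "mean_dose",
    "compute_dvh_record",
    "cumulative_dvh",
]

#: Dose levels (Gy) of the Vx / HAVx% families reported by default.
DEFAULT_DOSE_GRID_GY = (2.0, 5.0, 10.0, 20.0, 30.0)

#: Exact column order of the per-patient record table.
DVH_COLUMNS = [
    "patient_id", "TLV_mm3", "LAV_pct", "MLD_Gy",
    "V2", "V5", "V10", "V20", "V30",
    "MHALD_Gy", "HAV2_pct", "HAV5_pct", "HAV10_pct", "HAV20_pct", "HAV30_pct",
    "dose_coverage",
]

#: Conventional counterpart of each high-attenuation parameter.
HAV_COUNTERPARTS = {
    "MHALD_Gy": "MLD_Gy",
    "HAV2_pct": "V2",
    "HAV5_pct": "V5",
    "HAV10_pct": "V10",
    "HAV20_pct": "V20",
    "HAV30_pct": "V30",
}


@dataclass
class DvhRecord:
    """One patient's dose-volume parameter vector."""

    patient_id: str
    tlv_mm3: float
    lav_percent: float
    mld_gy: float
    v_percent: dict[float, float]
    mhald_gy: float
    hav_percent: dict[float, float]
    dose_coverage_fraction: float = 1.0

    def as_row(self) -> dict:
        """Flatten to the canonical CSV column names."""
        row = {
            "patient_id": self.patient_id,
            "TLV_mm3": self.tlv_mm3,
            "LAV_pct": self.lav_percent,
            "MLD_Gy": self.mld_gy,
            "MHALD_Gy": self.mhald_gy,
            "dose_coverage": self.dose_coverage_fraction,
        }
        for x, v in self.v_percent.items():
            row[f"V{x:g}"] = v
        for x, v in self.hav_percent.items():
            row[f"HAV{x:g}_pct"] = v
        return row


@dataclass
class DvhCurve:
    """Cumulative DVH: fraction of a mask's volume receiving >= each edge."""

    bin_edges_gy: np.ndarray
    volume_fraction: np.ndarray
    mask_name: str = ""

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.bin_edges_gy, self.volume_fraction])


def v_x(dose: ImageVolume, mask: BinaryMask, x: float,
        denominator_mm3: float | None = None) -> float:
    """Percentage of ``denominator_mm3`` receiving >= x Gy inside ``mask``.

    The denominator defaults to the mask's own volume; passing TLV turns
    this into the HAVx% family when ``mask`` is the HAV mask.
    """
    if not dose.same_geometry(mask.reference):
        raise GridIOError("dose and mask geometries differ")
    denom = mask.volume_mm3 if denominator_mm3 is None else float(denominator_mm3)
    if denom <= 0:
        raise ValueError(f"denominator must be positive, got {denom}")
    hit = int(np.count_nonzero(mask.values & (dose.values >= x)))
    return 100.0 * hit * mask.reference.voxel_volume_mm3 / denom


def mean_dose(dose: ImageVolume, mask: BinaryMask) -> float:
    """Arithmetic mean of the dose over the mask voxels (Gy).

    Voxel volumes are equal on one grid, so the unweighted mean is the
    volume-weighted mean.  An empty mask raises: a mean dose over nothing
    (e.g. MHALD with no high-attenuation lung) is undefined.
    """
    if not dose.same_geometry(mask.reference):
        raise GridIOError("dose and mask geometries differ")
    if mask.voxel_count == 0:
        raise ValueError("mean dose over an empty mask is undefined")
    return float(dose.values[mask.values].mean())


def compute_dvh_record(
    dose: ImageVolume,
    seg: LungSegmentation,
    patient_id: str,
    dose_grid_gy: tuple[float, ...] = DEFAULT_DOSE_GRID_GY,
    dose_coverage_fraction: float | None = None,
) -> DvhRecord:
    """Assemble the full parameter vector for one patient.

    ``dose`` must already be resampled to the CT grid.  Vx and HAVx% both
    use TLV as denominator; MLD is over the whole lung, MHALD over HAV
    only.  If HAV is empty, MHALD and every HAVx% are NaN.
    """
    tlv = seg.tlv_mm3
    mld = mean_dose(dose, seg.lung_mask)
    vx = {x: v_x(dose, seg.lung_mask, x, denominator_mm3=tlv) for x in dose_grid_gy}
    if seg.hav_mask.voxel_count == 0:
        mhald = math.nan
        havx = {x: math.nan for x in dose_grid_gy}
    else:
        mhald = mean_dose(dose, seg.hav_mask)
        havx = {x: v_x(dose, seg.hav_mask, x, denominator_mm3=tlv) for x in dose_grid_gy}
    if dose_coverage_fraction is None:
        dose_coverage_fraction = 1.0 - float(dose.meta.get("uncovered_fraction", 0.0))
    return DvhRecord(
        patient_id=str(patient_id),
        tlv_mm3=tlv,
        lav_percent=seg.lav_percent,
        mld_gy=mld,
        v_percent=vx,
        mhald_gy=mhald,
        hav_percent=havx,
        dose_coverage_fraction=float(dose_coverage_fraction),
    )


def cumulative_dvh(dose: ImageVolume, mask: BinaryMask,
                   bin_width_gy: float = 0.1, mask_name: str = "") -> DvhCurve:
    """Cumulative dose-volume curve for export/plotting.

    Edges run from 0 to just past the maximum in-mask dose in fixed
    steps; each entry is the fraction of mask volume with dose >= edge.
    """
    if bin_width_gy <= 0:
        raise ValueError("bin_width_gy must be positive")
    if mask.voxel_count == 0:
        raise ValueError("cumulative DVH of an empty mask is undefined")
    d = np.sort(dose.values[mask.values])
    edges = np.arange(0.0, float(d[-1]) + 2 * bin_width_gy, bin_width_gy)
    # count of doses >= edge, via binary search on the sorted doses
    frac = 1.0 - np.searchsorted(d, edges, side="left") / d.size
    return DvhCurve(bin_edges_gy=edges, volume_fraction=frac, mask_name=mask_name)
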