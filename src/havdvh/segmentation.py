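"""Lung partition into low- and high-attenuation sub-volumes.

On free-breathing planning CT, emphysematous lung is identified as the
low attenuation volume (LAV): lung voxels below -856 HU.  Everything at
or above the threshold is high attenuation volume (HAV), i.e.
non-emphysematous lung, so HAV = TLV - LAV exactly.  The boundary value
-856 HU itself belongs to HAV.

No smoothing, morphology or connected-component filtering is applied:
the partition is a plain voxelwise threshold on the CT inside the given
lung contour.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grids_io import BinaryMask, GridIOError, ImageVolume

__all__ = ["LungSegmentation", "SegmentationError", "segment_lung", "DEFAULT_HU_THRESHOLD"]

#: Free-breathing emphysema threshold (HU).  The inspiratory-CT
#: convention (-950 HU) is a different acquisition protocol, not a mode
#: of this pipeline.
DEFAULT_HU_THRESHOLD = -856.0


class SegmentationError(ValueError):
    pass


@dataclass
class LungSegmentation:
    """Voxelwise partition of the lung into LAV (< threshold) and HAV (>=)."""

    lung_mask: BinaryMask
    lav_mask: BinaryMask
    hav_mask: BinaryMask
    hu_threshold: float

    @property
    def tlv_mm3(self) -> float:
        return self.lung_mask.volume_mm3

    @property
    def lav_mm3(self) -> float:
        return self.lav_mask.volume_mm3

    @property
    def hav_mm3(self) -> float:
        return self.hav_mask.volume_mm3

    @property
    def lav_percent(self) -> float:
        return 100.0 * self.lav_mask.voxel_count / self.lung_mask.voxel_count

    def summary(self) -> dict:
        return {
            "hu_threshold": self.hu_threshold,
            "tlv_mm3": self.tlv_mm3,
            "lav_mm3": self.lav_mm3,
            "hav_mm3": self.hav_mm3,
            "lav_percent": self.lav_percent,
        }


def segment_lung(
    ct: ImageVolume,
    lung_mask: BinaryMask,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
) -> LungSegmentation:
    """Partition the lung at ``hu_threshold`` into LAV and HAV masks.

    Parameters
    ----------
    ct : ImageVolume
        CT in Hounsfield units, on the same geometry as ``lung_mask``.
    lung_mask : BinaryMask
        Planning lung contour, non-empty.
    hu_threshold : float
        Upper HU limit for low attenuation; voxels with HU >= threshold
        go to HAV (the boundary is high attenuation).
    """
    if not ct.same_geometry(lung_mask.reference):
        raise GridIOError("CT and lung mask geometries differ")
    if lung_mask.voxel_count == 0:
        raise SegmentationError("lung mask is empty")
    hav = lung_mask.values & (ct.values >= hu_threshold)
    lav = lung_mask.values & ~hav
    return LungSegmentation(
        lung_mask=lung_mask,
        lav_mask=BinaryMask(lav, reference=ct),
        hav_mask=BinaryMask(hav, reference=ct),
        hu_threshold=float(hu_threshold),
    )
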