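"""Quantitative CT of the lung: segmentation, metrics, PPSH, fibrosis index.

The imaging chain mirrors a standard small-animal fibrosis readout:
the lung is segmented from a CT volume by 3-D region growing inside an
aerated-lung Hounsfield window (default -900..-100 HU), segmented
volume (mm^3) and mean density (HU) are measured, and the fibrosis
index condenses the two hallmark radiological changes of fibrosis -
densification and volume loss relative to an age-matched reference
cohort - into a single score:

    FI = sqrt(dHU_up * dV_down)

PPSH (peak position of the smoothed HU histogram) is a companion
diagnostic: emphysema or pleural effusion shift the histogram peak and
would bias volume/density metrics, so the peak is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SeedPointError, SegmentationError, ValidationError

__all__ = [
    "VoxelVolume",
    "LungMask",
    "LungScanMetrics",
    "FibrosisScore",
    "PPSHResult",
    "segment_lung",
    "lung_metrics",
    "ppsh",
    "fibrosis_index",
    "HU_WINDOW",
]

#: Default aerated-lung segmentation window (lower, upper) in HU.
HU_WINDOW = (-900.0, -100.0)


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D CT-like image: HU array plus per-axis voxel spacing in mm."""

    hu: np.ndarray
    spacing_mm: tuple

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu)
        if hu.ndim != 3:
            raise ValidationError("VoxelVolume requires a 3-D HU array")
        if not np.all(np.isfinite(hu)):
            raise ValidationError("HU values must be finite")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing_mm must be 3 positive values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class LungMask:
    """Boolean segmentation mask with its provenance."""

    mask: np.ndarray
    seed_point: tuple | None = None
    hu_window: tuple = HU_WINDOW
    connectivity: int = 6


@dataclass(frozen=True)
class LungScanMetrics:
    """Volume and density summary of a segmented lung."""

    volume_mm3: float
    mean_hu: float
    voxel_count: int


@dataclass(frozen=True)
class FibrosisScore:
    delta_hu: float
    delta_v: float
    fi: float
    non_fibrotic_pattern: bool = False


@dataclass(frozen=True)
class PPSHResult:
    peak_hu: float
    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    smooth_window_hu: float
    single_bin: bool = False


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError("connectivity must be 6 or 26")


def segment_lung(volume: VoxelVolume, lower_hu: float = HU_WINDOW[0],
                 upper_hu: float = HU_WINDOW[1], seed_point: tuple = None,
                 exclusion_mask: np.ndarray | None = None,
                 connectivity: int = 6) -> LungMask:
    """Region-growing lung segmentation.

    Grows the connected component of the HU window ``[lower_hu,
    upper_hu]`` that contains ``seed_point`` (array indices), then
    removes ``exclusion_mask`` voxels.  The exclusion mask is the
    reproducible stand-in for manual resection of trachea and primary
    bronchi from the segmentation.
    """
    if lower_hu >= upper_hu:
        raise ValidationError("lower_hu must be < upper_hu")
    if seed_point is None:
        raise ValidationError("seed_point is required")
    hu = np.asarray(volume.hu)
    seed = tuple(int(i) for i in seed_point)
    try:
        seed_val = hu[seed]
    except IndexError as exc:
        raise SeedPointError(f"seed point {seed} outside volume") from exc
    if not (lower_hu <= seed_val <= upper_hu):
        raise SeedPointError(
            f"seed voxel HU {seed_val} outside window [{lower_hu}, {upper_hu}]"
        )

    window = (hu >= lower_hu) & (hu <= upper_hu)
    labels, _ = ndimage.label(window, structure=_structure(connectivity))
    mask = labels == labels[seed]
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != mask.shape:
            raise ValidationError("exclusion mask shape mismatch")
        mask = mask & ~excl
    if not mask.any():
        raise SegmentationError("segmentation empty after exclusion")
    return LungMask(mask=mask, seed_point=seed,
                    hu_window=(lower_hu, upper_hu), connectivity=connectivity)


def lung_metrics(volume: VoxelVolume, mask: LungMask) -> LungScanMetrics:
    """Segmented volume (voxel count x voxel volume) and mean HU."""
    m = np.asarray(mask.mask, dtype=bool)
    count = int(m.sum())
    if count == 0:
        raise SegmentationError("empty mask")
    return LungScanMetrics(
        volume_mm3=count * volume.voxel_volume_mm3,
        mean_hu=float(np.asarray(volume.hu)[m].mean()),
        voxel_count=count,
    )


def ppsh(volume: VoxelVolume, mask: LungMask, bin_width_hu: float = 10.0,
         smooth_window_hu: float = 50.0) -> PPSHResult:
    """Peak position of the smoothed HU histogram inside the mask.

    Histogram at ``bin_width_hu``, centred moving-average smoothing over
    ``smooth_window_hu``; the peak is the bin centre of the global
    maximum, ties broken towards lower HU.
    """
    if bin_width_hu <= 0:
        raise ValidationError("bin_width_hu must be > 0")
    if smooth_window_hu < bin_width_hu:
        raise ValidationError("smooth_window_hu must be >= bin_width_hu")
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise SegmentationError("empty mask")
    vals = np.asarray(volume.hu)[m].astype(float)

    lo = np.floor(vals.min() / bin_width_hu) * bin_width_hu
    hi = np.ceil(vals.max() / bin_width_hu) * bin_width_hu
    if hi <= lo:
        hi = lo + bin_width_hu
    edges = np.arange(lo, hi + bin_width_hu / 2, bin_width_hu)
    counts, edges = np.histogram(vals, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    single_bin = len(centers) == 1 or np.count_nonzero(counts) == 1

    # centred moving average; window in bins is odd so the peak is unbiased
    w = max(1, int(round(smooth_window_hu / bin_width_hu)))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")

    peak_idx = int(np.argmax(smoothed))  # argmax returns the first (lowest-HU) tie
    return PPSHResult(peak_hu=float(centers[peak_idx]), bin_centers=centers,
                      counts=counts, smoothed=smoothed,
                      smooth_window_hu=smooth_window_hu, single_bin=single_bin)


def fibrosis_index(treated, reference=None, convention: str = "relative",
                   scale: float = 1.0) -> FibrosisScore:
    """Fibrosis index FI = sqrt(dHU * dV), clamped to 0 if either delta <= 0.

    ``convention="relative"`` (default): ``treated`` is a
    :class:`LungScanMetrics` and ``reference`` a ``(ref_volume_mm3,
    ref_mean_hu)`` pair (or an object with those attributes); the deltas
    are the relative density increase and relative volume loss, each
    multiplied by ``scale``:

        dHU = scale * (HU_t - HU_ref) / |HU_ref|
        dV  = scale * (V_ref - V_t) / V_ref

    ``convention="direct"``: ``treated`` is a precomputed
    ``(delta_hu, delta_v)`` pair, passed through unchanged (used by the
    synthetic back-fill path).

    A negative delta on either axis (lung got larger, or less dense,
    than reference) is a non-fibrotic radiological pattern: FI is 0 and
    the score is flagged.
    """
    if convention == "direct":
        delta_hu, delta_v = (float(x) for x in treated)
    elif convention == "relative":
        ref_vol, ref_hu = _reference_pair(reference)
        if ref_vol <= 0:
            raise ValidationError("reference volume must be > 0")
        if ref_hu == 0:
            raise ValidationError("reference mean HU must be nonzero")
        delta_hu = scale * (treated.mean_hu - ref_hu) / abs(ref_hu)
        delta_v = scale * (ref_vol - treated.volume_mm3) / ref_vol
    else:
        raise ValidationError(f"unknown convention {convention!r}")

    if delta_hu > 0 and delta_v > 0:
        fi = float(np.sqrt(delta_hu * delta_v))
    else:
        fi = 0.0
    flag = delta_hu < 0 or delta_v < 0
    return FibrosisScore(delta_hu=delta_hu, delta_v=delta_v, fi=fi,
                         non_fibrotic_pattern=flag)


def _reference_pair(reference):
    if reference is None:
        raise ValidationError("reference summary required for relative convention")
    if hasattr(reference, "volume_mm3"):
        return float(reference.volume_mm3), float(reference.mean_hu)
    vol, hu = reference
    return float(vol), float(hu)
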