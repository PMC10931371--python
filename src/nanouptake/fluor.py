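"""Bead-pixels-per-cell quantification from confocal z-stacks.

The chain follows standard fluorescence cytometry practice: maximum
z-projection and channel splitting; nuclei segmentation on the DAPI channel
(Gaussian blur, threshold, watershed split, size and circularity filter);
a cell-area mask from the actin channel (or, as fallback, Canny edges plus
binary morphology on the brightfield channel) that excludes extracellular
fluorescence; a calibrated intensity threshold on the bead channel; and the
two summary numbers — the count of above-threshold bead pixels inside the
cell area, and that count divided by the number of nuclei ("bead pixels per
cell").
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "ConfocalStack",
    "SegmentationParams",
    "NucleiSegmentation",
    "UptakeRecord",
    "NoCellsError",
    "CELL_LINE_MIN_NUCLEUS_AREA",
    "z_project",
    "segment_nuclei",
    "segment_cell_area_actin",
    "segment_cell_area_brightfield",
    "calibrate_bead_threshold",
    "mask_beads",
    "count_bead_pixels",
    "beads_per_cell",
    "quantify_fov",
]

#: Minimum nucleus area (um^2) per cell line, as used in the particle filter.
CELL_LINE_MIN_NUCLEUS_AREA: dict[str, float] = {
    "THP-1": 20.0,
    "A549": 10.0,
    "CaCo-2": 10.0,
}

CHANNEL_ROLES = ("beads", "nuclei", "actin", "brightfield")


class NoCellsError(ValueError):
    """No nuclei were detected, so per-cell normalization is undefined."""


@dataclass
class ConfocalStack:
    """Multi-channel confocal z-stack.

    channels maps a role in {beads, nuclei, actin, brightfield} to an
    8-bit image stack of shape (n_z, n_y, n_x); all channels must share
    dimensions.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack has no channels")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            a = np.asarray(arr)
            if a.ndim != 3 or a.shape[0] < 1:
                raise ValueError(
                    f"channel {role!r} must be a (n_z, n_y, n_x) stack"
                )
            self.channels[role] = a
            shapes.add(a.shape)
        if len(shapes) != 1:
            raise ValueError("all channels must share dimensions")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def fov_area_um2(self) -> float:
        _, ny, nx = self.shape
        return ny * nx * self.pixel_size_um**2


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation chain.

    The defaults mirror common practice for DAPI/actin imaging: a sigma-3
    Gaussian blur before nuclei thresholding, automatic (Otsu) thresholds
    that can be overridden by explicit 8-bit values, a 20 um^2 minimum
    nucleus area for THP-1 (10 um^2 for A549/CaCo-2 via
    :data:`CELL_LINE_MIN_NUCLEUS_AREA`), and an inclusive 0.0-1.0
    circularity window (a configurable no-op by default).
    """

    nuclei_blur_sigma: float = 3.0
    nuclei_threshold: float | str = "auto"
    min_nucleus_area_um2: float = 20.0
    circularity_range: tuple[float, float] = (0.0, 1.0)
    canny_sigma: float = 2.0
    maxfilter_radius: int = 3
    morph_radius: int = 5
    bead_threshold: float | str = "calibrate"

    def __post_init__(self) -> None:
        if self.min_nucleus_area_um2 <= 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        lo, hi = self.circularity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("circularity_range must be within [0, 1]")

    @classmethod
    def for_cell_line(cls, cell_line: str, **kwargs) -> "SegmentationParams":
        area = CELL_LINE_MIN_NUCLEUS_AREA.get(cell_line)
        if area is None:
            raise KeyError(f"no profile for cell line {cell_line!r}")
        return cls(min_nucleus_area_um2=area, **kwargs)


@dataclass
class NucleiSegmentation:
    """Retained nuclei: label image, count and per-nucleus areas (um^2)."""

    label_image: np.ndarray
    count: int
    areas_um2: np.ndarray


@dataclass
class UptakeRecord:
    """Per-field-of-view uptake quantification result."""

    bead_pixels: int
    n_nuclei: int
    bead_px_per_cell: float
    bead_area_um2: float
    fov_area_um2: float
    cell_line: str = ""
    concentration: float = float("nan")
    time_h: float = float("nan")
    replicate: int = 0
    valid: bool = True
    cell_mask_source: str = ""


# --------------------------------------------------------------------------
# pipeline steps


def z_project(
    stack: ConfocalStack, method: str = "max"
) -> dict[str, np.ndarray]:
    """Collapse the z-stack into one 2-D image per channel.

    Maximum-intensity projection is the default: beads are sparse bright
    puncta, and the maximum preserves a punctum regardless of the plane it
    is in focus in.  A sum projection is available via ``method="sum"``.
    """
    if method == "max":
        return {r: a.max(axis=0) for r, a in stack.channels.items()}
    if method == "sum":
        return {
            r: a.astype(np.int64).sum(axis=0) for r, a in stack.channels.items()
        }
    raise ValueError(f"unknown projection method {method!r}")


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected regions smaller than ``min_size`` pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def _circularity(region) -> float:
    p = region.perimeter
    if p == 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * region.area / p**2)


def segment_nuclei(
    nuclei_image: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 1.0,
) -> NucleiSegmentation:
    """Segment and count nuclei in a projected DAPI image.

    Gaussian blur -> threshold (Otsu when ``nuclei_threshold="auto"``) ->
    watershed split of touching nuclei (distance-transform maxima spaced at
    least one minimum-nucleus equivalent diameter apart) -> filter by area
    in um^2 and circularity 4*pi*A/P^2 (inclusive bounds).
    """
    params = params or SegmentationParams()
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    img = np.asarray(nuclei_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("nuclei image must be a non-empty 2-D array")

    empty = NucleiSegmentation(
        label_image=np.zeros(img.shape, dtype=np.int32),
        count=0,
        areas_um2=np.array([]),
    )
    blurred = filters.gaussian(img, sigma=params.nuclei_blur_sigma,
                               preserve_range=True)
    if params.nuclei_threshold == "auto":
        # an (almost) flat field has no nuclei; Otsu on pure noise would
        # otherwise hallucinate foreground, so require real contrast
        if np.ptp(blurred) < 5.0:
            return empty
        thr = filters.threshold_otsu(blurred)
    else:
        thr = float(params.nuclei_threshold)
    mask = blurred >= thr
    if not mask.any():
        return empty

    # watershed on the distance transform, seeded by well-separated maxima
    dist = ndi.distance_transform_edt(mask)
    min_area_px = params.min_nucleus_area_um2 / pixel_size_um**2
    eq_diam_px = max(int(round(2.0 * np.sqrt(min_area_px / np.pi))), 1)
    coords = feature.peak_local_max(
        dist, min_distance=eq_diam_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    labels = segmentation.watershed(-dist, markers, mask=mask)

    lo, hi = params.circularity_range
    keep_labels = []
    areas = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * pixel_size_um**2
        if area_um2 < params.min_nucleus_area_um2:
            continue
        c = _circularity(region)
        if not (lo <= c <= hi):
            continue
        keep_labels.append(region.label)
        areas.append(area_um2)

    out = np.zeros_like(labels)
    for new, old in enumerate(keep_labels, start=1):
        out[labels == old] = new
    return NucleiSegmentation(
        label_image=out, count=len(keep_labels), areas_um2=np.asarray(areas)
    )


def segment_cell_area_actin(
    actin_image: np.ndarray, threshold: float | str = "auto"
) -> np.ndarray:
    """Binary cell-area mask from the actin (IF555) channel.

    Threshold (Otsu by default), morphological closing, hole filling.
    """
    img = np.asarray(actin_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("actin image must be a non-empty 2-D array")
    if threshold == "auto":
        if np.ptp(img) == 0:
            return img > 0  # constant image: saturated -> full, blank -> empty
        thr = filters.threshold_otsu(img)
    else:
        thr = float(threshold)
    mask = img >= thr
    mask = morphology.closing(mask, morphology.disk(5))
    mask = ndi.binary_fill_holes(mask)
    return _remove_small(mask, 50)


def segment_cell_area_brightfield(
    bf_image: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Binary cell-area mask from the brightfield channel.

    Percentile contrast stretch, Canny edge detection, maximum filter,
    binary closing and opening, hole filling; connected regions smaller
    than one minimum nucleus area are removed.
    """
    params = params or SegmentationParams()
    img = np.asarray(bf_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("brightfield image must be a non-empty 2-D array")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    p2, p98 = np.percentile(img, (2, 98))
    if p98 > p2:
        img = np.clip((img - p2) / (p98 - p2), 0, 1)
    edges = feature.canny(img, sigma=params.canny_sigma)
    thick = ndi.maximum_filter(edges, size=2 * params.maxfilter_radius + 1)
    closed = morphology.closing(thick, morphology.disk(params.morph_radius))
    filled = ndi.binary_fill_holes(closed)
    opened = morphology.opening(filled, morphology.disk(params.morph_radius))
    # the maximum filter thickened edges outward by its radius; erode the
    # filled mask back so the boundary sits on the detected edge
    opened = morphology.erosion(
        opened, morphology.disk(params.maxfilter_radius)
    )
    min_px = int(params.min_nucleus_area_um2 / pixel_size_um**2)
    return _remove_small(opened, max(min_px, 1))


def calibrate_bead_threshold(
    control_images: list[np.ndarray],
    cell_masks: list[np.ndarray],
    percentile: float = 99.95,
) -> int:
    """Bead threshold from unexposed control images.

    The threshold is the given percentile of the within-cell intensity
    pooled over all control images, rounded up (and at least 1), so that
    essentially all autofluorescence falls below it.  It may subsequently
    be overridden with an explicit value, mirroring manual adjustment
    against the recorded image.
    """
    if not control_images:
        raise ValueError("need at least one control image")
    if len(control_images) != len(cell_masks):
        raise ValueError("one cell mask per control image required")
    pooled = []
    for img, mask in zip(control_images, cell_masks):
        img = np.asarray(img)
        mask = np.asarray(mask, dtype=bool)
        if img.shape != mask.shape:
            raise ValueError("control image and mask shapes differ")
        if mask.any():
            pooled.append(img[mask])
    if not pooled:
        raise ValueError("all control cell masks are empty")
    values = np.concatenate(pooled)
    thr = int(math.ceil(np.percentile(values, percentile)))
    return int(np.clip(thr, 1, 255))


def mask_beads(
    bead_image: np.ndarray,
    threshold: float,
    cell_mask: np.ndarray,
) -> np.ndarray:
    """Binary bead mask: above-threshold pixels inside the cell area.

    Fluorescence outside the cell mask (residual extracellular beads) is
    omitted.  Returns an 8-bit image with foreground 255.
    """
    if not 1 <= threshold <= 255:
        raise ValueError("threshold must be within [1, 255]")
    img = np.asarray(bead_image)
    mask = np.asarray(cell_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("bead image and cell mask shapes differ")
    return (((img >= threshold) & mask) * np.uint8(255)).astype(np.uint8)


def count_bead_pixels(binary_mask: np.ndarray) -> int:
    """Count foreground pixels of a binary 0/255 mask via the mean gray value.

    Implements the mean-gray identity used with 8-bit binary masks:
    ``n_pixels * mean / 255``, which equals the foreground count exactly.
    """
    m = np.asarray(binary_mask)
    if not np.isin(m, (0, 255)).all():
        raise ValueError("mask must contain only 0 and 255")
    mean_gray = m.mean(dtype=np.float64)
    return int(round(m.size * mean_gray / 255.0))


def beads_per_cell(bead_pixels: int, n_nuclei: int) -> float:
    """Bead pixels per cell: bead-pixel count over the nuclei count."""
    if n_nuclei < 1:
        raise NoCellsError("no cells detected; record must be excluded")
    return bead_pixels / n_nuclei


def _actin_mask_sufficient(
    mask: np.ndarray, nuclei_labels: np.ndarray
) -> bool:
    """An actin mask is usable when it covers most of the nuclei area."""
    nuc = nuclei_labels > 0
    if not nuc.any():
        return mask.any()
    return (mask & nuc).sum() / nuc.sum() >= 0.8


def quantify_fov(
    stack: ConfocalStack,
    params: SegmentationParams | None = None,
    cell_line: str = "",
    concentration: float = float("nan"),
    time_h: float = float("nan"),
    replicate: int = 0,
    bead_threshold: float | None = None,
    control_images: list[np.ndarray] | None = None,
    projection: str = "max",
) -> UptakeRecord:
    """End-to-end quantification of one field of view.

    Projects the stack, segments nuclei, builds the cell-area mask (actin
    preferred; brightfield fallback when the actin mask misses too much of
    the nuclei area), thresholds the bead channel inside the cell area and
    reports bead pixels and bead pixels per cell.

    The bead threshold is, in order of precedence: the ``bead_threshold``
    argument, an explicit numeric ``params.bead_threshold``, or a
    calibration from ``control_images`` (unexposed fields).

    A field with zero detected nuclei yields a record flagged
    ``valid=False`` with ``bead_px_per_cell = nan``.
    """
    params = params or (
        SegmentationParams.for_cell_line(cell_line)
        if cell_line in CELL_LINE_MIN_NUCLEUS_AREA
        else SegmentationParams()
    )
    if "beads" not in stack.channels or "nuclei" not in stack.channels:
        raise ValueError("stack must provide 'beads' and 'nuclei' channels")
    if "actin" not in stack.channels and "brightfield" not in stack.channels:
        raise ValueError(
            "stack must provide an 'actin' or 'brightfield' channel "
            "for cell-area masking"
        )
    proj = z_project(stack, method=projection)
    nuclei = segment_nuclei(proj["nuclei"], params, stack.pixel_size_um)

    cell_mask = None
    source = ""
    if "actin" in stack.channels:
        cand = segment_cell_area_actin(proj["actin"])
        if _actin_mask_sufficient(cand, nuclei.label_image):
            cell_mask, source = cand, "actin"
    if cell_mask is None and "brightfield" in stack.channels:
        cell_mask = segment_cell_area_brightfield(
            proj["brightfield"], params, stack.pixel_size_um
        )
        source = "brightfield"
    if cell_mask is None:
        cell_mask = cand  # insufficient actin mask, nothing better available
        source = "actin"

    if bead_threshold is not None:
        thr = float(bead_threshold)
    elif params.bead_threshold != "calibrate":
        thr = float(params.bead_threshold)
    elif control_images is not None:
        thr = calibrate_bead_threshold(
            control_images, [cell_mask] * len(control_images)
        )
    else:
        raise ValueError(
            "no bead threshold: pass bead_threshold, set an explicit "
            "params.bead_threshold, or provide control_images to calibrate"
        )

    bead_mask = mask_beads(proj["beads"], thr, cell_mask)
    n_bead_px = count_bead_pixels(bead_mask)
    px2 = stack.pixel_size_um**2

    try:
        ratio = beads_per_cell(n_bead_px, nuclei.count)
        valid = True
    except NoCellsError:
        warnings.warn(
            "no nuclei detected in this field of view; record flagged invalid",
            stacklevel=2,
        )
        logger.warning("FOV with zero nuclei excluded from per-cell ratio")
        ratio, valid = float("nan"), False

    return UptakeRecord(
        bead_pixels=n_bead_px,
        n_nuclei=nuclei.count,
        bead_px_per_cell=ratio,
        bead_area_um2=n_bead_px * px2,
        fov_area_um2=stack.fov_area_um2,
        cell_line=cell_line,
        concentration=concentration,
        time_h=time_h,
        replicate=replicate,
        valid=valid,
        cell_mask_source=source,
    )
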