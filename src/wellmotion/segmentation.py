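"""Per-well movement quantification from frame pairs.

A well is imaged twice in quick succession (500 ms apart in the original
assay).  Worm bodies are segmented from one frame into a binary *reference*
mask (edge detection -> adaptive threshold -> morphological closing ->
circular well mask), and the absolute difference between the two frames
flags pixels associated with movement.  Because the raw difference image
contains the moving pixels of *both* frames, it is intersected with the
reference mask so that movement is counted in a single frame only.  The
fractional mobility score (FMS) is then

    FMS = |moving pixels| / |non-background pixels|

which is 0 when nothing moved between the frames and 1 when every worm
pixel moved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters

__all__ = [
    "SegmentationParams",
    "WellMasks",
    "MobilityRecord",
    "preprocess",
    "build_reference_mask",
    "remove_small_objects",
    "difference_mask",
    "partition_movement",
    "fractional_mobility",
    "quantify_well",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the per-well segmentation.

    Parameters
    ----------
    blur_sigma : float
        Gaussian pre-blur in pixels applied to both frames; 0 disables.
    adaptive_block : int
        Odd side length (pixels) of the local-mean neighbourhood used to
        adaptively threshold the edge (Sobel) image.
    adaptive_offset : float
        Amount (in [0, 1] intensity units) by which a Sobel response must
        exceed its local mean to count as an edge pixel.
    closing_iterations : int
        Iterations of binary closing (3x3 square element) that fill the
        interior between a worm's two side edges.
    diff_threshold : float
        Global threshold on the absolute frame difference; pixels whose
        intensity changed by more than this are movement candidates.
    mask_radius_frac : float
        Radius of the circular well mask as a fraction of ``min(shape)/2``;
        removes the bright well rim from the analysis.
    min_object_px : int
        Connected components of the reference mask smaller than this are
        discarded (8-connectivity).  Used in adult mode to drop eggs,
        which some compounds stimulate worms to lay.  0 disables.
    min_worm_pixels : int
        A well whose reference mask holds fewer pixels than this is marked
        invalid (empty or failed well) and its FMS is undefined.
    """

    blur_sigma: float = 1.0
    adaptive_block: int = 51
    adaptive_offset: float = 0.01
    closing_iterations: int = 2
    diff_threshold: float = 0.01
    mask_radius_frac: float = 0.95
    min_object_px: int = 0
    min_worm_pixels: int = 50

    def __post_init__(self) -> None:
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise ValueError("adaptive_block must be odd and >= 3")
        if not 0.0 < self.mask_radius_frac <= 1.0:
            raise ValueError("mask_radius_frac must be in (0, 1]")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be > 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.min_object_px < 0 or self.min_worm_pixels < 0:
            raise ValueError("pixel-count parameters must be >= 0")

    def with_adult_mode(self, min_object_px: int = 50) -> "SegmentationParams":
        """Return a copy with the egg-removal size filter enabled."""
        return replace(self, min_object_px=min_object_px)


@dataclass
class WellMasks:
    """Binary segmentation state of one well at one timepoint.

    ``reference`` marks non-background (worm) pixels of the reference
    frame; ``moving`` the subset that changed between the two frames;
    ``stationary`` the complement within the reference.  The three masks
    always satisfy ``moving | stationary == reference`` and
    ``moving & stationary == 0``.
    """

    reference: np.ndarray
    moving: np.ndarray
    stationary: np.ndarray

    def check(self) -> None:
        if (self.moving & self.stationary).any():
            raise ValueError("moving and stationary masks overlap")
        if ((self.moving | self.stationary) != self.reference).any():
            raise ValueError("moving + stationary do not partition reference")


@dataclass
class MobilityRecord:
    """One FMS measurement: a well at a timepoint.

    ``fms`` is NaN when ``valid`` is False (empty or unusable well).
    """

    well_id: str = ""
    timepoint_min: float = 0.0
    fms: float = float("nan")
    moving_px: int = 0
    total_px: int = 0
    valid: bool = False
    masks: WellMasks | None = field(default=None, repr=False, compare=False)


def preprocess(frame: np.ndarray, blur_sigma: float) -> np.ndarray:
    """Gaussian-blur a frame to suppress sensor noise.

    ``blur_sigma == 0`` returns the input unchanged (same object).
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if blur_sigma == 0:
        return frame
    return ndi.gaussian_filter(np.asarray(frame, dtype=float), sigma=blur_sigma)


def _circular_mask(shape: tuple[int, int], radius_frac: float) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.ogrid[:rows, :cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    radius = radius_frac * min(rows, cols) / 2.0
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def build_reference_mask(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Segment non-background (worm) pixels of a preprocessed frame.

    Sobel edge magnitude -> local-mean adaptive threshold -> binary
    closing (fills worm interiors between their side edges) -> circular
    mask removing the well rim.  An all-zero result is legal (blank
    well); validity is decided downstream by the pixel-count floor.
    """
    frame = np.asarray(frame, dtype=float)
    edges = filters.sobel(frame)
    # skimage subtracts `offset` from the local mean; negate so that
    # adaptive_offset is the margin an edge must clear above it.
    local = filters.threshold_local(
        edges,
        block_size=params.adaptive_block,
        method="mean",
        offset=-params.adaptive_offset,
    )
    binary = edges > local
    if params.closing_iterations > 0:
        binary = ndi.binary_closing(
            binary,
            structure=np.ones((3, 3), dtype=bool),
            iterations=params.closing_iterations,
        )
    binary &= _circular_mask(frame.shape, params.mask_radius_frac)
    return binary


def remove_small_objects(mask: np.ndarray, min_object_px: int) -> np.ndarray:
    """Drop 8-connected components smaller than ``min_object_px`` pixels.

    With ``min_object_px == 0`` the mask is returned unchanged.  Used to
    exclude eggs from adult-worm wells.
    """
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    if min_object_px == 0:
        return mask
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = areas >= min_object_px
    keep[0] = False
    return keep[labels]


def difference_mask(
    frame1: np.ndarray, frame2: np.ndarray, diff_threshold: float
) -> np.ndarray:
    """Binarized absolute difference of a (preprocessed) frame pair.

    The result flags movement pixels from *both* parent frames — roughly
    double the number of truly moving worm pixels — which is corrected
    later by intersecting with the single-frame reference mask.
    """
    frame1 = np.asarray(frame1, dtype=float)
    frame2 = np.asarray(frame2, dtype=float)
    if frame1.shape != frame2.shape:
        raise ValueError(
            f"frame shapes differ: {frame1.shape} vs {frame2.shape}"
        )
    return np.abs(frame1 - frame2) > diff_threshold


def partition_movement(diff: np.ndarray, reference: np.ndarray) -> WellMasks:
    """Split the reference mask into moving and stationary pixels.

    moving = diff AND reference (double-count correction); stationary =
    reference AND NOT moving.
    """
    diff = np.asarray(diff, dtype=bool)
    reference = np.asarray(reference, dtype=bool)
    if diff.shape != reference.shape:
        raise ValueError("difference and reference masks differ in shape")
    moving = diff & reference
    stationary = reference & ~moving
    return WellMasks(reference=reference, moving=moving, stationary=stationary)


def fractional_mobility(
    masks: WellMasks, min_worm_pixels: int = 50
) -> MobilityRecord:
    """Compute the FMS from a partitioned well.

    Wells whose reference mask holds fewer than ``min_worm_pixels``
    pixels are flagged invalid (FMS = NaN) rather than raising.
    """
    total_px = int(masks.reference.sum())
    moving_px = int(masks.moving.sum())
    if total_px < min_worm_pixels:
        return MobilityRecord(
            fms=float("nan"),
            moving_px=moving_px,
            total_px=total_px,
            valid=False,
            masks=masks,
        )
    return MobilityRecord(
        fms=moving_px / total_px,
        moving_px=moving_px,
        total_px=total_px,
        valid=True,
        masks=masks,
    )


def quantify_well(
    frame1: np.ndarray,
    frame2: np.ndarray,
    params: SegmentationParams | None = None,
    *,
    keep_masks: bool = False,
) -> MobilityRecord:
    """Full per-well pipeline: a frame pair in, a MobilityRecord out.

    Frame 1 is the designated reference frame.  Deterministic for fixed
    inputs and parameters.
    """
    if params is None:
        params = SegmentationParams()
    f1 = preprocess(frame1, params.blur_sigma)
    f2 = preprocess(frame2, params.blur_sigma)
    if np.asarray(f1).shape != np.asarray(f2).shape:
        raise ValueError("frame pair shapes differ")
    reference = build_reference_mask(f1, params)
    reference = remove_small_objects(reference, params.min_object_px)
    diff = difference_mask(f1, f2, params.diff_threshold)
    masks = partition_movement(diff, reference)
    record = fractional_mobility(masks, params.min_worm_pixels)
    if not keep_masks:
        record.masks = None
    return record
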