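"""Previewing, ROI-selecting and screening phases.

These three phases decide which stacks and which depths enter the ratio
computation.  Previewing rejects whole stacks (motion blur, visible
melanin, a provisional ratio above the phototype-I level of 1.6); ROI
selection derives a rectangular analysis window from intensity
thresholding; screening checks each candidate depth for sufficient
collagen coverage, visible fiber orientation and at least 10 basal cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu

from .stack_io import HGMStack

__all__ = [
    "RectROI", "PreviewDecision", "SubimageQC", "NoROIError",
    "select_roi", "snr_at_threshold", "focus_score",
    "detect_melanin_pieces", "preview_stack", "screen_subimage",
    "qualify_stack",
]

#: Default grayscale threshold used both for THG-based ROI selection and
#: for the SHG collagen-coverage rule (SNR > 10 over a ~150 noise floor).
DEFAULT_THRESHOLD = 1600.0
#: Ratio above which basal cells are presumed melanin-containing
#: (the phototype-I cytoplasm/collagen level).
MELANIN_RATIO_CUTOFF = 1.6
#: Structure-tensor coherence below which fiber orientation is deemed
#: unclear.
DEFAULT_COHERENCE_FLOOR = 0.3
#: Focus-score floor for previewing; calibrated once against the blurred
#: synthetic scenario (see the run configuration).
DEFAULT_FOCUS_FLOOR = 0.01


class NoROIError(ValueError):
    """No suprathreshold pixel exists, so no analysis window can be drawn."""


@dataclass(frozen=True)
class RectROI:
    """Rectangular analysis window with 0-based half-open pixel bounds."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop
                and 0 <= self.col_start < self.col_stop):
            raise ValueError(f"degenerate ROI bounds {self}")

    @property
    def area(self) -> int:
        return (self.row_stop - self.row_start) * (self.col_stop - self.col_start)

    def validate_for(self, frame: np.ndarray) -> None:
        if self.row_stop > frame.shape[0] or self.col_stop > frame.shape[1]:
            raise ValueError(f"ROI {self} exceeds frame shape {frame.shape}")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        self.validate_for(frame)
        return frame[self.row_start:self.row_stop, self.col_start:self.col_stop]

    def outside_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels outside the rectangle."""
        m = np.ones(shape, dtype=bool)
        m[self.row_start:self.row_stop, self.col_start:self.col_stop] = False
        return m


@dataclass(frozen=True)
class PreviewDecision:
    """Outcome of the previewing phase for one stack."""

    blurred: bool
    melanin_pieces: bool
    ratio_over_1p6: bool
    focus_score: float
    notes: str = ""

    @property
    def admitted(self) -> bool:
        return not (self.blurred or self.melanin_pieces or self.ratio_over_1p6)


@dataclass(frozen=True)
class SubimageQC:
    """Screening record for one depth."""

    depth_index: int
    shg_coverage_frac: float
    orientation_clear: bool
    cell_count: int
    coverage_min: float = 0.25
    min_cells: int = 10

    @property
    def qualified(self) -> bool:
        # Coverage strictly above the floor, at least ``min_cells`` cells.
        return (self.shg_coverage_frac > self.coverage_min
                and self.orientation_clear
                and self.cell_count >= self.min_cells)


def _majority(mask: np.ndarray) -> np.ndarray:
    """3x3 majority vote: a pixel is set when >= 5 of its 9-neighbourhood
    (itself included) are set.  Single-pixel speckle disappears and 1-px
    gaps between large regions are bridged."""
    counts = ndi.uniform_filter(mask.astype(float), size=3, mode="constant")
    return counts > 0.5


# Footprint for bridging gaps between tissue phases before the largest
# component is taken: basal cells and the collagen network are separated
# by dark interstices up to about half a cell diameter wide, and without
# the closing the "largest component" would be a single phase (or a
# fragment of one) rather than the tissue field.  Isolated hot pixels are
# already removed by the majority vote, so the closing cannot latch onto
# detector noise.
_CLOSE_R = 8
_CLOSE_FOOT = (lambda r: (np.add.outer(np.arange(-r, r + 1) ** 2,
                                       np.arange(-r, r + 1) ** 2)
                          <= r ** 2))(_CLOSE_R)


def select_roi(thg_frame: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
               method: str = "fixed") -> RectROI:
    """Derive the rectangular analysis window from intensity thresholding.

    The ROI is the axis-aligned bounding box of the largest 8-connected
    component of suprathreshold pixels after a 3x3 majority cleanup and a
    small binary closing.  The majority vote stops an isolated hot pixel
    in the dim border from inflating the window; the closing bridges the
    few-pixel dark interstices between basal cells and collagen so the
    window covers the whole tissue field rather than a single tissue
    phase.  With ``method="otsu"`` the threshold is computed from the
    frame histogram instead of being supplied.
    """
    frame = np.asarray(thg_frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if method == "otsu":
        threshold = float(threshold_otsu(frame))
    elif method == "fixed":
        if not 0 < threshold <= 16383:
            raise ValueError(f"threshold {threshold} outside (0, 16383]")
    else:
        raise ValueError(f"unknown method {method!r}")
    supra = _majority(frame > threshold)
    if not supra.any():
        raise NoROIError(
            f"no pixel above threshold {threshold} after cleanup")
    bridged = ndi.binary_closing(supra, structure=_CLOSE_FOOT)
    labels, n = ndi.label(bridged, structure=np.ones((3, 3), dtype=int))
    sizes = ndi.sum_labels(bridged, labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    component = (labels == biggest) & supra  # bbox from real pixels only
    rows, cols = np.nonzero(component)
    return RectROI(int(rows.min()), int(rows.max()) + 1,
                   int(cols.min()), int(cols.max()) + 1)


def snr_at_threshold(threshold: float, noise_mean: float) -> float:
    """Signal-to-noise ratio implied by analysing only pixels above
    ``threshold`` given the dark-region mean ``noise_mean``.

    Callers choosing thresholds may assert the result is >= 10.
    """
    if noise_mean <= 0:
        raise ValueError("noise_mean must be positive")
    return threshold / noise_mean


def focus_score(thg_frame: np.ndarray) -> float:
    """Sharpness metric: variance of the discrete Laplacian normalised by
    the squared frame mean.  Higher is sharper; invariant under a global
    intensity gain; 0 for a constant frame."""
    frame = np.asarray(thg_frame, dtype=float)
    if frame.shape[0] < 8 or frame.shape[1] < 8:
        raise ValueError("frame must be at least 8x8")
    mean = frame.mean()
    if mean == 0 or np.ptp(frame) == 0:
        return 0.0
    lap = ndi.laplace(frame)
    return float(lap.var() / mean ** 2)


def detect_melanin_pieces(thg_frame: np.ndarray,
                          cytoplasm_mask: np.ndarray,
                          min_blob_px: int = 20) -> bool:
    """Detect THG-bright pieces indicating melanin accumulation.

    True when any connected blob of at least ``min_blob_px`` pixels inside
    or adjacent to the cytoplasm exceeds twice the cytoplasm median
    intensity.
    """
    frame = np.asarray(thg_frame, dtype=float)
    mask = np.asarray(cytoplasm_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cytoplasm mask")
    median = float(np.median(frame[mask]))
    near = ndi.binary_dilation(mask, iterations=2)
    bright = (frame > 2.0 * median) & near
    if not bright.any():
        return False
    labels, n = ndi.label(bright)
    sizes = ndi.sum_labels(bright, labels, index=np.arange(1, n + 1))
    return bool((sizes >= min_blob_px).any())


def _provisional_masks(thg: np.ndarray, shg: np.ndarray,
                       threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Coarse threshold-based cytoplasm/collagen proxies for previewing."""
    fiber = shg > threshold
    cyt = (thg > threshold) & ~ndi.binary_dilation(fiber, iterations=1)
    return cyt, fiber


def preview_stack(stack: HGMStack, dej_frames: list[int],
                  focus_floor: float = DEFAULT_FOCUS_FLOOR,
                  threshold: float = DEFAULT_THRESHOLD,
                  ratio_cutoff: float = MELANIN_RATIO_CUTOFF,
                  noise_guess: float = 150.0) -> PreviewDecision:
    """Previewing phase: decide whether a stack is worth analysing at all.

    Checks, on the DEJ frames, the focus metric against the admission
    floor, the melanin-piece detector, and a provisional noise-corrected
    ratio built from simple threshold masks (no manual exclusions).  A
    stack is admitted only when none of the three exclusion flags fires.
    """
    if not dej_frames:
        raise ValueError("dej_frames must be nonempty")
    if stack.n_depths == 0:
        raise ValueError("empty stack")
    scores, melanin_flags, ratios = [], [], []
    for z in dej_frames:
        thg = stack.thg[z].astype(float)
        shg = stack.shg[z].astype(float)
        scores.append(focus_score(thg))
        cyt, fiber = _provisional_masks(thg, shg, threshold)
        if cyt.any():
            melanin_flags.append(detect_melanin_pieces(thg, cyt))
        if cyt.any() and fiber.any():
            denom = thg[fiber].mean() - noise_guess
            if denom > 0:
                ratios.append((thg[cyt].mean() - noise_guess) / denom)
    score = float(np.median(scores))
    blurred = score < focus_floor
    melanin = any(melanin_flags)
    over = bool(ratios) and float(np.median(ratios)) > ratio_cutoff
    notes = f"median focus {score:.4g}"
    if ratios:
        notes += f"; provisional ratio {float(np.median(ratios)):.3f}"
    return PreviewDecision(blurred=blurred, melanin_pieces=melanin,
                           ratio_over_1p6=over, focus_score=score,
                           notes=notes)


def screen_subimage(stack: HGMStack, depth_index: int, roi: RectROI,
                    cell_count: int, orientation_coherence: float,
                    shg_threshold: float = DEFAULT_THRESHOLD,
                    coherence_floor: float = DEFAULT_COHERENCE_FLOOR,
                    coverage_min: float = 0.25,
                    min_cells: int = 10) -> SubimageQC:
    """Screening phase for one depth.

    Coverage is the fraction of ROI pixels whose SHG intensity exceeds the
    threshold; orientation is clear when the supplied structure-tensor
    coherence reaches the floor.  Qualification demands coverage strictly
    above 25%, clear orientation, and at least 10 cells.
    """
    if not 0 <= depth_index < stack.n_depths:
        raise IndexError(f"depth {depth_index} out of range")
    shg = stack.shg[depth_index]
    roi.validate_for(shg)
    crop = roi.crop(shg).astype(float)
    coverage = float((crop > shg_threshold).mean())
    return SubimageQC(
        depth_index=depth_index,
        shg_coverage_frac=coverage,
        orientation_clear=orientation_coherence >= coherence_floor,
        cell_count=cell_count,
        coverage_min=coverage_min,
        min_cells=min_cells,
    )


def qualify_stack(qc_records: list[SubimageQC],
                  min_qualified: int = 3) -> bool:
    """A stack enters the final results only with at least three
    qualified subimages."""
    return sum(r.qualified for r in qc_records) >= min_qualified
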