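"""Collagen, cytoplasm and nucleus segmentation.

Collagen fibers are segmented from the SHG channel as pixels that are
simultaneously suprathreshold and ridge-like; basal cells are segmented
from the THG channel by smoothing, Otsu foreground extraction and
distance-transform watershed, with the interior dark basin of each cell
taken as its nucleus.  Interactive edits are replaced by declarative
exclusion regions so that every "manual" step is reproducible.

All operations are per-frame and deterministic: identical inputs produce
identical masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max, structure_tensor
from skimage.filters import sato, threshold_otsu
from skimage.segmentation import watershed

from .qc_phases import DEFAULT_THRESHOLD, RectROI

__all__ = [
    "SegmentationMasks", "segment_collagen", "apply_exclusions",
    "segment_cells", "manual_select_cytoplasm", "count_cells",
    "orientation_coherence",
]

logger = logging.getLogger(__name__)

_CROSS = ndi.generate_binary_structure(2, 1)


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Remove connected components smaller than ``min_px`` pixels."""
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]

#: Minimum component sizes (pixels) at the 0.576 um/px acquisition scale.
MIN_FIBER_PX = 30
MIN_CELL_PX = 100
MIN_NUCLEUS_PX = 15


@dataclass
class SegmentationMasks:
    """Per-frame boolean masks plus the integer cell labelling.

    ``excluded`` records manually removed regions; pixels there never
    appear in a measurement mask.  ``cell_labels`` is 0 for background and
    a positive id per cell; every positive id has nonempty cytoplasm.
    """

    collagen: np.ndarray
    cytoplasm: np.ndarray
    nucleus: np.ndarray
    excluded: np.ndarray
    cell_labels: np.ndarray
    manual: bool = False

    def validate(self) -> None:
        if (self.collagen & self.cytoplasm).any():
            raise ValueError("collagen and cytoplasm masks overlap")
        if (self.nucleus & ~(self.cell_labels > 0)).any():
            raise ValueError("nucleus pixels outside cell regions")
        for m in (self.collagen, self.cytoplasm, self.nucleus):
            if (m & self.excluded).any():
                raise ValueError("excluded pixels leaked into a measurement mask")


def segment_collagen(shg_frame: np.ndarray, roi: RectROI,
                     threshold: float = DEFAULT_THRESHOLD,
                     min_size: int = MIN_FIBER_PX) -> np.ndarray:
    """Segment collagen fibers inside the ROI from the SHG channel.

    A pixel is labelled collagen when it is suprathreshold *and* its
    multiscale tubular-structure (Sato) filter response lies above that
    response's Otsu cut within the ROI; the result is cleaned by closing
    1-px gaps and dropping components below ``min_size``, and is empty
    outside the ROI.  No sub-threshold pixel can ever be labelled
    collagen (enforced on every call).
    """
    frame = np.asarray(shg_frame, dtype=float)
    roi.validate_for(frame)
    crop = roi.crop(frame)
    supra = crop > threshold
    if not supra.any():
        return np.zeros(frame.shape, dtype=bool)
    response = sato(crop, sigmas=(1.0, 2.0, 3.0), black_ridges=False)
    rcut = threshold_otsu(response) if np.ptp(response) > 0 else 0.0
    mask = supra & (response > rcut)
    mask = ndi.binary_closing(mask, structure=_CROSS)
    mask = _drop_small(mask, min_size)
    mask &= supra  # hard invariant: never below threshold
    out = np.zeros(frame.shape, dtype=bool)
    out[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop] = mask
    return out


def _region_mask(region, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an exclusion/selection region.

    Accepts a boolean mask of matching shape, a :class:`RectROI`, or an
    ``(N, 2)`` array of polygon vertices in (row, col) order.
    """
    if isinstance(region, RectROI):
        if region.row_stop > shape[0] or region.col_stop > shape[1]:
            raise ValueError(f"region {region} outside frame {shape}")
        m = np.zeros(shape, dtype=bool)
        m[region.row_start:region.row_stop, region.col_start:region.col_stop] = True
        return m
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != shape:
            raise ValueError(f"mask region shape {region.shape} != frame {shape}")
        return region
    verts = region.astype(float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("polygon region must be an (N, 2) vertex array")
    if (verts < 0).any() or (verts[:, 0] > shape[0]).any() \
            or (verts[:, 1] > shape[1]).any():
        raise ValueError("polygon vertices outside frame")
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def apply_exclusions(mask: np.ndarray, exclusions: list) -> np.ndarray:
    """Remove declared regions from a measurement mask.

    Never adds pixels; with an empty exclusion list this is the identity.
    The excluded area fraction is logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not exclusions:
        return mask.copy()
    union = np.zeros(mask.shape, dtype=bool)
    for region in exclusions:
        union |= _region_mask(region, mask.shape)
    removed = (mask & union).sum()
    if mask.sum():
        logger.info("exclusions removed %.1f%% of the mask",
                    100.0 * removed / mask.sum())
    return mask & ~union


def segment_cells(thg_frame: np.ndarray, roi: RectROI,
                  cell_diameter_px: float = 17.4,
                  min_cell_px: int = MIN_CELL_PX,
                  min_nucleus_px: int = MIN_NUCLEUS_PX,
                  shg_frame: np.ndarray | None = None,
                  shg_threshold: float = DEFAULT_THRESHOLD) -> SegmentationMasks:
    """Segment basal cells (cytoplasm + nucleus) inside the ROI from THG.

    Pipeline: Gaussian smoothing, Otsu foreground extraction, hole
    filling, distance-transform watershed with seeds at least half a cell
    diameter apart, removal of components below ``min_cell_px`` or
    touching the ROI border.  When the co-registered SHG frame is given,
    candidate cells that are mostly SHG-bright are vetoed as collagen
    picked up by the THG foreground.  Within each cell the nucleus is the
    interior dark basin (below the cell's own Otsu cut, at least
    ``min_nucleus_px`` pixels); the cytoplasm is the remaining bright part
    of the cell, with a 1-px guard ring around the nucleus to keep
    partial-volume pixels out of the intensity statistics.

    An empty foreground yields zero cells, not an error.
    """
    frame = np.asarray(thg_frame, dtype=float)
    roi.validate_for(frame)
    crop = roi.crop(frame)
    smoothed = ndi.gaussian_filter(crop, 1.0)
    out = SegmentationMasks(
        collagen=np.zeros(frame.shape, dtype=bool),
        cytoplasm=np.zeros(frame.shape, dtype=bool),
        nucleus=np.zeros(frame.shape, dtype=bool),
        excluded=np.zeros(frame.shape, dtype=bool),
        cell_labels=np.zeros(frame.shape, dtype=np.int32),
    )
    if np.ptp(smoothed) == 0:
        return out
    fg = smoothed > threshold_otsu(smoothed)
    fg = ndi.binary_fill_holes(fg)
    fg = _drop_small(fg, min_cell_px)
    if not fg.any():
        return out

    dist = ndi.distance_transform_edt(fg)
    min_dist = max(int(round(cell_diameter_px / 2)), 1)
    comp, ncomp = ndi.label(fg)
    peaks = peak_local_max(dist, min_distance=min_dist, labels=comp,
                           exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # every foreground component must receive at least one seed
    seeded = set(np.unique(comp[markers > 0]))
    missing = [c for c in range(1, ncomp + 1) if c not in seeded]
    if missing:
        nid = len(peaks)
        for c in missing:
            sel = comp == c
            flat = np.argmax(np.where(sel, dist, -1.0))
            nid += 1
            markers[np.unravel_index(flat, fg.shape)] = nid
    labels = watershed(-dist, markers, mask=fg)

    border = np.zeros(fg.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    drop = set(np.unique(labels[border])) - {0}
    if shg_frame is not None:
        shg_crop = roi.crop(np.asarray(shg_frame, dtype=float))
        fibery = ndi.binary_dilation(shg_crop > shg_threshold, iterations=1)
    else:
        fibery = None

    cyt = np.zeros(fg.shape, dtype=bool)
    nuc = np.zeros(fg.shape, dtype=bool)
    relabeled = np.zeros(fg.shape, dtype=np.int32)
    next_id = 0
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if lab in drop or region.sum() < min_cell_px:
            continue
        if fibery is not None:
            # Collagen picked up by the THG foreground: discard regions
            # that are mostly SHG-bright, strip fiber pixels from the rest.
            if fibery[region].mean() > 0.6:
                continue
            region = region & ~fibery
            if region.sum() < min_cell_px // 2:
                continue
        vals = crop[region]
        cut = threshold_otsu(vals) if np.ptp(vals) > 0 else -np.inf
        dark = region & (crop < cut)
        nucleus_i = np.zeros(fg.shape, dtype=bool)
        if dark.any():
            dlab, dn = ndi.label(dark)
            interior_ok = ndi.binary_erosion(region, border_value=0)
            for d in range(1, dn + 1):
                comp = dlab == d
                if comp.sum() >= min_nucleus_px and (comp <= interior_ok).all():
                    nucleus_i |= comp
        guard = ndi.binary_dilation(nucleus_i, iterations=1) \
            if nucleus_i.any() else np.zeros(fg.shape, dtype=bool)
        # Strip sub-cut pixels (membranes, partial-volume rims) from the
        # intensity statistics, but only when the cut actually separates a
        # dark subpopulation -- on a near-uniform bright cell Otsu would
        # just bisect the noise and bias the mean upward.
        if dark.sum() >= 0.05 * region.sum():
            cyt_i = region & (crop >= cut) & ~guard
        else:
            cyt_i = region & ~guard
        if not cyt_i.any():
            continue
        next_id += 1
        relabeled[region] = next_id
        cyt |= cyt_i
        nuc |= nucleus_i

    sl = (slice(roi.row_start, roi.row_stop), slice(roi.col_start, roi.col_stop))
    out.cytoplasm[sl] = cyt
    out.nucleus[sl] = nuc
    out.cell_labels[sl] = relabeled
    return out


def manual_select_cytoplasm(regions: list,
                            shape: tuple[int, int]) -> np.ndarray:
    """Union of declared regions as the cytoplasm mask (manual fallback
    when automatic detection leaves fewer than 10 cells).  Overlapping
    regions are not double counted."""
    if not regions:
        raise ValueError("manual selection requires at least one region")
    mask = np.zeros(shape, dtype=bool)
    for region in regions:
        mask |= _region_mask(region, shape)
    return mask


def count_cells(masks: SegmentationMasks) -> int:
    """Number of distinct cell labels that still have nonempty cytoplasm
    (after any exclusions)."""
    labels = masks.cell_labels[masks.cytoplasm & ~masks.excluded]
    return int(np.unique(labels[labels > 0]).size)


def orientation_coherence(shg_frame: np.ndarray, mask: np.ndarray,
                          sigma: float = 2.0) -> float:
    """Structure-tensor coherence of fiber orientation over a mask.

    Returns ``(l1 - l2) / (l1 + l2)`` for the eigenvalues of the
    mask-averaged smoothed gradient outer product: 1 for a single
    orientation, 0 for an isotropic texture.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 50:
        raise ValueError("mask must contain at least 50 pixels")
    frame = np.asarray(shg_frame, dtype=float)
    Arr, Arc, Acc = structure_tensor(frame, sigma=sigma, order="rc")
    jrr, jrc, jcc = Arr[mask].mean(), Arc[mask].mean(), Acc[mask].mean()
    trace = jrr + jcc
    if trace <= 0:
        return 0.0
    spread = np.hypot(jrr - jcc, 2.0 * jrc)
    return float(spread / trace)
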