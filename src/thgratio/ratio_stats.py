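"""Noise estimation, noise-corrected ratios and cohort aggregation.

The quantity of interest is the intrinsic basal-cell-cytoplasm to
collagen-fiber THG brightness ratio

    (THG_cytoplasm - noise) / (THG_collagen - noise)

where the noise term is the mean THG brightness outside the rectangular
ROI at a designated deep frame (index 80 by default, clamped to the
deepest frame for shorter stacks).  One noise value serves all subimages
of a stack.  Per-stack ratios are unweighted means over qualified
subimages; the cohort summary reports the mean and the standard error of
the mean over included stacks, with every excluded stack carrying an
explicit reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .qc_phases import RectROI, SubimageQC
from .stack_io import HGMStack

__all__ = [
    "RatioResult", "CohortSummary", "EXCLUSION_REASONS",
    "estimate_noise", "subimage_ratio", "stack_ratio", "inspect_stack",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_NOISE_DEPTH_INDEX = 80

EXCLUSION_REASONS = frozenset({
    "blurred", "melanin_pieces", "ratio_over_1p6", "no_roi",
    "insufficient_qualified_subimages",
})


@dataclass(frozen=True)
class RatioResult:
    """Noise-corrected ratio for one subimage."""

    depth_index: int
    thg_cytoplasm: float
    thg_collagen: float
    noise: float

    def __post_init__(self) -> None:
        if self.thg_collagen <= self.noise:
            raise ValueError(
                f"collagen mean {self.thg_collagen} does not exceed noise "
                f"{self.noise}: bad noise frame or failed segmentation")

    @property
    def ratio(self) -> float:
        return (self.thg_cytoplasm - self.noise) / (self.thg_collagen - self.noise)


@dataclass
class CohortSummary:
    """Cohort-level aggregation over included stacks."""

    stack_ratios: list[float]
    included_n: int
    excluded: list[tuple[str, str]]  # (stack id, reason)
    mean: float
    sem: float | None


def estimate_noise(stack: HGMStack, roi: RectROI,
                   noise_depth_index: int = DEFAULT_NOISE_DEPTH_INDEX) -> float:
    """Mean THG brightness outside the ROI at the designated deep frame.

    For stacks shorter than ``noise_depth_index + 1`` frames the deepest
    frame is used instead (and logged).
    """
    if stack.n_depths == 0:
        raise ValueError("empty stack")
    z = min(noise_depth_index, stack.n_depths - 1)
    if z != noise_depth_index:
        logger.info("noise frame clamped from %d to deepest frame %d",
                    noise_depth_index, z)
    frame = stack.thg[z].astype(float)
    roi.validate_for(frame)
    outside = roi.outside_mask(frame.shape)
    if not outside.any():
        raise ValueError("ROI covers the entire frame; no outside pixels")
    return float(frame[outside].mean())


def subimage_ratio(thg_frame: np.ndarray, cytoplasm_mask: np.ndarray,
                   collagen_mask: np.ndarray, noise: float,
                   depth_index: int = 0) -> RatioResult:
    """Masked means and the noise-corrected ratio for one subimage."""
    frame = np.asarray(thg_frame, dtype=float)
    cyt = np.asarray(cytoplasm_mask, dtype=bool)
    col = np.asarray(collagen_mask, dtype=bool)
    if not cyt.any():
        raise ValueError("empty cytoplasm mask")
    if not col.any():
        raise ValueError("empty collagen mask")
    return RatioResult(
        depth_index=depth_index,
        thg_cytoplasm=float(frame[cyt].mean()),
        thg_collagen=float(frame[col].mean()),
        noise=float(noise),
    )


def stack_ratio(results: list[RatioResult], qc: list[SubimageQC],
                min_qualified: int = 3) -> float:
    """Unweighted mean ratio over the qualified subimages of one stack.

    ``results`` and ``qc`` are matched by depth index; at least
    ``min_qualified`` qualified results are required.
    """
    qualified_depths = {r.depth_index for r in qc if r.qualified}
    kept = [r.ratio for r in results if r.depth_index in qualified_depths]
    if len(kept) < min_qualified:
        raise ValueError(
            f"only {len(kept)} qualified subimages; need {min_qualified}")
    return float(np.mean(kept))


def inspect_stack(stack_mean_ratio: float, cutoff: float = 1.6) -> bool:
    """Inspecting phase: a stack is included unless its mean ratio is
    strictly above the melanin cutoff (phototype-I level 1.6)."""
    if not math.isfinite(stack_mean_ratio):
        raise ValueError("ratio must be finite")
    return stack_mean_ratio <= cutoff


def cohort_summary(per_stack: list[tuple[str, float | str]]) -> CohortSummary:
    """Aggregate per-stack outcomes into the cohort mean +- SEM.

    Each entry is ``(stack id, ratio)`` for an included stack or
    ``(stack id, reason)`` for an excluded one.  SEM uses the n-1 sample
    standard deviation and is ``None`` for a single included stack.
    """
    ratios: list[float] = []
    excluded: list[tuple[str, str]] = []
    for sid, outcome in per_stack:
        if isinstance(outcome, str):
            if outcome not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {outcome!r}")
            excluded.append((sid, outcome))
        else:
            ratios.append(float(outcome))
    if not ratios:
        raise ValueError("no included stacks; cohort mean undefined")
    mean = float(np.mean(ratios))
    sem = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios))) \
        if len(ratios) >= 2 else None
    return CohortSummary(stack_ratios=ratios, included_n=len(ratios),
                         excluded=excluded, mean=mean, sem=sem)
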