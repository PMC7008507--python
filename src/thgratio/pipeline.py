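"""End-to-end orchestration of the five analysis phases, plus the
seven-point Physician Global Assessment (PGA) score lookup.

``run_pipeline`` drives, for every input stack: previewing, ROI
selection, per-depth segmentation and screening, noise estimation,
per-subimage ratios, the stack mean, the inspecting-phase exclusion, and
finally the cohort aggregation.  Phases never mutate their inputs; every
stack appears in the report exactly once, either included or excluded
with a reason, and every numeric constant comes from the
:class:`RunConfig` so re-running an identical configuration is
bit-identical.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc_phases, ratio_stats, segmentation, synthetic_skin
from .qc_phases import NoROIError, RectROI, SubimageQC
from .ratio_stats import CohortSummary, RatioResult
from .stack_io import HGMStack, read_stack

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "process_stack",
           "pga_score", "pga_descriptor", "PGA_TABLE"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of the five-phase protocol in one place.

    ``inputs`` is a list of stack sources, each either
    ``{"path": <tiff>, "dej_depth_window": [lo, hi]}`` or
    ``{"preset": <name>, "seed": <int>}`` (the DEJ window of a generated
    stack comes from its ground truth).
    """

    inputs: list = field(default_factory=list)
    dej_depth_window: tuple[int, int] | None = None  # inclusive, for files
    roi_threshold: float = 1600.0
    roi_method: str = "fixed"
    shg_coverage_min: float = 0.25
    min_cells: int = 10
    min_qualified_subimages: int = 3
    melanin_ratio_cutoff: float = 1.6
    noise_depth_index: int = 80
    coherence_floor: float = 0.3
    focus_floor: float = 0.01
    cell_diameter_px: float = 17.4
    manual_exclusions: dict = field(default_factory=dict)  # stack id -> regions
    manual_cytoplasm: dict = field(default_factory=dict)   # stack id -> regions
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("roi_threshold", "shg_coverage_min", "min_cells",
                     "min_qualified_subimages", "melanin_ratio_cutoff",
                     "coherence_floor", "focus_floor", "cell_diameter_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_depth_index < 0:
            raise ValueError("noise_depth_index must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dej_depth_window" in raw and raw["dej_depth_window"] is not None:
            raw["dej_depth_window"] = tuple(raw["dej_depth_window"])
        for key in ("manual_exclusions", "manual_cytoplasm"):
            regions = raw.get(key) or {}
            raw[key] = {
                sid: [np.asarray(poly, dtype=float) for poly in polys]
                for sid, polys in regions.items()
            }
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: CohortSummary
    stack_table: pd.DataFrame
    subimage_table: pd.DataFrame


def _load_input(entry: dict, config: RunConfig,
                index: int) -> tuple[str, HGMStack, list[int]]:
    if "path" in entry:
        stack = read_stack(entry["path"])
        window = entry.get("dej_depth_window") or config.dej_depth_window
        if window is None:
            raise ValueError(
                f"input {entry['path']}: no DEJ depth window configured")
        lo, hi = int(window[0]), int(window[1])
        if not 0 <= lo <= hi < stack.n_depths:
            raise ValueError(f"DEJ window {window} outside stack depth")
        return str(entry.get("id", entry["path"])), stack, list(range(lo, hi + 1))
    if "preset" in entry:
        seed = int(entry.get("seed", config.seed))
        params = synthetic_skin.preset(entry["preset"], seed=seed)
        stack, truth = synthetic_skin.generate_stack(params)
        sid = str(entry.get("id", f"{entry['preset']}-{seed}"))
        return sid, stack, list(truth.dej_frames)
    if "params" in entry:  # programmatic use with explicit conditions
        stack, truth = synthetic_skin.generate_stack(entry["params"])
        sid = str(entry.get("id", f"params-{entry['params'].seed}"))
        return sid, stack, list(truth.dej_frames)
    raise ValueError(f"input entry {index} needs a 'path' or a 'preset'")


def process_stack(stack: HGMStack, dej_frames: list[int], config: RunConfig,
                  stack_id: str = "stack"):
    """Run phases 1-5 on one stack.

    Returns ``(outcome, stack_row, subimage_rows)`` where ``outcome`` is
    the per-stack mean ratio (float) or an exclusion reason (str).
    """
    rows: list[dict] = []
    base = {"stack_id": stack_id}

    decision = qc_phases.preview_stack(
        stack, dej_frames, focus_floor=config.focus_floor,
        threshold=config.roi_threshold,
        ratio_cutoff=config.melanin_ratio_cutoff)
    if not decision.admitted:
        reason = ("blurred" if decision.blurred
                  else "melanin_pieces" if decision.melanin_pieces
                  else "ratio_over_1p6")
        row = dict(base, outcome="excluded", reason=reason,
                   focus_score=decision.focus_score, noise=np.nan,
                   ratio=np.nan, n_qualified=0)
        return reason, row, rows

    mid = dej_frames[len(dej_frames) // 2]
    try:
        roi = qc_phases.select_roi(stack.thg[mid],
                                   threshold=config.roi_threshold,
                                   method=config.roi_method)
    except NoROIError:
        row = dict(base, outcome="excluded", reason="no_roi",
                   focus_score=decision.focus_score, noise=np.nan,
                   ratio=np.nan, n_qualified=0)
        return "no_roi", row, rows

    exclusions = config.manual_exclusions.get(stack_id, [])
    qc_records: list[SubimageQC] = []
    masks_by_depth: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for z in dej_frames:
        shg_z = stack.shg[z].astype(float)
        thg_z = stack.thg[z].astype(float)
        collagen = segmentation.segment_collagen(
            shg_z, roi, threshold=config.roi_threshold)
        collagen = segmentation.apply_exclusions(collagen, exclusions)
        cells = segmentation.segment_cells(
            thg_z, roi, cell_diameter_px=config.cell_diameter_px,
            shg_frame=shg_z, shg_threshold=config.roi_threshold)
        cytoplasm = cells.cytoplasm & ~collagen
        cells.cytoplasm = cytoplasm
        n_cells = segmentation.count_cells(cells)
        manual = False
        manual_regions = config.manual_cytoplasm.get(stack_id)
        if n_cells < config.min_cells and manual_regions:
            cytoplasm = segmentation.manual_select_cytoplasm(
                manual_regions, thg_z.shape) & ~collagen
            manual = True
        if collagen.sum() >= 50:
            coherence = segmentation.orientation_coherence(shg_z, collagen)
        else:
            coherence = 0.0
        qc = qc_phases.screen_subimage(
            stack, z, roi, cell_count=n_cells,
            orientation_coherence=coherence,
            shg_threshold=config.roi_threshold,
            coherence_floor=config.coherence_floor,
            coverage_min=config.shg_coverage_min,
            min_cells=config.min_cells)
        qc_records.append(qc)
        masks_by_depth[z] = (cytoplasm, collagen)
        rows.append(dict(base, depth_index=z,
                         shg_coverage_frac=qc.shg_coverage_frac,
                         coherence=coherence, cell_count=n_cells,
                         qualified=qc.qualified, manual_cytoplasm=manual))

    if not qc_phases.qualify_stack(qc_records, config.min_qualified_subimages):
        row = dict(base, outcome="excluded",
                   reason="insufficient_qualified_subimages",
                   focus_score=decision.focus_score, noise=np.nan,
                   ratio=np.nan,
                   n_qualified=sum(r.qualified for r in qc_records))
        return "insufficient_qualified_subimages", row, rows

    noise = ratio_stats.estimate_noise(stack, roi, config.noise_depth_index)
    results: list[RatioResult] = []
    for qc in qc_records:
        if not qc.qualified:
            continue
        cytoplasm, collagen = masks_by_depth[qc.depth_index]
        try:
            results.append(ratio_stats.subimage_ratio(
                stack.thg[qc.depth_index].astype(float), cytoplasm, collagen,
                noise, depth_index=qc.depth_index))
        except ValueError as exc:
            logger.warning("%s depth %d dropped: %s", stack_id,
                           qc.depth_index, exc)
    try:
        mean_ratio = ratio_stats.stack_ratio(
            results, qc_records, config.min_qualified_subimages)
    except ValueError:
        row = dict(base, outcome="excluded",
                   reason="insufficient_qualified_subimages",
                   focus_score=decision.focus_score, noise=noise,
                   ratio=np.nan, n_qualified=len(results))
        return "insufficient_qualified_subimages", row, rows

    included = ratio_stats.inspect_stack(mean_ratio,
                                         config.melanin_ratio_cutoff)
    row = dict(base, outcome="included" if included else "excluded",
               reason="" if included else "ratio_over_1p6",
               focus_score=decision.focus_score, noise=noise,
               ratio=mean_ratio, n_qualified=len(results))
    return (mean_ratio if included else "ratio_over_1p6"), row, rows


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full protocol over every configured input stack."""
    if not config.inputs:
        raise ValueError("no input stacks configured")
    per_stack: list[tuple[str, float | str]] = []
    stack_rows: list[dict] = []
    sub_rows: list[dict] = []
    for i, entry in enumerate(config.inputs):
        sid, stack, dej_frames = _load_input(entry, config, i)
        outcome, row, rows = process_stack(stack, dej_frames, config, sid)
        per_stack.append((sid, outcome))
        stack_rows.append(row)
        sub_rows.extend(rows)
        logger.info("%s: %s", sid,
                    f"ratio {outcome:.3f}" if isinstance(outcome, float)
                    else f"excluded ({outcome})")
    summary = ratio_stats.cohort_summary(per_stack)
    result = PipelineResult(summary=summary,
                            stack_table=pd.DataFrame(stack_rows),
                            subimage_table=pd.DataFrame(sub_rows))
    if config.output_dir:
        _write_reports(result, Path(config.output_dir))
    return result


def _write_reports(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.stack_table.to_csv(outdir / "stacks.tsv", sep="\t", index=False)
    result.subimage_table.to_csv(outdir / "subimages.tsv", sep="\t",
                                 index=False)
    s = result.summary
    (outdir / "summary.json").write_text(json.dumps({
        "mean": round(s.mean, 3),
        "sem": round(s.sem, 3) if s.sem is not None else None,
        "included_n": s.included_n,
        "excluded": [list(e) for e in s.excluded],
    }, indent=2))


# --------------------------------------------------------------------------
# Seven-point Physician Global Assessment score

#: Canonical descriptor for each PGA score.
PGA_TABLE: dict[int, str] = {
    -2: "Disease progression as patches",
    -1: "Active border extension",
    0: "No change",
    1: "Round follicular repigmentation",
    2: "Perifollicular repigmentation with confluence <10% of the lesion",
    3: "Repigmentation between 10% and 90% of the lesion",
    4: "Repigmentation with confluence >90% of the lesion",
}


def _normalize(text: str) -> str:
    t = re.sub(r"\s+", " ", text.strip().lower())
    # The short caption form omits the trailing qualifier.
    return re.sub(r" of the lesion$", "", t)


_PGA_LOOKUP = {_normalize(desc): score for score, desc in PGA_TABLE.items()}


def pga_score(descriptor: str) -> int:
    """Map a canonical seven-point PGA descriptor to its score.

    Matching is case-insensitive and whitespace-normalised, and accepts
    the short form without the trailing "of the lesion"; anything else is
    rejected (no fuzzy matching).
    """
    key = _normalize(descriptor)
    if key not in _PGA_LOOKUP:
        raise KeyError(f"unrecognised PGA descriptor {descriptor!r}")
    return _PGA_LOOKUP[key]


def pga_descriptor(score: int) -> str:
    """Canonical descriptor text for a PGA score in [-2, 4]."""
    if score not in PGA_TABLE:
        raise KeyError(f"PGA score must be in [-2, 4], got {score}")
    return PGA_TABLE[score]
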