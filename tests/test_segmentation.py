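"""Segmentation operators scored against generator ground truth."""

import numpy as np
import pytest

from thgratio import segmentation as seg
from thgratio import synthetic_skin as ss
from thgratio.qc_phases import RectROI
from conftest import small_params


def _dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="module")
def single_fiber():
    params = small_params(seed=4, cell_count=0, fiber_count=1,
                          n_depths=1, dej_depth_index=0, dej_band=1,
                          noise_sd=30.0)
    return ss.generate_stack(params)


@pytest.fixture(scope="module")
def single_cell():
    params = small_params(seed=4, cell_count=1, fiber_count=0,
                          n_depths=1, dej_depth_index=0, dej_band=1,
                          noise_sd=30.0)
    return ss.generate_stack(params)


# ------------------------------------------------------------ segment_collagen

def test_blank_frame_yields_empty_collagen_mask():
    frame = np.full((64, 64), 150.0)
    roi = RectROI(0, 64, 0, 64)
    assert not seg.segment_collagen(frame, roi).any()


def test_single_fiber_recovered_with_good_overlap(single_fiber):
    stack, truth = single_fiber
    side = stack.shg.shape[1]
    roi = RectROI(0, side, 0, side)
    mask = seg.segment_collagen(stack.shg[0].astype(float), roi)
    assert _dice(mask, truth.collagen_mask[0]) >= 0.7


def test_collagen_mask_never_contains_subthreshold_pixels(cohort_stack):
    stack, truth = cohort_stack
    z = truth.dej_frames[-1] + 4  # dermal frame below the junction
    frame = stack.shg[z].astype(float)
    roi = RectROI(24, 232, 24, 232)
    mask = seg.segment_collagen(frame, roi)
    assert mask.any()
    assert (frame[mask] > 1600).all()


# ------------------------------------------------------------ apply_exclusions

def test_empty_exclusion_list_is_identity():
    mask = np.zeros((32, 32), dtype=bool)
    mask[4:20, 4:20] = True
    out = seg.apply_exclusions(mask, [])
    np.testing.assert_array_equal(out, mask)


def test_full_frame_exclusion_empties_mask():
    mask = np.ones((32, 32), dtype=bool)
    out = seg.apply_exclusions(mask, [RectROI(0, 32, 0, 32)])
    assert not out.any()


def test_exclusion_area_bookkeeping_matches_overlap():
    """Removing a capillary-wall-like rectangle shrinks the mask by
    exactly the overlap, never adds pixels."""
    rng = np.random.default_rng(1)
    mask = rng.random((64, 64)) > 0.5
    region = RectROI(10, 30, 20, 50)
    rmask = np.zeros((64, 64), dtype=bool)
    rmask[10:30, 20:50] = True
    out = seg.apply_exclusions(mask, [region])
    assert out.sum() == mask.sum() - (mask & rmask).sum()
    assert not (out & ~mask).any()


def test_exclusion_region_outside_frame_rejected():
    mask = np.ones((16, 16), dtype=bool)
    with pytest.raises(ValueError):
        seg.apply_exclusions(mask, [RectROI(0, 32, 0, 32)])
    with pytest.raises(ValueError):
        seg.apply_exclusions(mask, [np.array([[0, 0], [0, 40], [40, 40]])])


# --------------------------------------------------------------- segment_cells

def test_cells_recovered_on_synthetic_junction_frame(cohort_stack):
    stack, truth = cohort_stack
    z = truth.dej_frames[1]
    roi = RectROI(10, 246, 10, 246)
    masks = seg.segment_cells(stack.thg[z].astype(float), roi,
                              shg_frame=stack.shg[z].astype(float))
    n = seg.count_cells(masks)
    assert 0.7 * 30 <= n <= 1.3 * 30  # configured 30 cells per frame
    assert _dice(masks.cytoplasm, truth.cytoplasm_mask[z]) >= 0.6
    masks.validate()


def test_blank_frame_yields_zero_cells():
    frame = np.full((64, 64), 150.0)
    masks = seg.segment_cells(frame, RectROI(0, 64, 0, 64))
    assert seg.count_cells(masks) == 0


def test_single_cell_scene_yields_one_label_with_interior_nucleus(single_cell):
    stack, truth = single_cell
    side = stack.thg.shape[1]
    masks = seg.segment_cells(stack.thg[0].astype(float),
                              RectROI(0, side, 0, side))
    assert seg.count_cells(masks) == 1
    assert masks.nucleus.any()
    cell = masks.cell_labels > 0
    assert (masks.nucleus <= cell).all()
    assert not (masks.nucleus & masks.cytoplasm).any()


def test_segmentation_is_deterministic(small_stack):
    stack, truth = small_stack
    z = truth.dej_frames[0]
    roi = RectROI(8, 120, 8, 120)
    a = seg.segment_cells(stack.thg[z].astype(float), roi)
    b = seg.segment_cells(stack.thg[z].astype(float), roi)
    np.testing.assert_array_equal(a.cell_labels, b.cell_labels)
    np.testing.assert_array_equal(a.cytoplasm, b.cytoplasm)
    c1 = seg.segment_collagen(stack.shg[z].astype(float), roi)
    c2 = seg.segment_collagen(stack.shg[z].astype(float), roi)
    np.testing.assert_array_equal(c1, c2)


def test_cytoplasm_mean_recovers_configured_expectation():
    """Over 10 melanin-free scenes the segmented-cytoplasm THG mean stays
    within 3% of the generator's configured 1809."""
    vals = []
    for seed in range(10):
        params = small_params(seed=seed)
        stack, truth = ss.generate_stack(params)
        z = truth.dej_frames[1]
        roi = RectROI(8, 120, 8, 120)
        masks = seg.segment_cells(stack.thg[z].astype(float), roi,
                                  shg_frame=stack.shg[z].astype(float))
        if masks.cytoplasm.any():
            vals.append(stack.thg[z][masks.cytoplasm].mean())
    assert len(vals) >= 8
    assert np.mean(vals) == pytest.approx(1809, rel=0.03)


def test_count_cells_after_excluding_whole_cells():
    """Excluding 3 of 12 cells leaves 9 countable cells."""
    labels = np.zeros((60, 80), dtype=np.int32)
    cyt = np.zeros((60, 80), dtype=bool)
    for i in range(12):
        r, c = 10 + 20 * (i // 4), 10 + 20 * (i % 4)
        labels[r:r + 8, c:c + 8] = i + 1
        cyt[r:r + 8, c:c + 8] = True
    masks = seg.SegmentationMasks(
        collagen=np.zeros_like(cyt), cytoplasm=cyt,
        nucleus=np.zeros_like(cyt), excluded=np.zeros_like(cyt),
        cell_labels=labels)
    assert seg.count_cells(masks) == 12
    masks.excluded[:20, :] = True  # first row of 4... covers labels 1-4
    masks.cytoplasm &= ~masks.excluded
    assert seg.count_cells(masks) == 8
    masks.validate()


# ------------------------------------------------------ manual_select_cytoplasm

def test_manual_selection_unions_without_double_counting():
    a = np.array([[0, 0], [0, 20], [10, 20], [10, 0]])
    b = np.array([[30, 30], [30, 50], [40, 50], [40, 30]])
    mask = seg.manual_select_cytoplasm([a, b], (64, 64))
    overlap = seg.manual_select_cytoplasm([a, a], (64, 64))
    assert mask.sum() == (seg.manual_select_cytoplasm([a], (64, 64)).sum()
                          + seg.manual_select_cytoplasm([b], (64, 64)).sum())
    assert overlap.sum() == seg.manual_select_cytoplasm([a], (64, 64)).sum()
    with pytest.raises(ValueError):
        seg.manual_select_cytoplasm([], (64, 64))


def test_manual_truth_regions_reproduce_truth_ratio(small_stack):
    """Feeding the generator's own masks through the ratio path returns
    exactly the masked-mean ratio."""
    from thgratio.ratio_stats import subimage_ratio
    stack, truth = small_stack
    z = truth.dej_frames[1]
    thg = stack.thg[z].astype(float)
    cyt = seg.manual_select_cytoplasm([truth.cytoplasm_mask[z]], thg.shape)
    res = subimage_ratio(thg, cyt, truth.collagen_mask[z], noise=150.0)
    direct = ((thg[truth.cytoplasm_mask[z]].mean() - 150)
              / (thg[truth.collagen_mask[z]].mean() - 150))
    assert res.ratio == pytest.approx(direct, rel=1e-12)


# -------------------------------------------------------- orientation_coherence

def test_single_straight_fiber_is_highly_coherent():
    frame = np.full((64, 64), 150.0)
    frame[30:34, :] = 3000.0
    mask = np.zeros((64, 64), dtype=bool)
    mask[26:38, :] = True
    assert seg.orientation_coherence(frame, mask) > 0.8


def test_isotropic_noise_is_incoherent():
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        frame = rng.normal(1000, 200, (64, 64))
        vals.append(seg.orientation_coherence(frame, np.ones((64, 64), bool)))
    assert np.mean(vals) < 0.2


def test_coherence_invariant_under_quarter_rotation(cohort_stack):
    stack, truth = cohort_stack
    z = truth.dej_frames[0]
    frame = stack.shg[z].astype(float)
    mask = truth.collagen_mask[z]
    c1 = seg.orientation_coherence(frame, mask)
    c2 = seg.orientation_coherence(np.rot90(frame), np.rot90(mask))
    assert c2 == pytest.approx(c1, abs=1e-6)


def test_undersized_mask_rejected():
    with pytest.raises(ValueError):
        seg.orientation_coherence(np.zeros((32, 32)),
                                  np.zeros((32, 32), dtype=bool))
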