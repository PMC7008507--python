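"""Previewing, ROI selection and screening rules."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st

from thgratio import qc_phases as qc
from thgratio.qc_phases import RectROI, SubimageQC
from thgratio.stack_io import AcquisitionMeta, HGMStack
from conftest import small_preset


# ---------------------------------------------------------------- select_roi

def test_roi_is_bounding_box_of_solid_block():
    frame = np.full((512, 512), 150.0)
    frame[100:400, 120:380] = 3000.0
    roi = qc.select_roi(frame, threshold=1600)
    assert (roi.row_start, roi.row_stop, roi.col_start, roi.col_stop) \
        == (100, 400, 120, 380)


def test_uniform_noise_floor_frame_has_no_roi():
    with pytest.raises(qc.NoROIError):
        qc.select_roi(np.full((64, 64), 150.0), threshold=1600)


def test_roi_on_synthetic_junction_excludes_dim_border(cohort_stack):
    stack, truth = cohort_stack
    z = truth.dej_frames[2]
    frame = stack.thg[z].astype(float)
    roi = qc.select_roi(frame)
    outside = roi.outside_mask(frame.shape)
    # every pixel left outside is below threshold after the cleanup
    cleaned = qc._majority(frame > 1600)
    assert not (cleaned & outside).any()


def test_roi_idempotent_on_its_own_crop(cohort_stack):
    stack, truth = cohort_stack
    frame = stack.thg[truth.dej_frames[2]].astype(float)
    roi = qc.select_roi(frame)
    again = qc.select_roi(roi.crop(frame))
    assert again.row_stop - again.row_start <= roi.row_stop - roi.row_start
    assert again.col_stop - again.col_start <= roi.col_stop - roi.col_start


def test_roi_otsu_method_runs_without_explicit_threshold():
    frame = np.full((64, 64), 150.0)
    frame[20:40, 20:40] = 3000.0
    roi = qc.select_roi(frame, method="otsu")
    assert (roi.row_start, roi.row_stop) == (20, 40)


def test_degenerate_roi_bounds_rejected():
    with pytest.raises(ValueError):
        RectROI(5, 5, 0, 10)


# ----------------------------------------------------------- snr_at_threshold

def test_snr_of_published_threshold_meets_desired_floor():
    snr = qc.snr_at_threshold(1600, 150)
    assert snr == pytest.approx(1600 / 150)
    assert snr >= 10


def test_snr_boundary_and_identity():
    assert qc.snr_at_threshold(1500, 150) == pytest.approx(10.0)
    assert qc.snr_at_threshold(321.5, 321.5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        qc.snr_at_threshold(1600, 0)


@settings(max_examples=50, derandomize=True)
@given(t=st.floats(1, 1e4), n=st.floats(1, 1e4), k=st.floats(1e-3, 1e3))
def test_snr_scale_invariant(t, n, k):
    assert qc.snr_at_threshold(k * t, k * n) \
        == pytest.approx(qc.snr_at_threshold(t, n), rel=1e-9)


# ----------------------------------------------------------------- focus_score

def test_focus_zero_on_constant_frame():
    assert qc.focus_score(np.full((32, 32), 900.0)) == 0.0


def test_focus_drops_under_blur_and_ignores_gain(cohort_stack):
    stack, truth = cohort_stack
    frame = stack.thg[truth.dej_frames[2]].astype(float)
    sharp = qc.focus_score(frame)
    blurred = qc.focus_score(ndi.gaussian_filter(frame, 8.0))
    assert sharp > blurred
    assert qc.focus_score(2.0 * frame) == pytest.approx(sharp, rel=1e-9)


def test_focus_requires_minimum_frame():
    with pytest.raises(ValueError):
        qc.focus_score(np.zeros((4, 4)))


# ------------------------------------------------------- detect_melanin_pieces

def test_melanin_pieces_found_in_melanin_scene(small_melanin_stack):
    stack, truth = small_melanin_stack
    hits = [qc.detect_melanin_pieces(stack.thg[z].astype(float),
                                     truth.cytoplasm_mask[z])
            for z in truth.dej_frames]
    assert any(hits)


def test_no_melanin_pieces_in_melanin_free_scene(small_stack):
    stack, truth = small_stack
    for z in truth.dej_frames:
        assert not qc.detect_melanin_pieces(stack.thg[z].astype(float),
                                            truth.cytoplasm_mask[z])


def test_uniform_cytoplasm_has_no_pieces_and_empty_mask_errors():
    frame = np.full((32, 32), 1800.0)
    mask = np.zeros((32, 32), dtype=bool)
    mask[8:24, 8:24] = True
    assert not qc.detect_melanin_pieces(frame, mask)
    with pytest.raises(ValueError):
        qc.detect_melanin_pieces(frame, np.zeros((32, 32), dtype=bool))


# ---------------------------------------------------------------- preview_stack

def test_preview_admits_melanin_free_and_rejects_defect_presets(
        small_stack, small_melanin_stack):
    stack, truth = small_stack
    assert qc.preview_stack(stack, list(truth.dej_frames)).admitted
    mstack, mtruth = small_melanin_stack
    dec = qc.preview_stack(mstack, list(mtruth.dej_frames))
    assert not dec.admitted
    assert dec.melanin_pieces or dec.ratio_over_1p6


def test_preview_flags_blurred_stack():
    from thgratio import synthetic_skin as ss
    stack, truth = ss.generate_stack(small_preset("blurred", seed=3))
    dec = qc.preview_stack(stack, list(truth.dej_frames))
    assert dec.blurred and not dec.admitted


def test_preview_requires_frames(small_stack):
    with pytest.raises(ValueError):
        qc.preview_stack(small_stack[0], [])


# --------------------------------------------------------------- screen/qualify

def _coverage_stack(frac, side=16):
    """Two-channel stack whose single SHG frame has ``frac`` of the ROI
    above threshold (to the nearest whole pixel)."""
    n_supra = int(round(frac * side * side))
    shg = np.full((1, side, side), 150, dtype=np.uint16)
    shg.reshape(1, -1)[0, :n_supra] = 3000
    thg = np.full((1, side, side), 150, dtype=np.uint16)
    meta = AcquisitionMeta(pixel_count_xy=side, field_of_view_um=side * 0.576)
    return HGMStack(shg=shg, thg=thg, meta=meta)


@pytest.mark.parametrize("frac,cells,clear,expect", [
    (0.25, 12, True, False),       # coverage must be strictly above 25%
    (0.26171875, 10, True, True),  # 67/256 px; 10 cells is the minimum
    (0.90, 9, True, False),        # one cell short
    (0.40, 15, False, False),      # orientation unclear
])
def test_screening_boundaries_are_strict(frac, cells, clear, expect):
    stack = _coverage_stack(frac)
    roi = RectROI(0, 16, 0, 16)
    qc_rec = qc.screen_subimage(stack, 0, roi, cell_count=cells,
                                orientation_coherence=0.5 if clear else 0.1)
    exact = (stack.shg[0] > 1600).sum() / roi.area
    assert qc_rec.shg_coverage_frac == pytest.approx(exact)
    assert qc_rec.qualified is expect


def test_coverage_equals_brute_force_pixel_count():
    rng = np.random.default_rng(0)
    side = 16
    shg = rng.integers(0, 4000, (1, side, side)).astype(np.uint16)
    thg = np.full((1, side, side), 150, dtype=np.uint16)
    meta = AcquisitionMeta(pixel_count_xy=side, field_of_view_um=side * 0.576)
    stack = HGMStack(shg=shg, thg=thg, meta=meta)
    roi = RectROI(2, 13, 3, 15)
    rec = qc.screen_subimage(stack, 0, roi, cell_count=10,
                             orientation_coherence=0.5)
    count = 0
    for r in range(2, 13):
        for c in range(3, 15):
            if shg[0, r, c] > 1600:
                count += 1
    assert rec.shg_coverage_frac == pytest.approx(count / roi.area)


def _rec(q):
    return SubimageQC(depth_index=0, shg_coverage_frac=0.5 if q else 0.0,
                      orientation_clear=True, cell_count=12)


def test_qualify_requires_three_qualified_subimages():
    assert qc.qualify_stack([_rec(True)] * 3 + [_rec(False)] * 2)
    assert not qc.qualify_stack([_rec(True)] * 2 + [_rec(False)] * 8)
    assert not qc.qualify_stack([])


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.booleans(), max_size=12))
def test_qualify_monotone_in_added_qualified_record(flags):
    records = [_rec(f) for f in flags]
    before = qc.qualify_stack(records)
    after = qc.qualify_stack(records + [_rec(True)])
    assert after >= before  # adding a qualified record never flips True->False
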