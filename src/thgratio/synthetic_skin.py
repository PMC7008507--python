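"""Synthetic two-channel skin stacks with exact ground truth.

The generator emulates the statistical structure the ratiometry pipeline
assumes of an in-vivo harmonic-generation stack of skin:

* epidermal frames holding a mosaic of polygonal basal cells with
  THG-bright cytoplasm, dark elliptical nuclei and dark intercellular
  boundaries;
* a dermal–epidermal-junction (DEJ) band where the cell mosaic sits next
  to oriented collagen fibers that are bright in SHG and carry a weaker
  co-registered THG signal;
* deeper dermal frames dominated by fibers whose signal decays
  exponentially with depth;
* radial edge vignetting that multiplies the optical signal but not the
  detector noise, and an additive Gaussian photomultiplier noise floor
  with mean ~150 grayscale everywhere.

Scene content is confined to a central disc well inside the vignetted
border, mirroring the fact that only the optically uniform centre of a
scanned field is analysable; the frame corners therefore contain pure
detector noise.  Every rendered structure is returned as a boolean truth
mask, so segmentation and ratio recovery can be scored against a known
answer.  Identical parameters and seed reproduce a stack voxel for voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .stack_io import AcquisitionMeta, HGMStack

__all__ = ["SkinSceneParams", "SyntheticTruth", "generate_stack", "preset",
           "PRESET_NAMES"]

_MAX_GRAY = 16383
# Rendered grayscale of dark intercellular boundaries and of melanin caps.
_BOUNDARY_GRAY = 300.0
_MELANIN_GRAY = 8000.0


@dataclass(frozen=True)
class SkinSceneParams:
    """Generative conditions for one synthetic stack.

    The defaults are the melanin-free (vitiligo) study conditions: the
    cytoplasm and collagen THG expectations of 1809 and 1650 grayscale
    together with the 150 noise floor give a true noise-corrected ratio of
    (1809-150)/(1650-150) = 1.106.
    """

    n_depths: int = 96
    dej_depth_index: int = 24
    dej_band: int = 5
    pixel_count: int = 256
    cell_count: int = 30
    cell_diameter_um: float = 10.0
    cytoplasm_mean: float = 1809.0
    nucleus_mean: float = 450.0
    collagen_shg_mean: float = 3500.0
    collagen_thg_mean: float = 1650.0
    fiber_count: int = 60
    fiber_orientation_kappa: float = 8.0
    fiber_radius_px: float = 2.0
    fiber_edge_sigma_px: float = 0.4
    noise_floor_mean: float = 150.0
    noise_sd: float = 60.0
    vignette_radius_frac: float = 0.75
    content_radius_frac: float = 0.82
    attenuation_length_um: float = 20.0
    melanin_fraction: float = 0.0
    blur_sigma_px: float = 0.0
    z_step_um: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_depths < 1:
            raise ValueError("n_depths must be >= 1")
        if not 0 <= self.dej_depth_index < self.n_depths:
            raise ValueError("dej_depth_index must lie within the stack")
        if self.dej_depth_index + self.dej_band > self.n_depths:
            raise ValueError("DEJ band extends past the last frame")
        if self.pixel_count < 32:
            raise ValueError("pixel_count must be >= 32")
        for name in ("cytoplasm_mean", "nucleus_mean", "collagen_shg_mean",
                     "collagen_thg_mean", "noise_floor_mean"):
            v = getattr(self, name)
            if not 0 <= v <= _MAX_GRAY:
                raise ValueError(f"{name}={v} outside [0, {_MAX_GRAY}]")
        if self.cytoplasm_mean <= self.noise_floor_mean:
            raise ValueError("cytoplasm_mean must exceed noise_floor_mean")
        if self.collagen_thg_mean <= self.noise_floor_mean:
            raise ValueError("collagen_thg_mean must exceed noise_floor_mean")
        if not 0.0 <= self.melanin_fraction <= 1.0:
            raise ValueError("melanin_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")
        if self.cell_count < 0 or self.fiber_count < 0:
            raise ValueError("cell_count and fiber_count must be >= 0")

    @property
    def um_per_px(self) -> float:
        # Fixed at the acquisition scale: 295 um over 512 px.
        return 295.0 / 512.0

    @property
    def field_of_view_um(self) -> float:
        return self.pixel_count * self.um_per_px

    @property
    def dej_frames(self) -> tuple[int, ...]:
        return tuple(range(self.dej_depth_index,
                           self.dej_depth_index + self.dej_band))


@dataclass
class SyntheticTruth:
    """Exact description of the noiseless scene behind a generated stack.

    The reference means are taken over the unvignetted core of the DEJ
    band, the region a correct analysis measures; ``true_ratio`` follows
    the noise-corrected formula
    ``(cytoplasm - noise) / (collagen - noise)``.
    """

    cytoplasm_mask: np.ndarray
    nucleus_mask: np.ndarray
    collagen_mask: np.ndarray
    melanin_mask: np.ndarray
    background_mask: np.ndarray
    true_cytoplasm_mean: float
    true_collagen_thg_mean: float
    true_noise_mean: float
    true_ratio: float
    dej_frames: tuple[int, ...]


def _vignette(n: int, radius_frac: float) -> np.ndarray:
    """Radial cosine falloff: 1 inside ``radius_frac`` of the half-width,
    dropping to 0 at the frame corner."""
    half = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - half, xx - half)
    r0 = radius_frac * half
    r_corner = half * math.sqrt(2.0)
    v = np.ones((n, n))
    outer = r > r0
    v[outer] = np.cos(0.5 * np.pi * (r[outer] - r0) / (r_corner - r0))
    return np.clip(v, 0.0, 1.0)


def _sample_centers(rng: np.random.Generator, count: int, max_r: float,
                    min_sep: float, frame_center: float) -> np.ndarray:
    """Dart-throwing placement of cell centres in a disc."""
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < count and attempts < 200 * max(count, 1):
        attempts += 1
        rad = max_r * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        cy = frame_center + rad * math.sin(ang)
        cx = frame_center + rad * math.cos(ang)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep ** 2
               for y, x in centers):
            centers.append((cy, cx))
    return np.asarray(centers).reshape(-1, 2)


def _render_cells(params: SkinSceneParams, rng: np.random.Generator,
                  content_r: float):
    """Render one frame's basal-cell mosaic.

    Returns the THG scene signal (noise-floor-subtracted amplitudes) and
    the cytoplasm / nucleus / melanin / whole-cell masks.
    """
    n = params.pixel_count
    center = (n - 1) / 2.0
    cell_r = 0.65 * params.cell_diameter_um / params.um_per_px
    signal = np.zeros((n, n))
    empty = np.zeros((n, n), dtype=bool)
    if params.cell_count == 0:
        return signal, empty, empty.copy(), empty.copy(), empty.copy()

    centers = _sample_centers(rng, params.cell_count,
                              max_r=max(content_r - cell_r, 1.0),
                              min_sep=1.1 * cell_r, frame_center=center)
    yy, xx = np.mgrid[0:n, 0:n]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    dist, idx = cKDTree(centers).query(pts, workers=1)
    dist = dist.reshape(n, n)
    labels = (idx.reshape(n, n) + 1).astype(np.int32)
    cellmask = dist <= cell_r
    labels[~cellmask] = 0

    # 2-px dark intercellular boundary: a pixel is interior only when its
    # whole 5x5 window lies in the same cell.
    same = (ndi.minimum_filter(labels, size=5) ==
            ndi.maximum_filter(labels, size=5))
    interior = cellmask & same
    boundary = cellmask & ~interior

    nucleus = np.zeros((n, n), dtype=bool)
    melanin = np.zeros((n, n), dtype=bool)
    amp_floor = params.noise_floor_mean
    for i, (cy, cx) in enumerate(centers, start=1):
        # Draws are taken unconditionally so the RNG stream (and hence the
        # cell geometry) does not depend on the melanin fraction.
        jit = rng.normal(0.0, 1.0, size=2)
        frac_a, frac_b = rng.uniform(0.4, 0.6, size=2)
        rot = rng.uniform(0.0, np.pi)
        mel_draw = rng.uniform()
        mel_ang = rng.uniform(0.0, 2.0 * np.pi)
        mel_r = rng.uniform(3.5, 5.5)
        a = 0.5 * frac_a * params.cell_diameter_um / params.um_per_px
        b = 0.5 * frac_b * params.cell_diameter_um / params.um_per_px
        rr, cc = draw_ellipse(cy + jit[0], cx + jit[1], a, b,
                              shape=(n, n), rotation=rot)
        keep = (labels[rr, cc] == i) & interior[rr, cc]
        nucleus[rr[keep], cc[keep]] = True
        if mel_draw < params.melanin_fraction:
            off = 0.45 * cell_r
            my = cy + off * math.sin(mel_ang)
            mx = cx + off * math.cos(mel_ang)
            rr, cc = draw_ellipse(my, mx, mel_r, mel_r, shape=(n, n))
            keep = (labels[rr, cc] == i) & interior[rr, cc] & ~nucleus[rr, cc]
            melanin[rr[keep], cc[keep]] = True

    cytoplasm = interior & ~nucleus & ~melanin
    signal[cytoplasm] = params.cytoplasm_mean - amp_floor
    signal[nucleus] = params.nucleus_mean - amp_floor
    signal[boundary] = _BOUNDARY_GRAY - amp_floor
    signal[melanin] = _MELANIN_GRAY - amp_floor
    return signal, cytoplasm, nucleus, melanin, cellmask


def _render_fibers(params: SkinSceneParams, rng: np.random.Generator,
                   content_mask: np.ndarray, content_r: float,
                   exclude: np.ndarray, fiber_mu: float):
    """Render one frame's collagen fibers as smooth random-walk tubes.

    Tubes have a flat core of radius ``fiber_radius_px`` and a narrow
    Gaussian shoulder; the core (profile >= 0.5) is the truth mask.
    Returns the unit-amplitude profile map, the truth mask, and the mean
    core profile used for amplitude calibration.
    """
    n = params.pixel_count
    empty = np.zeros((n, n), dtype=bool)
    if params.fiber_count == 0:
        return np.zeros((n, n)), empty, 1.0
    center = (n - 1) / 2.0
    skeleton = np.zeros((n, n), dtype=bool)
    step = 6.0
    for _ in range(params.fiber_count):
        rad = content_r * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        start = np.array([center + rad * math.sin(ang),
                          center + rad * math.cos(ang)])
        theta0 = fiber_mu + 0.5 * rng.vonmises(0.0, params.fiber_orientation_kappa)
        for direction in (1.0, -1.0):
            pos = start.copy()
            theta = theta0
            for _ in range(60):
                theta += rng.normal(0.0, 0.04)
                nxt = pos + direction * step * np.array(
                    [math.sin(theta), math.cos(theta)])
                if np.hypot(nxt[0] - center, nxt[1] - center) > content_r:
                    break
                rr, cc = draw_line(int(round(pos[0])), int(round(pos[1])),
                                   int(round(nxt[0])), int(round(nxt[1])))
                ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
                skeleton[rr[ok], cc[ok]] = True
                pos = nxt
    if not skeleton.any():
        return np.zeros((n, n)), empty, 1.0
    d = ndi.distance_transform_edt(~skeleton)
    excess = np.clip(d - params.fiber_radius_px, 0.0, None)
    profile = np.exp(-0.5 * (excess / params.fiber_edge_sigma_px) ** 2)
    profile[~content_mask] = 0.0
    profile[exclude] = 0.0
    core = profile >= 0.5
    m = float(profile[core].mean()) if core.any() else 1.0
    return profile, core, m


def generate_stack(params: SkinSceneParams) -> tuple[HGMStack, SyntheticTruth]:
    """Render a full two-channel stack and its exact ground truth.

    The composition order per frame is: scene amplitudes (cells and/or
    fibers), multiplication by the vignette and the depth-attenuation
    factor, addition of Gaussian detector noise with the configured floor
    mean, optional global blur, and clipping to the 14-bit range.
    """
    rng = np.random.default_rng(params.seed)
    n = params.pixel_count
    nz = params.n_depths
    vign = _vignette(n, params.vignette_radius_frac)
    half = (n - 1) / 2.0
    content_r = params.content_radius_frac * half
    yy, xx = np.mgrid[0:n, 0:n]
    content_mask = np.hypot(yy - half, xx - half) <= content_r
    core_region = vign >= 0.999  # unvignetted centre used for calibration

    band = set(params.dej_frames)
    band_end = max(band)
    fiber_mu = rng.uniform(0.0, np.pi)  # dominant fiber orientation per stack

    shg = np.zeros((nz, n, n), dtype=np.uint16)
    thg = np.zeros((nz, n, n), dtype=np.uint16)
    cyt_v = np.zeros((nz, n, n), dtype=bool)
    nuc_v = np.zeros((nz, n, n), dtype=bool)
    col_v = np.zeros((nz, n, n), dtype=bool)
    mel_v = np.zeros((nz, n, n), dtype=bool)
    bg_v = np.zeros((nz, n, n), dtype=bool)

    cyt_sum = cyt_n = col_sum = col_n = 0.0
    floor = params.noise_floor_mean

    for z in range(nz):
        has_cells = z <= band_end and params.cell_count > 0
        has_fibers = z >= params.dej_depth_index and params.fiber_count > 0
        att = 1.0 if z <= band_end else math.exp(
            -(z - band_end) * params.z_step_um / params.attenuation_length_um)

        thg_sig = np.zeros((n, n))
        shg_sig = np.zeros((n, n))
        cellmask = np.zeros((n, n), dtype=bool)
        if has_cells:
            csig, cyt, nuc, mel, cellmask = _render_cells(params, rng, content_r)
            thg_sig += csig
            cyt_v[z], nuc_v[z], mel_v[z] = cyt, nuc, mel
        if has_fibers:
            # Pericellular clearance keeps the two tissue phases optically
            # resolvable in the THG channel.
            exclude = ndi.binary_dilation(cellmask, iterations=4) \
                if cellmask.any() else cellmask
            profile, fcore, m = _render_fibers(params, rng, content_mask,
                                               content_r, exclude, fiber_mu)
            thg_sig += (params.collagen_thg_mean - floor) / m * profile
            shg_sig += (params.collagen_shg_mean - floor) / m * profile
            col_v[z] = fcore

        bg_v[z] = (thg_sig == 0.0) & (shg_sig == 0.0)
        if z in band:
            sel = cyt_v[z] & core_region
            cyt_sum += thg_sig[sel].sum()
            cyt_n += sel.sum()
            sel = col_v[z] & core_region
            col_sum += thg_sig[sel].sum()
            col_n += sel.sum()

        for sig, out in ((thg_sig, thg), (shg_sig, shg)):
            img = sig * vign * att + rng.normal(floor, params.noise_sd, (n, n))
            if params.blur_sigma_px > 0:
                img = ndi.gaussian_filter(img, params.blur_sigma_px)
            out[z] = np.clip(np.rint(img), 0, _MAX_GRAY).astype(np.uint16)

    true_cyt = floor + cyt_sum / cyt_n if cyt_n else float("nan")
    true_col = floor + col_sum / col_n if col_n else float("nan")
    denom = true_col - floor
    true_ratio = (true_cyt - floor) / denom if col_n and cyt_n else float("nan")

    meta = AcquisitionMeta(pixel_count_xy=n,
                           field_of_view_um=params.field_of_view_um,
                           z_step_um=params.z_step_um, bit_depth=14)
    stack = HGMStack(shg=shg, thg=thg, meta=meta)
    truth = SyntheticTruth(
        cytoplasm_mask=cyt_v, nucleus_mask=nuc_v, collagen_mask=col_v,
        melanin_mask=mel_v, background_mask=bg_v,
        true_cytoplasm_mean=true_cyt, true_collagen_thg_mean=true_col,
        true_noise_mean=floor, true_ratio=true_ratio,
        dej_frames=params.dej_frames,
    )
    return stack, truth


#: Named study conditions.
PRESET_NAMES = ("paper_cohort", "melanin_containing", "blurred",
                "sparse_collagen", "few_cells")


def preset(name: str, seed: int = 0) -> SkinSceneParams:
    """Return the generative conditions for a named scenario.

    ``paper_cohort`` is the melanin-free vitiligo condition whose true
    ratio is (1809-150)/(1650-150) = 1.106.  The remaining presets each
    trigger one quality-control exclusion: ``melanin_containing`` (bright
    melanin caps and a true ratio above 1.6), ``blurred`` (motion blur
    defeating the focus metric), ``sparse_collagen`` (SHG coverage below
    the 25% screening floor) and ``few_cells`` (fewer than 10 basal
    cells).
    """
    base = SkinSceneParams(seed=seed)
    if name == "paper_cohort":
        return base
    if name == "melanin_containing":
        return replace(base, melanin_fraction=0.6, cytoplasm_mean=2700.0)
    if name == "blurred":
        return replace(base, blur_sigma_px=8.0)
    if name == "sparse_collagen":
        return replace(base, fiber_count=4)
    if name == "few_cells":
        return replace(base, cell_count=6)
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
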