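"""Reading, writing and validating two-channel harmonic-generation z-stacks.

A stack holds co-registered SHG and THG intensity volumes acquired
simultaneously at successive depths below the skin surface.  On disk a
stack is a multi-page 16-bit grayscale TIFF with the two channels
interleaved depth-major: page ``2k`` is the SHG frame and page ``2k + 1``
the THG frame at depth index ``k`` (the order flips when
``channel_order = "thg_first"``).  Sample values are 14-bit by default and
stored in unsigned 16-bit containers; the declared bit depth, not the
container, defines the valid intensity range.

Acquisition metadata travels inside the TIFF ``ImageDescription`` tag as a
JSON block, with a ``<file>.meta.yaml`` sidecar accepted as a fallback for
files produced elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "AcquisitionMeta",
    "HGMStack",
    "read_stack",
    "write_stack",
    "render_pseudocolor",
]

#: Metadata keys recognised in the embedded JSON block and the sidecar.
_META_KEYS = ("pixel_count_xy", "field_of_view_um", "z_step_um", "bit_depth")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Geometry and digitisation of one acquisition.

    Parameters
    ----------
    pixel_count_xy : int
        Pixels per frame side (frames are square).
    field_of_view_um : float
        Physical side length of a frame in micrometres.
    z_step_um : float
        Spacing between consecutive depths in micrometres.
    bit_depth : int
        Bits per intensity sample; every value in an associated stack
        must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixel_count_xy: int = 512
    field_of_view_um: float = 295.0
    z_step_um: float = 1.8
    bit_depth: int = 14

    def __post_init__(self) -> None:
        if self.pixel_count_xy <= 0:
            raise ValueError("pixel_count_xy must be positive")
        if self.field_of_view_um <= 0:
            raise ValueError("field_of_view_um must be positive")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if not 1 <= int(self.bit_depth) <= 16:
            raise ValueError("bit_depth must be in [1, 16]")

    @property
    def max_value(self) -> int:
        return (1 << int(self.bit_depth)) - 1

    @property
    def um_per_px(self) -> float:
        return self.field_of_view_um / self.pixel_count_xy


@dataclass
class HGMStack:
    """Co-registered SHG and THG volumes indexed ``(depth, row, col)``.

    Depth index 0 is the shallowest frame (skin surface side); depth
    increases toward the dermis.
    """

    shg: np.ndarray
    thg: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    depth0_um: float = 0.0

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg)
        self.thg = np.asarray(self.thg)
        if self.shg.shape != self.thg.shape:
            raise ValueError(
                f"channel shapes differ: shg {self.shg.shape} vs thg {self.thg.shape}"
            )
        if self.shg.ndim != 3:
            raise ValueError("volumes must be 3-D (depth, row, col)")
        if self.shg.size == 0:
            raise ValueError("stack is empty")
        for name, vol in (("shg", self.shg), ("thg", self.thg)):
            lo, hi = vol.min(), vol.max()
            if lo < 0 or hi > self.meta.max_value:
                raise ValueError(
                    f"{name} values [{lo}, {hi}] exceed the declared "
                    f"{self.meta.bit_depth}-bit range [0, {self.meta.max_value}]"
                )

    @property
    def n_depths(self) -> int:
        return self.shg.shape[0]

    def depth_um(self, depth_index: int) -> float:
        """Physical depth below the surface of frame ``depth_index``."""
        return self.depth0_um + depth_index * self.meta.z_step_um


def write_stack(stack: HGMStack, path: str | Path,
                channel_order: str = "shg_first") -> Path:
    """Write a stack as an interleaved multi-page 16-bit TIFF.

    The metadata (including the channel order) is embedded as JSON in the
    ImageDescription tag so the file is self-describing; ``read_stack``
    round-trips it losslessly.
    """
    if channel_order not in ("shg_first", "thg_first"):
        raise ValueError(f"unknown channel_order {channel_order!r}")
    path = Path(path)
    n, h, w = stack.shg.shape
    pages = np.empty((2 * n, h, w), dtype=np.uint16)
    first, second = (stack.shg, stack.thg) if channel_order == "shg_first" \
        else (stack.thg, stack.shg)
    pages[0::2] = first
    pages[1::2] = second
    desc = json.dumps(
        {
            "pixel_count_xy": stack.meta.pixel_count_xy,
            "field_of_view_um": stack.meta.field_of_view_um,
            "z_step_um": stack.meta.z_step_um,
            "bit_depth": stack.meta.bit_depth,
            "channel_order": channel_order,
            "depth0_um": stack.depth0_um,
        }
    )
    tifffile.imwrite(path, pages, description=desc, photometric="minisblack")
    return path


def _load_meta(path: Path, description: str | None) -> dict:
    if description:
        try:
            meta = json.loads(description)
            if all(k in meta for k in _META_KEYS):
                return meta
        except (json.JSONDecodeError, TypeError):
            pass
    sidecar = path.with_name(path.name + ".meta.yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        if not isinstance(meta, dict) or not all(k in meta for k in _META_KEYS):
            raise ValueError(f"sidecar {sidecar} lacks required keys {_META_KEYS}")
        return meta
    raise ValueError(
        f"{path}: no embedded acquisition metadata and no sidecar {sidecar.name}"
    )


def read_stack(path: str | Path) -> HGMStack:
    """Read a two-channel interleaved TIFF stack written by :func:`write_stack`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On an odd page count, values exceeding the declared bit depth, or
        missing metadata with no sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        description = tif.pages[0].description
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages cannot hold an interleaved "
            "two-channel layout"
        )
    meta_dict = _load_meta(path, description)
    meta = AcquisitionMeta(
        pixel_count_xy=int(meta_dict["pixel_count_xy"]),
        field_of_view_um=float(meta_dict["field_of_view_um"]),
        z_step_um=float(meta_dict["z_step_um"]),
        bit_depth=int(meta_dict["bit_depth"]),
    )
    order = meta_dict.get("channel_order", "shg_first")
    if order not in ("shg_first", "thg_first"):
        raise ValueError(f"{path}: unknown channel_order {order!r}")
    first, second = pages[0::2], pages[1::2]
    shg, thg = (first, second) if order == "shg_first" else (second, first)
    # HGMStack.__post_init__ enforces the bit-depth range.
    return HGMStack(shg=shg, thg=thg, meta=meta,
                    depth0_um=float(meta_dict.get("depth0_um", 0.0)))


def render_pseudocolor(stack: HGMStack, depth_index: int) -> np.ndarray:
    """Render one depth as an RGB image: SHG in green, THG in magenta.

    Each channel is normalised to its own frame maximum, so the output is
    for visual documentation only, not quantitation.  Returns a
    ``(rows, cols, 3)`` float array in [0, 1].
    """
    if not 0 <= depth_index < stack.n_depths:
        raise IndexError(
            f"depth {depth_index} out of range for {stack.n_depths} frames"
        )
    shg = stack.shg[depth_index].astype(float)
    thg = stack.thg[depth_index].astype(float)
    shg_n = shg / shg.max() if shg.max() > 0 else shg
    thg_n = thg / thg.max() if thg.max() > 0 else thg
    rgb = np.stack([thg_n, shg_n, thg_n], axis=-1)
    return np.clip(rgb, 0.0, 1.0)
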