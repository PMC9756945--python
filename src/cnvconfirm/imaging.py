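"""Encoding a candidate CNV's depth profile as a fixed-size RGB image.

Each image shows the normalized read depth of the case sample (blue,
#0000FF) on top of its reference panel (gray, #808080) over the targets the
CNV spans plus flanking context.  Two log transforms stabilize the drawing:
inter-target gaps on the x-axis are compressed as

    x'_t = x_0 + sum_{i<=t} ln(1 + (x_i - x_{i-1}))

so a CNV whose exons straddle a large intron still renders as a contiguous
profile, and depth on the y-axis becomes y' = ln(1 + y), which maps the
diploid baseline 1 to ln 2 and keeps deletion/duplication offsets visually
symmetric.  Each target is a dot; adjacent dots of the same sample are
connected by a straight line.

Rendering is done by a deterministic in-package rasterizer at the final
224x224 resolution: identical inputs give byte-identical pixels, and the
case/reference colors appear exactly (no anti-aliasing, no fonts, no axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calls import CNVCall
from .depthio import NORMALIZED, DepthMatrix
from .errors import MissingDataError, OrderingError, ValidationError
from .references import ReferencePanel

CASE_COLOR = (0, 0, 255)  # #0000FF
REF_COLOR = (128, 128, 128)  # #808080
BACKGROUND = (255, 255, 255)


def transform_x(midpoints) -> np.ndarray:
    """Cumulative log-compression of inter-target distances.

    x'_0 = x_0 and x'_t = x_0 + sum_{i=1..t} ln(1 + (x_i - x_{i-1})).
    Strictly increasing input is required and preserved.
    """
    x = np.asarray(midpoints, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("midpoints must be a non-empty 1-D sequence")
    diffs = np.diff(x)
    if np.any(diffs <= 0):
        raise OrderingError("midpoints must be strictly increasing")
    out = np.empty_like(x)
    out[0] = x[0]
    out[1:] = x[0] + np.cumsum(np.log1p(diffs))
    return out


def transform_y(depths) -> np.ndarray:
    """Elementwise y' = ln(1 + y); maps 0 to 0, monotone increasing."""
    y = np.asarray(depths, dtype=float)
    if np.any(y < 0):
        raise ValidationError("depth values must be non-negative")
    return np.log1p(y)


@dataclass
class RenderStyle:
    """Deterministic raster configuration.

    ``y_max`` fixes the y'-axis range to [0, ln(1+5)] for every image so a
    given copy-number contrast always occupies the same pixel offset; higher
    values are clipped.
    """

    width: int = 224
    height: int = 224
    line_width: int = 2
    dot_size: int = 3
    y_max: float = float(np.log1p(5.0))
    case_color: tuple[int, int, int] = CASE_COLOR
    ref_color: tuple[int, int, int] = REF_COLOR
    background: tuple[int, int, int] = BACKGROUND


@dataclass
class EncodedImage:
    """A rendered candidate: 224x224x3 8-bit RGB plus provenance metadata."""

    pixels: np.ndarray
    cnv_ref: str
    render_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (224, 224, 3):
            raise ValidationError(f"image shape {self.pixels.shape} != (224, 224, 3)")

    def save_png(self, path: str) -> None:
        from PIL import Image

        Image.fromarray(self.pixels, mode="RGB").save(path)


def _paint(canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray, size: int, color) -> None:
    """Stamp a size x size square brush at each (row, col), clipped to canvas."""
    h, w, _ = canvas.shape
    lo = -(size // 2)
    for dr in range(lo, lo + size):
        for dc in range(lo, lo + size):
            rr = np.clip(rows + dr, 0, h - 1)
            cc = np.clip(cols + dc, 0, w - 1)
            canvas[rr, cc] = color


def _draw_series(canvas: np.ndarray, cols: np.ndarray, rows: np.ndarray, style: RenderStyle, color) -> None:
    # connecting lines, sampled densely enough that no pixel gap remains
    all_cc, all_rr = [], []
    for i in range(len(cols) - 1):
        c0, c1, r0, r1 = cols[i], cols[i + 1], rows[i], rows[i + 1]
        n = int(max(abs(c1 - c0), abs(r1 - r0))) + 1
        all_cc.append(np.rint(np.linspace(c0, c1, n + 1)).astype(int))
        all_rr.append(np.rint(np.linspace(r0, r1, n + 1)).astype(int))
    if all_cc:
        _paint(canvas, np.concatenate(all_rr), np.concatenate(all_cc), style.line_width, color)
    # dots on top of the lines, one per target
    _paint(canvas, rows, cols, style.dot_size, color)


def cnv_target_window(
    cnv: CNVCall, matrix: DepthMatrix, flank_targets: int | None = None
) -> tuple[np.ndarray, int]:
    """Indices of the targets drawn for a CNV: overlapped ones plus flanks.

    The default flank is max(number of overlapped targets, 10) per side,
    clipped at the chromosome's target-list bounds.  Returns the index array
    and the flank actually requested.
    """
    chrom_idx = np.array(
        [i for i, t in enumerate(matrix.targets) if t.chrom == cnv.chrom]
    )
    if chrom_idx.size == 0:
        raise MissingDataError(f"no targets on chromosome {cnv.chrom}")
    inside = np.array(
        [
            i
            for i in chrom_idx
            if matrix.targets[i].start < cnv.end and matrix.targets[i].end > cnv.start
        ]
    )
    if inside.size == 0:
        raise MissingDataError(
            f"CNV {cnv.key} overlaps no capture target (no depth signal)"
        )
    flank = flank_targets if flank_targets is not None else max(inside.size, 10)
    lo = np.searchsorted(chrom_idx, inside[0])
    hi = np.searchsorted(chrom_idx, inside[-1])
    window = chrom_idx[max(0, lo - flank) : hi + flank + 1]
    return window, flank


def encode_cnv_image(
    cnv: CNVCall,
    matrix: DepthMatrix,
    panel: ReferencePanel,
    flank_targets: int | None = None,
    style: RenderStyle | None = None,
) -> EncodedImage:
    """Render case + reference depth polylines over the CNV window.

    References are drawn first in panel order, the case last so it is always
    on top.  No axes, legends or text enter the pixel area.
    """
    style = style or RenderStyle()
    if matrix.state != NORMALIZED:
        raise ValidationError("encode_cnv_image expects a normalized matrix")
    if not panel.reference_ids:
        raise ValidationError("reference panel is empty")
    if cnv.sample_id not in matrix:
        raise MissingDataError(f"case {cnv.sample_id!r} not in matrix")
    for ref in panel.reference_ids:
        if ref not in matrix:
            raise MissingDataError(f"reference {ref!r} not in matrix")

    window, flank = cnv_target_window(cnv, matrix, flank_targets)
    mids = np.array([matrix.targets[i].midpoint for i in window])
    xprime = transform_x(mids)
    span = xprime[-1] - xprime[0]
    if span > 0:
        cols = np.rint((xprime - xprime[0]) / span * (style.width - 1)).astype(int)
    else:
        cols = np.full(xprime.shape, style.width // 2, dtype=int)

    def to_rows(depths: np.ndarray) -> np.ndarray:
        yp = np.clip(transform_y(depths), 0.0, style.y_max)
        return np.rint((1.0 - yp / style.y_max) * (style.height - 1)).astype(int)

    canvas = np.empty((style.height, style.width, 3), dtype=np.uint8)
    canvas[:] = style.background
    for ref in panel.reference_ids:
        _draw_series(canvas, cols, to_rows(matrix.row(ref)[window]), style, style.ref_color)
    _draw_series(canvas, cols, to_rows(matrix.row(cnv.sample_id)[window]), style, style.case_color)

    meta = {
        "flank_targets": int(flank),
        "panel_size": len(panel.reference_ids),
        "x_range": (float(xprime[0]), float(xprime[-1])),
        "y_max": float(style.y_max),
        "line_width": style.line_width,
        "dot_size": style.dot_size,
        "n_targets_drawn": int(window.size),
    }
    return EncodedImage(pixels=canvas, cnv_ref=cnv.key, render_meta=meta)
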