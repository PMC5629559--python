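"""Axis detection, pure-logo cropping, and letter-column segmentation.

Coordinates are 0-based with row 0 at the top; all intervals are half-open.

Axes are assumed to be drawn in black.  A long straight black run — at
least half the image height for a vertical line, half the width for a
horizontal one — hugging the left or bottom edge of the content is taken
as the Y or X axis.  When axes exist they define the logo region (the
paper area between them) and, crucially, the Y-axis pixel length is the
scale bar: it corresponds to the maximum information content of 2 bits.
Without a Y axis the tallest letter stack is *assumed* to reach 2 bits,
which systematically inflates the reconstruction of logos whose true
maximum column is weaker; this bias is inherent to the convention and is
not corrected here.

Column segmentation projects letter pixels onto the X axis, finds peaks
(maximal nonzero runs), votes on the modal peak-center spacing to get the
column pitch, divides the region width by the pitch to count columns, and
finally snaps the uniform column boundaries to nearby projection minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BlankImageError, ValidationError
from .image_prep import ColorClass, ColorMap, _letter_mask

#: fraction of the image dimension a black run must span to count as an axis
AXIS_RUN_FRACTION = 0.5

#: color-to-nucleotide assignment of the common DNA logo scheme
COLOR_TO_BASE = {
    ColorClass.GREEN: "A",
    ColorClass.BLUE: "C",
    ColorClass.YELLOW: "G",
    ColorClass.RED: "T",
}
BASE_ORDER = ("A", "C", "G", "T")


@dataclass(frozen=True)
class LogoRegion:
    """The pure-logo pixel area, with axis metadata."""

    top: int
    bottom: int
    left: int
    right: int
    has_x_axis: bool
    has_y_axis: bool
    y_axis_height_px: int | None

    def __post_init__(self) -> None:
        if self.bottom <= self.top or self.right <= self.left:
            raise ValidationError("LogoRegion must be non-empty")
        if self.has_y_axis != (self.y_axis_height_px is not None):
            raise ValidationError("y_axis_height_px present iff has_y_axis")

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def height(self) -> int:
        return self.bottom - self.top


@dataclass(frozen=True)
class ColumnLayout:
    """Per-position column boundaries inside a LogoRegion."""

    n_columns: int
    boundaries: tuple[tuple[int, int], ...]
    column_width_px: int

    def __post_init__(self) -> None:
        if self.n_columns != len(self.boundaries) or self.n_columns < 1:
            raise ValidationError("n_columns must match the number of intervals")
        prev = None
        for left, right in self.boundaries:
            if right <= left:
                raise ValidationError("column intervals must be non-empty")
            if prev is not None and left < prev:
                raise ValidationError("column intervals must be ordered and disjoint")
            prev = right


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of True in a 1-D boolean array."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _longest_run(mask: np.ndarray) -> tuple[int, int] | None:
    runs = _runs(mask)
    if not runs:
        return None
    return max(runs, key=lambda se: se[1] - se[0])


def _axis_lines(black: np.ndarray, axis: int, min_len: int) -> list[tuple[int, tuple[int, int]]]:
    """Indices (rows for axis=0 scan, columns for axis=1) with a straight
    black run of at least ``min_len``, with that run's extent."""
    counts = black.sum(axis=1 - axis)
    out = []
    for i in np.flatnonzero(counts >= min_len):
        line = black[:, i] if axis == 1 else black[i, :]
        run = _longest_run(line)
        if run and run[1] - run[0] >= min_len:
            out.append((int(i), run))
    return out


def detect_axes(cmap: ColorMap) -> LogoRegion:
    """Locate black X/Y axis lines and the pure logo region between them.

    Without axes the region is the bounding box of letter-colored pixels;
    with axes, the axis-line extents define the logo's full width/height so
    that even a position that rendered no visible letters stays inside the
    region.  Tick marks and label text (black, outside the axis lines) are
    excluded automatically.
    """
    classes = cmap.classes
    h, w = classes.shape
    if not (classes != int(ColorClass.WHITE)).any():
        raise BlankImageError("blank image: no non-white pixels")
    letters = _letter_mask(classes)
    if not letters.any():
        raise BlankImageError("blank image: no letter-colored pixels")
    rows = np.flatnonzero(letters.any(axis=1))
    cols = np.flatnonzero(letters.any(axis=0))
    rmin, rmax = int(rows[0]), int(rows[-1])
    cmin, cmax = int(cols[0]), int(cols[-1])

    black = classes == int(ColorClass.BLACK)
    vert = _axis_lines(black, axis=1, min_len=int(np.ceil(AXIS_RUN_FRACTION * h)))
    horiz = _axis_lines(black, axis=0, min_len=int(np.ceil(AXIS_RUN_FRACTION * w)))

    # Y axis: leftmost contiguous group of qualifying columns left of letters
    y_group = []
    for x, run in vert:
        if x > cmin:  # must hug the left of the letter area
            continue
        if not y_group or x == y_group[-1][0] + 1:
            y_group.append((x, run))
        else:
            break
    has_y = bool(y_group)
    # X axis: bottom-most contiguous group of qualifying rows
    x_group = []
    for y, run in reversed(horiz):
        if y < rmax - 1:  # must hug the bottom of the letter area
            continue
        if not x_group or y == x_group[-1][0] - 1:
            x_group.append((y, run))
        else:
            break
    has_x = bool(x_group)

    if has_y:
        y_run = max((run for _, run in y_group), key=lambda se: se[1] - se[0])
        y_height = y_run[1] - y_run[0]
        y_right = max(x for x, _ in y_group)
        top = y_run[0]
    else:
        y_height = None
        y_right = None
        top = rmin
    if has_x:
        x_top = min(y for y, _ in x_group)
        x_left = min(run[0] for _, run in x_group)
        x_right = max(run[1] for _, run in x_group)
        bottom = x_top
        left = x_left
        right = x_right
    else:
        bottom = rmax + 1
        left = cmin
        right = cmax + 1
    if has_y:
        left = max(left, y_right + 1)
    if bottom <= top or right <= left:
        raise BlankImageError("degenerate logo region")
    return LogoRegion(
        top=int(top),
        bottom=int(bottom),
        left=int(left),
        right=int(right),
        has_x_axis=has_x,
        has_y_axis=has_y,
        y_axis_height_px=int(y_height) if has_y else None,
    )


def full_scale_pixels(region: LogoRegion, cmap: ColorMap) -> int:
    """Pixel height corresponding to 2 bits of information content.

    The Y-axis length when present; otherwise the tallest letter stack in
    the region (assumed to reach the 2-bit maximum).
    """
    if region.has_y_axis:
        return int(region.y_axis_height_px)
    sub = _letter_mask(cmap.classes[region.top : region.bottom, region.left : region.right])
    proj = sub.sum(axis=0)
    # per letter stack (maximal nonzero projection run), count occupied rows;
    # letterform holes make single pixel columns unreliable
    tallest = 0
    for start, stop in _runs(proj > 0):
        tallest = max(tallest, int(sub[:, start:stop].any(axis=1).sum()))
    if tallest <= 0:
        raise BlankImageError("blank region: no letter pixels to scale by")
    return tallest


def segment_columns(
    cmap: ColorMap, region: LogoRegion, n_override: int | None = None
) -> ColumnLayout:
    """Split the logo region into per-position letter columns.

    The X-projection counts letter pixels per image column.  Peaks (maximal
    nonzero runs, after a 3-px closing when 1-px gaps fragment letters) vote
    with their center spacings; the modal spacing is the column pitch, and
    ``round(region width / pitch)`` is the column count unless ``n_override``
    forces it.  Uniform boundaries are then snapped to the nearest projection
    minimum within a quarter pitch.
    """
    if n_override is not None and n_override <= 0:
        raise ValidationError("n_override must be a positive count")
    sub = cmap.classes[region.top : region.bottom, region.left : region.right]
    proj = _letter_mask(sub).sum(axis=0)
    w = proj.size
    if proj.max() == 0:
        raise BlankImageError("blank region: projection is entirely zero")

    runs = _runs(proj > 0)
    gaps = [runs[i + 1][0] - runs[i][1] for i in range(len(runs) - 1)]
    if any(g < 2 for g in gaps):
        closed = ndimage.maximum_filter1d(proj, size=3)
        runs = _runs(closed > 0)

    if n_override is not None:
        n = int(n_override)
        col_w = w / n
    else:
        centers = np.array([(s + e) / 2.0 for s, e in runs])
        if centers.size >= 2:
            spacings = np.rint(np.diff(centers)).astype(int)
            spacings = spacings[spacings >= 1]
            if spacings.size:
                col_w = float(np.argmax(np.bincount(spacings)))  # mode, ties -> smaller
            else:
                col_w = float(w)
        else:
            col_w = float(w)
        n = max(1, int(np.floor(w / col_w + 0.5)))

    edges_f = np.linspace(0.0, float(w), n + 1)
    edges = [0]
    window = max(1, int(round(0.25 * col_w)))
    for i in range(1, n):
        x0 = int(round(edges_f[i]))
        lo = max(1, x0 - window)
        hi = min(w - 1, x0 + window)
        vals = proj[lo : hi + 1]
        m = vals.min()
        cands = lo + np.flatnonzero(vals == m)
        snapped = int(cands[np.argmin(np.abs(cands - x0))])
        edges.append(max(snapped, edges[-1] + 1))
    edges.append(w)
    # degenerate snaps could push an edge past the end; repair monotonically
    for i in range(n, 0, -1):
        if edges[i - 1] >= edges[i]:
            edges[i - 1] = edges[i] - 1
    if edges[0] < 0:
        raise ValidationError("column boundaries could not be laid out")

    bounds = tuple(
        (region.left + edges[i], region.left + edges[i + 1]) for i in range(n)
    )
    return ColumnLayout(n_columns=n, boundaries=bounds, column_width_px=int(round(col_w)))


def measure_column(
    cmap: ColorMap, region: LogoRegion, bounds: tuple[int, int]
) -> tuple[int, dict[str, int]]:
    """Stack height and per-nucleotide letter heights for one column.

    The stack height is the number of pixel rows containing at least one
    letter pixel.  Each such row is assigned to a nucleotide by consensus
    vote (majority letter class among its pixels), and a letter's height is
    the number of rows it wins — robust to anti-aliasing fringes from a
    vertically adjacent glyph.
    """
    left, right = bounds
    if not (region.left <= left < right <= region.right):
        raise ValidationError("column bounds must lie within the region")
    sub = cmap.classes[region.top : region.bottom, left:right]
    heights = {b: 0 for b in BASE_ORDER}
    # per-row counts for each letter class, in A,C,G,T order
    counts = np.stack(
        [(sub == int(cls)).sum(axis=1) for cls, _ in sorted(COLOR_TO_BASE.items(), key=lambda kv: kv[1])],
        axis=1,
    )
    row_total = counts.sum(axis=1)
    occupied = row_total > 0
    stack = int(occupied.sum())
    if stack:
        winners = np.argmax(counts[occupied], axis=1)  # ties -> first (A,C,G,T order)
        for win, cnt in zip(*np.unique(winners, return_counts=True)):
            heights[BASE_ORDER[int(win)]] = int(cnt)
    return stack, heights
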