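"""Synthetic sequence-logo renderer with recorded ground-truth geometry.

Renders a PWM as a raster logo: per position, a stack of solid-color
letterforms whose total height is ``(I_j / 2) * full_scale`` pixels and
whose per-letter heights are proportional to ``P_ij * I_j``, largest letter
on top.  Axes, when enabled, are pure black; the Y-axis line is drawn at
exactly the full-scale height so it doubles as the 2-bit scale bar that the
reconstruction side reads back.

The renderer exists as the test fixture generator for round-trip
experiments: every render returns a :class:`RenderRecord` carrying the true
PWM, the logo drawing box, and each glyph's exact pixel box, so geometry
tests never have to re-derive the truth from pixels.  It deliberately
shares no measurement code with the reconstruction pipeline.

Glyph shapes come from a standard bold sans-serif font (DejaVu Sans Bold),
binarized and stretched to the exact target box with nearest-neighbor
resampling, so glyphs are solid single-color regions with no anti-aliased
fringe of their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.font_manager import FontProperties, findfont
from PIL import Image, ImageDraw, ImageFont

from .errors import LogoError, ValidationError
from .pwm_core import ALPHABET, PWM

#: default letter colors: the common DNA scheme (also the classifier centroids)
DEFAULT_LETTER_COLORS = {
    "A": (57, 178, 65),    # green
    "C": (43, 60, 147),    # blue
    "G": (240, 173, 10),   # yellow
    "T": (200, 25, 32),    # red
}

_AXIS_THICKNESS = 2


@dataclass(frozen=True)
class RenderStyle:
    """Controls one rendered logo's geometry and palette."""

    width_px: int = 600
    height_px: int = 200
    draw_x_axis: bool = True
    draw_y_axis: bool = True
    margin_px: int = 10
    letter_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LETTER_COLORS)
    )
    background: tuple[int, int, int] = (255, 255, 255)
    inter_column_gap_px: int = 4

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1 or self.margin_px < 0:
            raise ValidationError("style dimensions must be positive")
        for color in list(self.letter_colors.values()) + [tuple(self.background)]:
            if any(not 0 <= c <= 255 for c in color):
                raise ValidationError("colors must be within channel range 0-255")
        if self.inter_column_gap_px < 0:
            raise ValidationError("inter_column_gap_px must be nonnegative")


@dataclass(frozen=True)
class RenderRecord:
    """Ground truth for one rendered logo."""

    image_path: Path
    truth_pwm: PWM
    logo_box: tuple[int, int, int, int]  # (left, top, right, bottom), half-open
    per_glyph_boxes: tuple[tuple[int, str, tuple[int, int, int, int]], ...]
    full_scale_px: int

    def to_json(self) -> dict:
        return {
            "image_path": str(self.image_path),
            "truth_pwm": self.truth_pwm.probs.tolist(),
            "logo_box": list(self.logo_box),
            "per_glyph_boxes": [
                [pos, base, list(box)] for pos, base, box in self.per_glyph_boxes
            ],
            "full_scale_px": self.full_scale_px,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RenderRecord":
        return cls(
            image_path=Path(obj["image_path"]),
            truth_pwm=PWM(probs=np.array(obj["truth_pwm"], dtype=float)),
            logo_box=tuple(obj["logo_box"]),
            per_glyph_boxes=tuple(
                (int(pos), str(base), tuple(box))
                for pos, base, box in obj["per_glyph_boxes"]
            ),
            full_scale_px=int(obj["full_scale_px"]),
        )


@lru_cache(maxsize=8)
def _glyph_mask(base: str) -> np.ndarray:
    """Tight boolean raster of one bold letterform, binarized at 50% cover."""
    font_path = findfont(FontProperties(family="DejaVu Sans", weight="bold"))
    font = ImageFont.truetype(font_path, 160)
    l, t, r, b = font.getbbox(base)
    im = Image.new("L", (r - l + 8, b - t + 8), 0)
    ImageDraw.Draw(im).text((4 - l, 4 - t), base, fill=255, font=font)
    arr = np.asarray(im) >= 128
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    return arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _paste_glyph(
    canvas: np.ndarray, base: str, box: tuple[int, int, int, int], color
) -> None:
    left, top, right, bottom = box
    w, h = right - left, bottom - top
    mask_img = Image.fromarray(_glyph_mask(base).astype(np.uint8) * 255, mode="L")
    resized = np.asarray(mask_img.resize((w, h), Image.NEAREST)) >= 128
    canvas[top:bottom, left:right][resized] = color


def render_logo(pwm: PWM, style: RenderStyle, out_path: str | Path) -> RenderRecord:
    """Render ``pwm`` as a raster logo and record the drawn geometry.

    Stack height of column j is ``round((I_j / 2) * full_scale)``; letters
    are stacked largest on top with cumulative rounding so that the glyph
    heights stay proportional to ``P_ij * I_j`` within one pixel and sum to
    the stack height exactly.
    """
    out_path = Path(out_path)
    style = style or RenderStyle()
    W, H, m = style.width_px, style.height_px, style.margin_px
    logo_left = m + (_AXIS_THICKNESS + 2 if style.draw_y_axis else 0)
    logo_right = W - m
    logo_top = m
    logo_bottom = H - m - (_AXIS_THICKNESS + 1 if style.draw_x_axis else 0)
    if logo_right - logo_left < pwm.length or logo_bottom - logo_top < 4:
        raise ValidationError("style too small for this PWM")
    full_scale = logo_bottom - logo_top

    canvas = np.empty((H, W, 3), dtype=np.uint8)
    canvas[:] = np.asarray(style.background, dtype=np.uint8)
    black = (0, 0, 0)
    if style.draw_y_axis:
        canvas[logo_top:logo_bottom, m : m + _AXIS_THICKNESS] = black
        if m >= 3:  # tick marks at 0 and 2 bits
            canvas[logo_top, m - 3 : m] = black
            canvas[logo_bottom - 1, m - 3 : m] = black
    if style.draw_x_axis:
        x0 = m if style.draw_y_axis else logo_left
        canvas[H - m - _AXIS_THICKNESS : H - m, x0:logo_right] = black

    info = pwm.information_content()
    edges = np.rint(
        logo_left + (logo_right - logo_left) * np.arange(pwm.length + 1) / pwm.length
    ).astype(int)
    gap = style.inter_column_gap_px
    glyph_boxes: list[tuple[int, str, tuple[int, int, int, int]]] = []
    for j in range(pwm.length):
        stack_h = int(round(info[j] / 2.0 * full_scale))
        if stack_h < 1:
            continue
        gx0 = int(edges[j]) + (gap + 1) // 2
        gx1 = int(edges[j + 1]) - gap // 2
        if gx1 - gx0 < 1:
            raise ValidationError("column too narrow for the requested gap")
        order = sorted(range(4), key=lambda i: (-pwm.probs[i, j], ALPHABET[i]))
        y0 = logo_bottom - stack_h
        cum = 0.0
        for i in order:
            h_exact = pwm.probs[i, j] * info[j] / 2.0 * full_scale
            top_px = y0 + int(round(cum))
            cum += h_exact
            bot_px = y0 + int(round(cum))
            if bot_px - top_px < 1:
                continue
            base = ALPHABET[i]
            box = (gx0, top_px, gx1, bot_px)
            _paste_glyph(canvas, base, box, style.letter_colors[base])
            glyph_boxes.append((j, base, box))

    image = Image.fromarray(canvas, mode="RGB")
    fmt = out_path.suffix.lower().lstrip(".")
    try:
        if fmt in ("jpg", "jpeg"):
            image.save(out_path, quality=95, subsampling=0)
        else:
            image.save(out_path)
    except OSError as exc:
        raise LogoError(f"cannot write image to {out_path}: {exc}") from exc

    return RenderRecord(
        image_path=out_path,
        truth_pwm=pwm,
        logo_box=(logo_left, logo_top, logo_right, logo_bottom),
        per_glyph_boxes=tuple(glyph_boxes),
        full_scale_px=full_scale,
    )


def random_pwm(length: int, concentration: float = 1.0, seed=None) -> PWM:
    """Draw a PWM with independent per-column Dirichlet columns.

    ``concentration`` is the symmetric Dirichlet parameter: 1 gives columns
    uniform on the simplex, small values give sharp (high-information)
    columns, large values give near-uniform columns.  ``seed`` may be an int
    or a ``numpy.random.Generator``.
    """
    if length < 1:
        raise ValidationError("length must be at least 1")
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = rng.dirichlet([concentration] * 4, size=length)
    return PWM(probs=cols.T)


def render_corpus(
    n: int,
    style_variants: Sequence[RenderStyle] | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
    min_length: int = 6,
    max_length: int = 15,
    concentration: float = 1.0,
) -> list[RenderRecord]:
    """Render ``n`` random logos (lengths uniform in [min, max]), cycling
    through the style variants, and persist a JSON-lines manifest.

    Deterministic given (n, styles, seed); the manifest at
    ``out_dir/manifest.jsonl`` holds one record per logo.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    styles = list(style_variants) if style_variants else [RenderStyle()]
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(min_length, max_length + 1))
        pwm = random_pwm(length, concentration=concentration, seed=rng)
        style = styles[i % len(styles)]
        rec = render_logo(pwm, style, out_dir / f"logo_{i:04d}.png")
        records.append(rec)
    with open(out_dir / "manifest.jsonl", "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json()) + "\n")
    return records


def load_manifest(path: str | Path) -> list[RenderRecord]:
    """Read back a corpus manifest written by :func:`render_corpus`."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(RenderRecord.from_json(json.loads(line)))
    return records
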