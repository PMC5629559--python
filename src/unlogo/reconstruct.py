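"""End-to-end reconstruction: logo image file -> position weight matrix.

The pipeline is: load -> optional user crop -> nearest-centroid color
classification -> noise removal -> axis detection -> full-scale (2-bit)
height -> column segmentation (honoring a user-supplied column count) ->
per-column height measurement and entropy inversion -> PWM assembly.

Recoverable anomalies (a column with no visible letters, a two-strong solve
that falls back to single-strong, a column-count override that disagrees
with what the image suggests) produce warnings on the result rather than
errors; hard errors are reserved for unreadable or blank input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import LogoError, ValidationError
from .image_prep import ColorMap, LogoImage, classify_image, load_image, remove_noise
from .logo_geometry import (
    ColumnLayout,
    LogoRegion,
    detect_axes,
    full_scale_pixels,
    measure_column,
    segment_columns,
)
from .pwm_core import PWM, ColumnEstimate, estimate_column, uniform_estimate


class Rect(NamedTuple):
    """A crop rectangle: top-left corner plus size, in pixels."""

    x: int
    y: int
    w: int
    h: int


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tunable knobs for one reconstruction run."""

    n_columns_override: int | None = None
    crop_rect: Rect | None = None
    secondary_min_px: int = 3
    flatten_alpha: bool = False
    noise_min_component_px: int = 4

    def __post_init__(self) -> None:
        if self.n_columns_override is not None and self.n_columns_override <= 0:
            raise ValidationError("n_columns_override must be positive")
        if self.secondary_min_px <= 0 or self.noise_min_component_px <= 0:
            raise ValidationError("pixel thresholds must be positive")


@dataclass(frozen=True)
class ReconstructionResult:
    pwm: PWM
    per_column: tuple[ColumnEstimate, ...]
    region: LogoRegion
    layout: ColumnLayout
    warnings: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (
            self.pwm.length == self.layout.n_columns == len(self.per_column)
        ):
            raise ValidationError("result column counts must agree")


def crop(img: LogoImage, rect: Rect) -> LogoImage:
    """Copy the sub-image under ``rect`` (x, y, w, h)."""
    rect = Rect(*rect)
    if rect.w < 1 or rect.h < 1:
        raise ValidationError("crop rectangle must have positive size")
    if (
        rect.x < 0
        or rect.y < 0
        or rect.x + rect.w > img.width_px
        or rect.y + rect.h > img.height_px
    ):
        raise ValidationError(
            f"crop rectangle {tuple(rect)} exceeds image bounds "
            f"{img.width_px}x{img.height_px}"
        )
    sub = img.pixels[rect.y : rect.y + rect.h, rect.x : rect.x + rect.w].copy()
    return LogoImage(pixels=sub, source_format=img.source_format)


def reconstruct(
    path: str | Path, config: ReconstructionConfig | None = None
) -> ReconstructionResult:
    """Reconstruct a PWM from a sequence-logo raster image."""
    cfg = config or ReconstructionConfig()
    img = load_image(path, flatten_alpha=cfg.flatten_alpha)
    if cfg.crop_rect is not None:
        img = crop(img, cfg.crop_rect)
    cmap = remove_noise(classify_image(img), cfg.noise_min_component_px)
    region = detect_axes(cmap)
    full_scale = full_scale_pixels(region, cmap)

    warnings: list[str] = []
    if cfg.n_columns_override is not None:
        try:
            auto_n = segment_columns(cmap, region, None).n_columns
            if auto_n != cfg.n_columns_override:
                warnings.append(
                    f"image suggests {auto_n} columns but override "
                    f"{cfg.n_columns_override} wins"
                )
        except LogoError:
            pass
    layout = segment_columns(cmap, region, cfg.n_columns_override)

    estimates: list[ColumnEstimate] = []
    for j, bounds in enumerate(layout.boundaries):
        stack, heights = measure_column(cmap, region, bounds)
        if stack == 0 or max(heights.values()) == 0:
            est = uniform_estimate("no letter pixels, filled with uniform 0.25")
        else:
            est = estimate_column(
                stack, heights, full_scale, secondary_min_px=cfg.secondary_min_px
            )
        warnings.extend(f"column {j + 1}: {w}" for w in est.warnings)
        estimates.append(est)

    pwm = PWM(probs=np.column_stack([e.probs for e in estimates]))
    return ReconstructionResult(
        pwm=pwm,
        per_column=tuple(estimates),
        region=region,
        layout=layout,
        warnings=tuple(warnings),
    )
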