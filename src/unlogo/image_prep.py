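"""Image loading, six-class color classification, and noise removal.

Every pixel of a logo image is assigned to the nearest of six fixed RGB
centroids: black (axes, tick marks, labels), white (background), and the
four letter colors of the common DNA scheme — green A, blue C, yellow G,
red T.  Nearest-centroid classification is deterministic and cheap, and
anti-aliased edge pixels are simply absorbed by whichever centroid is
closest; downstream height measurement works in whole pixel rows, which
tolerates a one-pixel fringe.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import AlphaChannelError, FormatError, LogoError, ValidationError

SUPPORTED_FORMATS = ("png", "jpg", "jpeg", "gif")


class ColorClass(enum.IntEnum):
    """The six color classes, in fixed tie-break order."""

    BLACK = 0
    WHITE = 1
    RED = 2
    GREEN = 3
    BLUE = 4
    YELLOW = 5


#: pre-determined color central points (RGB), indexed by ColorClass
CENTROIDS = np.array(
    [
        [0, 0, 0],        # black
        [255, 255, 255],  # white
        [200, 25, 32],    # red
        [57, 178, 65],    # green
        [43, 60, 147],    # blue
        [240, 173, 10],   # yellow
    ],
    dtype=float,
)

#: letter classes (everything that is neither background nor axis ink)
LETTER_CLASSES = (ColorClass.RED, ColorClass.GREEN, ColorClass.BLUE, ColorClass.YELLOW)


@dataclass(frozen=True)
class LogoImage:
    """An RGB pixel grid plus provenance metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    source_format: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("LogoImage pixels must be an H x W x 3 array")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ColorMap:
    """Per-pixel color classes, same shape as the source image."""

    classes: np.ndarray  # (H, W) uint8 of ColorClass values

    def __post_init__(self) -> None:
        cl = np.asarray(self.classes, dtype=np.uint8)
        if cl.ndim != 2:
            raise ValidationError("ColorMap classes must be 2-D")
        object.__setattr__(self, "classes", cl)

    @property
    def height_px(self) -> int:
        return self.classes.shape[0]

    @property
    def width_px(self) -> int:
        return self.classes.shape[1]


def _has_alpha(im: Image.Image) -> bool:
    return (
        im.mode in ("RGBA", "LA", "PA")
        or (im.mode == "P" and "transparency" in im.info)
    )


def load_image(path: str | Path, flatten_alpha: bool = False) -> LogoImage:
    """Load a PNG/JPG/JPEG/GIF file as a three-channel RGB grid.

    PNG files with an alpha channel are rejected unless ``flatten_alpha`` is
    set, in which case they are composited over white.  Animated GIFs
    contribute their first frame only; grayscale images are promoted to RGB
    by channel replication.
    """
    path = Path(path)
    ext = path.suffix.lower().lstrip(".")
    if ext not in SUPPORTED_FORMATS:
        raise FormatError(
            f"unsupported image format '.{ext}'; supported: {SUPPORTED_FORMATS}"
        )
    try:
        with Image.open(path) as im:
            im.load()
            if getattr(im, "n_frames", 1) > 1:
                im.seek(0)
            if _has_alpha(im):
                if ext == "png" and not flatten_alpha:
                    raise AlphaChannelError(
                        "PNG with alpha (transparency) channel is not supported; "
                        "pass flatten_alpha to composite over white"
                    )
                rgba = im.convert("RGBA")
                bg = Image.new("RGBA", rgba.size, (255, 255, 255, 255))
                im = Image.alpha_composite(bg, rgba)
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except LogoError:
        raise
    except OSError as exc:
        raise LogoError(f"cannot read image file {path}: {exc}") from exc
    return LogoImage(pixels=pixels, source_format=ext)


def classify_pixel(rgb) -> ColorClass:
    """Class of the nearest centroid under Euclidean RGB distance.

    Ties break by fixed class order (black, white, red, green, blue, yellow).
    """
    rgb = np.asarray(rgb, dtype=float).ravel()
    if rgb.shape != (3,):
        raise ValidationError("rgb must be a 3-tuple")
    d2 = ((CENTROIDS - rgb) ** 2).sum(axis=1)
    return ColorClass(int(np.argmin(d2)))


def classify_image(img: LogoImage) -> ColorMap:
    """Nearest-centroid classification of every pixel."""
    px = img.pixels.astype(np.int32)
    # (H, W, 6) squared distances; argmin keeps the first class on ties
    d2 = ((px[:, :, None, :] - CENTROIDS[None, None, :, :]) ** 2).sum(axis=3)
    return ColorMap(classes=np.argmin(d2, axis=2).astype(np.uint8))


def _letter_mask(classes: np.ndarray) -> np.ndarray:
    return np.isin(classes, [int(c) for c in LETTER_CLASSES])


_EIGHT = np.ones((3, 3), dtype=int)


def _strip_thin_black_lines(classes: np.ndarray) -> bool:
    """Remove 1-px-tall horizontal black components (dashes, gridlines).

    Axis lines are preserved: a component spanning at least half the image
    width is only removed when it sits strictly above the letter baseline
    (a background gridline crossing the logo), never at the baseline itself.
    Returns True when anything changed.
    """
    h, w = classes.shape
    black = classes == int(ColorClass.BLACK)
    if not black.any():
        return False
    letters = _letter_mask(classes)
    baseline = int(np.max(np.nonzero(letters.any(axis=1))[0])) if letters.any() else None
    labels, n = ndimage.label(black, structure=_EIGHT)
    changed = False
    for i, sl in enumerate(ndimage.find_objects(labels)):
        if sl is None:
            continue
        comp_h = sl[0].stop - sl[0].start
        comp_w = sl[1].stop - sl[1].start
        if comp_h != 1:
            continue
        wide = comp_w >= 0.5 * w
        inside = baseline is not None and sl[0].start < baseline - 1
        if (not wide) or inside:
            classes[labels == i + 1] = int(ColorClass.WHITE)
            changed = True
    return changed


def _strip_small_components(classes: np.ndarray, min_px: int) -> bool:
    """Reclassify non-white connected components below ``min_px`` pixels."""
    nonwhite = classes != int(ColorClass.WHITE)
    if not nonwhite.any():
        return False
    labels, n = ndimage.label(nonwhite, structure=_EIGHT)
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_px)
    small = small[small > 0]
    if small.size == 0:
        return False
    classes[np.isin(labels, small)] = int(ColorClass.WHITE)
    return True


def remove_noise(cmap: ColorMap, min_component_px: int = 4) -> ColorMap:
    """Remove speckle and background line patterns from a color map.

    Two rules, iterated to a fixpoint (which makes the operation idempotent):
    small non-white connected components (< ``min_component_px`` pixels) and
    1-px-tall horizontal black runs — dashed background lines, or full-width
    gridlines strictly inside the logo region — become white.  Letter pixels
    in components at or above the threshold are untouched, and white pixels
    are never converted to anything else.
    """
    if min_component_px < 1:
        raise ValidationError("min_component_px must be positive")
    classes = cmap.classes.copy()
    while True:  # terminates: every pass strictly shrinks the non-white set
        changed = _strip_thin_black_lines(classes)
        changed |= _strip_small_components(classes, min_component_px)
        if not changed:
            return ColorMap(classes=classes)
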