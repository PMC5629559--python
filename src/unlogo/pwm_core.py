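"""Position weight matrices and Shannon information-content inversion.

A DNA sequence logo encodes each motif position as a stack of letters whose
total height is the column's information content

    I = 2 + sum_i p_i * log2(p_i)        (bits, 0 for uniform, 2 for certain)

and whose per-letter heights are proportional to ``p_i * I``.  Reading
probabilities straight off the letter heights is unreliable for short stacks
(a 1-px rounding error on a 5-px stack is 20%), so reconstruction instead
measures the stack height, converts it to bits, and *inverts* the information
content equation under one of two structural assumptions:

* **single strong letter** — the three minor letters share the residual
  probability equally, ``p_weak = (1 - p_1st) / 3``;
* **two strong letters** — the second letter's probability is tied to the
  first by the measured height ratio, ``p_2nd = p_1st * h_2nd / h_1st``, and
  the remaining two letters share ``p_weak = (1 - p_1st - p_2nd) / 2``.

The two-strong case is used when the second-tallest letter shows at least
``secondary_min_px`` (default 3) pixel rows; below that, measured ratios are
dominated by rasterization noise and the single-strong model is safer.

Both equations are monotone in ``p_1st`` on their feasible domain, so they
are solved by a pre-computed lookup table bracket followed by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.optimize import bisect

from .errors import InfeasibleError, ValidationError

ALPHABET: tuple[str, str, str, str] = ("A", "C", "G", "T")

#: measured information content may overshoot [0, 2] by this much (bits)
#: before it is treated as an error rather than clamped; absorbs pixel
#: rounding and anti-aliasing slack.
INFO_CLAMP_SLACK = 0.05

_SUM_TOL = 1e-9


def _plogp(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the convention 0 * log2(0) = 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


@dataclass(frozen=True)
class PWM:
    """A 4 x L column-stochastic probability matrix.

    Rows are the nucleotides A, C, G, T in that fixed order (top to bottom in
    memory and in every file this package writes); columns are motif
    positions.
    """

    probs: np.ndarray
    alphabet: tuple[str, ...] = field(default=ALPHABET, init=False, repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValidationError(
                f"PWM must be a 4 x L matrix with L >= 1, got shape {probs.shape}"
            )
        if np.any(probs < -_SUM_TOL) or np.any(probs > 1 + _SUM_TOL):
            raise ValidationError("PWM entries must lie in [0, 1]")
        sums = probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _SUM_TOL):
            raise ValidationError("every PWM column must sum to 1 within 1e-9")
        probs = np.clip(probs, 0.0, 1.0)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits, each in [0, 2]."""
        return np.clip(2.0 + _plogp(self.probs).sum(axis=0), 0.0, 2.0)

    def column(self, j: int) -> np.ndarray:
        return self.probs[:, j]


def information_content(col) -> float:
    """Information content ``2 + sum p*log2 p`` of one probability column.

    Raises :class:`ValidationError` if the column is not a normalized
    4-vector of probabilities.
    """
    col = np.asarray(col, dtype=float).ravel()
    if col.shape != (4,):
        raise ValidationError("column must be a 4-vector")
    if np.any(col < -_SUM_TOL) or np.any(col > 1 + _SUM_TOL):
        raise ValidationError("column entries must lie in [0, 1]")
    if abs(col.sum() - 1.0) > _SUM_TOL:
        raise ValidationError("column must sum to 1 within 1e-9")
    return float(np.clip(2.0 + _plogp(col).sum(), 0.0, 2.0))


def _ic_single(p) -> np.ndarray:
    """I(p) for a single strong letter with the three weak letters equal."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    weak = np.zeros_like(p)
    pos = q > 0
    weak[pos] = q[pos] * np.log2(q[pos] / 3.0)
    return 2.0 + _plogp(p) + weak


def _ic_two(p1: float, r: float) -> float:
    """I(p1) for two strong letters with fixed height ratio r = p2/p1."""
    p2 = r * p1
    pw = (1.0 - p1 - p2) / 2.0
    pw = max(pw, 0.0)
    return float(2.0 + _plogp(np.array([p1, p2, pw, pw])).sum())


@dataclass(frozen=True)
class LookupTable:
    """Tabulated map from information content to p_1st.

    Entries pair ``p_1st`` on a regular grid over [0.25, 1.00] with
    ``I(p_1st)`` under the single-strong model; ``I`` is strictly increasing
    on this domain, which makes the table usable for bracketing.
    """

    p: np.ndarray
    info: np.ndarray

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.p.tolist(), self.info.tolist()))

    def bracket(self, target: float) -> tuple[float, float]:
        """Return (p_lo, p_hi) whose I values bracket ``target``."""
        idx = int(np.searchsorted(self.info, target))
        idx = min(max(idx, 1), len(self.p) - 1)
        return float(self.p[idx - 1]), float(self.p[idx])


def build_lookup(step: float = 0.01) -> LookupTable:
    """Tabulate I(p_1st) for p_1st from 0.25 to 1.00 at the given step."""
    if not 0 < step <= 0.25:
        raise ValidationError("lookup step must be in (0, 0.25]")
    n = int(np.floor(0.75 / step + 1e-12)) + 1
    p = 0.25 + step * np.arange(n)
    if p[-1] < 1.0 - 1e-12:
        p = np.append(p, 1.0)
    p = np.minimum(p, 1.0)
    return LookupTable(p=p, info=_ic_single(p))


@lru_cache(maxsize=1)
def _default_lookup() -> LookupTable:
    return build_lookup(0.01)


def _clamp_info(value: float, slack: float = INFO_CLAMP_SLACK) -> float:
    if value < -slack or value > 2.0 + slack:
        raise ValidationError(
            f"information content {value:.4f} bits outside [0, 2] beyond "
            f"the {slack} clamping slack"
        )
    return float(np.clip(value, 0.0, 2.0))


def solve_single_strong(info: float, table: LookupTable | None = None) -> float:
    """Invert I = 2 + p*log2 p + (1-p)*log2((1-p)/3) for p in [0.25, 1].

    The lookup table supplies a bracket; bisection refines it well below
    1e-4 bits.  Monotone nondecreasing in ``info``.
    """
    info = _clamp_info(info)
    if table is None:
        table = _default_lookup()
    if info <= 0.0:
        return 0.25
    if info >= 2.0:
        return 1.0
    lo, hi = table.bracket(info)
    f = lambda p: float(_ic_single(np.asarray(p))) - info  # noqa: E731
    if f(lo) > 0:
        return lo
    if f(hi) < 0:
        return hi
    return float(bisect(f, lo, hi, xtol=1e-7))


def solve_two_strong(info: float, height_ratio: float) -> tuple[float, float]:
    """Invert the two-strong-letter equation for (p_1st, p_2nd).

    ``height_ratio`` is h_2nd / h_1st in (0, 1], which pins
    ``p_2nd = height_ratio * p_1st``.  The feasible domain for p_1st is
    [1/(1+3r), 1/(1+r)] (second letter at least as probable as the weak pair,
    weak probability nonnegative), on which I is monotone increasing.

    Raises :class:`InfeasibleError` when ``info`` lies outside the achievable
    range by more than the clamping slack (an inconsistent measurement);
    callers fall back to the single-strong model.
    """
    if not 0 < height_ratio <= 1 + 1e-9:
        raise ValidationError("height_ratio must be in (0, 1]")
    info = _clamp_info(info)
    r = min(float(height_ratio), 1.0)
    lo = 1.0 / (1.0 + 3.0 * r)
    hi = 1.0 / (1.0 + r)
    info_lo = _ic_two(lo, r)
    info_hi = _ic_two(hi, r)
    if info < info_lo - INFO_CLAMP_SLACK or info > info_hi + INFO_CLAMP_SLACK:
        raise InfeasibleError(
            f"no two-strong solution: I={info:.4f} outside "
            f"[{info_lo:.4f}, {info_hi:.4f}] for ratio {r:.4f}"
        )
    if info <= info_lo:
        p1 = lo
    elif info >= info_hi:
        p1 = hi
    else:
        p1 = float(bisect(lambda p: _ic_two(p, r) - info, lo, hi, xtol=1e-7))
    return p1, r * p1


@dataclass(frozen=True)
class ColumnEstimate:
    """Reconstructed probabilities for one motif position."""

    probs: np.ndarray
    info_content: float
    case_used: str  # "single_strong" | "two_strong"
    top_letter: str | None
    second_letter: str | None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4,):
            raise ValidationError("ColumnEstimate.probs must be a 4-vector")
        if abs(probs.sum() - 1.0) > _SUM_TOL or np.any(probs < -_SUM_TOL):
            raise ValidationError("ColumnEstimate.probs must be a probability simplex point")
        if not 0.0 <= self.info_content <= 2.0:
            raise ValidationError("info_content must lie in [0, 2]")
        probs = np.clip(probs, 0.0, 1.0)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)


def uniform_estimate(warning: str | None = None) -> ColumnEstimate:
    """The fallback estimate for a column with no measurable letters."""
    return ColumnEstimate(
        probs=np.full(4, 0.25),
        info_content=0.0,
        case_used="single_strong",
        top_letter=None,
        second_letter=None,
        warnings=(warning,) if warning else (),
    )


def estimate_column(
    stack_height_px: int,
    letter_heights_px: Mapping[str, int],
    full_scale_px: int,
    secondary_min_px: int = 3,
    table: LookupTable | None = None,
) -> ColumnEstimate:
    """Convert measured pixel heights for one column into probabilities.

    Parameters
    ----------
    stack_height_px
        Number of pixel rows occupied by the whole letter stack.
    letter_heights_px
        Pixel rows per nucleotide (missing letters count as 0).
    full_scale_px
        Pixel height corresponding to the maximum 2 bits.
    secondary_min_px
        Minimum pixel rows for the second-tallest letter to count as a
        strong secondary letter (two-strong model); default 3.
    """
    if full_scale_px <= 0:
        raise ValidationError("full_scale_px must be positive")
    heights = {b: int(letter_heights_px.get(b, 0)) for b in ALPHABET}
    if any(h < 0 for h in heights.values()):
        raise ValidationError("letter heights must be nonnegative")
    if max(heights.values()) <= 0:
        raise ValidationError("empty column: all letter heights are zero")

    info = _clamp_info(2.0 * stack_height_px / full_scale_px)
    # tallest first; ties broken alphabetically (deterministic, no effect on
    # the probabilities themselves when heights are equal)
    order = sorted(ALPHABET, key=lambda b: (-heights[b], b))
    top, second = order[0], order[1]
    warnings: list[str] = []

    if heights[second] >= secondary_min_px:
        ratio = heights[second] / heights[top]
        try:
            p1, p2 = solve_two_strong(info, ratio)
            pw = max((1.0 - p1 - p2) / 2.0, 0.0)
            probs = np.full(4, pw)
            probs[ALPHABET.index(top)] = p1
            probs[ALPHABET.index(second)] = p2
            probs /= probs.sum()
            return ColumnEstimate(
                probs=probs,
                info_content=info,
                case_used="two_strong",
                top_letter=top,
                second_letter=second,
                warnings=tuple(warnings),
            )
        except InfeasibleError as exc:
            warnings.append(f"two-strong solve failed ({exc}); using single-strong model")

    p1 = solve_single_strong(info, table)
    pw = (1.0 - p1) / 3.0
    probs = np.full(4, pw)
    probs[ALPHABET.index(top)] = p1
    probs /= probs.sum()
    return ColumnEstimate(
        probs=probs,
        info_content=info,
        case_used="single_strong",
        top_letter=top,
        second_letter=None,
        warnings=tuple(warnings),
    )
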