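import numpy as np
import pytest

from unlogo import PWM, RenderStyle, render_logo

# A motif-like 8-position PWM: a mix of near-certain, two-letter, and
# softer columns, the regimes a transcription-factor binding site shows.
MOTIF8 = np.array(
    [
        # A     C     G     T
        [0.94, 0.02, 0.02, 0.02],
        [0.02, 0.90, 0.04, 0.04],
        [0.45, 0.45, 0.05, 0.05],
        [0.10, 0.10, 0.70, 0.10],
        [0.25, 0.25, 0.25, 0.25],
        [0.05, 0.15, 0.05, 0.75],
        [0.60, 0.30, 0.05, 0.05],
        [0.02, 0.02, 0.94, 0.02],
    ]
).T


@pytest.fixture(scope="session")
def motif8() -> PWM:
    return PWM(probs=MOTIF8)


@pytest.fixture(scope="session")
def rendered_motif8(motif8, tmp_path_factory):
    """The canonical test logo: motif8 rendered 600x200 with both axes."""
    path = tmp_path_factory.mktemp("logos") / "motif8.png"
    record = render_logo(motif8, RenderStyle(), path)
    return record


def ic_single_oracle(p: np.ndarray) -> np.ndarray:
    """Single-strong information content, written out independently."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log2(p), 0.0)
        q = 1.0 - p
        t2 = np.where(q > 0, q * np.log2(q / 3.0), 0.0)
    return 2.0 + t1 + t2


def grid_invert_single(target: float, step: float = 1e-6) -> float:
    """Brute-force inversion of the single-strong equation on [0.25, 1]."""
    p = np.arange(0.25, 1.0 + step / 2, step)
    return float(p[np.argmin(np.abs(ic_single_oracle(p) - target))])


def ic_two_oracle(p1: np.ndarray, r: float) -> np.ndarray:
    """Two-strong information content for p2 = r * p1, weak pair equal."""
    p1 = np.asarray(p1, dtype=float)
    p2 = r * p1
    pw = np.clip((1.0 - p1 - p2) / 2.0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = [np.where(x > 0, x * np.log2(x), 0.0) for x in (p1, p2, pw)]
    return 2.0 + terms[0] + terms[1] + 2.0 * terms[2]


def grid_invert_two(target: float, r: float, step: float = 1e-6) -> float:
    """Brute-force two-strong inversion over the feasible p1 interval."""
    lo, hi = 1.0 / (1.0 + 3.0 * r), 1.0 / (1.0 + r)
    p1 = np.arange(lo, hi + step / 2, step)
    return float(p1[np.argmin(np.abs(ic_two_oracle(p1, r) - target))])
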