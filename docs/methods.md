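# Methods

## The inversion model

A DNA sequence logo renders position *j* of a motif as a stack of letters
with total height proportional to the column's information content
`I_j = 2 + Σ_i P_ij log2 P_ij` (bits) and per-letter heights proportional to
`P_ij · I_j`. Reconstruction does not read probabilities off the letter
heights directly: for short stacks the relative error of a one-pixel height
difference is large, and it grows as information content falls. Instead the
pipeline measures the stack height, converts it to bits against the 2-bit
full scale, and inverts the information-content equation under one of two
structural assumptions:

- **Single strong letter.** The three minor letters share the residual
  probability equally, `p_weak = (1 − p_1st)/3`, and `p_1st` solves
  `I = 2 + p_1st log2 p_1st + 3 p_weak log2 p_weak`.
- **Two strong letters.** Used when the second-tallest letter occupies at
  least `secondary_min_px` pixel rows (default 3; below that, measured
  height ratios are dominated by rasterization). The second probability is
  tied to the first by the measured height ratio,
  `p_2nd = p_1st · h_2nd/h_1st`; the remaining two letters share
  `p_weak = (1 − p_1st − p_2nd)/2`.

Both equations are monotone in `p_1st` on their feasible domains, which
makes the inversion well posed:

- Single-strong: `p_1st` is restricted to [0.25, 1], where `I(p)` increases
  from 0 to 2. Below 0.25 the "strong letter" premise is violated, so that
  branch is excluded by construction.
- Two-strong with ratio `r`: `p_1st ∈ [1/(1+3r), 1/(1+r)]` — the lower end
  is where the second letter equals the weak pair, the upper end where the
  weak pair hits zero.

A column whose measured letters are all absent (a zero-information position
renders no pixels) is filled with the uniform column (0.25, 0.25, 0.25,
0.25) and flagged with a warning rather than treated as an error.

## Numerical choices

- **Lookup table + bisection.** `I → p_1st` is tabulated on a 0.01 grid over
  [0.25, 1] (76 entries); the table brackets the root and bisection refines
  it to well below 1e-4 bits. Nearest-entry lookup alone would bound the
  error only loosely; refinement is deterministic and costs microseconds.
- **Clamping slack.** Measured information content may fall slightly outside
  [0, 2] because stack heights are whole pixel rows; overshoot up to 0.05
  bits is clamped, larger overshoot is a validation error. The same slack
  applies at the ends of the two-strong feasible range: a measured `I` just
  beyond the achievable interval clamps to the endpoint, while one clearly
  outside it raises an infeasibility signal and the column falls back to the
  single-strong model with a warning. Without the endpoint slack, ordinary
  pixel rounding would needlessly demote consistent two-strong columns.
- **Ties.** Two equally tall top letters are treated as two-strong with
  ratio 1; top/second labels break alphabetically, which cannot change the
  probabilities. Nearest-centroid color ties break by fixed class order
  (black, white, red, green, blue, yellow).
- **Row order.** PWMs are always A, C, G, T top-to-bottom, in memory and in
  every file written.

## Image pipeline

- **Color classification.** Every pixel maps to the nearest of six fixed RGB
  centroids: black (0,0,0), white (255,255,255), red (200,25,32), green
  (57,178,65), blue (43,60,147), yellow (240,173,10); green/blue/yellow/red
  are A/C/G/T. Anti-aliased edge pixels simply take the nearest centroid —
  heights are measured in whole pixel rows, which absorbs a one-pixel
  fringe. PNG inputs with an alpha channel are rejected unless the caller
  asks for compositing over white; GIFs contribute their first frame;
  grayscale is promoted by channel replication.
- **Noise removal.** Two rules iterate to a fixpoint (hence idempotent):
  non-white connected components smaller than 4 pixels become white, and
  1-px-tall horizontal black components — dashed background lines, or
  full-width gridlines strictly above the letter baseline — become white.
  Axis lines are never touched: they are ≥ 2 px tall or sit at the baseline.
  Only the dashed-line case is canonical; the component-size heuristic and
  the threshold of 4 px are this package's own choice (configurable).
- **Axes and region.** Axes are assumed black: a straight black run spanning
  at least half the image height (width) hugging the left (bottom) of the
  letter area is the Y (X) axis. With axes present, the axis-line extents
  define the logo region, and the Y-axis pixel length is the 2-bit scale
  bar; this keeps the region (and hence the column count) correct even when
  an edge position renders no letters. Without axes the region is the
  bounding box of letter-colored pixels and the tallest stack is *assumed*
  to reach 2 bits — a stated convention that systematically inflates
  reconstructed information content for logos whose true maximum column is
  weaker. It is documented, not corrected.
- **Column segmentation.** The X-projection counts letter pixels per image
  column. Peaks are maximal nonzero runs (a 3-px closing is applied first if
  1-px gaps fragment single letters); consecutive peak-center spacings are
  rounded and the mode (ties toward the smaller value, which favors more
  columns and is recoverable by the snap step) is the column pitch. The
  column count is `round(region width / pitch)` unless the user supplies
  one, in which case the override wins and a disagreement is only a
  warning. Uniform boundaries are then snapped to the nearest projection
  minimum within ±25% of the pitch — a bounded correction that preserves
  the voted global layout.
- **Height measurement.** A column's stack height is the number of pixel
  rows containing any letter pixel. Each occupied row is assigned to a
  nucleotide by consensus vote (majority letter class in the row), and a
  letter's height is the number of rows it wins.

## The synthetic generator

The renderer is the test-fixture generator and deliberately shares no
measurement code with the reconstruction side, so round trips are a genuine
cross-check. It draws solid letterforms (DejaVu Sans Bold, binarized and
stretched to the exact target box with nearest-neighbor resampling — no
anti-aliasing of its own), stacks them largest-on-top with cumulative
rounding so glyph heights stay within one pixel of `P_ij · I_j` and sum to
the stack height exactly, and records the true PWM plus every glyph's pixel
box in a manifest.

Default study conditions, used by the evaluation harness and the acceptance
script: 100 logos, PWM columns drawn Dirichlet(1,1,1,1) (uniform on the
probability simplex), lengths uniform in 6–15, rendered 600 × 200 px with
both axes, 10 px margin, 4 px inter-column gap, standard colors. Evaluation
metric: Pearson correlation over the 4×L matrix entries flattened row-major
(a per-column averaged variant is available as an option). The correlation
definition is this package's choice of metric; for constant matrices the
correlation is defined as 1 when the matrices are equal and is otherwise an
error.

What the generator does *not* emulate: font anti-aliasing, JPEG-style
compression artifacts beyond what the JPEG coverage tests exercise,
numeric axis labels, per-letter outlines, below-axis (negative) letters,
multi-row wrapped logos, and non-standard color schemes. Passing round-trip
tests therefore demonstrate correctness of the geometry and inversion
pipeline under clean rendering, not robustness to arbitrary scraped
figures — the `--columns` and `--crop` rescue paths exist for those.

## Accuracy profile and known limitations

- On the default synthetic corpus the median round-trip correlation is
  ≈ 0.97–0.98 across seeds. The worst logos sit near 0.90, and that floor is
  a property of the *model*, not the pixel pipeline: re-running the
  inversion with exact continuous heights (no rasterization) on the same
  corpus moves the minimum by less than 0.003. Dirichlet(1) columns
  frequently carry three comparable letters, and a two-case model that folds
  the third letter into the equal-share weak pair cannot represent them.
  Sharp, real transcription-factor motifs are far from simplex-uniform, so
  their worst cases are milder.
- Without a Y axis, the 2-bit assumption for the tallest stack biases all
  probabilities upward whenever the true maximum column is weaker than 2
  bits.
- The 3-pixel secondary-letter threshold is absolute, not
  resolution-relative (configurable via `secondary_min_px`); at very high
  resolutions it admits faint second letters, at very low resolutions it
  suppresses real ones.
- Protein (20-letter) logos, probability-scaled logo styles, and count
  matrices with pseudocounts are out of scope.

## Problem sizes

The test suite renders and reconstructs one 100-logo corpus (the default
conditions above), a 50-logo corpus for column-count recovery (lengths
4–20), and assorted single fixtures; the whole suite runs in well under a
minute on one CPU. `scripts/acceptance.py` re-renders the 100-logo corpus
from scratch at the caller's seed.
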