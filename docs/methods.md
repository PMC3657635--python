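# Methods

This note documents the models, defaults and numerical choices behind
`mazedecode`, and what the synthetic testbed does and does not establish.

## Maze world

The maze is a 22 × 22 occupancy grid with an outer corridor ring, a central
cross and an inner ring. Seven door *pairs* sit on internal corridors; on
every trial exactly one door of each pair is open, and a closed door is a
wall for both route planning and rendering. The bundled layout was designed
so that the start, the four fixed-reward cells and all bonus sites remain
mutually reachable under **all 128** door configurations (verified
exhaustively); inner corridors may be temporarily walled off, which is
legitimate maze behavior, and detour waypoints are therefore drawn only
from the reachable component. Layouts are plain text (legend in
`maze_world`'s docstring) or a 22 × 22 grayscale image plus an annotation
file.

Coordinates are 0-based (row, col) tiles; continuous pose (x, y) in tile
units with tile centers at half-integers; heading in degrees,
counter-clockwise positive, 0° = east. Travel is 1 tile / 0.78 s at
20 frames/s (1/15.6 tiles per frame). The original apparatus's angular
speed is not documented anywhere we know of; turning is modeled as in-place
rotation at a default 6°/frame (0.75 s per 90° turn — commensurate with
the 0.78 s tile time), configurable. Straight runs are merged into single
segments before quantization so that frame counts follow
ceil(distance × 15.6) per segment rather than accumulating per-tile
rounding; a 22-tile corridor then takes ≈ 17 s as expected. Reward-cue
events fire at frame 0 (trial start) and at the frame each *cued* reward's
tile center is reached; crossing a reward cell out of turn does not collect
it. The bonus reward is inserted into the route at the point of minimum
added length, reflecting that it may be collected at any time.

The route planner stands in for the human navigator: breadth-first
shortest paths between consecutive goals, plus an optional per-leg detour
probability (default 0.25 in pipeline runs) that routes a leg through a
random reachable waypoint. This keeps candidate-track pools from being
degenerate and spreads trial durations over a plausible range; pipeline
track generation re-plans (with adapted detour rate, up to 8 attempts) when
a track falls outside the 57–195 s clamp.

The renderer is a textured ray-caster: one DDA ray per screen column,
perpendicular-distance projection, procedural brick texture with two-tone
side shading, darker sky above the horizon, and pictures as textured quads
on specific wall faces. Picture pixels are flagged in an integer mask, so
visibility is measured from actually rendered (occlusion-aware) pixels.
Default standalone resolution is 150 × 200 (H × W) at 60° field of view;
pipeline runs default to 72 × 96 and the test fixtures to 48 × 64 — scene
summaries at these resolutions are statistically indistinguishable for
decoding purposes and render an order of magnitude faster. The original
software's textures, field of view and exact screen geometry are unknown;
these are deliberate stand-ins.

## Variables

All variables are computed per frame and averaged in blocks of 60 frames
(20 fps × 3 s TR); a final partial block is averaged over the frames
available, so a track of F frames yields ceil(F/60) TRs. The census is
fixed: 6 quadrant pairs + 9 picture visibilities + 1 motion + 1 reward +
28 scene RMS + 28 scene Temp = 73.

* **Quadrant**: four 9 × 9-tile rectangles separated by a 2-tile central
  cross (the interior splits 9 + 2 + 9); the cross belongs to no quadrant.
  The label is taken from the TR-mean position; unassigned TRs are masked
  from training. Pair variables encode quadrant i as 1, j as 0, neither
  as 0.5.
* **Visibility**: share of scene pixels showing each picture (0 to 1,
  1 = picture fills the scene), from the rendered mask rather than
  projected-quad geometry — exact and occlusion-aware.
* **Motion**: signed per-frame heading change, left positive.
* **Reward**: 1 at TRs containing a reward-cue frame.
* **Scene RMS / Temp**: the scene is divided into a 5 × 5 grid whose middle
  square splits into 4 (28 regions; remainder pixels join the last
  row/column of cells). RMS is the *population* SD of luminance per region
  (the sample/population choice is not dictated by anything; population SD
  is fixed for reproducibility). Temp sums positive frame-to-frame
  luminance increases per region; the first frame scores 0.

## Synthetic fMRI

Each ROI has an encoding spec: voxel × 73 tuning matrix, noise SD (1.0),
drift amplitude, 2-TR lag. A voxel trace is

    data[v,t] = Σ_k tuning[v,k] · z_k(t − lag) + d1·t + d2·t² + ε,

with z the per-run standardized variables (time points before the run take
the run mean, i.e. 0), drift coefficients drawn per voxel and run uniformly
within ±2 on a time axis normalized to [−1, 1], and ε i.i.d. Gaussian.
Hemodynamics are a pure 2-TR shift — exactly the assumption the analysis
makes — with an optional double-gamma HRF convolution mode for robustness
checks. Noise is spatially independent; spatial correlation would degrade
but not bias decoding.

The default ROI roster mirrors the qualitative decodability structure of
cortical navigation data: V1/Ve/Pa tuned to scene content, visibility (and
partly motion), M1/PM to motion and reward, hippocampus weakly to quadrant
(snr multiplier 0.3), white matter to nothing. Tuned voxels (70% of an ROI)
each load on 1–3 variables of their ROI's sources, with a round-robin first
pass guaranteeing every variable of a tuned source at least one voxel.
Voxel counts (V1 100, Ve 80, Pa 60, M1 24, PM 36, Hi 40, WM 80) follow the
relative magnitudes typical of such ROI definitions, scaled down about
10-fold so the full 73 × ROIs × folds classifier census runs in minutes on
one CPU; they are config-driven. No quantitative effect sizes exist to
match, so `snr` is a free dial (default 3 "moderate"; recovery checks use
8 "high") and only the qualitative source × ROI pattern is claimed.

## Signal preparation

Normalization subtracts the scalar mean over all voxels and TRs of a run,
then removes per-voxel least-squares fits of [1, t, t²] (order: grand mean
first, matching the narrative order of the procedure; both steps are linear
so the order is benign; per-voxel detrending is the stricter of the two
possible readings). Alignment pairs the variable at TR t with the signal at
TR t + 2 *within* each trial, dropping the trailing unpaired TRs — the lag
never crosses trial boundaries.

## Decoding

Binarization rules (all thresholds fitted per cross-validation fold on the
training trials only, then reused on the held-out trial):

* quadrant — pairwise labels, out-of-pair TRs excluded;
* visibility / reward — yes vs no, with the "no" class subsampled
  (seeded, uniform) to at most 3× the "yes" class during training;
* motion — lower vs upper tertile of training values (right vs left
  turning); because simulated navigation is mostly straight, the tertile
  boundaries are clamped to be sign-consistent (negative = right,
  positive = left), which reduces to the sign split when zeros dominate;
* scene squares — below vs above the training median; constant squares
  (e.g. pure-sky regions under scene Temp) are skipped with a logged
  message, as is any fold whose training set degenerates to one class.

The classifier is a linear SVM with C = 1 (sklearn `SVC`), injectable for
alternatives such as regularized LDA/logistic regression. An iteration cap
of 10⁴ bounds non-separable (noise) fits, which otherwise spend seconds
converging to an equally uninformative hyperplane.

Calibration sorts training DVs, forms bins of 20 (a final partial bin is
kept if it has ≥ 10 points), and fits y = c + (1−c−d)/(1+exp((x−a)/b)) to
the per-bin (mean DV, mean positive-rate) pairs by least squares, seeded at
a = median DV, |b| = range/10 with the sign taken from the bin trend
(b < 0 gives an increasing curve), c = d = 0.05, c and d bounded in [0, 1].
Three guards make the fit robust: outputs are clipped to [0, 1]; outside
the binned DV support the boundary value is extrapolated as a constant (the
fit carries no information there); and the sigmoid is kept only when it
reduces bin SSE by at least 20% relative to the flat base-rate model —
otherwise predictions fall back to the base rate, preventing least squares
from chasing a single extreme noise bin. A clipped linear map through the
extreme bins serves as fallback when the fit fails outright.

Corrected accuracy pools hits and false alarms over folds; proportions of
exactly 0 or 1 are clipped to 1/(2n) and 1 − 1/(2n) with a *common* n (the
number of scored time points) for H and F. The common n is what makes the
always-majority worked example exact: H = F = 1 clips to equal values,
d' = 0, P = 50%. Per-class n's would break that identity.

## Ranking and combination

Per variable, predicted and actual traces are resampled (linear
interpolation, endpoints preserved) to the longest track's TR count and
standardized *separately, per variable, before concatenation* — the
wording of the procedure supports this reading, though it is ambiguous;
standardizing the concatenated vectors instead would change little since
every piece is already zero-mean/unit-variance. Zero-variance vectors
standardize to zeros rather than erroring, keeping degenerate variables
neutral. Ties in SS_diff receive midranks, so the expected rank under
exchangeability is exactly (n+1)/2. Combined scores are weighted means of
rank vectors with weight max(0, (R_chance − mean calibration rank) /
(R_chance − 1)); re-ranking weighted mean ranks or weighted mean normalized
ranks is equivalent when all pools are equal-sized, which holds here.
Weights come from a separate calibration split (session 1) by default, with
a same-split option for bias checks. Note the chance-rank formula gives
195.5 for a 390-track pool (not the rounded 196 sometimes quoted).

## Statistics

The empirical null collects normalized correct-track ranks of
non-informative (white-matter) decodings, one value per source × session
combination (each a mean over that combination's trials); significance
threshold is mean − 2.4 SD, reported to 2 decimals (≈ p = 0.01 under a
normal fit). A mean-of-k resampler (k = 6, 5000 draws, without replacement
within draws) provides the null for averaged combinations. The
foil-similarity analysis measures track similarity as the SS_diff between
standardized actual traces of the named source, compares the 5 most- vs 5
least-similar foils' assigned ranks across trials with a paired t-test,
and backs it with a 10,000-draw sign-flip permutation test for the small
samples typical of synthetic runs.

## Pipeline scales and determinism

Every random draw derives from the config seed through
`numpy.random.SeedSequence` children (all below 2³¹); reruns of a config
are byte-identical. The full default experiment is 2 sessions × 12 trials
with all 7 ROIs; the bundled fixture (2 × 6 trials, V1/M1/WM, 48 × 64
rendering) finishes in about a minute, and the test suite's study-scale
experiment uses 2 × 10 trials at snr 8. These sizes were chosen so a
complete simulate → render → encode → decode → rank → evaluate cycle is a
desk-scale computation while keeping ≥ 10 null values per run and a
20-track candidate pool.

## What the synthetic testbed shows — and what it does not

Passing tests establish that every stage is implemented correctly: the
extractors match brute-force recomputation, the decoder recovers planted
tunings at high snr and stays at chance on zero-tuning controls, ranking
is unbiased under the null, and combining complementary sources strictly
improves identification. They do *not* establish that real BOLD data
behave like the encoding model: real hemodynamics are convolutional and
variable, noise is spatially and temporally correlated, voxel tuning is
not sparse-linear, and eye movements decouple retinal input from the
rendered scene. Quantities that depend on those properties (absolute
accuracies, exact null SDs) transfer only qualitatively. The weighting
step can also dilute a single near-perfect combination at these small
scales — the integration benefit is therefore asserted on complementary
information sources, where it is the designed, robust effect.
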