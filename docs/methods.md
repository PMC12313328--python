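# Methods

This note documents the models, parameter choices, numerical schemes,
and known limitations of the `undulate` package: what is being
simulated, what the measured features mean, and what passing tests do
and do not establish about real recordings.

## Channel model

The undulating channel is three 50 µm regions of width 25/50/25 µm and
height 20 µm, fed from a wider lead-in.  The smooth width profile
`w(x)` interpolates the stepped geometry with logistic transitions;
`transition_scale` (default 10 µm) is defined as the 10–90 % width of
each step, so the width equals the nominal region width at every
region midpoint to better than 1 %.

The full 3-D flow field is reduced to a 1-D mass-conservation profile:
`v(x) = S·Q/(w(x)·h)` with flow rate `Q` (µL/min) and a single
calibration constant `S` (default 3.748×10⁷) chosen so a tracer
crosses the 150 µm channel in ~30 frames at 11 000 fps — the sampling
density the imaging configuration produces.  The shear-stress proxy is
the axial gradient `dv/dx = −S·Q·w′/(h·w²)`, computed analytically.
Its sign structure drives everything downstream: positive entering
each constriction, exactly one zero crossing at the cavity midpoint
(75 µm under defaults), negative on each expansion.  Only the shape of
`dv/dx` matters for the deformation trace; no absolute stress scale is
claimed.

The *effective* lead-in width (default 60 µm) sets how fast cells move
upstream of the constriction.  It is an effective parameter, not a
fabricated dimension: it is constrained by two facts about the
recordings being emulated — ~30 frames across the 150 µm channel, and
full coverage of the −30…170 µm alignment window within the 50-frame
sequence budget.  A physically wide reservoir with sheath focusing
behaves, on the centerline, like a moderately wider channel; 60 µm is
the value consistent with both constraints (window transit ≈ 47
frames).

One geometric consequence worth noting: the positive `dv/dx` maximum
in the second constriction sits just past the cavity/constriction
interface, ≈ 26–27 µm downstream of the zero crossing.  The approach
to the *first* peak is roughly twice as long, which is why every cell
deforms less in the second constriction than the first.

## Cell model and synthetic data

A cell is a constant-area ellipse (`a·b = r²`) whose anisotropy
`D = a/b` relaxes toward a stress-set equilibrium with a single time
constant:

    dD/dt = (D_eq(x(t)) − D)/τ,   D_eq = max(1 + k·dv/dx, 0.25)

This is the simplest constitutive law that reproduces the observed
trace — peak, relaxation to a sphere where `dv/dx = 0`, smaller second
peak, relaxation — and it makes the linear R2/R3 slopes meaningful.
`k` (seconds) and `τ` (milliseconds) are *generator constructs*: they
parameterize how strongly and how fast a phenotype responds, and are
not estimates of any real cell's rheology.  `D_eq` is floored at 0.25
to keep extreme parameter draws physical.

Default phenotypes (normal distributions truncated at zero):

| phenotype | k mean ± sd (s) | τ mean ± sd (ms) | radius (µm) | role |
|---|---|---|---|---|
| HL60-like  | 6.0e-5 ± 1.0e-5 | 0.042 ± 0.008 | 6.0 ± 0.4 | untreated control |
| HL60d-like | 8.5e-5 ± 1.2e-5 | 0.034 ± 0.007 | 6.0 ± 0.4 | actin-disrupted: most deformable, fastest |
| HL60n-like | 4.0e-5 ± 1.5e-5 | 0.050 ± 0.010 | 6.0 ± 0.4 | microtubule-disrupted: least deformable, slowest, most variable |

The gains are calibrated against the channel's peak `dv/dx`
(≈ 4.8×10³ s⁻¹ per µL/min at the first entrance) so the untreated-like
population peaks near AR ≈ 1.25 and orderings rD1, |R2 slope|:
HL60d > HL60 > HL60n hold with clear margins.  The τ values keep the
relaxation lag small enough that cells pass closest to a sphere within
5 µm of the stress zero crossing (lag ≈ v·τ ≈ 1.5–2.5 µm, plus ±1.7 µm
frame quantization at ~3.4 µm/frame in the cavity).  Radii are drawn
from the same distribution for all phenotypes by design: size and
resting morphology carry no class information, so classification can
only exploit mechanics — the hardest version of the problem, and the
property several acceptance checks rely on (the cavity-mask control
must sit at chance).

Integration is fixed-step RK4 on (x, D), vectorized over cells, with
≥ 10 substeps per frame and the substep count raised automatically so
`dt ≤ τ/2` (the relaxation equation is stiff when τ is far below the
frame interval; the τ→0 quasi-static check runs at τ = 1 ns-scale with
a few hundred substeps).  A halved step changes trajectories at the
1e-6 level, far below any tolerance used.

Masks are rasterized at 0.26 µm/pixel: a pixel is set when its center
lies inside the ellipse boundary, optionally perturbed by smooth
angular noise (Fourier modes 2–8, RMS `boundary_noise_sd` = 0.5 px) to
emulate segmentation error.  Cells ride the channel axis with a small
per-cell lateral offset (σ = 0.8 µm).  Entry times are exponential
with mean 10 ms, floored at 1.2 ms because consecutive cells are
excluded-volume objects — two cells cannot occupy the same axial
position, and the floor keeps inter-cell spacing ≥ 13× the per-frame
advance everywhere, which is also what makes nearest-neighbor linking
well-posed.  Artifact injection (cells first appearing mid-channel;
single concave crescent frames) uses exact counts `round(fraction·n)`
so filter tests can assert exactly.

Every stochastic draw comes from a substream keyed by (seed, cell id),
so datasets are byte-reproducible and invariant to generation order.

What the generator does **not** emulate: brightfield texture, motion
blur, cell–wall interactions, friction, 3-D lift forces, segmentation
failures other than boundary noise and the injected crescents, and any
nonlinear or multi-timescale rheology.  Consequently, passing tests
demonstrate that the *pipeline* measures, filters, classifies and
ranks correctly on data whose generative truth is known — not that the
specific accuracies transfer to real recordings.

## Tracking

Greedy frame-to-frame nearest-neighbor linking with a forward-motion
constraint (Δx ≥ −1 µm), a gate of 15 µm (≈ 2× the largest per-frame
advance), ties broken by smallest Δx then lowest y, and track
termination after 3 consecutive missed frames.  Cells are strictly
advected and cannot cross, so global assignment is unnecessary.
Detections beyond the alignment window + 3 µm are ignored by the
tracker: near the outlet cells leave the camera field at slightly
different positions, and linking there can hand a track to a trailing
cell; the 3 µm margin exceeds the largest per-frame advance, so every
surviving track still reaches the window end.  Validation discards
trajectories that first appear past x = 0 ("impossible start" — no
real transit begins mid-channel) or fail to span −30…170 µm
("incomplete span").

## Features

The ellipse fit is moment-based (exact for solid ellipses): centroid
from first moments, principal axes from the second-central-moment
eigen-decomposition.  AR uses the axis-aligned convention —
`sqrt(μ20/μ02)`, the projected extent along the channel over the
perpendicular extent — so compression is representable as AR < 1.
This matters because the model (and plausibly the real flow) compresses
cells on cavity entry; the cavity AR *minimum* is then a true baseline
and rD ≥ 0 holds exactly.

The convex-hull ratio is hull area over mask area, computed from the
hull of pixel centers (no half-pixel offset) so digitized convex shapes
score ≈ 1.0 rather than inheriting an O(1/r) bias; the filter threshold
1.1 is strict (`>`).  The 3-SD radius filter is defined on the pooled
population of per-trajectory mean radii and applied after pooling
(`≥ 3·SD` excludes).  Phase partition: peak 1 = AR argmax before the
cavity, baseline = AR argmin inside the cavity, peak 2 = AR argmax
downstream of the baseline; phases with fewer than three frames are
flagged degenerate and their slopes propagate as NaN rather than
raising.  Slopes are plain OLS of AR against x, in µm⁻¹.  Moments use
the standard normalized central moments and Hu's seven invariants.

Sequences clip to the alignment window, post-pad with zeros to length
50 and carry an explicit validity mask (padding side/value are a free
choice; the mask makes it irrelevant).  Mask sequences center each
mask in a 96×96 crop, add the rasterized fitted ellipse as a second
channel, and pad the same way.

## Classifiers

Protocol for every model: stratified seeded 70:15:15 split;
standardization statistics from the training partition only;
hyperparameters (tabular grid) or the best epoch (sequence models)
selected on validation accuracy, with ties resolved toward later
epochs (a barely-trained network can ace a small validation set by
luck); reporting on the untouched test partition.  The confusion
matrix is row-normalized by true-label count and accuracy is the mean
of its diagonal.  Stratified five-fold cross-validation reports
mean ± SEM with every fold trained from scratch.

The random forest and SVM are scikit-learn.  Feature attributions are
*exact* interventional Shapley values by subset enumeration (all 2^d
coalitions for d ≤ 12, the base feature set being d = 5), with the
coalition value averaged over a background sample; the efficiency
identity (per-sample attributions sum to prediction − base value)
holds to numerical precision and is asserted.  Beyond 12 features a
seeded permutation-sampling estimator is used.

The GRU and CNN-GRU are compact numpy implementations with manual
backpropagation (gradient-checked against finite differences in the
test suite) and Adam.  Padded steps are skipped by carrying the hidden
state through unchanged, so padding cannot masquerade as signal — a
property tested directly by hiding the label in the padded tail.  The
CNN-GRU encoder (weights shared across timesteps) is: 4×4 average
input pooling → 3×3 conv (8 filters) → ReLU → 2×2 max pool → 3×3 conv
(16 filters) → ReLU → global average pool → GRU.  The parameter-free
input pooling is precomputed once per fit, and the encoder runs in
float32; both are pure speed choices.  Global *average* pooling is
retained deliberately: the discriminative signal is a sub-pixel-scale
anisotropy of an otherwise blank mask, which average pooling encodes
as smooth fractional coverage.  Default training schedules for the
acceptance-scale fixtures (800 sequences) are 50 epochs for the GRU
and 30 for the CNN-GRU; the 175-epoch default in the pipeline config
reflects the full training protocol for larger runs.  Sequence-model
results are reproducible to within ~0.02 accuracy across environments
(BLAS reduction order); tabular reports are bit-reproducible.

On the default synthetic fixture the scalar features are a nearly
sufficient statistic for the generative parameters, so the GRU and
CNN-GRU match rather than beat the random forest (the tested property
is parity within 0.05).  The paper-scale deep-learning gains would
require the real recordings' unmodeled structure.

## Enrichment

Expected-value Bayes accounting: `precision = TPR·p/(TPR·p+FPR·(1−p))`,
`enrichment = precision/p ≤ 1/p`, strictly increasing in TPR and
decreasing in FPR and p, equal to 1 when TPR = FPR, and ≈ TPR/FPR for
rare targets — so enrichment doubles each time FPR halves until it
saturates near 1/p.  No finite-sample (hypergeometric) correction is
applied.

## Problem sizes

The test suite and acceptance script run the full method at desk
scale, chosen as the smallest sizes at which the statistical checks
are well-powered: 300 cells/phenotype for simulator-fidelity
statistics (noise-free trajectories), 400/phenotype rendered and
tracked for feature and classifier checks (800 sequences for the
HL60-vs-HL60d pair), 150/phenotype in the acceptance script.  The
tracking-exactness check uses 20 independent two-cell recordings with
injected mid-channel artifacts.

## Known limitations

- The 1-D velocity profile has no cell–fluid coupling; `k` and `τ`
  absorb all rheology and are not identifiable from first principles.
- AR measurement bias from rasterization is ~0.5 % at the default
  resolution; slopes inherit a proportional bias.  The cavity AR
  plateau (|AR−1| < 0.002 over ~15 µm) means the *measured* most-
  relaxed frame is localized only to that plateau, while the
  generative trace localizes it to the zero crossing.
- Touching cells are rendered as separate detections (a perfect
  segmenter); the TIFF round-trip merges them into one component,
  which the hull filter then removes — a realistic but untested-at-
  scale failure mode.
- Binary tasks only; the three-phenotype problem is handled as pairs.
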