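# Methods

`arenatrack` models a parallel two-choice preference assay for small
walking insects (the motivating case is the Western flower thrips,
*Frankliniella occidentalis*, on leaf discs of two plant genotypes).
One insect is sealed into each well of a backlit multi-well plate; a
camera above the plate records all wells at once; per-well
trajectories are turned into choice and activity parameters; and the
same pipeline supports planning of multi-round genotype screens.
This note documents the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data do and
do not establish.

## Spatial conventions and calibration

Image coordinates have their origin at the top-left corner, x
rightward, y downward. Positions refer to pixel centers: the center
of pixel column *i* is at (*i* + 0.5)/s mm, where s is the pixel
density in px/mm. Calibration is isotropic; a horizontal/vertical
scale disagreement above 1% is rejected rather than averaged, because
silently averaging an anisotropic setup corrupts every downstream
distance. The default setup images a 100 × 75 mm field at 1280 × 960
px and 3.5 frames/s, giving s = 12.8 px/mm, 163.84 ≈ 164 px/mm², a
78 µm pixel, and a ~69 px footprint for a 1.4 × 0.3 mm insect.

Zones are simple polygons in mm. The standard two-choice arena has a
reference-leaf and a test-leaf half-disc (6 mm disc cut in half,
flat edges facing) and, in the three-zone scheme, an off-leaf zone.
The off-leaf zone is represented as the full well polygon *underlying*
the leaf zones; a fixed precedence (reference_leaf, test_leaf,
off_leaf) resolves every point deterministically, including boundary
points (boundaries count as inside). Two leaf zones strictly
containing the same point is a configuration error. This underlay
representation was chosen over a ring-with-holes polygon because it
keeps every zone a simple polygon while guaranteeing that the
three-zone scheme covers the arena exactly.

## Synthetic arenas

The generator has two layers.

**Behavioral states.** A discrete-time Markov chain at frame
resolution over four states: feeding on the reference leaf, feeding
on the test leaf, walking, resting off-leaf. Walking is a persistent
random walk (heading diffusion sd 0.6 rad/frame) with Gaussian speed
(default mean 0.7, sd 0.25 mm/s — above the movement-start
threshold); feeding and resting add only a 0.02 mm/s positional
jitter, below the movement-stop threshold. The well wall is
reflective; wall-climbing and lid-walking, which the real insects do,
are absorbed into the off-leaf state rather than modelled in 3-D.
When the chain enters a feeding state while the agent is outside the
target leaf, the position snaps to the nearest interior point of that
polygon. This keeps the state/zone consistency invariant exact; the
resulting one-frame speed transient is the abstraction of walking
onto the leaf, and with multi-minute feeding bouts it moves the
recovered not-moving time by well under the 5% round-trip tolerance.

Bout durations are geometric by construction (one per-frame exit
probability per state); no claim is made that real insects have
geometric bout-length distributions.

**Preset `cur3_vs_rmx`.** Fitted, not measured: walk bouts of mean
45 s; on leaving a walk, 55% of exits rest (mean 330 s) and 45% feed,
with a 0.53 entry bias toward the test leaf; feeding bouts of mean
280 s (reference) vs 450 s (test). Over an 8-h, ~68-arena run these
values put roughly 37/63 of on-leaf time on reference/test, zone
durations near 5100/8800 s, and a roughly two-fold activity-ratio
contrast between the leaves — the scale of contrast the assay is
meant to detect between a resistant and a susceptible genotype. The
`no_preference` preset equalizes the feeding bouts and the entry bias
and is used for null calibration.

**Rendering.** Subjects are drawn as dark ellipses (axes = body
length × width, long axis along the motion direction) on a bright
backlit background (gray 200) with mid-gray leaf polygons (130);
optional Gaussian pixel noise is seeded. No leaf texture, shadows or
illumination drift are simulated, so a perfect score on noise-free
synthetic video bounds tracker correctness, not real-video
robustness.

## Detection and tracking

Detection thresholds the difference (background − frame) in
[contrast_min, contrast_max] = [8, 255] gray levels — dark contrast
only, since a backlit subject can only be darker than the background.
"Medium" smoothing is one pass of 3 × 3 binary median filtering.
Connected components use 8-connectivity (4-connectivity splits thin
diagonal bodies); components outside [10, 160] px are discarded;
survivors are reported with their pixel-centroid in mm.

The background model is an exponential running average,
`new = (1 − rate) · old + rate · frame` with rate 0.05/frame,
optionally frozen under pixels currently occupied by a subject so a
long feeding bout is not absorbed into the background. The model
should be initialized from subject-free imagery (a rendered empty
scene, or a pixelwise median across spread-out frames, as the CLI
does); initializing from the first frame leaves a ghost at the
subject's starting position, and a subject that never moves is then
never detected.

Linking is single-target per arena: per frame the candidate nearest
the last accepted position wins (nearest the arena center on the
first frame); ties break by larger area, then lower index. Up to 14
consecutive missed frames (~4 s at 3.5 fps) are imputed, by holding
the last position (default — a hidden resting subject has not moved)
or by linear interpolation once the gap closes; longer gaps stay
undetected. Tracks whose total path length is below one body length
(1.4 mm) over the whole recording are discarded as dead subjects.

## Movement segmentation and summaries

Speed at sample *i* is the step distance from sample *i* − 1 divided
by the frame period; the first sample has speed 0. A two-state
hysteresis machine, starting in not-moving (subjects are placed
anesthetized), switches to moving when the trailing windowed mean
speed exceeds 0.5 mm/s and back when it drops below 0.1 mm/s. The
window is 10 frames (≈2.9 s at 3.5 fps), trailing (causal), with a
fixed denominator — the slots before the start of the recording count
as zero speed. Events are maximal runs of the per-sample state; each
sample owns [t, t + dt), so event durations tile the recording
exactly and whatever is open at the end closes at the final sample.
Near-exact ties between a window sum and a threshold are resolved by
floating-point rounding; they have measure zero for real speed data.

Summaries count samples: a sample with a valid (detected or imputed)
position contributes dt to exactly one zone and to exactly one of
moving/not-moving, which makes the tiling identities exact rather
than approximate. The activity ratio is moving/not-moving time (NaN,
never infinity, when not-moving is zero); movement velocity is
distance covered while moving divided by moving time. Time bins are
half-open, anchored at the recording start, so binned durations sum
to whole-recording values exactly. The preference proportion offers
both denominators in use for such assays — total detected time (the
screening metric) and on-leaf time — defaulting to total time.
Validation against reference annotation reports both Pearson and
Spearman correlation (with r²), since both are current practice.

## Screening statistics

Paired two-choice comparisons use the Wilcoxon signed-rank test
(zero differences dropped, midranks for ties; exact p by
dynamic-programming enumeration of the signed-rank null for n ≤ 25,
normal approximation with tie correction beyond) or the paired
Student's t, routed automatically by a Shapiro test on the
differences at the same alpha. scipy's implementation serves as an
independent cross-check in the tests, not as the implementation.
No multiple-testing correction is applied across accessions in a
screen; users comparing hundreds of genotypes should apply their own.

The multi-round screen design allocates N accessions to b blocks of
k per round, independently re-randomized each round, with the
reference leaf-disc side alternating by plate row to cancel position
bias. Efficient alpha-lattice generators are deliberately not
implemented: the analysis model, not lattice optimality, is what the
genotype means require. Genotype means (BLUEs) come from the mixed
model Y = µ + REP + GEN + REP:BLOCK + E with blocks-within-round
random, fitted by REML with the single variance ratio
λ = σ²_block/σ²_e profiled out: the λ-profile is evaluated on a log
grid and refined by bounded scalar optimization, with an explicit
λ = 0 boundary comparison. Group-sum (Woodbury) identities make each
profile evaluation O(N·p), so the full 360-genotype, 5-round fit
takes well under a second. Estimated marginal means average over
rounds; with a balanced design and λ → 0 they reduce to raw genotype
means (tested).

## Replicate-number power simulation

Two pools of 10,000 values are drawn from the group normals; for each
replicate level n ∈ {5, 10, 15, 20, 25, 30}, 1000 (or more) paired
subsamples of size n are drawn without replacement within an
iteration (pools are reused across iterations), a paired t-test is
run per iteration, and the percent of p < 0.05 outcomes is reported
per level, along with the smallest level strictly exceeding a 50%
threshold. Within-replacement row draws with duplicate-row rejection
implement the without-replacement sampling exactly.

Two numerical points. First, the paired members are drawn from
independent pools, so the implied cross-correlation is zero; real
paired designs are positively correlated, making these percentages
conservative. Second, pools are moment-matched by default (shifted
and scaled to their specified mean and SD): near 50% power the
sampling error of a finite pool's realized moments otherwise
dominates the Monte-Carlo error and can flip the minimum-replicates
answer between adjacent levels; matching enforces the stated group
parameters exactly and is standard variance reduction
(`standardize_pools=False` restores raw draws). A closed-form
noncentral-t power (effect size d = |Δµ|/√(σ₁² + σ₂²),
noncentrality d√n) is computed alongside as an independent oracle;
simulation and closed form agree within 3 percentage points at 1000
iterations for all built-in presets. Negative values can arise from
normal draws for damage-scale presets and are retained untruncated.

Built-in presets (assay units): `video_8h` 7926 ± 5252 vs
12159 ± 5610 s, `video_1h` 1352 ± 783 vs 1890 ± 912 s,
`detached_leaf` 8.5 ± 9.9 vs 45.6 ± 24.4 mm², `whole_plant`
837.7 ± 187.2 vs 25.7 ± 16.5 mm².

## Problem sizes in the test suite

Tests scale simulations to what the checks need: render-based checks
use a 2 × 2-arena plate on a 20 × 20 mm field at the same 12.8 px/mm
scale (250 frames → 1000 arena-frames for the one-detection-per-frame
invariant; 2-min recordings for the position round trip); the
simulator symmetry check uses 200 agents for 1 h; the end-to-end
plate check runs the full 88 arenas for 8 h on the tracks-first path
(no rendering), which completes in about two minutes. The
minimum-replicates checks use 10,000 iterations per level; null
calibrations use 4,000–10,000 replicates.

## Known limitations

- The renderer's uniform background and noise model are far cleaner
  than real backlit video (condensation, flicker, leaf texture);
  passing round-trip tests demonstrates internal consistency, not
  field robustness.
- Micro-behaviors (probing, head-nodding) and short- vs long-bout
  classification are out of scope; the not-moving state is a proxy
  for feeding that deliberately aggregates them.
- One subject per arena is assumed throughout; the linker has no
  identity model for multiple subjects.
- The commercial trackers' exact background, contrast and smoothing
  algorithms are proprietary; the definitions here (running-average
  background, darkness contrast, 3 × 3 binary median) are the
  standard open equivalents and are recorded in run provenance.
- Simulator bout lengths are geometric; real bout-length
  distributions are not claimed or calibrated.
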