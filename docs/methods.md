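# Methods

## Scope and model

The package quantifies three things about zebrafish lateral-line hair
cells: (i) the kinetics of stimulus-evoked calcium responses in the
cytoplasm and in mitochondria, (ii) per-cell cumulative mitochondrial
state read out as a background-subtracted red:green fluorescence ratio
normalized within each neuromast, and (iii) how well a cell's
ratio — split at its neuromast's median — predicts death after neomycin
exposure. Real inputs are exported microscopy artifacts (OME-TIFF
stacks, integer label maps, CSV trace/cell tables); a synthetic-data
generator stands in for them with known ground truth so the whole chain
is testable.

## Trace kinetics

Traces are normalized to F/F₀ with F₀ the **arithmetic mean** of the
pre-stimulus baseline frames (≥ 3 required); the mean rather than the
median is the common ΔF/F convention and no robust estimator is needed
for synthetic or well-behaved data. Three metrics:

* **Integrated area** — Σ over stimulus-window frames of (F/F₀ − 1).
  Summing the baseline *excess* (not raw F/F₀) makes a flat trace score
  zero and keeps the area additive over window partitions; the raw sum
  is available behind `baseline_excess=False`. Windows are half-open
  frame-index ranges [start, end).
* **Peak** — max of F/F₀ from stimulus onset to trace end.
* **75% rise time** — elapsed time from onset to the first crossing of
  1 + 0.75·(peak − 1), linearly interpolated between the bracketing
  frames. The threshold is relative to baseline because 0.75·peak would
  lie below baseline whenever peak < 4/3 (true of typical cytoplasmic
  peaks ≈ 1.3). A trace whose peak does not exceed baseline has *no*
  rise time; it is reported missing, never zero.

All three metrics are invariant to multiplicative rescaling of the raw
trace (property-tested).

## Synthetic traces

The generator uses a saturating-exponential rise toward
baseline·(1 + amplitude) during the stimulus and an exponential decay
after it, plus additive Gaussian noise. The functional form is a
modeling choice — only summary kinetics constrain it — and it is the
simplest shape with independently tunable rise and decay. The rise
constant is parameterized by the target 75% rise time via
t75 = τ·ln 4 (the asymptotic relation), so configurations cite rise
times directly; defaults are t75 = 8.9 s / amplitude 0.3 (cytoplasmic)
and 13 s / 0.5 (mitochondrial), the reported summary kinetics. With the
default 40 s stimulus at 1 s frames the finite stimulus window biases
the measured rise time by ≤ 0.4 s, inside the one-frame tolerance the
tests use. Decay constants (5 s cytoplasmic, 30 s mitochondrial) are
free parameters chosen only to reproduce the qualitative fast/slow
offset asymmetry; nothing downstream depends on them.

Ground truth stores the analytic noise-free peak and rise time and the
noise-free area on the sampling grid. Note a structural limit: with the
configured peaks and rise times and a single shared stimulus window,
this trace family yields a mitochondrial:cytoplasmic area ratio of
roughly 1.5, not the ≈ 2 seen in real recordings (11 vs 5.6) — real
responses are not single saturating exponentials. The generator
reproduces the ordering (mito > cyto), which is what the tests assert.

## Synthetic cohorts

Each cell's outcome is Bernoulli(death_frac = 74/216); its ratio is
then drawn from the outcome-group normal — live N(0.77, 0.37), die
N(1.30, 0.34), the printed group summaries — truncated at zero
(ratios are nonnegative). A logistic mode draws the ratio from the
two-group mixture and the outcome with P(die) = expit(β₀ + β₁·ratio).
Ratios are re-normalized per neuromast so every neuromast's median is
exactly 1, mirroring the analysis convention; ground truth keeps both
pre- and post-normalization values. Hoechst/age status marks the top
`frac_older` fraction (default 0.36, the observed labeled fraction) of
each neuromast ranked by pre-normalization ratio — a deliberate,
deterministic coupling standing in for the empirical older-cells-are-
redder association.

The default layout is 15 cells × 3 neuromasts per fish, matching ~216
cells over ~14 neuromasts from six fish. The **odd** cluster size
matters: the median cell of an odd-sized neuromast equals the median
exactly and therefore classifies green under the strict ">" rule, which
is what brings simulated sensitivity to ≈ 0.78–0.80 (with even-sized
clusters it sits near 0.83). The observed accounting (100 red vs 116
green of 216) shows the same one-extra-green-per-cluster signature.

What the generator does **not** emulate: skewed or heavy-tailed ratio
distributions, within-neuromast spatial correlation of fate,
fish-level random effects, and any dependence between a cell's ratio
and its neighbors. Passing tests therefore show the pipeline's
arithmetic and the statistics' behavior under the stated distributional
model, not robustness to real-data pathologies.

## Synthetic stacks

Cells are laid out as a rosette (center spot plus concentric rings, arc
spacing 2.4 cell radii) well clear of an auto-placed 30 × 30 µm
background square in the far image corner; generation fails loudly if
the geometry cannot keep them disjoint. Each cell is a cluster of
puncta deposited at random sub-cell offsets; green punctum intensity is
fixed and red is green × true ratio, so after identical Gaussian PSF
blurring of both channels the in-mask red:green ratio equals the true
ratio exactly in noise-free renders (blur cancels in the ratio). The
nuclear channel renders Hoechst-positive nuclei as crisp whole-cell
disks (the sub-pixel PSF is irrelevant at nuclear scale and blur spill
into neighboring masks would corrupt the 1-SD retention rule). Uniform
background plus optional Gaussian camera noise completes the render.
Optics deliberately omitted: photobleaching, shot noise, z-dependent
aberration, drift.

Defaults: 9 z-planes at 2 µm (the acquisition sectioning), 160×160
pixels at 0.4 µm, cell radius 2.8 µm, 8 puncta/cell, PSF σ 0.3 µm,
background 20 AU.

## Ratiometric measurement

Background mean and SD are taken on the **max projection**, per channel
independently, from the 30 µm square (side = round(30/pixel-size)
pixels); the square must not intersect any cell label. The per-cell
value is (mean in-mask intensity − background mean); negatives
propagate by default so error accumulation is visible (clipping is
opt-in), and a cell with non-positive green mean has an *undefined*
ratio — it is excluded from summaries and counted, never silently
dropped. The ratio is the ratio of background-subtracted channel means
(not the mean of per-pixel ratios). The Hoechst rule uses the sample SD
(n−1 denominator) of the nuclear-channel background. Per-neuromast
normalization divides by the within-neuromast median; per-fish
aggregation averages neuromast means so the statistical n is fish.

## Classification statistics

Ties at the median (normalized ratio exactly 1) classify green —
"above median" is strict — and the tie count is logged so totals
reconcile. The diagnostic odds ratio with a zero cell returns a flagged
non-finite value by default; the Haldane–Anscombe +0.5 correction is
opt-in. Fisher's two-sided p sums hypergeometric probabilities of all
same-margin tables with probability ≤ the observed table's (the
"probability-at-most-observed" convention), computed with log-gamma
arithmetic; tests verify it against exact-fraction enumeration and
scipy. The probability of superiority is provided both empirically
(pair counting with ties at ½, identical to U_B/(n_A·n_B) by
construction) and as the normal reconstruction
Φ((μ_B − μ_A)/√(σ_A² + σ_B²)) for when only group summaries are
printed; the 0.85 figure is the reconstruction route. The Mann-Whitney
p-value uses the tie- and continuity-corrected normal approximation.
Display rounds proportions and the DOR to 2 d.p. and percent changes to
1 d.p.; machine outputs keep full precision.

## Determinism and problem sizes

Every artifact kind draws from its own child stream
(`SeedSequence(seed, spawn_key=(k,))`) of the single master seed, so
equal (seed, config) gives bit-identical artifacts and adding one
artifact kind never perturbs another. The reproduction script uses a
5040-cell cohort (112 fish at the default layout) for the stochastic
recovery of the median-split statistics, 10⁴ draws per group for the
Monte-Carlo probability of superiority, and a 15-cell noise-free render
for ratio closure; these sizes put Monte-Carlo error comfortably inside
the quoted tolerances while the whole script runs in seconds.

## Known limitations

* The median-split statistics from the generative model depend on the
  neuromast size parity (see above); real cohorts with mixed cluster
  sizes will land between the odd and even regimes.
* The empirical probability of superiority on *renormalized* cohort
  data (~0.82) sits slightly below the summary-based reconstruction
  (0.85) because per-neuromast renormalization shrinks between-group
  separation relative to the idealized two-normal model.
* Area-normalized nuclear (ROS-dye) intensity has per-pixel units that
  are not comparable across magnifications; both the normalized and raw
  means are reported.
* No segmentation, registration, or photophysics correction is
  attempted; label maps are inputs.
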