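# Methods

## Assay model

The package models a paper-based vertical-flow immunoassay read out in two
optical modes. Sixteen reaction spots sit on a 4×4 grid (plus one
non-reaction vent): four cTnI spots, three CK-MB, three NT-proBNP, two
positive controls (anti-detection-antibody IgG, signal regardless of
analyte) and four negative controls (buffer only). Colorimetric contrast
(gold-nanoparticle absorption) is carried by the green channel of an RGB
image; chemiluminescent (CL) contrast by the blue channel of a
long-exposure image. Every cartridge yields a pre-assay background image
and a post-assay image per modality.

Per spot, the absorption signal is `X = 1 − s/b`, where `s` and `b` are
the mean ROI intensities of the assay and background images on the
modality's channel. Alike spots are averaged, giving ten signals per
cartridge (5 conditions × 2 modalities). `X` may be negative (assay
brighter than background); negative values are retained — clipping would
distort the control-signal distributions used by QC and the models.

## Synthetic data generator

The generator is the package's ground-truth factory; all tests and the
acceptance analysis run on it.

**Dose response.** Colorimetric CK-MB, NT-proBNP, cTnI and CL cTnI follow
power laws `y = a·x^k` with

| channel | a | k |
|---|---|---|
| CK-MB / Color | 0.0002 | 0.6901 |
| NT-proBNP / Color | 0.0001 | 0.6752 |
| cTnI / CL | 0.0742 | 0.2744 |
| cTnI / Color | 0.0179 | 0.2739 |

The CL cTnI channel saturates: signals follow the power law `p(x)` at low
concentration and plateau at `S = p(10⁴)` (onset 10⁴ pg/mL, where the
colorimetric channel takes over clinically). The transition is a
generalised-Hill soft minimum `y = S/(1+(S/p)^h)^{1/h}` with sharpness
h = 4, chosen so that (a) the low-concentration limit is exactly the power
law, and (b) the signal change from 10⁵ to 10⁶ pg/mL is below 5% of the
plateau, i.e. genuinely saturated, while remaining strictly monotone.

**Noise.** Replicate (cartridge-to-cartridge) variability is mean-one
multiplicative lognormal noise applied per cartridge × condition ×
modality — assay/flow variability is shared by alike spots; independent
1% spot-to-spot noise is added before alike-spot averaging, and Gaussian
pixel noise (SD 2 digital numbers on the 8-bit scale) at rendering. Each
patient sample carries one lognormal matrix-effect factor (default CV
10%) shared by all spots of both duplicate cartridges, mimicking serum
composition effects; 10% sits in the middle of the range typically quoted
for serum matrix effects on immunoassay signals and is deliberately large
enough that a single-signal calibration readout is visibly degraded while
multi-spot models can compensate via the control channels.

**Replicate-CV parameterisation.** Assay studies report replicate
precision as the mean sample CV of triplicates. The sample SD of n = 3
draws is biased low: E[s] = c4(3)·σ with c4(3) = √π/2 ≈ 0.886. The
generator therefore stores *population* CVs, and
`population_cv_from_triplicate_cv()` converts a reported triplicate CV
into the population value; the defaults are the reported per-biomarker
CVs (CK-MB 3.0%, NT-proBNP 1.5%, cTnI 4.5%) divided by c4(3). With this
calibration the simulated triplicate protocol reproduces the reported
numbers in expectation (verified by Monte Carlo), while large-replicate
empirical CVs converge to the configured population values.

**Cohort.** Patient concentrations are log-uniform per biomarker. Each
patient falls below the reference assay's reporting limit (cTnI 4, CK-MB
50, NT-proBNP 10 pg/mL) with probability 20/92, 58/92 and 33/92
respectively, matching the clinical cohort composition; censored samples
are flagged and carry a true concentration between 2% of the limit and
the limit. Quantifiable ranges default to 4–10⁵ (cTnI), 50–10⁵ (CK-MB)
and 10–4×10⁴ pg/mL (NT-proBNP). Calibration grids are log-spaced: CK-MB
8 points over 500–10⁵, NT-proBNP 8 points over 40–4×10⁴, cTnI 10 points
over 1–10⁶ pg/mL (the spiked levels are not published; these spans match
the quoted dynamic ranges). Control spots default to signal 0.5
(positive) and the blank baseline 0.005 (negative) per modality —
likewise unpublished, chosen so positive controls sit well inside the
dynamic range.

**What the generator does not emulate:** cross-reactivity between
analytes, flow non-uniformity across the membrane, illumination gradients,
spot-morphology defects, inter-batch reagent drift, and assay-specific
ground-truth error in the reference methods. Passing tests therefore
demonstrate correctness of the analysis pipeline under the stated
statistical model, not clinical performance on real serum.

## Signal extraction

Spot segmentation is rigid template registration, not blob detection: the
wax-printed geometry is fixed by fabrication, and low-signal spots have no
blob to detect. The absorption image `1 − assay/bg` is scored against the
full-printed-radius disk template over all integer shifts within ±8 px;
the argmax wins. Measurement ROIs then use 0.7× the printed radius to
avoid wax-edge pixels. If even the best shift accumulates < 0.01 mean
absorption per template pixel (a blank membrane — impossible for a valid
assay, whose positive controls always carry signal), registration falls
back to the nominal grid with a logged warning. ROI means are unweighted
over all pixels; no outlier rejection. Coordinates are row-major,
origin top-left, 0-based.

## Digital QC

A cartridge fails if any of the four control channels (positive/negative
control × modality) leaves `[mean − 3σ, mean + 3σ]` of that channel over
the batch (sample SD, n−1). The interval is **closed**: boundary points
pass, so pass/fail does not depend on float rounding. The reference is
fit on the full batch including the cartridge under test (matching a
retrospective whole-study analysis); a leave-one-out mode exists behind a
flag. A zero-SD channel fails on any deviation and passes on exact
equality. Under Gaussian controls the per-cartridge false-exclusion
probability is `1 − (1 − 2Φ(−3))⁴ ≈ 1.08%`.

## Calibration and detection limits

Power laws are fit by ordinary least squares of log₁₀(y) on log₁₀(x)
(convex, reproducible; R² reported on the log-log scale). The 4-PL uses
`y = D + (A−D)/(1+(x/C)^B)` with A the low-signal asymptote and an
unconstrained slope sign, fit by nonlinear least squares from a multi-start
grid of C values with both slope signs; non-convergence from every start
raises with diagnostics. Both forms invert in closed form; 4-PL inversion
requires the signal strictly between the asymptotes.

LoB and LoD follow the blank-based convention with both terms expressed in
concentration units: the blank bound `mean + 1.645·SD` is inverted through
the calibration curve, and the low-concentration SD is computed after
inverting each replicate signal. (The defining formulas mix signal and
concentration domains; since reported concentrations are derived from the
calibration curves, inverting before combining is the consistent reading.)
Sample SD (n−1) is used throughout; CV = 100·SD/mean.

## Neural-network cascade

Eight shallow fully connected networks, implemented directly on numpy
(forward/backward passes, Adam, batch normalisation) — the models are
small enough that a framework adds nothing.

Classifiers (per biomarker; hidden widths / dropout): CK-MB
(128, 64, 32)/0.6, NT-proBNP (64, 32)/0.4, cTnI (128, 64)/0.4. Hidden
layers use batch norm (batch size 4, running statistics at inference),
ReLU and dropout; L2 α = 1e−3 on weights; initial learning rates 1e−3 /
1e−2 / 3e−3, attenuated ×0.99 every 10 epochs; categorical cross-entropy
on softmax outputs. Classes: CK-MB <500/≥500, NT-proBNP <125/≥125, cTnI
<40/40–1000/>1000 pg/mL (lower bounds closed; 1000 belongs to the middle
class).

Quantifiers: cTnI models (128, 64)/dropout 0.1, CK-MB and NT-proBNP
(128, 32)/0.3 and 0.4; ReLU + dropout, no batch norm; Adam with batch
size 20, lr 1e−3 halved every 50 epochs; loss MSE (CK-MB, cTnI) or the
per-sample absolute log1p error (NT-proBNP) — note this per-sample form
(root and square cancel sample-wise) is not the conventional batch-level
RMSLE, which is available behind a flag; natural logarithms. Targets:
CK-MB ÷500, NT-proBNP ÷125, cTnI z-scored on each model's own training
subset. Early stopping: training ends once the epoch loss has not
improved by ≥1e−4 for 200 consecutive epochs (cap 2000); classifiers have
no published stopping rule and train for a fixed budget (default 400
epochs — they converge well before that on desk-scale cohorts); in both
cases the lowest-epoch-loss checkpoint is kept. The epoch loss is the
full training set evaluated in inference mode, which makes "best
checkpoint" well defined under dropout.

Inputs are standardised to zero mean/unit variance with statistics frozen
from each model's training subset. Censored samples join classifier
training (lowest class) but are excluded from that biomarker's quantifier
training. Cross-entropy as implemented is the standard form
`−mean(log y'_true)`. Training is deterministic under a fixed seed
(initialisation, shuffling and dropout masks share one generator).

**Gating and cross-check.** The classifier's range routes the sample:
CK-MB <500 and NT-proBNP <125 are reported *negative* without
quantification; every other range invokes its quantifier. A quantified
value more than 5% outside a finite boundary of the assigned range —
relative to the boundary value, e.g. 43 pg/mL against the cTnI <40 range
(42 = 40×1.05 is still accepted) — marks the sample *undetermined* and
the value is withheld; bounds at 0 or ∞ cannot be violated. Predictions
are floored at zero. The boundary-relative reading of the 5% rule is one
of two possible interpretations (the other being relative to the
predicted value); it was chosen for being checkable without iterating.

**Feature subsets.** The default specs carry the per-model optimal
subsets found by backward elimination on the clinical study (e.g. the
CK-MB quantifier uses only the CK-MB colorimetric signal; the cTnI
40–1000 quantifier only the CL cTnI signal; the cTnI >1000 quantifier
mixes colorimetric and CL channels to sidestep CL saturation). The
elimination itself retrains each leave-one-out candidate with the same
base seed (so criterion differences reflect features, not
initialisation), evaluates the criterion on the training set (no
validation split — small clinical cohorts make one counterproductive),
takes the global best over all evaluated subsets, and breaks ties toward
smaller subsets, then lexicographic order.

## Evaluation

Per biomarker: accuracy + confusion matrix over that biomarker's ranges;
Pearson r between quantified predictions and truth on the linear pg/mL
scale (a log₁₀ option exists because concentrations span decades), with
undetermined, negative and censored samples excluded and counted
separately; mean per-patient duplicate CV. The baseline comparator
inverts one power calibration on the designated single signal
(colorimetric for CK-MB/NT-proBNP, CL for cTnI); saturated CL signals
fall outside its invertible range, which is precisely the regime the
cascade's colorimetric branch covers.

## Problem sizes and numerical choices

The end-to-end analysis uses 200 patients × 2 duplicate cartridges (130
patients train / 70 test, split by patient so duplicates never straddle
the split), signal-table route; Monte-Carlo checks use 1000 repetitions
(replicate CVs) and 10⁵ cartridges (QC false-exclusion rate). These sizes
give ~1% Monte-Carlo precision while keeping the full suite in the
low minutes on a single CPU. Degenerate inputs are contracts, not
crashes: blank registration falls back with a warning, background ≤ 0 and
missing conditions raise typed errors, all-equal 4-PL signals raise a
degenerate-fit error, zero-probability true classes are clipped at 1e−12
with a warning.

## Known limitations

The generator's independence assumptions (no cross-reactivity, no spatial
structure) make extraction and QC easier than on real membranes; reported
end-to-end correlations characterise the pipeline under the stated noise
model only. The printed clinical figures that depend on the unpublished
92-patient dataset (blind-test accuracies, clinical Pearson r, LoDs,
5/184 QC exclusions) are structural templates here, not reproduction
targets. Batch normalisation with batch size 4 is noisy by construction;
the best-checkpoint rule absorbs most of that variance but small-cohort
classifier training remains seed-sensitive.
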