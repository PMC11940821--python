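# Methods

## The calibration problem

Activity counts from body-worn motion sensors are unitless, device- and
position-specific summaries of movement over a fixed epoch (30 s here, the
epoch used for long-term sleep/circadian recording). To interpret counts
as physical-activity intensity in 3-year-old children, thresholds must be
calibrated against a ground truth; `behavcal` uses directly observed
behaviour as that criterion. Six directed behaviours form a strict
intensity order (sedentary screen time < recumbent listening < sedentary
crafts < floor play < floorball/walk < sprinting), each performed for 8–10
minutes per child, with start/stop times logged by an observer. Epochs
fully contained in an observed interval inherit its behaviour label;
labelled epochs are pooled across children per channel (device ×
position) before any ROC fitting, treating epochs as exchangeable.

## Binarisation and threshold selection

Composite classes collapse adjacent behaviours: VPA (sprinting), MVPA
(+ floorball/walk), LMVPA (+ floor play; equivalently mobile vs
stationary), and MOA (sedentary screen time alone, the motionless-alert
class). Each is tested One-vs-Rest. MOA is a *below*-threshold class:
scores are negated internally so that "higher score = more likely
positive" holds uniformly, and the selected threshold is mapped back to
the count scale with a "<" direction.

Candidate thresholds are the observed count values plus sentinels outside
the data range; prediction is positive iff count strictly exceeds the
threshold. The operating point maximises the Youden index J = sensitivity
+ specificity − 1. Ties in J are broken toward the smallest threshold,
i.e. the most sensitive tied point; the selection deliberately does not
prioritise sensitivity or specificity beyond this fixed, documented
tie-break. The sedentary band is derived, not fitted: SED = [MOA cut,
LMVPA cut], closed on both ends, with MOA strictly below its cut. The
classifier therefore partitions the count axis into MOA / SED / LPA_band /
MPA_band / VPA; the middle bands are named after the thresholds that
delimit them rather than after behaviours, because outside the observed
protocol a count cannot identify what the child was doing.

AUC is the Mann–Whitney statistic (ties counted half), identical to the
trapezoidal area under the swept curve. The 95% CI uses the DeLong
placement-variance estimator by default — deterministic, so repeated runs
are byte-identical — with a stratified percentile bootstrap (2000
replicates, seeded) as an alternative; the original study does not state
its CI method, so the method used is always recorded in the output. AUC
bands: ≥ 0.90 outstanding, 0.80–0.89 excellent, 0.70–0.79 acceptable,
< 0.70 poor.

## Synthetic cohort generator

The generator emulates the calibration session: `n_children` (default 30)
× six behaviours × one bout each, bout length uniform on [8, 10] minutes
floored to whole 30-s epochs and shared across the four channels so that
paired devices align epoch-for-epoch. Per-cell (device × position ×
behaviour) count means and SDs default to the published calibration
moments of the four channels.

Only means and SDs are published per cell, not distribution shapes (real
count data are right-skewed with zero epochs during stationary
behaviours), so the marginal family is configurable:

* `normal` (default): count = μ + σz. Closed-form AUC oracles exist
  (below), which is why acceptance testing uses it; near-zero cells can
  produce slightly negative counts, which rank-based analyses ignore and
  which are clipped at zero only when writing device-style CSV files.
* `truncated_normal`: left-truncated at 0; moments shift upward for cells
  with mean within ~2 SD of zero.
* `lognormal`: moment-matched; strictly positive.
* `zero_inflated_gamma`: recommended for realism; an epoch is exactly 0
  with probability p (per behaviour), otherwise a moment-matched gamma
  draw whose mean is rescaled by 1/(1−p) so the cell mean is preserved
  (the cell SD refers to the continuous component).

Same-position channels observe the same movement, so they share a latent
per-epoch standard-normal intensity through a Gaussian copula. The
configured `cross_device_rank_correlation` (default 0.9) is the
**within-behaviour** Spearman correlation between paired devices; the
latent Pearson correlation is obtained by the exact inversion
ρ_gauss = 2·sin(π·ρ_s/6). The *pooled* cross-device correlation across all
behaviours is an emergent quantity and is necessarily larger, because the
wide separation of behaviour means adds rank concordance on top of the
within-cell coupling: at the defaults it comes out near 0.95–0.97 at the
wrist and 0.94 at the hip, bracketing the pooled values reported from
real wrist/hip pairs (0.94/0.90). Tests therefore check the configured
correlation within behaviour cells (±0.05) and check the pooled value only
for being at least as large.

A child-level random intercept on the latent scale (`child_effect_sd`) is
available but defaults to 0: no published variance decomposition exists to
set it from, and with it at 0 epochs are exchangeable within cells.

What the generator does **not** emulate: rest breaks between bouts and
non-wear (only labelled bouts are emitted), autocorrelation within bouts
(epochs are conditionally independent given the cell), device saturation,
and any systematic observer timing error. Passing tests on synthetic
cohorts therefore demonstrate the correctness and internal consistency of
the calibration machinery under the published first- and second-moment
structure — not the field validity of any particular threshold.

The MW8 count-accumulation rule is implemented for raw-sample fixtures:
counts per epoch are the sum over the epoch's seconds of the maximum
sample within each second (50 Hz default), which makes the count invariant
to within-second sample permutations.

## The Gaussian surrogate oracle

For normal marginals the OvR AUC of a scheme has a closed form: with equal
epoch weight per behaviour, the AUC decomposes exactly into the unweighted
mean over (positive, negative) behaviour pairs of the pairwise AUCs, and
each normal pair contributes Φ((μ_p − μ_q)/√(σ_p² + σ_q²)). (A
zero-variance pair with equal means contributes ½.) Evaluated on the
published channel moments, the surrogate reproduces the published OvR AUCs
at their 2-decimal table precision for both devices at both positions, and
it provides the ±0.02 agreement oracle for the empirical pipeline on
default synthetic cohorts. Equal weighting reflects the near-equal bout
durations of the protocol (bout-length jitter makes empirical class
weights only approximately equal; at 16–20 epochs per bout the effect on
AUC is well inside the ±0.02 band).

## Numerical and design choices

* **Epoch labelling**: intervals are half-open [start, stop); an epoch is
  labelled only if fully contained. How the original spreadsheet handled
  partial boundary epochs is unstated; full containment is this package's
  choice — conservative, and an epoch can never receive two labels.
* **Cut-off convention**: thresholds are observed count values (published
  tables print integer cut-offs taken from the data), ">" for mobile
  classes, "<" for MOA, SED closed on both ends.
* **Durations**: bouts outside [8, 10] minutes are flagged by
  `validate_durations`, mirroring the protocol's repeat-if-short rule.
* **Missing channels**: a missing series (e.g. one child's hip MW8) is
  simply absent — never zero-filled; pairing drops unmatched epochs and
  reports the count.
* **Device comparison**: Spearman correlation with average ranks; linear
  fit for wrist pairs, degree-2 polynomial for hip pairs by default (the
  hip relationship is visibly non-linear; the degree is configurable and
  recorded in output). Boxplot summaries use Q1/Q3 and 1.5·IQR whiskers;
  plots use the log10(count + 1) transform so zero epochs stay visible.
* **Degenerate inputs**: one-class problems raise a degenerate-problem
  error; constant scores yield only the trivial ROC points; constant
  margins make Spearman undefined (NaN with a warning); small cohorts can
  produce tied adjacent cut-offs, in which case the table fails monotone
  validation and classification is refused (the pipeline skips that
  channel with a warning rather than emitting a non-partition).
* **Reproducibility**: every stochastic path takes a seed
  (`numpy.random.default_rng`); JSON artifacts embed config and seed and
  are byte-identical across repeated runs.
* **Problem sizes**: tests and the acceptance script use the study-sized
  default cohort (30 children, ~12.5k labelled epochs over four channels),
  which runs in well under a second per channel calibration.

## Known limitations

* Cut-offs calibrated on pooled epochs ignore within-child clustering;
  DeLong CIs treat epochs as independent, so real-data CIs are likely
  anti-conservative. A child-clustered bootstrap would be the remedy and
  the bootstrap machinery accepts it naturally, but it is not wired in by
  default.
* The surrogate oracle is exact only for the normal family; for skewed
  families the empirical AUC is compared against brute-force pair counting
  instead.
* No wear-time, non-wear or sleep detection: inputs are assumed to be
  awake, worn, protocol-covered epochs.
* Thresholds produced from synthetic cohorts are demonstrations of the
  machinery; applying thresholds to real recordings requires matching
  device, sensor mode, position, epoch length and age group.
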