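# Methods

## The problem and the model

A developmental time course is assayed by RT-qPCR: organoids from two
treatment arms (vehicle control and a transient neurosteroid exposure) are
collected at fixed days in vitro (DIV 0, 26, 55, 78, 95, 138; n = 3
replicates per arm per day by default, with an optional per-day replicate
override for unbalanced final-day collections), and a panel of
developmentally regulated transcripts plus a housekeeping gene (GAPDH) is
measured as quantification cycles (Cq) over a 40-cycle run.

Relative quantification follows the standard ΔΔCq scheme with
amplification efficiency fixed at 2 (primers are assumed
efficiency-validated; no per-gene efficiency correction is attempted):

* ΔCq = Cq_gene − Cq_GAPDH (per sample; within-sample normalization);
* ΔΔCq = ΔCq − mean(ΔCq over the calibrator group), the calibrator being
  the undifferentiated DIV0 samples; fold change FC = 2^−ΔΔCq. The
  calibrator mean is the arithmetic mean of ΔCq — the geometric mean of
  expression — because ΔΔCq is defined on the log scale;
* scaled relative abundance = 2^−ΔCq × 10⁴, expression relative to the
  housekeeping gene.

A well-level measurement is *not detected* when it is missing or sits at
the 40-cycle bound; non-detection propagates through every derived value
as missing, never as zero. Group-level detectability (a gene is reported
"detected" in, say, one organoid type) requires that at every assayed day
at least `min_detected_fraction` (default 0.5; the threshold is a package
choice, configurable) of replicate wells amplify below `detection_cq_max`
(default 40).

## The segmented developmental index

The course is divided into four contiguous segments — DIV26–55, 55–78,
78–95, 95–138 — that share boundary days (day 55 contributes to the first
and second segment). Per segment:

1. **Trend classification (control arm only).** For each gene, the
   Pearson correlation r of replicate-level log₂FC against day is computed
   over all control observations in the segment, with a two-sided p from
   the t transform (df = n_obs − 2). Replicate-level observations are
   essential: with two days per segment, per-day means would force
   |r| = 1 with no p-value, so the significance rule is only computable
   at replicate level (6 points at n = 3). Genes are classified up
   (r > 0, p < α), down (r < 0, p < α), or ns; α defaults to the
   unadjusted 0.05 of the classification rule (multiplicity correction
   belongs to the ANOVA reporting stage, not here). Genes with fewer than
   3 observations or zero variance are ns with undefined r.
2. **Index.** Each gene's FC is rescaled by that gene's control-arm
   segment mean, and a sample's index is the ratio of its rescaled up-set
   average to its rescaled down-set average. The rescaling is the
   operational meaning adopted for giving all genes equal weight: it
   makes the index invariant to multiplying any gene's FC by a positive
   constant, so no high-abundance gene dominates. The control-derived
   gene sets and rescaling constants are applied unchanged to the treated
   arm. A segment whose up- or down-set is empty is flagged
   non-evaluable; there is no silent default.
3. **Slopes and ANCOVA.** Index-versus-day slopes are fitted by OLS on
   replicate-level rows (a per-day-mean option exists), and arms are
   compared by the F-test of the day×arm interaction in
   index ~ day + arm + day×arm, fitted independently per segment.

### Index scale

The package exposes two averaging scales. With `linear` averaging the
index is the arithmetic ratio-of-means the index's verbal definition
suggests. The pipeline's default for slope fitting and testing, however,
is `log`: geometric means inside the index, with slopes and the ANCOVA
computed on log₂(index). Three properties motivate the default, all
verified by the test suite and the acceptance script:

* log₂(index) is an exactly linear function of the latent developmental
  time (see the maturation clock below), because each gene's log₂FC is
  linear in it; the arithmetic ratio of exponentials is not. In
  particular, a constant developmental *lag* with a recovered *rate* — the
  post-recovery regime — leaves log-scale slopes equal, whereas it bends
  the linear-scale two-day slopes apart and masquerades as a rate change.
* replicate noise is additive and homoscedastic on the log scale (it is
  multiplicative on the linear scale, with variance growing with the
  index), so the interaction F-test holds its nominal level: in 1,000
  null simulations (recomputed by the acceptance script) every segment's
  rejection rate at α = 0.05 falls inside the 99% binomial band around
  0.05, whereas the linear scale runs visibly above it (≈7%).
* the reported index values are the positive ratio on either scale; only
  the internal averaging and the testing scale differ.

### Degenerate fits

With zero residual variance (noiseless data) the F ratio is 0/0. Such
fits are flagged `degenerate` and resolved by the sums of squares: if the
interaction term carries material sum of squares (relative tolerance
1e−9 of the total) the comparison is reported as F = ∞, p = 0; otherwise
F = 0, p = 1. A noiseless pair of arms with equal slopes is therefore
*not* a detection — resolving the 0/0 always in favor of rejection would
produce false positives in every noiseless segment without a slope
difference.

## Group statistics

Two-way factorial ANOVAs use Type II sums of squares, which handle the
unbalanced final-day replicate counts and coincide with the classical
balanced decomposition otherwise. Benjamini–Hochberg adjustment is the
step-up procedure; adjustment families are defined per reported analysis
and recorded with a `family_id`. The post-hoc procedure is a per-stratum
Welch unequal-variance t-test with BH across strata — a documented package
choice, since pairwise post-hoc machinery is not otherwise pinned down.
Percent change is reported as 100 × (mean_a/mean_b − 1).

## The synthetic generator

The generator emulates the study design as a ground-truthed null and
alternative world, not any particular dataset:

* **Latent maturation clock.** Control organoids accrue one maturation
  unit per day. The treated arm's clock matches the control clock until
  the withdrawal day (67), advances at rate 1−δ inside the delay window
  (67–95), and then recovers its rate while keeping the accumulated lag
  as a constant offset. δ = 0 gives exchangeable arms (the null preset);
  δ = 0.5 is the withdrawal-delay preset. The piecewise-linear form makes
  "which segments carry a slope difference" available in closed form:
  exactly the segments whose day range overlaps (67, 95].
* **Expression model.** Each panel gene has a baseline ΔCq at DIV0 and a
  linear slope in clock units; replicate noise is Gaussian on the ΔCq
  (log-expression) scale, sd 0.3 cycles by default. The housekeeping Cq
  is a constant 20 cycles (optionally noisy), so ΔCq noise has a single
  source. Cq values are clipped at the 40-cycle run length and clipped
  wells are flagged not-detected.
* **Panel.** 23 transcripts named for the markers a cortical-organoid
  maturation panel would carry: 14 rising (immature/mature neuron and
  interneuron markers, e.g. DCX, MAP2, GAD1, SST), 6 falling
  (proliferation and radial-glia markers, e.g. PCNA, SOX2, VIM), 3 flat
  (region-identity markers FOXG1, NR2F2, TTF1). Slopes are 0.075–0.13
  cycles/day, i.e. 2^10–2^18-fold over the 138-day course — the dynamic
  range of markers that move between undetectable and robustly
  expressed. This sizing is deliberate: it keeps per-gene classification
  essentially deterministic at n = 3 and σ = 0.3 even in the shortest
  (17-day) segment. When many genes are *borderline* instead, gene sets
  are selected on the same control observations the ANCOVA reuses, and
  the selection noise inflates the control slope (a winner's-curse
  effect) well above the nominal rejection rate; with unambiguous
  classification the test is calibrated, as the null simulations verify.

### What the generator does not emulate

Real qPCR data have per-gene amplification efficiencies ≠ 2, plate and
batch effects, correlated replicate structure (shared RNA extractions),
non-Gaussian outliers, nonlinear (sigmoidal, transient) trajectories, and
housekeeping-gene drift. Passing tests on the generator therefore show
that the pipeline's statistics do what they claim under the design's
idealized assumptions — not that any particular biological conclusion is
robust to those real-data complications.

## Problem sizes and numerics

Monte-Carlo calibration runs use 1,000 null replicates and 500
delay replicates of the full simulate → quantify → classify → index →
ANCOVA chain (a replicate takes ~50 ms). Rejection rates are computed over
evaluable replicates; under the null, evaluability depends only on the
control arm, so the conditioning does not bias the attained level.
Pearson statistics use centered sums with an exact range test for the
zero-variance guard, so bit-identical noiseless replicates are reliably
flagged flat. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical CSVs and
manifests (manifests deliberately contain no wall-clock fields).

## Known limitations

* The per-gene classification p-value ignores the multiplicity over genes
  and segments by design (it mirrors the index's defining rule); it is a
  gene-set construction device, not an inference about individual genes.
* With two days per segment the ANCOVA has 8 residual df at n = 3; its
  power profile is meaningful but its robustness to heavy-tailed noise is
  limited.
* The detectability filter's 0.5 fraction threshold is a convention; data
  with systematically late amplification may need a lower
  `detection_cq_max`.
* The linear-scale index remains available but its interaction test
  slightly exceeds the nominal level under multiplicative noise and can
  misread a recovered-rate lag as a rate change; use the default log
  scale for trajectory comparisons.
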