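# Methods

## Model and pipeline

A landing trial is modelled as a low-dimensional synergy organization
driving 13 leg muscles: the conditioned, time-normalized EMG matrix
V (13 muscles × 300 cycle points) is approximated as V ≈ M P, where the
motor modules M (13 × p) hold nonnegative, time-invariant muscle
weightings and the motor primitives P (p × 300) hold nonnegative,
time-dependent activation patterns. The 300-point cycle is anchored on
the landing's mechanics: points 1–100 are the final 300 ms of flight,
point 101 is the touchdown, points 101–300 span the stance up to force
stabilization. Because every trial shares this time base, primitives are
comparable across trials, participants and surfaces.

### EMG conditioning

Raw EMG is high-pass filtered (Butterworth, 4th order, 50 Hz), full-wave
rectified, and low-pass filtered (Butterworth, 4th order, 20 Hz). Both
filters are realized as second-order sections and applied
forward–backward (`scipy.signal.sosfiltfilt`), giving zero phase lag;
"4th order" refers to the single-pass design, so the effective order is
doubled. The envelope is clipped at zero (the smoothing of a rectified
signal can undershoot slightly). Zero phase is applied to the low-pass as
well as the high-pass; with symmetric filtering, conditioning commutes
with time reversal except for boundary transients, and scales linearly
with the input. Amplitude normalization divides each muscle by its
maximum activity over all samples of all stable-ground intervals of
interest of the same participant, so SG envelopes peak at 1 per muscle
and unstable-ground trials may exceed 1. A muscle with an all-zero
reference is flagged and left unscaled rather than divided.

### Segmentation and time normalization

Touchdown is the first vertical-GRF sample *strictly* above 20 N
(strictness resolves flutter at the threshold). The stance ends at the
first sample entering the body-weight ± 2.5 % band after the first strict
local minimum of the vertical GRF following the impact peak; "entering
the band" (not crossing the body-weight line) was chosen as the reading
of the stabilization rule and is recorded per trial in the segmentation
sidecar. A landing whose force never re-enters the band is quarantined,
mirroring the exclusion of failed landings. Flight (300 ms before
touchdown) is resampled to 100 points and stance to 200 by linear
interpolation — exact for affine signals — and concatenated; this ~1:2
allocation respects the typical flight-to-stance duration ratio of a drop
landing. Event detection uses the vertical component only; the force
channel kept on the cycle is the Euclidean norm of the 3-D GRF.

### Synergy extraction

Classical Gaussian NMF: Lee–Seung multiplicative updates minimizing
‖V − MP‖²_F, which preserve nonnegativity at every iteration and never
increase the loss. Implementation choices:

* initialization elementwise-uniform in (0, 1]; 10 restarts per rank run
  as one stacked batch, best final R² kept;
* convergence when no restart improves R² by more than 10⁻⁵ over 20
  consecutive iterations, hard cap 1000 iterations;
* R² = 1 − ‖V − MP‖²_F / ‖V − V̄‖²_F against the grand-mean baseline;
* per-rank, per-trial seed substreams (`numpy` `SeedSequence`), so runs
  are bit-reproducible and the R² curve over ranks 1..13 is non-decreasing
  up to local-minimum noise (tolerated at 10⁻⁴);
* scale indeterminacy fixed after convergence by rescaling each primitive
  to unit maximum and transferring the scale to its module column
  (the reconstruction is unchanged; module columns are *not* additionally
  normalized, a choice recorded in the extraction metadata).

The model order p is the smallest rank k such that a least-squares line
fitted to the R²-vs-rank curve restricted to ranks k..13 has mean squared
error below 10⁻⁵; segments of fewer than three points are vacuous and do
not qualify, and if no segment qualifies the maximum rank is returned
with a flag. Extraction is per landing trial.

### Classification

Per condition, the primitives of all extracted synergies are pooled and
clustered by k-means (squared Euclidean distance on the 300-point series,
20 random restarts) for every candidate count k = 1..13. The
within-cluster sum-of-squares curve is min–max normalized and the count
is selected by an automated elbow rule: the smallest k whose trailing
curve segment (k..13) is fitted by a least-squares line with MSE below
10⁻³ — the exact parallel of the extraction's rank rule. Motor modules
are then clustered with that k imposed. Each partition is scored by
(mean FWHM + mean CoA)/300, with metric means taken within clusters and
then averaged across clusters (an unweighted grand mean would not depend
on the grouping at all). Module-cluster labels are aligned to
primitive-cluster labels by maximal co-occurrence (exhaustive permutation
for k ≤ 6, Hungarian assignment above). Synergies with concordant aligned
assignments are fundamental; discordant ones are combined (spurious
merges). Matching as a whole fails — and the primitive-based partition
alone is retained — when the two scores differ by more than 0.05 or the
aligned agreement rate does not exceed 0.5; both thresholds are exposed
in the configuration because no quantitative failure rule is canonical.
Clusters are named post hoc by centroid timing: for k = 3, touchdown,
weight acceptance and stabilization in increasing centroid-CoA order.

The pooling choice deserves a note: averaging "one primitive per series"
before classification is ill-defined while synergies are still unordered,
so the pipeline clusters the pooled per-trial synergies of a condition
and labels each one individually.

### Spatiotemporal metrics

* **FWHM**: number of cycle points strictly exceeding half of the
  minimum-subtracted maximum; non-contiguous lobes all count; invariant
  to positive affine transforms and circular shifts. Strict inequality
  breaks ties at exactly half maximum deterministically.
* **CoA**: the cycle is mapped to the unit circle (point t → angle
  2π(t−1)/300) and the primitive treated as a circular mass distribution;
  the CoA is the direction of the resultant vector, reported in cycle
  points on [0, 300) so it composes directly with FWHM in the
  classification score. The cycle minimum is *not* subtracted before
  weighting (the subtraction belongs to the FWHM definition only); a
  configuration switch exposes the subtracted variant since the original
  convention is not stated.
* **Overlap**: a cycle point where at least two primitives simultaneously
  exceed their own half maximum (same rule as FWHM); the profile records
  the count and the ≥ 2 indicator per point.
* **CaI** = Flex̄/(Flex̄ + Ext̄) per joint, with the group means forced to
  sum to 1: hip flexors FL + RF vs extensors ME + MA; knee flexors
  ST + BF vs extensors RF + VM + VL; ankle dorsiflexor TA vs plantar
  flexors PL + GM + GL + SO. Bounded in [0, 1]; 0 = extensors only,
  1 = flexors only, 0.5 = balanced; undefined (flagged) at a silent joint.
* **CoP area**: 95 % confidence-ellipse area π · χ²₂(0.95) · √(λ₁λ₂) with
  λᵢ the eigenvalues of the 2 × 2 sample covariance of the stance CoP and
  χ²₂(0.95) = 5.991 (documented constant, computed from the χ² quantile).
  Degenerate point clouds give zero area with a warning.
* **Moment scalars** (on supplied joint-moment/angle series): stance
  maximum, time from touchdown to that maximum, rate = max / time-to-peak
  (flagged undefined when the peak sits at touchdown), and range of
  motion = angle at touchdown minus the stance minimum.

## Synthetic-data generator

The generator emulates the study conditions so the pipeline can be
validated against known ground truth:

* **Synergy structure.** Three planted synergies by default: touchdown
  (plantar-flexor dominant, primitive centered at cycle point 90, FWHM
  55), weight acceptance (knee extensors, center 120, FWHM 60) and
  stabilization (hamstrings/dorsiflexors/hip muscles, center 210, FWHM
  80). Primitives are truncated Gaussians (FWHM = 2.355 σ, giving an
  analytic width for tests). Trial-to-trial variability: center jitter
  SD 5 points, width jitter SD 5 points, amplitude ±15 %, multiplicative
  log-normal module jitter (σ = 0.1).
* **Raw EMG.** Cycle-domain envelopes M·P are mapped onto the trial's own
  time axis (flight ↔ the 300 ms before touchdown, stance ↔ touchdown to
  stance end), relaxed to a small baseline tonus outside the interval of
  interest, and multiplied with zero-mean unit-RMS white-noise carriers
  band-passed to 20–450 Hz, so the raw signal has EMG-like spectral
  content, survives the 50 Hz high-pass, and is exactly zero-mean
  (AC-coupled acquisition). Envelope noise is additive Gaussian truncated
  at zero, band-limited to the 20 Hz envelope band so the SNR parameter
  (default 20 dB) describes the envelope SNR the conditioning chain
  actually sees; `None` disables it, and strongly negative SNRs make the
  structure unrecoverable, which the tests use as negative controls. No
  quantitative noise model for real EMG exists for this task, so the SNR
  default is a generator choice, not an empirical claim.
* **Mechanics.** Vertical GRF: rectified sensor noise < 20 N during
  flight, a first crossing above 20 N at an exactly known sample, a
  half-cosine rise to the impact peak (SG 3.2 × BW in 45 ms; UG 2.4 × BW
  in 65 ms — the foam lowers and slows force development), a dip to
  ≈ 0.55–0.60 × BW, and an exponential settle whose nominal entry into
  the ± 2.5 % body-weight band matches the drawn stance duration
  (SG 0.491 ± 0.062 s, UG 0.629 ± 0.085 s), plus small smooth (≤ 8 Hz,
  0.4 % BW) noise. CoP: a mean-reverting AR(1) walk during stance with
  stationary SD 10 mm (SG) vs 6 mm (UG), reproducing the smaller sway
  area on foam.
* **Reproducibility.** One global integer seed fans out through
  `SeedSequence` substreams to every trial; cohorts are bit-reproducible.

What the generator does **not** emulate: motion capture and inverse
dynamics (joint moments are accepted as inputs, not simulated),
electromechanical delay, muscle-specific spectral signatures, fatigue or
electrode-related nonstationarity, cross-talk between channels, and any
biomechanical coupling between the EMG and the GRF streams (they are
generated independently given the condition). Passing tests therefore
demonstrate correctness of the analysis chain on signals with the stated
structure, not biological validity of conclusions drawn from real
recordings.

## Validation scale and determinism

The test suite validates extraction on a 50-trial stable-ground cohort at
20 dB envelope SNR, segmentation on 200 trials across both surfaces, and
classification recovery on a 30-trial cohort factorized at the true model
order; the Monte-Carlo check of the CoP ellipse area uses 20 seeds of
10⁵ points against the analytic value π · 5.991 · σ². These sizes give
stable modal statistics while keeping a full run in a few minutes on one
core. All stochastic steps (generation, NMF initialization, k-means
restarts) are seeded; the file pipeline derives stage seeds
deterministically from the global seed, the stage and the trial index, so
re-running any stage from cached upstream artifacts reproduces identical
downstream artifacts byte for byte.

## Known limitations

* On realistic carrier-demodulated envelopes the R²-regression rank rule
  tends to select one or two synergies *above* the number of planted
  generators (4–5 for 3 planted): the rectified-carrier envelope estimate
  carries an irreducible multiplicative fluctuation whose structured
  residual keeps the R² curve convex past the true rank. The
  classification stage is the corrective: pooled clustering collapses the
  extracted synergies back onto the three functional clusters. Studies
  using this rule on real landings report the same behaviour (mean
  selected ranks near 4–5 with three fundamental synergies after
  classification).
* The elbow and rank rules compare regression MSEs against fixed
  thresholds (10⁻³ on a [0, 1]-normalized curve, 10⁻⁵ on R²); both are
  scale conventions inherited from the method, not estimated quantities.
* k-means uses Lloyd's algorithm (scikit-learn) with 20 restarts; the
  classical Hartigan–Wong algorithm optimizes the same within-cluster
  sum-of-squares objective and differs only in its local search.
* The CoP ellipse assumes an approximately bivariate-normal point cloud;
  for strongly non-Gaussian sway the 95 % coverage is nominal.
* Only the fixture CSV + JSON format is read natively; motion-capture
  container formats are out of scope.
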