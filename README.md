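# landsyn

Muscle-synergy analysis of perturbed single-leg landings: a tested,
reusable pipeline for researchers in neuromechanics and motor control who
record multichannel surface EMG and ground reaction forces (GRF) during
drop landings on stable (SG) and unstable (UG) surfaces and want to
quantify how the modular organization of leg-muscle control changes under
perturbation.

## What it computes

Each landing trial carries 13 leg-muscle EMG channels, a 3-component GRF
and the 2-D center of pressure (CoP), all at 1 kHz. The pipeline:

1. **Conditions the EMG** into linear envelopes: 4th-order zero-phase
   Butterworth high-pass at 50 Hz, full-wave rectification, 4th-order
   zero-phase low-pass at 20 Hz; amplitudes are normalized per muscle to
   the maximum activity in the participant's SG series.
2. **Segments the landing** from the vertical GRF: touchdown is the first
   sample crossing 20 N; the interval of interest runs from 300 ms before
   touchdown to the first sample entering the body-weight ± 2.5 % band
   after the post-impact force minimum. All channels are time-normalized
   to a fixed 300-point cycle (100 flight + 200 stance points).
3. **Extracts muscle synergies** by non-negative matrix factorization.
   The cycle matrix V (13 × 300) is factorized as V ≈ M P with motor
   modules M (13 × p, time-invariant muscle weightings) and motor
   primitives P (p × 300, time-dependent activation patterns), using
   classical Gaussian NMF (Lee–Seung multiplicative updates on the squared
   Frobenius loss, 10 seeded restarts). The number of synergies p is the
   smallest rank from which the curve of reconstruction R² versus rank is
   fitted by a regression line with MSE < 10⁻⁵.
4. **Classifies synergies without an operator**: k-means (20 restarts)
   over candidate cluster counts 1..13 on the pooled motor primitives, an
   automated elbow rule (MSE < 10⁻³ on the normalized within-cluster
   sum-of-squares curve) to fix k, module clustering with that k imposed,
   and a concordance rule — synergies on which primitive- and module-based
   partitions agree are *fundamental*, discordant ones *combined*.
   Clusters are named touchdown / weight acceptance / stabilization by the
   timing (center of activity) of their centroid primitives.
5. **Measures spatiotemporal metrics**: FWHM (points above the
   minimum-subtracted half maximum), circular center of activity (CoA),
   primitive overlap intervals, the coactivation index
   CaI = Flex̄ / (Flex̄ + Ext̄) per joint from fixed flexor/extensor muscle
   groups, the 95 % confidence-ellipse area of the stance CoP
   (π · χ²₂(0.95) · √(λ₁λ₂)), and joint-moment scalars (maximum, time to
   peak, rate of moment development, range of motion).

A synthetic-trial generator with known ground truth (planted modules and
truncated-Gaussian primitives riding on band-limited stochastic carriers,
landing-shaped GRF, condition-scaled CoP sway) makes every stage testable
end to end without external recordings.

## Worked example

```bash
landsyn all --run-dir demo --seed 1 --n-trials 8
```

runs the whole chain (simulate → preprocess → segment → extract →
classify → metrics → report) on 8 synthetic landings per surface and
prints:

```
SG: 8 trials, modal rank 5, 3 clusters, 92% fundamental
UG: 8 trials, modal rank 4, 3 clusters, 97% fundamental
```

`demo/report/summary.json` then holds, per condition, e.g. for SG:

```json
{
 "n_trials": 8,
 "modal_rank": 5,
 "k_clusters": 3,
 "fundamental_fraction": 0.918918918918919,
 "fwhm_by_cluster": {"stabilization": 59.4, "touchdown": 47.8,
                     "weight_acceptance": 52.1},
 "coa_by_cluster": {"stabilization": 199.1, "touchdown": 95.6,
                    "weight_acceptance": 128.1},
 "mean_cop_area_m2": 0.00069
}
```

Reading: although 4–5 synergies are needed to reconstruct the noisy EMG
(modal rank), the classifier collapses them onto **3 functional clusters**
whose centroid timing is ordered touchdown (CoA ≈ 96, late flight) <
weight acceptance (≈ 128, early stance) < stabilization (≈ 199,
mid-stance), with primitive widths (FWHM) of ≈ 48–59 cycle points — and
the CoP sway ellipse is smaller on the unstable foam (0.29 cm² vs
0.69 cm² ≈ `mean_cop_area_m2` × 10⁴). Every stage writes plain CSV/JSON
artifacts under the run directory, and the same stages are callable as a
library (`SynergyNMF`, `SynergyClassifier`, `EmgConditioner` are
scikit-learn-style estimators).

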