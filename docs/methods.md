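# Methods

## Problem and model

`stairclust` recognizes stair ambulation against a background of ground
walking (level, uphill, downhill) in free-living thigh-worn accelerometer
recordings of a single subject, without any labeled training data. The
pipeline is:

1. **Band-pass filter** the tri-axial signal to 0.4–3 Hz, removing the
   gravitational component and high-frequency muscle artifact while
   keeping the gait fundamental (≈0.8–2 Hz) and its first in-band
   harmonics. The filter is a 4th-order Butterworth applied
   forward-backward (zero phase), so filtered samples stay aligned with
   the ground-truth intervals. The pass band is part of the method; the
   order and zero-phase realization are this package's choices.
2. **Window** into non-overlapping 2 s segments (40 samples at the
   default 20 Hz); the trailing partial window is dropped, never padded.
3. **Feature extraction**: a named registry evaluated in declared order.
   The default bank (73 features) holds per-axis time-domain statistics
   (mean, variance, s.d., RMS, min, max, range, IQR, skewness, kurtosis,
   zero crossings, mean absolute value, energy), per-axis spectral
   features on the 40-sample FFT (dominant frequency and its power,
   spectral entropy, band powers over 0.4–1, 1–2, 2–3 Hz), the three
   pairwise axis correlations, and the time-domain set on the resultant
   magnitude. The bank is configurable and its composition is hashed into
   the output metadata; matching any particular external feature list is
   explicitly not a goal.
4. **Standardization**: per-subject column z-scoring with the sample
   standard deviation (n−1). Constant columns are zeroed and flagged so
   no NaN can reach the embedding.
5. **t-SNE** to 2-D: perplexity 30, exaggeration 4, Euclidean distance on
   the standardized features, no PCA pre-reduction, random initialization
   under an explicit seed. Seeds 1–5 give five reproducible model
   variants per subject.
6. **DBSCAN** on the embedding with eps = 3 and minPts = 15 (closed-ball
   neighborhoods; minPts counts the point itself).
7. **Stair identification** from three empirical hypotheses: (I) the
   largest cluster is walking; (II) stair clusters lie farthest from the
   walking cluster; (III) stair clusters are more compact. Distance is
   measured as the negative log-likelihood l_K of a candidate centroid
   under a single Gaussian fitted to the main walking cluster;
   compactness as the median pairwise member distance; candidates are
   ranked by compactness with a multiplicative reward φ in steps of 0.05
   (least compact = 1.00), and scored by

   P(C_i = C_stairs) = 1 − 1 / (l_K(c_i ∈ C_w) · φ_j(C_i)).

   With 0 clusters the run reports `no_cluster_error`; with 1 cluster
   `single_cluster_error`; with 2 the larger is Walk and the other Stair
   by elimination; with 3+ the argmax-scored candidate becomes Stair and
   every other cluster is relabeled Walk.
8. **Evaluation**: stair-cluster purity (fraction of stair-cluster
   windows whose ground truth is upstairs/downstairs) and NMI of the
   cluster identities against the binary Walk/Stair truth, before
   correction (raw DBSCAN ids) and after (two-identity model).

## Numerical and design choices

* **Exaggeration semantics.** The exaggeration factor multiplies the
  joint probabilities for the whole optimization (openTSNE's
  `exaggeration`), implemented by rescaling P once before gradient
  descent. Libraries disagree here: with an early-only phase the
  embedding of a ~4200-window subject relaxes to a span of ±60–90 units,
  where the walking cloud's density falls below what a radius-3,
  15-point DBSCAN neighborhood can chain, and the walking mass shatters
  into dozens of fragments. Constant exaggeration compresses clusters by
  roughly the factor 4, which is the density regime the fixed DBSCAN
  parameters are meant for. This is a deliberate operating-point choice
  and is recorded in the embedding metadata.
* **Solver.** Exact t-SNE gradients up to 500 points, Barnes–Hut (angle
  0.5) above; learning rate 200 and 1000 iterations are pinned so that
  embeddings are bit-reproducible within one installation. Cross-library
  bit-compatibility is not promised.
* **Recording length matters.** With eps fixed at 3, the embedding of a
  short recording (under roughly an hour) is small enough that stair and
  walking points fall within one neighborhood radius and merge into a
  single cluster (`single_cluster_error`). This mirrors the method's
  stated sparse-data failure mode and is why the study conditions use
  ~140-minute recordings (~4200 windows).
* **Ties.** Equal sizes in walking-cluster identification → lower id;
  equal compactness in ranking → the larger-nll cluster counts as more
  compact; equal final scores → larger nll wins. Window labels tie toward
  the stair class so purity is evaluated conservatively.
* **Degenerate cases.** Singleton clusters get compactness 0 and a flag;
  near-singular walking covariances are regularized with +1e-6·I; nll is
  floored at 1e-9 before the score so candidates inside the walking
  Gaussian are pushed toward −∞ and effectively disqualified. The score
  is a ranking statistic, not a calibrated probability — it leaves [0, 1]
  whenever nll·φ < 1.
* **NMI variant.** Arithmetic-mean normalization of the two entropies,
  computed from the contingency table directly; constant labelings give
  0 by convention. Outlier windows and windows labelled `other` are
  excluded from purity and NMI.

## Synthetic data

The generator exists so every stage is testable without recorded data.

* `gen_embedding` draws isotropic Gaussian blobs with the hypothesis
  geometry directly: a dominant walking cluster (90–99% of points), the
  stair cluster most distant and most compact, extraneous walking
  clusters closer in and more diffuse.
* `gen_recording` synthesizes thigh acceleration per activity bout as a
  fundamental sinusoid at the activity's cadence plus two harmonics plus
  white noise, over a static gravity projection. Defaults: flat 1.80 Hz,
  uphill 1.74 Hz, downhill 1.86 Hz at ~0.35 g; stairs 0.95/1.05 Hz at
  ~0.5 g — stair gait is slower and has larger thigh excursion, the
  walking-speed contrast the clustering exploits. Inter-axis and harmonic
  phase offsets are drawn once per subject (a stable waveform identity,
  as for a real wearer); cadence and amplitude drift slowly within bouts
  (8% and 15% relative s.d., ~5 s correlation) to emulate natural gait
  variability; white noise s.d. is 0.08 g. The default free-living
  schedule repeats 700 s units of flat/uphill/downhill walking with two
  short stair bouts per unit, hitting the requested stair fraction by
  exact bout arithmetic.
* `gen_cohort` applies a shared cadence shift and amplitude scale per
  subject, which makes pooled embeddings cluster by subject rather than
  activity — the phenomenon that motivates per-subject modeling.

What the generator does **not** emulate: transitions and pauses between
bouts, turning, non-gait movement, step-to stair patterns, asymmetric or
prosthetic gait, sensor artifacts. Synthetic subjects are therefore
*cleaner* than recorded ones: purity and NMI near 1.0 on synthetic data
show that the pipeline recovers the intended geometry under the stated
conditions, not that it would achieve those numbers on clinical
recordings.

## Problem sizes

Unit tests run on 60–2100-window inputs; the synthetic end-to-end check
uses one 140-minute-equivalent subject (4200 windows) across t-SNE seeds
1–5, and the stair-recovery check uses 100 randomized 1000-point
embeddings. `scripts/acceptance.py` recomputes the recovery rate and the
five-seed subject metrics from scratch at these sizes.

## Known limitations

* The stair/walk distinction is binary; upstairs vs. downstairs is not
  attempted.
* All guarantees are per-subject; no pooled-population model is provided
  (pooling is demonstrated to fail in the cohort test).
* The default feature bank is a representative HAR set, not a
  reimplementation of any specific published feature list.
* Statistical comparisons (Shapiro–Wilk, rank-sum, t-tests, paired
  one-sided NMI test) are provided as a harness; their outputs on
  synthetic cohorts carry no clinical meaning.
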