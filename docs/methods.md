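# Methods

## The decoding problem

A listener attends to one of two concurrent speech streams (left or right
ear). The attended side is decodable from cortical activity; in particular,
parietal alpha (8–13 Hz) power lateralizes with the attended direction, and
inter-regional coupling in the alpha and beta bands carries additional
information. `neurixn` implements a decoding-and-interpretation pipeline
whose input is *region-level* source activity — per trial, a few source time
courses for each of 10 coarse cortical regions (left/right occipital,
parietal, temporal, central, frontal; codes `LO, LP, LT, LC, LF, RO, RP, RT,
RC, RF`) sampled at 64 Hz — and whose classifier is deliberately restricted
to *pairwise interactions between regions*, so that its learned weights can
be read as statements about inter-regional coupling.

Raw scalp EEG ingestion and source reconstruction are out of scope: the
package starts from region-grouped source signals (its HDF5 + JSON
container), and ships a synthetic generator that emulates that structure
with planted, recoverable effects.

## Band enhancement (GEDb)

For each region and each band b ∈ {delta-theta 2–8, alpha 8–13, beta
15–32 Hz}, a spatial weighting **w** of the region's sources is found by the
generalized eigendecomposition

  S_b w = λ R w,

where S_b is the covariance of the band-filtered sources and R the
covariance of the broadband sources. The leading eigenvector maximizes the
band-to-broadband power ratio (a Rayleigh quotient), and λ is that ratio.
Only the first component is kept, giving 3 components × 10 regions = 30
channels per trial.

Choices that the GED literature leaves open, resolved here:

* **Estimation window.** Covariances are computed per trial and averaged
  over a participant's *training* trials before the eigensolve; components
  are then applied to all trials. Validation/test statistics never enter
  the fit.
* **Regularization.** The reference covariance is shrunk 1% toward the
  scaled identity (`shrinkage=0.01`) to guard the generalized eigensolve
  against rank deficiency. A rank check raises `SingularCovarianceError`
  rather than silently returning garbage.
* **Application.** Component weights are applied to the **band-filtered**
  sources, so each channel is a band-specific component time course. The
  alternative (weights on broadband data) makes the three channels of a
  region carry nearly identical broadband content and pushes the band
  separation into the classifier; empirically the decoder then needs
  several times more epochs and plateaus well below the band-specific
  variant on the same synthetic cohort (~0.78 vs ~0.85 test accuracy at
  matched budgets), with a non-monotone validation loss. The four-band
  input ablations (below) remain meaningful because delta (2–4 Hz) and
  theta (4–8 Hz) are sub-bands of the delta-theta channel.
* **Sign and scale.** Eigenvector signs are arbitrary; each is flipped so
  its largest-magnitude weight is positive, and unit-normalized. Channels
  are centered to zero mean but *not* variance-normalized — band-power
  differences are signal, not nuisance.
* **Band edges.** Filters are order-4 Butterworth, applied forward-backward
  (zero phase). The beta band's upper edge (32 Hz) coincides with Nyquist
  at 64 Hz; the design edge is clipped to 99.8% of Nyquist.

## The interaction decoder

Input windows are 30 × T (default T = 320 samples = 5 s, cut with 50%
overlap). The network, all convolutions bias-free:

1. **Temporal convolution** — 4 kernels of length 31 (≈ half the sampling
   rate, so the passband can cover 2–32 Hz), same padding → 4 maps of
   30 × T; batch normalization per map over (batch, channels, time).
2. **Region collapse** — per map, a grouped pointwise convolution mixes each
   region's 3 band channels into 1 signal (10 groups of size 3), followed by
   a depthwise temporal convolution (kernel 31, 10 groups) → 4 maps of
   10 × T.
3. **Interaction stage** — element-wise products of all C(10,2) = 45
   unordered region pairs → 4 maps of 45 × T. Everything downstream sees
   region *interactions* only; single-region amplitude reaches the
   classifier only through products with other regions.
4. **Spatial filters** — a depthwise (45, 1) convolution: one 45-vector per
   map, Euclidean norm constrained ≤ 1 by projection after every optimizer
   step; batch norm, ELU, average pooling (1, 4) (64 → 16 Hz), dropout 0.5.
   These four 45-vectors are the interpretable objects.
5. **Separable convolution** — depthwise temporal kernel of length 16 (1 s
   at 16 Hz), pointwise mix to 4 channels; batch norm, ELU, average pooling
   (1, 8), dropout 0.5.
6. **Classifier** — flatten → bias-free linear map to 2 units → softmax.

Total trainable parameters at T = 320: 1848 (closed form in
`count_parameters`).

The network is implemented directly in numpy with hand-written
backpropagation. Temporal correlations run in the frequency domain
(real FFTs with frequency-domain reductions), arithmetic is single
precision by default (a float64 mode exists and is used by the
numerical-gradient verification test), and every layer's gradient is
checked against central finite differences in the test suite.

Initialization: convolution kernels are He-normal and batch-norm affines
unit/zero, while the final readout is **zero-initialized** — the first
optimizer steps then grow the classifier toward whatever upstream features
already discriminate instead of amplifying random feature directions. On
small cohorts this removes a long, seed-dependent plateau (test accuracy
at a fixed budget varied between 0.45 and 0.83 across seeds on identical
data with a random readout).

Readings of under-specified architecture details, fixed here: the grouped
pointwise stage uses group size 3 ("a single output signal for each
region"); each temporal map has its own stage-2 weights; stage-1 batch norm
normalizes per feature map (the compact-CNN convention; a per-(map, row)
variant is available via `ModelConfig.bn1_scope`); the separable stage uses
depthwise length 16 and 4 pointwise output channels; pooling truncates any
remainder; "no fully connected layer" is read as no *hidden* dense layer —
the softmax readout is a bias-free linear map.

## Training and evaluation

Cross-entropy loss, Adam (learning rate 1e-3, default moments), batch size
32, a fixed epoch budget with **validation stopping**: the parameters from
the epoch with the lowest validation loss are restored before the test set
is touched. Window order reshuffles every epoch; dropout and shuffling draw
from one seeded generator, so a run is exactly reproducible from its seed.

Two protocols:

* **Within-participant** — trials are assigned to 4 blocks, stratified
  jointly by condition tag and class label; fold f tests on block f,
  validates on block (f+1) mod 4, trains on the other two. Windows inherit
  their trial's block, so 50%-overlapping windows can never straddle a
  train/test boundary.
* **Cross-participant** — each participant is the test set in 5 iterations
  with 4 randomly drawn validation participants; 18 participants × 5 = 90
  folds, 13 training participants each.

Per-participant accuracies are fold-averaged first; the median across
participants is the headline number.

The **baseline** is a binary logistic regression on 40 features: per region,
the Welch spectra of its three channels are averaged (signals cannot be
summed — component signs are arbitrary), integrated in delta 2–4, theta
4–8, alpha 8–13, and beta 15–32 Hz, and log-scaled. Trained by full-batch
gradient descent (rate 0.05, 2000 iterations) on features standardized with
training-set statistics, with the same best-validation selection.

## Interpretation

Spatial filters are sign-aligned (largest-magnitude entry positive — v and
−v denote the same filter up to a sign absorbed downstream) before any
cosine computation. Two-level clustering:

1. per participant, k-means under cosine distance (spherical k-means, k = 4
   matching the filter count, best of 10 seeded restarts by within-cluster
   cosine inertia, ≤ 100 iterations);
2. across participants, agglomerative clustering of the centroids with
   average linkage on cosine distances, cut at a configured count (3 for
   within-participant, 4 for cross-participant analyses). Cluster counts
   can be examined with the elbow/silhouette scan.

**Significant interactions** of a filter: z-transform the 45 weights
against the filter's own mean and standard deviation (population SD), convert
to two-sided normal p-values, retain p < 0.05 (uncorrected). The two-sided
test is deliberate: strongly negative weights are informative (suppressed
interactions), and observed clusters do assign importance to negative
entries.

## Ablation retests

All ablations re-test trained models; nothing is retrained.

* **Kernel knockouts** zero spatial-filter columns: a bilateral region (17
  of 45 pairs), a hemisphere (35 of 45), or a cluster centroid's significant
  interactions. Zeroing is exact nullity: the logits of a region-ablated
  model are bit-invariant to that region's inputs (asserted in tests).
* **Input-band manipulations** filter the test windows per channel:
  band-stop (remove delta, theta, alpha, or beta) or band-pass (keep one
  band, with a 0.5 Hz DC block). Order-4 zero-phase Butterworth.
* The baseline mirror zeroes logistic weights by region (8 of 40) or band
  (10 of 40).

Paired per-participant accuracy differences go to the Wilcoxon signed-rank
test (W = positive-rank sum, zeros dropped, exact null for n ≤ 25, normal
approximation with continuity correction above) with Benjamini–Hochberg FDR
adjustment across a comparison family.

## Synthetic data

The generator emulates the geometry of a source-space listening experiment:
per participant, 50-s trials at 64 Hz, two balanced classes (left/right),
three condition tags carrying no signal (they exercise stratification), and
3 source time courses per region. Its full-size defaults are 18 participants
× 60 trials; studies in this package run a reduced cohort (4 × 24) noted
per experiment.

Construction per trial:

* each (region, band) has a unit-variance band-limited oscillation
  (band-filtered white noise, not sinusoids, so covariances are
  well-conditioned);
* each (region, band) has a fixed spatial loading over the region's sources;
  the three loadings of a region are **orthonormal** (QR of a Gaussian
  draw). Distinct within-region generators are what make per-band
  eigendecomposition identifiable; near-collinear generators would make
  band separation impossible for some random draws and add arbitrary
  participant-level difficulty unrelated to the planted effect sizes;
* **lateralization** (default: parietal alpha, power ratio 2): attend-left
  scales the right-hemisphere members' alpha amplitude by √ratio,
  attend-right the left members';
* **pairwise coupling** (default: RP–LP alpha, strength 1): in the
  attend-left class both regions' alpha oscillations are multiplied by a
  shared slow (< 1 Hz) envelope exp(c·m(t)), RMS-normalized so mean band
  power is unchanged — coupling moves co-modulation, not power. In the
  other class the envelopes are independent;
* per-source pink (1/f) noise at `noise_sd` (default 1.0).

What the generator does *not* emulate: volume conduction and source-leakage
correlations between regions, non-stationarities and artifacts, 1/f slope
variation, and phase–phase coupling (the planted interaction is amplitude
co-modulation, which is exactly the statistic an element-wise product layer
can express). Passing recovery tests therefore demonstrates that the
pipeline recovers planted amplitude-coupled, band-specific structure at
realistic SNR — not that it handles leakage or artifacts in real EEG.

## Study sizes and numerical choices

The packaged studies keep the full 5-s/50%-overlap window geometry and
batch size 32 but run reduced problem sizes chosen as sensible defaults for
a laptop-class single core: the parameter-recovery study uses 4 synthetic
participants × 24 trials, 10 replicates (one fold each, distinct
participant/fold combinations), 60 training epochs; the chance-level null
pools two folds of a label-shuffled participant (≥ 200 test windows) at 30
epochs. Per-window accuracies are quantized by trial (19 windows share a
trial), so fold-level accuracy moves in steps of ~1/6.

A property of this regime worth stating plainly: with 12 training trials
per fold the outcome of a single fold is strongly draw-dependent.
Favourable draws reach 0.79–0.86 test accuracy, recover the planted RP–LP
pair among the significant filter interactions, and lose the most accuracy
when the alpha band is stopped; unfavourable draws memorize the training
trials (training loss → 0.05) while the validation loss never drops below
its initial value, so the best-validation rule restores a near-initial
model that tests near or below chance. The same bimodality appears, less
often, at 60 trials. The binding constraint is trial count relative to
model flexibility, not information: a logistic oracle on pairwise-product
variance features separates held-out windows at 0.93–1.0 on every cohort
member. Consequently the recovery study's median accuracy and its
recovery/ablation rates understate what the pipeline achieves on favourable
draws; both the per-replicate values and their aggregates are reported.

Other numerics: Welch spectra use `nperseg = min(T, 128)`; band-power
features floor at 1e-12 before log; k-means reseeds empty clusters from the
farthest point; filters with zero standard deviation raise degenerate-filter
errors rather than returning empty significance sets; the final partial
window of a trial is dropped (no padding); all stochastic entry points take
explicit integer seeds.

## Known limitations

* The decoder is trained by a compact numpy implementation; it is exact
  (gradient-checked) but not fast — large cohorts or long window sweeps
  call for a GPU port of the same architecture.
* Validation-loss stopping with few validation trials is noisy; with very
  small cohorts the selected epoch can precede convergence. This mirrors
  the protocol rather than patching it.
* The interaction layer reads amplitude co-modulation; purely phase-coupled
  effects with flat envelopes would be invisible to it by design.
* When a planted amplitude lateralization coexists with a planted pairwise
  coupling, the lateralization is visible to *every* interaction touching
  the lateralized regions. Trained filters therefore tend to spread weight
  across many parietal-touching pairs, and the single coupled pair does not
  reliably stand out above the per-filter z threshold even in accurate
  models — pair-level attribution is considerably harder than band- or
  region-level attribution.
* Cross-participant experiments are implemented and split-tested, but the
  packaged studies exercise the within-participant protocol only; a full
  90-fold cross-participant run is a compute decision left to the user.
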