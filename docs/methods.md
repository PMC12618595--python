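# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `scfc`.

## Problem setting

Each subject is described by connectivity matrices over one fixed cortical +
subcortical parcellation (84 regions by default): five structural
connectomes from diffusion MRI (edge weights NS, NS/v, FA, iRD, FRt), four
MEG functional connectomes from amplitude–amplitude envelope correlations
(delta 1–4 Hz, theta 4–8 Hz, alpha 8–13 Hz, beta 13–30 Hz), and one
Euclidean-distance matrix between region centroids.  The question is how
well each subject's functional connectivity (FC) can be predicted from
their own structural connectivity (SC), how individual that mapping is, how
it changes with age, and whether it diverges in psychosis.

All edge-level computation uses the canonical upper-triangle edge vector
(row-major over pairs i < j, 0-based); with n = 84 that is 3486 edges.

## Analytical communication model

Edge weights w are converted to lengths L = 1/w (configurable to
−log w on normalized weights): stronger connections are shorter and
preferentially used.  Two communication predictors are derived:

* **SPL** — weighted shortest-path length, computed by Dijkstra.  Ties are
  broken by choosing, at each step of the path reconstruction, the
  smallest-index next node that still lies on an optimal path; this yields
  the lexicographically smallest optimal node sequence.  Determinism here
  is load-bearing because search information depends on the chosen path.
* **SI** — search information, the number of bits a random walker needs to
  follow the shortest path: SI(s→t) = −log2 Π P(v_m, v_{m+1}) with
  P(i,j) = w(i,j)/s(i).  The memory variant renormalizes each step after
  the first by excluding the edge just traversed,
  P'(v_m,v_{m+1}) = w / (s(v_m) − w(v_m, v_{m−1})).  SI is symmetrized as
  the mean of the two directions.  The no-memory form is the default; both
  are exposed.

Per subject, band and SC weighting, the observed FC edge vector is
regressed by OLS (with intercept) on [SPL, SI, ED]; fitted values are the
predicted FC and the Pearson correlation r between observed and fitted
edges is the accuracy (equal to the multiple correlation R, hence ≥ 0).
Predictors enter raw; z-scoring them is an affine change that alters the
coefficients but not the fitted values or r, and is available as a flag.

Correctness of SPL and SI is established against exhaustive simple-path
enumeration and brute-force probability products on 200 random connected
graphs with n ≤ 8 (exact for SPL, 1e-10 for SI).

## Graph multi-head-attention autoencoder

The supplementary-level architecture of the original model is not public;
the architecture here is this package's own design, fixed as follows and
exposed in configuration:

* **Node features** (per subject): mean, sample SD (divisor n−2) and
  minimum of the node's Euclidean distances to all other regions, SC node
  strength and degree, z-scored across nodes; optionally the node's
  max-normalized SC row (default on).  The SC-row block indexes nodes by
  position, trading exact relabeling equivariance (which the five
  intrinsic features retain and the tests verify) for expressiveness over
  a fixed parcellation.
* **Encoder**: 2 GAT-style attention layers, 4 heads.  Per head,
  e_ij = LeakyReLU(aᵀ[Wxᵢ ‖ Wxⱼ], 0.2) + u·log(1+wᵢⱼ), softmax-normalized
  over the neighbourhood {j : wᵢⱼ > 0} ∪ {i} (w_ii = 0 in the edge term);
  head output ELU(Σ αᵢⱼ Wxⱼ).  Hidden layer concatenates heads (width 64),
  the final layer averages them into an n×32 latent.  The learned per-head
  edge gain u lets SC strength modulate attention, which is how the SC
  acts as a weighted (not merely binary) adjacency.
* **Decoder**: latent dimensions are standardized across nodes (a
  symmetric normalization that keeps the pairwise features well-scaled
  whatever the attention output magnitude), then each pair (i, j) is
  scored by an MLP on [zᵢ⊙zⱼ ‖ |zᵢ−zⱼ|] (hidden width 64, ELU, linear
  output).  Symmetry and a zero diagonal hold by construction.  The output
  layer is initialized at the training targets' mean and spread so
  convergence does not depend on where the normalized FC distribution sits
  inside [0, 1].
* **Objective**: mean squared error over upper-triangle edges against the
  max-normalized observed FC, plus γ·‖θ‖² over all parameters, γ = 0.01.
* **Training**: Adam (default moments), learning rate 1e-3, 200 epochs,
  batches of 32 subject graphs, no early stopping.  All randomness (fold
  split, initialization, batch order) flows from one seed.

Evaluation is participant-level 5-fold cross-validation: each fold's
development set splits 75/25 into training and validation subjects;
hyperparameter candidates (grid ranges over heads/hidden/latent, default a
single point) are ranked by validation MSE; the winner is retrained on the
development set and scores the held-out subjects exactly once.  Reported
healthy-cohort accuracies aggregate the five held-out folds.  Subjects
outside the cohort (patients) are scored by averaging the five fold
models; scoring a subject seen in training raises an error unless
explicitly overridden.

The network runs on a small reverse-mode automatic-differentiation engine
written on numpy (`scfc.nn`), float64 throughout; its gradients are
verified against central finite differences in the test suite.

## Statistical battery

* Paired t-tests between edge weightings per band, BH-FDR across pairs.
* **Individuality shuffling**: the SC assignment is permuted across
  subjects (uniform permutations, fixed points allowed) and each subject's
  FC is re-predicted from the donor's SC; 500 rounds, per-subject mean r.
  For the analytical model the communication predictors are computed once
  per subject, so each shuffled evaluation is a single OLS refit.
* Age trends: Pearson correlation of accuracy with age per condition,
  BH-FDR across conditions.
* Group comparisons: two-sided Mann–Whitney U, exact when the smaller
  group has ≤ 8 members and no ties (the 5-patient design requires it;
  complete 5-vs-5 separation gives p = 2/252), tie-corrected normal
  approximation otherwise; Cohen's d with pooled Bessel-corrected SD
  (sign convention healthy − patient).  Patients are compared against the
  age-matched healthy subjects (18–35).
* PANSS: Spearman ρ between prediction error 1−r and symptom scores,
  exact permutation p for n ≤ 9, mid-ranks for ties.
* Model-vs-model: label-permutation test on the difference of group
  means, full enumeration when C(n, k) ≤ 184756 (5-vs-5 p-values move on
  the 1/252 grid), seeded Monte-Carlo (≥ 10⁴) otherwise.  Default
  two-sided; one-sided available.
* **FDR**: Benjamini–Hochberg step-up (largest k with p_(k) ≤ kα/m; flag
  all p ≤ p_(k); realized threshold = p_(k)).  The Benjamini–Yekutieli
  variant is available behind a flag.  Externally reported bounds such as
  "<1e-10" enter as their upper bound; internally computed p-values of
  exactly 0 are clipped to the smallest positive float before correction.
* Edge variability: per-edge across-subject sample SD of max-normalized
  FC, summarized by its median per band, with band-vs-band t-tests.

Type-I calibration: under simulated nulls every test's p-values are
approximately uniform (KS checks in the acceptance suite).  Exact discrete
tests are super-uniform (conservative) by construction; the calibration
therefore uses group sizes at which the attainable-p grid is fine (8 vs 40
for the exact Mann–Whitney — still the enumeration path).

## Synthetic cohort: the study conditions

The generator emulates the study design at matrix level: 126 healthy
subjects (ages uniform 18–50), 5 patients (18–35, integer PANSS with
positive+negative+general summing to the total, totals 35–60), 84 regions,
SC density 0.35.  It makes no attempt to simulate raw MEG/MRI signals,
tractograms or spectra.

* **Geometry**: centroids uniform in two mirrored hemispheric ellipsoids
  (semi-axes 30×45×35 mm, centers at x = ±33 mm); ED shared by the cohort.
* **Structure**: a cohort-level backbone with edge probability
  ∝ exp(−d/λ) (λ = mean distance / 2), calibrated by bisection to the
  target density and patched to be connected.  The five weight variants
  share each subject's topology: NS is log-normal with a mean that decays
  with distance (so NS and ED are negatively rank-correlated and NS is far
  more skewed than the bounded weights), NS/v divides by simulated region
  volume sums, and FA/iRD/FRt are Beta-distributed on (0, 1) with
  variant-specific shapes, coupled through a Gaussian copula (ρ = 0.6).
* **Function**: for each band, FC edges follow
  b0 + b_spl(−z(SPL)) + b_si(−z(SI)) + b_ed(−z(ED)) + ε,
  ε ~ N(0, σ_b), predictors from the subject's own FA-weighted SC
  (configurable), z-scored within subject and negated (shorter paths,
  lower search information, shorter distances ⇒ stronger coupling).
  Defaults: coefficients (0.4, 0.3, 0.2) in every band and
  σ = 1.2/0.8/0.5/0.45 for delta/theta/alpha/beta — delta is noisiest, so
  the accuracy ordering (alpha/beta best) and the across-subject
  edge-variability ordering (delta largest) both emerge from one knob.
  The result maps affinely into [0, 1] over a ±7 SD span around a
  per-subject level drawn iid around 0.5 for both groups: no clipping in
  practice (so the noiseless law stays exactly linear and the analytical
  model recovers it with r ≥ 0.999), and FC summary statistics such as
  total strength vary across subjects but carry no group signal.
* **Individuality**: one knob jitters the per-subject mapping
  coefficients *and* scales structural individuality (topology
  resampling probability 0.4·knob on top of the shared backbone, and
  multiplicative edge-weight jitter 0.01 + 0.6·knob).  The structural
  component is essential: a per-subject OLS refit absorbs coefficient
  changes, so coefficient jitter alone cannot make a subject's own SC
  predict their FC better than a donor's.  At knob = 0 subjects share the
  backbone topology and one mapping, realizing the shuffling null
  (|mean shuffled r − unshuffled r| ≤ 0.02); at large values (0.6)
  shuffling degrades essentially every subject.  Default 0.1.
* **Patients** are drawn from the same structural law; the only planted
  divergence is an additive coefficient shift — positive in delta (their
  delta FC follows the communication law more closely), zero in theta,
  negative in alpha and beta.  Because accuracy under refitting depends
  only on the signal-to-noise ratio, shrinking (growing) the coefficients
  lowers (raises) patient accuracy without touching any matrix summary:
  the relationship diverges while the matrices do not.
* An optional `panss_coupling` knob rank-aligns PANSS totals with each
  patient's expected prediction error in the weakened bands (computed in
  closed form from the realized signal SD, 1 − s/√(s²+σ²)) to give the
  Spearman stage a testable power case; by default PANSS is independent of
  prediction error.

What passing tests on this generator do **not** show: performance on real
dMRI/MEG connectomes, with their measurement noise, tractography biases,
source-leakage structure and non-linear SC–FC components.  The generator
plants a linear law, which makes the analytical model exactly
well-specified at zero noise (a closed-form oracle) and puts the
autoencoder on the analytical model's home turf; the autoencoder-recovery
check is a consistency bar, not a claim about relative performance on real
data.

## Problem sizes used by the checks

The verification suite runs at desk scale, chosen to finish in minutes
while leaving the tested properties meaningful: graph-algorithm oracles on
200 graphs with n ≤ 8; noiseless analytical recovery with 20 subjects at
n = 32 per weight; autoencoder recovery with 40 subjects, n = 32,
5 folds, 50 epochs with batches of 8 graphs (four gradient steps per
epoch — at this cohort size the full-scale batch of 32 would collapse an
epoch to a single step), and a 2000-epoch single-subject overfit run at
learning rate 3e-3; shuffling with 500 permutations over 20 subjects at
n = 32; the divergence signature on 20 replicates of the full 131-subject,
84-node cohort with the FA weighting; calibrations with 500 replicates per
test.

## Known limitations

* The autoencoder runs on CPU numpy; full-scale training (131 subjects ×
  84 nodes × 200 epochs × 20 conditions) is hours, not minutes.  The
  pipeline exposes per-condition training so conditions can be run
  selectively or in parallel.
* Shortest-path tie-breaking is exact only up to a relative tolerance of
  1e-9 when comparing path lengths; with continuous weights ties are
  measure-zero.
* The SC-row node feature breaks exact permutation equivariance (see
  above); disable it when equivariance matters more than accuracy.
* Exact Mann–Whitney requires no ties; with ties in a small group the
  tie-corrected normal approximation is used with a warning.
* The generator's FC is linear in the communication predictors by design;
  it cannot probe the autoencoder's advantage on non-linear structure.
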