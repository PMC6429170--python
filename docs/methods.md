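# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, with which defaults, and what the synthetic study can and cannot
show.

## 1. The synthetic familiarity experiment

Real recordings of the paradigm are not available, so every evaluation runs
on sessions from a generative model whose structure matches what the analysis
assumes.

**Paradigm.** One session = `n_tags = 6` four-digit codes (tag 1 familiar,
tags 2–6 random), each shown `reps_per_tag = 150` times in random order with
a stimulus onset asynchrony of 1.009 s, at `fs = 1000` Hz; each presentation
yields one 1000-sample epoch on 32 EEG channels (10-10 labels) plus EOG1 and
EOG2. Only epoch windows are materialized. The presentation order satisfies
the scheduling constraint that two equal codes are separated by at least two
other codes. Uniform-permutation rejection sampling cannot realize this
constraint at 6 × 150 (a random permutation carries ~300 expected
violations), so the schedule is drawn sequentially: each position picks among
the tags with remaining quota that do not occur in the previous two
positions, with probability proportional to the remaining quota, restarting
on the rare dead end. This is exact with respect to the constraint and fast;
it is not exactly uniform over the constrained set, which no downstream
stage is sensitive to.

**Signal model.** Every epoch is the sum of

* a smooth per-channel baseline ERP common to all codes (a few random
  low-frequency cosines, ~1–2 µV), representing the visual evoked response;
* for tag-1 epochs, the *familiarity component*: a temporal Gaussian bump of
  amplitude `A` (µV) centred at latency `µ` (ms) with width `σ` (ms),
  weighted across channels with mass concentrated on P7, P8, Pz, O1, O2 —
  the standard P300-family topography; optionally a scaled copy on one
  *parasitic* tag (a second, unintentionally familiar code);
* background noise: `1/f^α` (α = 1) plus white Gaussian noise, mixed 0.6/0.8
  in amplitude and scaled to `noise_sd` per sample — the standard EEG
  background model; channels are generated independently;
* with probability `blink_rate = 0.05` per epoch, a stereotyped biphasic
  blink deflection (nominally 250 µV, ±30%) on the EOG channels with a 15%
  copy on the frontal EEG channels.

**Calibration.** The literature gives no amplitude/SNR for the familiarity
response in this paradigm; the defaults were calibrated once so that the
*profiled* attack on a default user succeeds in the tens-of-observations
range (average rank 1 well before q = 40) while the non-profiled attack
degrades below q ≈ 100–200 — the qualitative operating point the methodology
is designed to resolve. This gives `A = 7 µV`, `noise_sd = 10 µV`
(effect size d ≈ 2 on the first average-PCA dimension after filtering, PI ≈
0.1–0.25 bits). A "high-SNR user" doubles the amplitude. Cohorts draw
user-specific amplitudes (log-normal, 25% scale), latencies (±60 ms), widths
(±20%) and channel-weight jitters around these defaults, scaled by a
`spread` parameter; `spread = 0` yields identical users (the portability
upper-bound fixture).

## 2. Preprocessing

* **Bandpass** 0.5–30 Hz, 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`): zero phase, so component latencies survive. Epochs are
  reflect-padded by three time constants of the low cutoff (≈ 955 samples,
  capped at epoch length − 1). Epochs shorter than 64 samples are rejected.
  Since filtering is per-channel, the pipeline filters only the channels it
  will use — identical results, 17× cheaper.
* **Blink rejection**: an epoch is dropped when any EOG channel's
  peak-to-peak exceeds 100 µV (default). Rejection never modifies surviving
  samples. With the default blink model this reproduces per-user survival in
  the 850–900 range out of 900.
* **Observation vectors**: the selected electrodes (default P7, P8) are
  concatenated per epoch into one vector (2 × 1000 = 2000 samples, µV). The
  electrode choice is a configuration default, not hard-coded.

## 3. Dimensionality reduction

Two PCA variants, both label-free with respect to the familiar/random secret:

* **Average PCA** — principal axes of the six per-tag mean traces
  (presentation tags are public). Six mean vectors admit at most five
  nonzero-eigenvalue components; requesting more is an error. The familiar
  component concentrates in the first dimension.
* **Raw PCA** — principal axes of all epoch vectors; scales to any number of
  components but extracts the discriminative direction less efficiently.

Both center with their own mean (global centering for raw PCA) and use a
deterministic sign convention (largest-magnitude coefficient positive) so
results are reproducible across linear-algebra backends. Default
dimensionality is `N_d = 5` for both variants. The decomposition itself is
scikit-learn's full-SVD PCA; tests cross-check it against an independent
eigendecomposition.

## 4. Density models and Bayes inversion

PCA dimensions are orthogonal and additionally treated as independent, so
each class-conditional density factorizes into `N_d` univariate ones.

* **KDE backend (default):** Gaussian kernels with Silverman's rule-of-thumb
  bandwidth `h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)` (sample sd with the
  n − 1 denominator, IQR by linear interpolation; if ties zero the IQR the sd
  alone is used; zero spread is an error). Nonparametric: no distributional
  assumption, slower convergence.
* **Gaussian backend:** per-class mean/SD templates — the classical
  alternative, faster converging when normality holds.

Likelihoods are computed in the log domain; each per-dimension log₂ density
is floored at −1000 before summing, which keeps every posterior and PI term
finite for arbitrarily extreme outliers independently of the posterior clip
below. Bayes inversion supports a uniform prior (maximum likelihood — the
default for attacks, because the 5/6 prior toward "random" inflates false
negatives on the familiar code) or the empirical class frequencies.

**Outlier clipping.** For raw-PCA pipelines, posteriors below 0.001 are
raised to 0.001 without renormalization before entering the log terms,
bounding the weight any single outlier can contribute to the PI sum. The
clip is not applied for average PCA (not needed there) but can be forced
either way.

## 5. Perceived information and security metrics

**PI estimator.** The observation set is split into k non-overlapping folds
(default k = n, leave-one-out, appropriate for ~900 observations); each
fold's model is fitted on the profiling set and evaluated on the held-out
observations, yielding one log₂-posterior-of-the-true-class term per
observation. The fold-wise per-class mean is degenerate under leave-one-out
(one test observation), so the per-observation terms are pooled across folds
and the class weights applied once — identical to fold averaging for
equal-size folds and well defined always. PI = H[P] + Σ_p Pr[p] · mean_p
(log terms), with empirical class weights (≈ 1/6, 5/6) by default. PI never
exceeds H[P]; estimation error only subtracts.

**Bootstrap CI.** 100 resamples (with replacement, within class, preserving
the class weighting) of the per-observation log terms; the 5th and 95th
percentiles of the 100 recomputed PI statistics are the interval endpoints.

**Success rate.** Per tag and per q: q observations of that tag are drawn
without replacement (1000 resampled draws by default) and classified by
comparing the products of per-observation posteriors under the two
hypotheses; computed from held-out (cross-validated) posteriors.

**Average rank.** Per draw, each of the six tags is scored with the
*real-code* model only (sum of log₂ Pr[p = 1 | o] over its q observations);
tags are sorted and the familiar tag's position recorded, ties averaged;
1 = perfect, 3.5 = chance.

## 6. Attack scenarios

* **Profiled:** leave-one-out over one session; reports PI with CI, the
  success/rank curves, and optionally a PI-vs-profiling-set-size learning
  curve (stratified subsampling, evaluation on the held-out remainder) —
  average PCA reaches an informative model with noticeably fewer profiling
  observations than raw PCA.
* **Non-profiled:** no labels; the PI is estimated once per assumed familiar
  tag (labels 1{tag = t}, leave-one-out on-the-fly modeling, average-PCA
  basis from the subset's tag means) and the maximal-PI tag wins. Assuming
  the true tag reproduces the supervised estimate exactly. The observation
  set may be split into 2 or 4 disjoint parts (no resampling) or truncated
  to q epochs to probe the attack's data complexity.
* **Portability:** a model (and basis) profiled on user A, applied unchanged
  to user B's observations; PI evaluated on B's labels. Transfers between
  dissimilar users yield negative PI. **All-against-one** pools every other
  user's observations, fits one basis and one model on the pool, and targets
  the held-out user; pooling averages out idiosyncrasies and transfers
  better than single-user models.
* **Identification:** classes = user identities, observations = familiar-code
  epochs of a cohort, uniform priors. One structural difference from the PIN
  pipeline is essential: the per-user mean traces that seed the PCA *are*
  class information, so the reduction is refitted inside every
  cross-validation fold from the profiling set only. With a full-set basis,
  two *identical* users would appear identifiable purely through
  basis-level overfitting of per-user noise means; the fold-aware estimator
  sends their partial PIs to ≤ 0 as it must. (The same concern does not
  apply to the PIN pipeline, whose PCA consumes only public tags.) Partial
  PI of user u is H[U] + mean log₂-posterior of u over u's held-out epochs;
  the overall PI(U;O) is their uniform-prior average. For the raw variant a
  full PCA per fold is costly — use a moderate fold count (k = 10) there.

**Measuring the parasitic-event plateau.** With a second familiar code at
full scale, the familiar and parasitic tags are exchangeable *in
distribution*. Within a single session evaluated by leave-one-out, however,
the class-1 model is fitted on the familiar tag's own epochs, so their
realized noise idiosyncrasies systematically favor tag 1 and the rank tends
to 1. The exchangeability statement — asymptotic rank 1 or 2 per run, mean
1.5 over runs — holds in the genuine two-phase setting and is measured that
way: profile on one session, rank fresh observations from a second session
of the same user.

## 7. I/O and reproducibility

Sessions interchange as EDF (16-bit, per-channel symmetric physical scaling;
quantization error ≤ range/2¹⁶) plus a plain-text events CSV (0-based onset
samples, half-open epoch windows, tags, artifact ground truth, user id);
profiles, bases and density models serialize to JSON. The EDF encoder is
built in; files are read back through MNE, so every round trip crosses an
independent implementation of the format. All stochastic stages take
explicit seeds; a run's manifest (stage parameters + seeds) regenerates its
outputs exactly.

## 8. Problem sizes

The analysis drivers run the full study scale (8 users × 900 epochs,
leave-one-out). The test suite exercises the same code paths at reduced
scale (typically 24–30 repetitions per tag, 2–3 user cohorts) and the
end-to-end checks at full scale where the claim requires it (full sessions
for the null control, non-profiled degradation and the parasitic plateau);
these sizes are the package's chosen trade-off between statistical
resolution and test-suite turnaround.

## 9. Limitations

The simulator reproduces the *statistical structure* the estimators assume —
a stereotyped familiarity component over parietal channels, stationary
colored noise, rare large blinks — not real EEG. It omits trial-to-trial
latency jitter and habituation of the P300, spatially correlated noise and
volume conduction, electrode drift and impedance changes, non-blink
artifacts (muscle, movement), and any between-session nonstationarity.
Passing tests therefore validate the estimators and attack logic under
their stated assumptions; they do not certify attack complexities on real
recordings. The KDE bandwidth is a heuristic (no cross-validated
selection); densities are products of univariate ones (no dependence across
PCA dimensions); PIN-space enumeration beyond the six-candidate ranking is
out of scope.
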