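# Methods

This note documents the statistical procedures implemented in `neurosync`,
the generative model behind the synthetic datasets, the numerical choices,
and what the validation suite does and does not establish.

## Leave-one-out inter-subject correlation (ISC)

For subject *i* and unit *v* (a voxel or a node), the statistic is the
Pearson correlation between the subject's time course and the simple mean
time course of all other same-group subjects. A group needs at least three
subjects. Undefined correlations (a constant series on either side) are
flagged NaN, excluded from group means with a logged count, and never
imputed. Constant series are detected by an exact zero-range test on the
raw values, because centring a constant series leaves floating-point
residue that would otherwise produce an arbitrary correlation.

The per-unit group summary maximized in the null is the **subject-mean of
raw leave-one-out correlations**; the Fisher-Z mean is also reported as a
variance-stabilized summary.

### Phase-randomization max-statistic inference

Surrogates are built in the Fourier domain: every non-DC phase is redrawn
uniformly on [0, 2π) while amplitudes are untouched; the DC bin keeps the
series mean and, for even lengths, the Nyquist bin is left as is so the
inverse transform is exactly real. Each subject × unit series is
randomized independently at every iteration, the per-unit group statistic
is recomputed, and the maximum over units is recorded. The significance
cutoff at level α is the empirical order statistic of the null maxima such
that `stat > threshold` is equivalent to the permutation p-value
`(1 + #{null ≥ stat}) / (1 + n_iter) ≤ α` (no interpolation; α below
`1/(n_iter+1)` is unattainable and yields an infinite threshold).
`n_iter` defaults to 1000 for desk-scale work; full-fidelity runs use
~175 000 iterations.

### Group contrast and ROIs

Within the joint mask (units significant in at least one group), groups are
compared with Welch's two-tailed *t*-test on Fisher-Z subject values
(raw-scale contrast available via `contrast_scale="raw"`). Welch was chosen
over the pooled-variance *t* because group variances need not match; the
degenerate identical-groups case (zero variance, zero difference) returns
t = 0, p = 1. Units significant at α are clustered into ROIs — contiguous
indices for tabular units, or a caller-supplied adjacency (e.g.
26-connectivity derived from a volumetric grid); coordinates are
pass-through metadata.

## Network Cohesion Index (NCI)

For a node set in a window of w TRs, all pairwise Pearson correlations are
clipped to ±(1 − 1e−7), Fisher-Z transformed, and summarized as the
one-sample t-statistic `mean(z) / (sd(z) / sqrt(E))` over the E edges.
Intra-NCI uses the n(n−1)/2 within-network edges (n ≥ 3); inter-NCI the
|A|·|B| cross-network edges of two disjoint sets (≥ 2 edges; computed in a
canonical node order so inter(A,B) equals inter(B,A) bit-exactly).
Degenerate windows (constant node series, zero edge variance) are NaN —
flagged, never inflated.

Sliding windows are half-open `[s, s + w)`, 0-based, with
`floor((n_tr − w)/step) + 1` windows; defaults w = 10 TRs and step = 1 TR.
At TR = 3 s the window spans 30 s, so the curves resolve slow processes
(sustained engagement, rumination-like states) rather than brief affective
reactions.

### Per-window group test, FDR, runs

Each window compares the two groups' subject NCI values with a Wilcoxon
rank-sum statistic using midranks, converted to a standard-normal Z with
the tie-corrected variance and no continuity correction; the sign is group
A minus group B. This Z equals the exact permutation standardization of
the rank sum, which is what the exactness tests verify by full enumeration
at n = 5 + 5. p is two-tailed from the normal approximation, or by
permutation (`method="perm"`; exact enumeration when the assignment count
is feasible, Monte Carlo with the add-one rule otherwise). A rank-based
test was chosen for robustness at ~20 subjects/group; subjects with a
degenerate value are dropped window-wise (≥ 3 per group required).

The FDR family is **all windows of a given NCI curve**, corrected with
Benjamini–Yekutieli (valid under arbitrary dependence — overlapping
windows are strongly dependent): `q_(i) = min_{j≥i} min(1, p_(j)·m·c(m)/j)`
with `c(m) = Σ 1/k`. Runs of consecutive q < α windows are reported as
run-length summaries. Epoch membership (from the rating curve) is an
annotation, not a restriction of the family.

### Spatial specificity

For a window with observed between-group |Z| on the target network(s),
`n_random` node sets of the same size(s) are drawn without replacement from
the whole-brain pool (target nodes excluded) and the |Z| recomputed for
each; specificity is `100 · fraction(random |Z| strictly below observed)`.
Near 100 means the effect does not reproduce on arbitrary node sets.
Caveat: when the effect saturates the rank-sum statistic at its
finite-sample maximum (complete separation), observed and random |Z| tie
and the percentile is no longer informative — the validation suite's
whole-brain scenario therefore uses a moderate effect amplitude.

### Rating epochs

Stimulus epochs are maximal runs of TRs whose median rating reaches a
threshold (default: half the rating ceiling, a "moderate" response on the
scale), mapped to the analysis windows lying fully inside the run.

## Behavior association

Spearman correlations (midranks; exact permutation p over all n! orderings
for n ≤ 8, t-approximation otherwise) between per-subject neural measures
and questionnaire scores, BY-corrected within one family per analysis call
(ROIs × measures, or curves × epochs × measures). Symptom–synchrony
correlations are referred to a phase-shuffled null — the whole synchrony
computation is repeated on phase-randomized series per iteration — with
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_iter)`, never exactly zero. Group
comparison of questionnaire scales is provided only as a plain two-sample
rank helper; multivariate modeling of scale profiles is out of scope.
Pearson variants are available via `assoc="pearson"`.

## Synthetic data generator

Signal model for subject *i*, unit *v*, TR *t*:

    x_iv(t) = λ_i · α_{g(i),v} · c_v(t)
            + Σ_k β_{g(i),k} · 1[t ∈ epoch_k] · u_ik(t) · w_kv
            + ε_iv(t)

* `c_v` — stimulus-locked course shared by all subjects, one per unit:
  white noise smoothed with a 3-TR moving average and z-scored. This gives
  BOLD-like smoothness without committing to a hemodynamic response model
  (deliberately out of scope, as is motion/physiological noise).
* `λ_i ~ Normal(1, τ²)`, default τ = 0.3 — per-subject synchrony gain; the
  causal quantity behavior couples to. Coupling behavior to the gain rather
  than to measured ISC keeps the model causal, so ISC is an estimator whose
  recovery can be tested.
* `u_ik` — subject-private network latent (smoothed, z-scored), switched on
  inside its epochs: it drives within-subject cohesion without adding any
  cross-subject synchrony. `w_kv` is the network's 0/1 membership.
* `ε` — stationary AR(1), default φ = 0.3, innovation SD 1.

Defaults mirror the study scale: 20 subjects/group, 169 TRs at TR = 3 s
(an 8 min 27 s stimulus), 60 units with a 6-node theory-of-mind network
(units 0–5), a 6-node affective-empathy network (units 6–11) and a 48-node
pool. Behavior columns are
`b = ρ·z(λ) + sqrt(1−ρ²)·Normal(0,1)` mapped affinely to questionnaire-like
ranges (IRI subscales centred at 14, spread 5; symptoms at 10, spread 3; no
clipping, so monotonicity is exact at |ρ| = 1). The rating curve is a
Gaussian bump peaking at ~0.9 of the scale ceiling inside a configurable
peak window (default: the 0.50–0.68 fraction of the timeline) with light
smoothed jitter and a small MAD band.

All randomness flows through `numpy` SeedSequences spawned from the config
seed; identical configs give bit-identical datasets, and network latents
are drawn whether or not their amplitude is zero so that toggling an effect
does not reshuffle unrelated streams.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses assume: two groups,
stimulus-locked shared components with group-specific loadings,
epoch-modulated within-network covariance, autocorrelated noise, and
behavior coupled to subject synchrony. It does **not** emulate hemodynamic
convolution, spatial smoothness/registration, head motion, physiological
artifacts, or realistic questionnaire discreteness. Passing the validation
suite therefore establishes the correctness and calibration of the
*statistical machinery* under the model's assumptions — not robustness to
fMRI artifacts.

## Validation scenarios and problem sizes

Defined once in `neurosync.scenarios` and used by both the test suite and
`scripts/acceptance.py`:

* **opposite_loading** — loadings 0.8 vs 0.3 swapped across the two
  networks between groups; the contrast must recover both difference signs.
* **epoch_cohesion** — patient-only network latent, amplitude β = 1.5
  (edge correlation ≈ 0.7 against unit noise — a strong movie-peak
  coupling), inside TRs [60, 100); significant windows must fall inside
  the epoch with runs ≥ 3.
* **global_cohesion** — the same latent on all 60 units at β = 0.8 (kept
  moderate to avoid rank-sum saturation; see above); specificity should be
  ~uniform.
* **behavior_power / behavior_null** — gain–behavior coupling ρ = 0.7 or 0
  at loading 1.0; association power and false-positive rate.
* **white_noise_null** — 3+3 subjects, 10 units, 100 TRs of white noise for
  family-wise-error calibration.

Problem sizes used by the suite — oracle batteries of 1000 random
instances, 150–200 null replicates at 500 null iterations, 40–50 seeds per
recovery scenario, 200 specificity draws — were chosen to give stable
Monte-Carlo estimates at desk scale; full-fidelity runs simply raise
`n_iter`, `n_random` and the seed counts.

## Known limitations

* The max-statistic null controls FWE for the group-mean ISC statistic; no
  cluster-extent inference is implemented.
* ROI extraction for tabular units uses index contiguity unless an
  adjacency is supplied; true volumetric clustering requires the caller's
  grid adjacency.
* The rank-sum Z saturates for complete separation at small n; permutation
  p-values remain valid, but specificity percentiles lose resolution there.
* Spearman's exact permutation p is limited to n ≤ 8 (n! enumeration);
  beyond that the t-approximation is used.
* NIfTI support targets the package's own grid layout plus plain 4-D
  images; arbitrary scanner metadata is not interpreted beyond affine and
  TR.
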