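# Methods

## The model and its assumptions

`repmix` treats the per-gene pair of two-sample t statistics from two
replicate two-group studies, (d_g1, d_g2), as one observation from a
three-component bivariate Gaussian mixture. The derivation behind this
reading is hierarchical: given a gene's expected group-mean difference in
study i, the t statistic is approximately N(δ_i μ_gi, 1) for large
samples; the study-level difference varies around a cross-study "true"
difference with between-study variance σ_g²; and the true difference is
either exactly zero (null gene), or drawn from a positive-mean Gaussian
(up-regulated) or a negative-mean Gaussian (down-regulated). Integrating
the gene-level quantities out gives

    (d_g1, d_g2) ~ pi0 N(0, Σ0) + pi1 N(mu1, Σ1) + pi2 N(mu2, Σ2)
    Σ0 = (σ_g² + 1) I₂
    Σk = (σ_g² + 1) I₂ + σ_Gk² J₂   (k = 1, 2)

The intermediate hierarchical quantities (per-study scale factors, the
component means on the expression scale) are not separately identifiable
from the statistics alone, so the code estimates the statistic-scale
quantities mu1, mu2, σ_g², σ_G1², σ_G2², pi directly and the hierarchy
stays documentation.

Assumptions this encodes:

- **Unit sampling variance.** The "+1" in every covariance is the
  variance of a standard-normal-approximated t statistic. With 10+10
  samples per group the statistic is really t with 18 degrees of freedom
  (variance 18/16 ≈ 1.13); the shared σ_g² term absorbs most of the
  difference, and no small-sample z-transformation is applied. This is a
  documented limitation for very small designs.
- **One shared σ_g².** Between-study variability is pooled across genes.
  A per-gene version would need replicate-level information the paired
  statistics do not carry.
- **Gaussian signed components.** Effect sizes within the up (down)
  group are Gaussian around a common positive (negative) mean; heavy-tailed
  effect distributions will leak extreme genes' influence into the
  variance parameters.
- **Two studies.** All covariance algebra is closed-form 2×2; the package
  does not generalize to I > 2.

The classification score is the posterior null probability p_g0 — a local
false discovery rate. A gene is reproducible when p_g0 < α (strict
inequality), with direction from the larger signed posterior. Because the
two signed components sit in the (+,+) and (−,−) quadrants, a
sign-discordant gene (large opposite-sign statistics) is near-orthogonal
to both and keeps p_g0 ≈ 1 — the central qualitative difference from
p-value-combination rules, which `classify.sign_discordant` makes
auditable and the two packaged 23- and 7-gene tables illustrate.

## Parameter estimation

The fit alternates:

- **E step** — posterior responsibilities under current parameters,
  computed in log space (closed-form 2×2 inverse/determinant, per-row
  max-subtraction) so statistics as extreme as |d| ≈ 10³ stay finite.
- **M step** — closed-form updates: component weights are mean
  responsibilities; mu1, mu2 are responsibility-weighted means;
  σ_g² is the null-weighted second moment (averaged over both
  coordinates) minus 1; σ_G1², σ_G2² are the signed-component weighted
  squared deviations from the component mean minus the null second-moment
  term.

Iteration stops when both the maximum absolute parameter change falls
below `tol_params` (default 1e-4) and the log-likelihood change does not
exceed `tol_loglik` (default 1e-6), or after `max_iter` (default 1000)
iterations. `n_starts` (default 10) random restarts are run and the final
log-likelihood selects the winner.

**The update scheme is moment matching, not an exact M step.** The
σ_G² updates use only the diagonal deviations of the signed components —
they never look at the cross-product d_g1·d_g2 — so they do not maximize
the expected complete-data log-likelihood under the structured covariance,
and the observed log-likelihood can *decrease* between iterations. On data
whose between-study correlation is weaker than the structure implies the
transient decrease can be large, yet the iteration converges to a stable
fixed point whose classification behavior is excellent (it is exactly the
fixed point at which the structured covariance matches the
responsibility-weighted diagonal moments). The package therefore runs the
iteration to the stopping rule regardless of monotonicity, and an ascent
monitor counts and warns about drops beyond a relative slack of 1e-6
(`EMFitResult.n_ascent_violations`). Replacing the updates with an exact
numerical M step was considered and rejected: the closed-form scheme is
the method's defined algorithm, its fixed points are what the simulation
results characterize, and an "improved" update would silently change the
estimator.

Other numerical choices:

- **Variance floors.** σ̂_g², σ̂_G1², σ̂_G2² are floored at `min_var`
  (default 1e-8): the "−1" and the null-term subtraction can go negative,
  and the floor keeps every Σ_l positive definite without matrix repair.
- **Initialization** (the method leaves it open): genes are partitioned by
  the sign of d1 + d2 against a magnitude threshold at a quantile drawn
  uniformly in [0.5, 0.9] per restart; weights, means and variances come
  from the partition moments, with signed means clipped away from zero.
  Deterministic given (seed, restart index); the quantile spread gives the
  restarts genuinely different basins.
- **Label normalization.** After fitting, the signed component with the
  larger mean sum is labeled "up". If a signed component's fitted mean
  entries disagree in sign, a warning is emitted and the mean-sum labels
  kept — the model does not constrain the means during iteration.
- **Permutation-stable normalization.** Posterior denominators sum the
  three weighted densities in sorted order, so mirror symmetries
  (reflecting all statistics while swapping the signed parameters) hold
  bitwise, not just approximately.
- **Degenerate data.** A component that loses all responsibility raises a
  collapse error; the multi-restart driver records it and moves on,
  failing only if every restart collapses. On data with *no* signal the
  three-component model is unidentifiable — a signed component can
  converge to a near-zero-mean duplicate of the null with nontrivial
  weight. This is harmless for classification (no gene reaches p_g0 < α)
  but means π̂₀ alone can understate the null mass on null-only data.

## The max-p baseline

The partial-conjunction rule specialized to "signal present in all
studies": convert each statistic to a two-sided p-value (t reference with
the design's degrees of freedom, or normal for df=∞), call a gene when
max(p₁, p₂) < α. The raw threshold (no multiplicity adjustment) is the
documented default: on independent null pairs it calls at rate α², which
matches the baseline's published specificities (≈ 0.994 at α = 0.1); a
Benjamini–Hochberg-adjusted variant is available behind `adjust="bh"`.
Direction is reported only when both statistics agree in sign — the rule
itself never sees signs, which is precisely its documented failure mode.

## The synthetic-data generator

`simulate.generate` emulates a pair of replicate two-group microarray
studies on the normalized log scale:

    x_gijk = mu + a_g + b_i + (ab)_gi + [delta + c_g + (cb)_gi]·1{k=2, g diff} + e_gijk

| parameter | meaning | default |
|---|---|---|
| `n_genes` | genes per study | 5000 |
| `n_per_group` | samples per group per study | 10 |
| `prop_reproducible` | proportion of truly differential genes | 0.8 |
| `prop_up` | fraction of differential genes that are up | 0.5 |
| `mu` | overall mean | 0 |
| `sd_alpha_g` | SD of the gene main effect a_g | 1 |
| `beta_i` | study main effect (both studies) | 0.1 |
| `sd_ab` | SD of the gene×study interaction | 0.5 |
| `delta` | fixed group-difference effect | 0 |
| `mu_gamma` | |mean| of the gene effect c_g on the group difference | 2 |
| `sd_gamma` | SD of c_g | 0.5 |
| `sd_gb` | SD of the gene×study interaction of the difference | 0.5 |
| `sd_eps` | residual SD | 0.5 |

Gene-level effects (a_g, c_g) are drawn once and shared by both studies;
interactions per gene×study; residuals per observation. Null genes carry
*no* group-difference terms, so their two groups are exchangeable and
their t statistics are centrally t-distributed. The 50/50 split of
differential genes between directions is a symmetry default. The effect
scale is deliberately strong: mean difference 2 against within-group SD
0.5 puts signed t statistics near ±9, so the three components are well
separated and errors come from the tail of genes whose realized effect in
one study is small.

What the generator does **not** emulate: gene–gene correlation, batch and
array-normalization artifacts, heavy-tailed or heteroscedastic noise,
per-gene variance differences, and probe-level structure. Passing the
simulation benchmarks therefore demonstrates correctness of the method
under its own generative assumptions plus this design, not performance on
arbitrary real microarray data. Note the generator's differential genes
are "reproducible" by construction even when interaction noise flips one
study's realized sign — ground truth follows the generative label, and the
separate `direction_accuracy` diagnostic exposes direction errors (it
degrades at very small signal proportions where the signed means are
estimated from a handful of genes, while the binary metrics stay intact).

The evaluation harness scores sensitivity (called among truly
differential), specificity (uncalled among null) and misclassification
((FP + FN)/G), averaged over replicates with a standard error;
per-replicate generator and EM seeds derive from the master seed via seed
sequences, making the whole study reproducible bit-for-bit.

## Problem sizes used by the test suite

The packaged benchmark runs (tests and `scripts/acceptance.py`) use the
study design itself — 50 replicates of 5000 genes with 10 samples per
group per configuration — which completes in a few minutes on one CPU.
Unit and property tests use smaller instances (hundreds to a few thousand
genes) chosen so each check's Monte-Carlo error is well inside its
asserted tolerance.

## Known limitations

- No small-sample correction of the t statistics; with tiny groups the
  unit-variance approximation is coarse.
- Shared σ_g² across genes and components; data whose null and signed
  components need different between-study inflation (as the generator's
  own data mildly do) are absorbed into σ_Gk² instead.
- Classification quality degrades gracefully but the *parameter*
  interpretation (especially σ_G² as effect-size spread) is only clean
  when the structured covariance is correctly specified.
- Two studies only; no u-out-of-n partial conjunction for u < n.
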