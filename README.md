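# repmix

Quantitative reproducibility analysis for replicate high-throughput
experiments.

A single high-throughput screen (microarray, RNA-seq, compound screen)
ranks thousands of candidates but is noisy; a finding only deserves trust
when it shows a **consistent and significant signal in the same direction**
across replicate studies. Popular replicability rules that combine
per-study *p*-values — notably the partial-conjunction rule, which for
"significant in *all* studies" reduces to thresholding the larger
*p*-value — are blind to direction: a gene strongly *up* in one study and
strongly *down* in the other sails through. `repmix` implements a mixture
model on the paired test statistics themselves that catches exactly this
failure mode, together with the max-p baseline and a simulation harness to
compare them.

## Model

For gene *g*, let *d*<sub>g1</sub>, *d*<sub>g2</sub> be the two-sample
t statistics (treatment − control) from two replicate studies. The pair is
modeled as a three-component bivariate Gaussian mixture

> (*d*<sub>g1</sub>, *d*<sub>g2</sub>) ∼ π₀ N(0, Σ₀) + π₁ N(μ₁, Σ₁) + π₂ N(μ₂, Σ₂)

with structured covariances (I₂ the identity, J₂ the all-ones matrix):

| component | meaning | mean | covariance |
|---|---|---|---|
| 0 | irreproducible / null | (0, 0) | Σ₀ = (σ<sub>g</sub>² + 1) I₂ |
| 1 | reproducibly up | μ₁ > 0 | Σ₁ = (σ<sub>g</sub>² + 1) I₂ + σ<sub>G1</sub>² J₂ |
| 2 | reproducibly down | μ₂ < 0 | Σ₂ = (σ<sub>g</sub>² + 1) I₂ + σ<sub>G2</sub>² J₂ |

σ<sub>g</sub>² is between-study variability (it inflates every variance
above the unit sampling variance of a t statistic); σ<sub>Gk</sub>² is the
spread of true effect sizes within a signed component, which also creates
the positive between-study correlation that only reproducible genes have.
Parameters are estimated by EM with multiple random restarts. The
posterior null probability

> p<sub>g0</sub> = π₀ φ(d<sub>g1</sub>, d<sub>g2</sub> | 0, Σ₀) / Σ<sub>ℓ</sub> π<sub>ℓ</sub> φ(d<sub>g1</sub>, d<sub>g2</sub> | μ<sub>ℓ</sub>, Σ<sub>ℓ</sub>)

is a local false discovery rate: gene *g* is called reproducible when
p<sub>g0</sub> < α, with direction from the larger of the two signed
posteriors. Because the null is zero-mean and the signed components sit in
the concordant quadrants, sign-discordant genes receive high
p<sub>g0</sub> no matter how small their *p*-values are.

## Worked example

Simulate two replicate two-group studies (2000 genes, 30% of them truly
differential, 10 samples per group), compute per-study t statistics, fit
the mixture, and call genes at α = 0.05:

```python
import numpy as np
from repmix import (ReproducibilityMixture, SimulationConfig, generate,
                    t_statistics, pair_studies, classify, posterior, evaluate)

cfg = SimulationConfig(n_genes=2000, prop_reproducible=0.3, seed=7)
study1, study2, truth = generate(cfg)
d1, ids1 = t_statistics(study1)
d2, ids2 = t_statistics(study2)
stats, dropped = pair_studies(d1, d2, ids1, ids2)

model = ReproducibilityMixture(n_starts=10, random_state=0, alpha=0.05).fit(stats)
p = model.params_
print(f"pi   = {np.round(p.pi, 3)}")
print(f"mu1  = {np.round(p.mu1, 2)}, mu2 = {np.round(p.mu2, 2)}")

calls = classify(posterior(stats, p), alpha=0.05)
m = evaluate(calls, truth)
print(f"called reproducible: {calls.n_called} / {len(calls)}")
print(f"sensitivity = {m.sensitivity:.3f}, specificity = {m.specificity:.3f}, "
      f"misclassification = {m.misclassification:.4f}")
```

Output:

```
pi   = [0.686 0.156 0.158]
mu1  = [8.99 9.27], mu2 = [-8.96 -8.89]
called reproducible: 593 / 2000
sensitivity = 0.988, specificity = 1.000, misclassification = 0.0035
```

The fitted weights track the generating design (70% null, 15% up, 15%
down — the generator's 30% differential split evenly); the signed
component means sit near ±9 because a mean expression shift of 2 with
within-group standard deviation 0.5 and 10 samples per group corresponds
to a t statistic of about 2 / (0.5·√(2/10)) ≈ 8.9. Of the 600 truly
differential genes, 593 are called with no false positives.

The same pipeline is scriptable from the shell:

```bash
repmix tstats --matrix study1.tsv --meta meta1.tsv \
              --matrix2 study2.tsv --meta2 meta2.tsv --out stats.tsv
repmix fit --stats stats.tsv --out params.json --seed 1
repmix classify --stats stats.tsv --params params.json --alpha 0.05 --out calls.tsv
repmix bh --stats stats.tsv --alpha 0.05 --df1 18 --df2 18 --out baseline.tsv
```

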