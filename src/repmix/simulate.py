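"""Synthetic two-study expression generator and the evaluation harness.

Data model (per gene g, study i, sample j, group k):

    x_gijk = mu + a_g + b_i + (ab)_gi
             + [delta + c_g + (cb)_gi] 1{k = 2, g differential}
             + e_gijk

with gene main effect a_g ~ N(0, 1), study effect b_i = 0.1, gene-study
interaction (ab)_gi ~ N(0, 0.5^2), fixed group effect delta = 0, gene
effect on the group difference c_g ~ N(+-2, 0.5^2) (up/down), its
gene-study interaction (cb)_gi ~ N(0, 0.5^2), and residual
e_gijk ~ N(0, 0.5^2).  Defaults: 5000 genes, two studies, 10 samples per
group.  A chosen proportion of genes is differential ("reproducible"
ground truth), split evenly between directions.

The gene-level effects a_g, c_g are drawn once and shared by both studies;
the interactions are drawn per gene x study; the residuals per
observation.  Everything is deterministic given the seed.

Methods are scored per replicate by sensitivity (called among truly
differential), specificity (uncalled among null) and misclassification
(FP + FN over all genes), then averaged over replicates with a standard
error.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .baselines import bh_partial_conjunction, two_sided_p
from .classify import ClassificationResult, classify
from .em import EMConfig, FitFailureError, fit
from .model import TestStatTable, posterior
from .tstats import ExpressionStudy, pair_studies, t_statistics

__all__ = [
    "SimulationConfig",
    "EvaluationMetrics",
    "StudySummary",
    "generate",
    "sample_statistics",
    "evaluate",
    "run_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All effect/noise parameters and design sizes of the generator."""

    n_genes: int = 5000
    n_per_group: int = 10
    prop_reproducible: float = 0.8
    prop_up: float = 0.5
    mu: float = 0.0
    sd_alpha_g: float = 1.0
    beta_i: float = 0.1
    sd_ab: float = 0.5
    delta: float = 0.0
    mu_gamma: float = 2.0
    sd_gamma: float = 0.5
    sd_gb: float = 0.5
    sd_eps: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_alpha_g", "sd_ab", "sd_gamma", "sd_gb", "sd_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("prop_reproducible", "prop_up"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes < 1 or self.n_per_group < 2:
            raise ValueError("need n_genes >= 1 and n_per_group >= 2")


@dataclass(frozen=True)
class EvaluationMetrics:
    """Binary classification scores against the generative truth.

    ``sensitivity`` is NaN when no gene is truly differential.
    ``direction_accuracy`` (diagnostic, not part of the headline scores) is
    the fraction of true positives whose called direction matches the true
    sign; NaN when there are no true positives.
    """

    sensitivity: float
    specificity: float
    misclassification: float
    direction_accuracy: float


@dataclass(frozen=True)
class StudySummary:
    """Mean and standard error of the metrics across simulation replicates."""

    method: str
    alpha: float
    n_reps: int
    per_replicate: pd.DataFrame
    mean: dict[str, float]
    se: dict[str, float]


def generate(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, NDArray[np.int_]]:
    """Two replicate two-group studies plus per-gene truth labels.

    Truth is +1 for up-regulated, -1 for down-regulated, 0 for null; for
    null genes every group-difference term is absent, so the two groups are
    exchangeable within a study.
    """
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_per_group
    n_diff = round(G * config.prop_reproducible)
    n_up = round(n_diff * config.prop_up)
    truth = np.zeros(G, dtype=int)
    truth[:n_up] = 1
    truth[n_up:n_diff] = -1

    alpha_g = rng.normal(0.0, config.sd_alpha_g, G)
    gamma_g = np.zeros(G)
    gamma_g[truth == 1] = rng.normal(config.mu_gamma, config.sd_gamma, n_up)
    gamma_g[truth == -1] = rng.normal(
        -config.mu_gamma, config.sd_gamma, n_diff - n_up
    )

    gene_ids = [f"g{i:05d}" for i in range(G)]
    group = np.repeat([1, 2], n)
    studies = []
    for i in range(2):
        ab_gi = rng.normal(0.0, config.sd_ab, G)
        gb_gi = rng.normal(0.0, config.sd_gb, G)
        base = config.mu + alpha_g + config.beta_i + ab_gi
        diff = np.where(truth != 0, config.delta + gamma_g + gb_gi, 0.0)
        eps = rng.normal(0.0, config.sd_eps, (G, 2 * n))
        mat = base[:, None] + eps
        mat[:, n:] += diff[:, None]
        studies.append(
            ExpressionStudy(gene_ids, mat, group, study_id=f"study{i + 1}")
        )
    return studies[0], studies[1], truth


def sample_statistics(
    params, n_genes: int, seed: int
) -> tuple[TestStatTable, NDArray[np.int_]]:
    """Draw paired statistics directly from the fitted mixture model.

    Unlike :func:`generate`, which simulates raw expression data, this
    samples (d1, d2) from the three-component mixture itself — useful for
    parameter-recovery checks where the model is exactly correct.
    Returns the table and the component label (0 null, 1 up, 2 down) of
    each gene.
    """
    from .model import component_covariances

    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n_genes, p=params.pi)
    covs = component_covariances(params)
    means = params.means
    out = np.empty((n_genes, 2))
    for l in range(3):
        mask = comp == l
        if mask.any():
            out[mask] = rng.multivariate_normal(means[l], covs[l], size=int(mask.sum()))
    table = TestStatTable(
        [f"g{i}" for i in range(n_genes)], out[:, 0], out[:, 1]
    )
    return table, comp


def evaluate(
    calls: ClassificationResult, truth: NDArray[np.int_]
) -> EvaluationMetrics:
    """Score calls against truth labels aligned with the calls' gene order."""
    truth = np.asarray(truth)
    if truth.shape != (len(calls),):
        raise ValueError(
            f"truth has {truth.size} labels for {len(calls)} classified genes"
        )
    is_diff = truth != 0
    called = np.asarray(calls.call, dtype=bool)
    tp = int(np.sum(called & is_diff))
    fp = int(np.sum(called & ~is_diff))
    fn = int(np.sum(~called & is_diff))
    tn = int(np.sum(~called & ~is_diff))
    n_true = tp + fn
    n_null = fp + tn
    sens = tp / n_true if n_true else float("nan")
    spec = tn / n_null if n_null else float("nan")
    mis = (fp + fn) / len(calls)
    if tp:
        dir_map = {"up": 1, "down": -1, "none": 0}
        called_dir = np.array([dir_map[d] for d in calls.direction])
        dir_acc = float(np.mean(called_dir[called & is_diff] == truth[called & is_diff]))
    else:
        dir_acc = float("nan")
    return EvaluationMetrics(sens, spec, mis, dir_acc)


def _rep_seed(master: int, rep: int, salt: int = 0) -> int:
    return int(
        np.random.SeedSequence([int(master), int(rep), int(salt)]).generate_state(1)[0]
        % (2**31)
    )


def _one_replicate(
    method: str,
    config: SimulationConfig,
    alpha: float,
    em_config: EMConfig,
) -> EvaluationMetrics:
    s1, s2, truth = generate(config)
    d1, ids1 = t_statistics(s1)
    d2, ids2 = t_statistics(s2)
    stats, _ = pair_studies(d1, d2, ids1, ids2)
    if method == "proposed":
        result = fit(stats, em_config)
        calls = classify(posterior(stats, result.params), alpha)
    elif method == "bh":
        df = 2 * config.n_per_group - 2
        calls = bh_partial_conjunction(
            two_sided_p(stats, df, df), alpha, stats=stats
        )
    else:
        raise ValueError(f"unknown method {method!r}; expected 'proposed' or 'bh'")
    return evaluate(calls, truth)


def run_study(
    method: str,
    config: SimulationConfig,
    alpha: float,
    n_reps: int,
    seed: int,
    em_config: EMConfig | None = None,
) -> StudySummary:
    """Replicate the full simulate -> t-stats -> fit -> classify -> score loop.

    Per-replicate seeds derive from the master ``seed``.  An EM fit failure
    in a replicate is recorded and the replicate re-drawn with a fresh
    derived seed (at most 3 retries).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        for retry in range(4):
            rep_cfg = dataclasses.replace(config, seed=_rep_seed(seed, rep, retry))
            em_cfg = em_config or EMConfig()
            em_cfg = dataclasses.replace(
                em_cfg, seed=_rep_seed(seed, rep, 100 + retry)
            )
            try:
                metrics = _one_replicate(method, rep_cfg, alpha, em_cfg)
                break
            except FitFailureError:
                if retry == 3:
                    raise
                warnings.warn(
                    f"replicate {rep}: EM fit failed; re-drawing with a fresh seed",
                    RuntimeWarning,
                    stacklevel=2,
                )
        rows.append(dataclasses.asdict(metrics))
    per_rep = pd.DataFrame(rows)
    mean = {k: float(per_rep[k].mean()) for k in per_rep.columns}
    if n_reps > 1:
        se = {
            k: float(per_rep[k].std(ddof=1) / np.sqrt(n_reps))
            for k in per_rep.columns
        }
    else:
        se = {k: float("nan") for k in per_rep.columns}
    return StudySummary(
        method=method,
        alpha=alpha,
        n_reps=n_reps,
        per_replicate=per_rep,
        mean=mean,
        se=se,
    )
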