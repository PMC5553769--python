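"""Core mixture model for paired test statistics from two replicate studies.

The model: for each gene g, the pair of two-sample t statistics
``(d_g1, d_g2)`` from two replicate two-group studies follows a
three-component bivariate Gaussian mixture,

    (d_g1, d_g2) ~ pi0 N(0, Sigma0) + pi1 N(mu1, Sigma1) + pi2 N(mu2, Sigma2)

where the zero-mean component collects irreproducible genes and the two
signed components collect genes consistently up- or down-regulated in both
studies.  The covariances are structured: with ``I2`` the identity and
``J2`` the all-ones matrix,

    Sigma0 = (sigma_g^2 + 1) I2
    Sigma1 = (sigma_g^2 + 1) I2 + sigma_G1^2 J2
    Sigma2 = (sigma_g^2 + 1) I2 + sigma_G2^2 J2

``sigma_g^2`` is the between-study variability of a gene's expected effect
(shared across genes), the ``+1`` is the unit sampling variance of a
large-sample t statistic, and ``sigma_Gk^2`` is the spread of true effect
sizes within a signed component, which also induces the positive
between-study correlation of reproducible genes.

The posterior probability ``p_g0`` of the null component given
``(d_g1, d_g2)`` is a local false discovery rate and is the score used
downstream to call genes reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "TestStatTable",
    "MixtureParams",
    "PosteriorTable",
    "component_covariances",
    "bivariate_normal_density",
    "bivariate_normal_logpdf",
    "posterior",
    "log_likelihood",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TestStatTable:
    """Per-gene paired test statistics from two replicate studies.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers.
    d1, d2 : array-like of float
        Test statistic of each gene in study 1 and study 2. Must be finite.
    """

    __test__ = False  # not a test class despite the name

    gene_ids: tuple[str, ...]
    d1: NDArray[np.float64]
    d2: NDArray[np.float64]

    def __init__(self, gene_ids: Sequence[str], d1: ArrayLike, d2: ArrayLike):
        ids = tuple(str(g) for g in gene_ids)
        d1 = np.asarray(d1, dtype=float)
        d2 = np.asarray(d2, dtype=float)
        if d1.ndim != 1 or d2.ndim != 1:
            raise ValueError("d1 and d2 must be one-dimensional")
        if not (len(ids) == d1.size == d2.size):
            raise ValueError(
                f"length mismatch: {len(ids)} gene ids, {d1.size} d1, {d2.size} d2"
            )
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(g for g in ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not np.all(np.isfinite(d1)) or not np.all(np.isfinite(d2)):
            raise ValueError("test statistics must be finite")
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "d1", d1)
        object.__setattr__(self, "d2", d2)

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def values(self) -> NDArray[np.float64]:
        """(n_genes, 2) array of the paired statistics."""
        return np.column_stack([self.d1, self.d2])


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the three-component constrained mixture.

    ``pi`` are the component weights (null, up, down); ``mu1 > 0`` and
    ``mu2 < 0`` component-wise after label normalization; the three variance
    parameters build the structured covariances (see module docstring).
    """

    pi: NDArray[np.float64]
    mu1: NDArray[np.float64]
    mu2: NDArray[np.float64]
    sigma_g2: float
    sigma_G1_2: float
    sigma_G2_2: float
    loglik: float | None = None
    n_iter: int | None = None
    converged: bool | None = None

    def __init__(
        self,
        pi: ArrayLike,
        mu1: ArrayLike,
        mu2: ArrayLike,
        sigma_g2: float,
        sigma_G1_2: float,
        sigma_G2_2: float,
        loglik: float | None = None,
        n_iter: int | None = None,
        converged: bool | None = None,
    ):
        pi = np.asarray(pi, dtype=float)
        mu1 = np.asarray(mu1, dtype=float)
        mu2 = np.asarray(mu2, dtype=float)
        if pi.shape != (3,):
            raise ValueError("pi must be a 3-vector")
        if mu1.shape != (2,) or mu2.shape != (2,):
            raise ValueError("mu1 and mu2 must be 2-vectors")
        if not np.all(np.isfinite(pi)) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be nonnegative and sum to 1")
        if not (np.all(np.isfinite(mu1)) and np.all(np.isfinite(mu2))):
            raise ValueError("component means must be finite")
        for name, v in (
            ("sigma_g2", sigma_g2),
            ("sigma_G1_2", sigma_G1_2),
            ("sigma_G2_2", sigma_G2_2),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "mu1", mu1)
        object.__setattr__(self, "mu2", mu2)
        object.__setattr__(self, "sigma_g2", float(sigma_g2))
        object.__setattr__(self, "sigma_G1_2", float(sigma_G1_2))
        object.__setattr__(self, "sigma_G2_2", float(sigma_G2_2))
        object.__setattr__(self, "loglik", loglik)
        object.__setattr__(self, "n_iter", n_iter)
        object.__setattr__(self, "converged", converged)

    @property
    def means(self) -> NDArray[np.float64]:
        """(3, 2) array of component means, null first."""
        return np.vstack([np.zeros(2), self.mu1, self.mu2])

    def as_vector(self) -> NDArray[np.float64]:
        """Flat parameter vector, used for the EM parameter-change criterion."""
        return np.concatenate(
            [self.pi, self.mu1, self.mu2,
             [self.sigma_g2, self.sigma_G1_2, self.sigma_G2_2]]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "pi": self.pi.tolist(),
                "mu1": self.mu1.tolist(),
                "mu2": self.mu2.tolist(),
                "sigma_g2": self.sigma_g2,
                "sigma_G1_2": self.sigma_G1_2,
                "sigma_G2_2": self.sigma_G2_2,
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureParams":
        d = json.loads(text)
        return cls(
            pi=d["pi"],
            mu1=d["mu1"],
            mu2=d["mu2"],
            sigma_g2=d["sigma_g2"],
            sigma_G1_2=d["sigma_G1_2"],
            sigma_G2_2=d["sigma_G2_2"],
            loglik=d.get("loglik"),
            n_iter=d.get("n_iter"),
            converged=d.get("converged"),
        )


@dataclass(frozen=True)
class PosteriorTable:
    """Per-gene posterior component probabilities (p0 = local fdr)."""

    gene_ids: tuple[str, ...]
    p0: NDArray[np.float64]
    p1: NDArray[np.float64]
    p2: NDArray[np.float64]

    def __post_init__(self) -> None:
        probs = self.probs
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("posterior probabilities must lie in [0, 1]")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("posterior rows must sum to 1")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def probs(self) -> NDArray[np.float64]:
        return np.column_stack([self.p0, self.p1, self.p2])


def component_covariances(params: MixtureParams) -> list[NDArray[np.float64]]:
    """The three structured 2x2 covariance matrices (Sigma0, Sigma1, Sigma2)."""
    eye = np.eye(2)
    ones = np.ones((2, 2))
    base = (params.sigma_g2 + 1.0) * eye
    return [
        base.copy(),
        base + params.sigma_G1_2 * ones,
        base + params.sigma_G2_2 * ones,
    ]


def bivariate_normal_logpdf(
    points: ArrayLike, mean: ArrayLike, cov: ArrayLike
) -> NDArray[np.float64]:
    """Log density of the bivariate normal, vectorized over rows of `points`.

    Uses the closed-form 2x2 inverse and determinant; raises on a covariance
    that is not symmetric positive definite.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mean = np.asarray(mean, dtype=float).reshape(2)
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
        raise ValueError("cov must be a finite 2x2 matrix")
    if abs(cov[0, 1] - cov[1, 0]) > 1e-12 * max(1.0, abs(cov[0, 1])):
        raise ValueError("cov must be symmetric")
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    if a <= 0 or det <= 0:
        raise np.linalg.LinAlgError("cov is not positive definite")
    dx = pts[:, 0] - mean[0]
    dy = pts[:, 1] - mean[1]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def bivariate_normal_density(
    point: ArrayLike, mean: ArrayLike, cov: ArrayLike
) -> float | NDArray[np.float64]:
    """Bivariate normal density; scalar for a single point."""
    out = np.exp(bivariate_normal_logpdf(point, mean, cov))
    return float(out[0]) if np.asarray(point).ndim == 1 else out


def _component_log_densities(
    stats: TestStatTable, params: MixtureParams
) -> NDArray[np.float64]:
    """(n_genes, 3) matrix of log pi_l + log phi_l, -inf where pi_l == 0."""
    covs = component_covariances(params)
    means = params.means
    pts = stats.values
    out = np.empty((len(stats), 3))
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    for l in range(3):
        if np.isneginf(log_pi[l]):
            out[:, l] = -np.inf
        else:
            out[:, l] = log_pi[l] + bivariate_normal_logpdf(pts, means[l], covs[l])
    return out


def posterior(stats: TestStatTable, params: MixtureParams) -> PosteriorTable:
    """Posterior component probabilities for each gene (log-space normalized).

    ``p0`` is the local false discovery rate: the probability the gene
    belongs to the zero-mean irreproducible component given its statistics.
    Stable for arbitrarily extreme statistics: normalization subtracts the
    per-gene maximum log term before exponentiating.
    """
    logp = _component_log_densities(stats, params)
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    # summing in sorted order makes normalization invariant to component
    # relabeling, so mirror symmetries hold bitwise
    w /= np.sort(w, axis=1).sum(axis=1, keepdims=True)
    return PosteriorTable(stats.gene_ids, w[:, 0], w[:, 1], w[:, 2])


def log_likelihood(stats: TestStatTable, params: MixtureParams) -> float:
    """Observed-data log-likelihood: sum over genes of the log mixture density."""
    if len(stats) == 0:
        raise ValueError("empty test-statistic table")
    logp = _component_log_densities(stats, params)
    m = logp.max(axis=1)
    terms = np.sort(np.exp(logp - m[:, None]), axis=1)
    return float(np.sum(m + np.log(terms.sum(axis=1))))
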