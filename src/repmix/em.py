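"""EM fitting of the constrained three-component mixture.

The algorithm alternates an E step (posterior responsibilities, delegating
to :func:`repmix.model.posterior`) with an M step whose closed-form updates
are:

    pi_l   = sum_g p_gl / p
    mu_k   = responsibility-weighted mean of (d_g1, d_g2) in component k
    sigma_g^2  = sum_g p_g0 (d_g1^2 + d_g2^2) / (2 sum_g p_g0) - 1
    sigma_Gk^2 = weighted mean squared deviation from mu_k (both coordinates)
                 - the null second-moment term above (without the -1)

Iteration stops when both the maximum absolute parameter change falls below
``tol_params`` and the log-likelihood change does not exceed ``tol_loglik``.
Multiple random restarts guard against local maxima; the restart with the
highest final log-likelihood wins.

The variance updates use only the diagonal deviations (no cross-products),
so the scheme is a moment-matching fixed-point iteration rather than an
exact EM: the log-likelihood can transiently decrease, especially when the
data's between-study correlation differs from what the structured
covariance implies.  The iteration is run to the printed stopping rule
regardless; an ascent monitor counts and warns about decreases beyond a
relative slack of 1e-6 (``EMFitResult.n_ascent_violations``) so pathologies
stay visible without changing the algorithm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator

from .model import (
    MixtureParams,
    PosteriorTable,
    TestStatTable,
    log_likelihood,
    posterior,
)

__all__ = [
    "EMConfig",
    "EMFitResult",
    "ComponentCollapseError",
    "FitFailureError",
    "ReproducibilityMixture",
    "e_step",
    "m_step",
    "initialize",
    "fit",
]

logger = logging.getLogger(__name__)

ASCENT_SLACK = 1e-6  # relative log-likelihood decrease tolerated per iteration


class ComponentCollapseError(RuntimeError):
    """A mixture component lost all posterior responsibility."""


class FitFailureError(RuntimeError):
    """Every EM restart collapsed or failed."""


@dataclass(frozen=True)
class EMConfig:
    """Settings for the EM fit.

    ``tol_params`` and ``tol_loglik`` are the two stopping tolerances
    (maximum absolute parameter change, absolute log-likelihood change);
    both must hold to stop.  ``min_var`` floors the variance estimates so
    all component covariances stay positive definite.
    """

    n_starts: int = 10
    max_iter: int = 1000
    tol_params: float = 1e-4
    tol_loglik: float = 1e-6
    seed: int = 0
    min_var: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol_params <= 0 or self.tol_loglik <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_var <= 0:
            raise ValueError("min_var must be positive")


@dataclass(frozen=True)
class EMFitResult:
    """Outcome of the multi-restart EM fit (winning restart).

    ``n_ascent_violations`` counts iterations whose log-likelihood dropped
    by more than ``ASCENT_SLACK * |loglik|`` — expected occasionally, since
    the printed updates are moment-matching rather than an exact M step.
    """

    params: MixtureParams
    loglik_trace: NDArray[np.float64]
    converged: bool
    n_iter: int
    start_index: int
    n_ascent_violations: int = 0


def e_step(stats: TestStatTable, params: MixtureParams) -> PosteriorTable:
    """Posterior responsibilities under the current parameters."""
    return posterior(stats, params)


def m_step(
    stats: TestStatTable, post: PosteriorTable, min_var: float = 1e-8
) -> MixtureParams:
    """Closed-form parameter updates given responsibilities.

    Variance estimates are floored at ``min_var``; a component with zero
    total responsibility raises :class:`ComponentCollapseError`.
    """
    d1, d2 = stats.d1, stats.d2
    probs = post.probs
    n = len(stats)
    totals = probs.sum(axis=0)
    if np.any(totals <= 0):
        raise ComponentCollapseError(
            f"component(s) {np.flatnonzero(totals <= 0).tolist()} "
            "have zero total responsibility"
        )
    pi = totals / n
    p0, p1, p2 = probs[:, 0], probs[:, 1], probs[:, 2]
    mu1 = np.array([np.dot(p1, d1), np.dot(p1, d2)]) / totals[1]
    mu2 = np.array([np.dot(p2, d1), np.dot(p2, d2)]) / totals[2]
    # null second moment per coordinate; reused by all three variance updates
    s0 = np.dot(p0, d1 * d1 + d2 * d2) / (2.0 * totals[0])
    sigma_g2 = s0 - 1.0
    sigma_G1_2 = (
        np.dot(p1, (d1 - mu1[0]) ** 2 + (d2 - mu1[1]) ** 2) / (2.0 * totals[1]) - s0
    )
    sigma_G2_2 = (
        np.dot(p2, (d1 - mu2[0]) ** 2 + (d2 - mu2[1]) ** 2) / (2.0 * totals[2]) - s0
    )
    return MixtureParams(
        pi=pi / pi.sum(),
        mu1=mu1,
        mu2=mu2,
        sigma_g2=max(sigma_g2, min_var),
        sigma_G1_2=max(sigma_G1_2, min_var),
        sigma_G2_2=max(sigma_G2_2, min_var),
    )


def initialize(
    stats: TestStatTable, seed: int, start_index: int, min_var: float = 1e-8
) -> MixtureParams:
    """Moment-based random initialization, deterministic per (seed, start_index).

    Genes are partitioned by the sign of d1 + d2 against a magnitude
    threshold at a quantile drawn uniformly in [0.5, 0.9]; component
    weights, means and variances are set from the partition moments.
    """
    if len(stats) < 10:
        raise ValueError("need at least 10 genes to initialize")
    rng = np.random.default_rng([int(seed), int(start_index)])
    q = rng.uniform(0.5, 0.9)
    s = stats.d1 + stats.d2
    thr = np.quantile(np.abs(s), q)
    up = s > thr
    down = s < -thr
    null = ~(up | down)

    n = len(stats)
    counts = np.array([null.sum(), up.sum(), down.sum()], dtype=float)
    pi = np.maximum(counts, 1.0)
    pi /= pi.sum()

    def _mean(mask: NDArray[np.bool_], fallback: float) -> NDArray[np.float64]:
        if mask.sum() == 0:
            return np.array([fallback, fallback])
        return np.array([stats.d1[mask].mean(), stats.d2[mask].mean()])

    mu1 = np.maximum(_mean(up, 2.0), 0.1)
    mu2 = np.minimum(_mean(down, -2.0), -0.1)

    if null.sum() > 0:
        s0 = float(np.mean(stats.d1[null] ** 2 + stats.d2[null] ** 2) / 2.0)
    else:
        s0 = 1.0
    sigma_g2 = max(s0 - 1.0, min_var)

    def _var(mask: NDArray[np.bool_], mu: NDArray[np.float64]) -> float:
        if mask.sum() < 2:
            return 1.0
        dev = (stats.d1[mask] - mu[0]) ** 2 + (stats.d2[mask] - mu[1]) ** 2
        return max(float(dev.mean() / 2.0) - (sigma_g2 + 1.0), min_var)

    return MixtureParams(
        pi=pi,
        mu1=mu1,
        mu2=mu2,
        sigma_g2=sigma_g2,
        sigma_G1_2=_var(up, mu1),
        sigma_G2_2=_var(down, mu2),
    )


def _normalize_labels(params: MixtureParams) -> MixtureParams:
    """Relabel the signed components so label 1 is 'up' (largest mean sum)."""
    if params.mu1.sum() >= params.mu2.sum():
        out = params
    else:
        out = MixtureParams(
            pi=params.pi[[0, 2, 1]],
            mu1=params.mu2,
            mu2=params.mu1,
            sigma_g2=params.sigma_g2,
            sigma_G1_2=params.sigma_G2_2,
            sigma_G2_2=params.sigma_G1_2,
            loglik=params.loglik,
            n_iter=params.n_iter,
            converged=params.converged,
        )
    if not (np.all(out.mu1 > 0) and np.all(out.mu2 < 0)):
        warnings.warn(
            "fitted 'reproducible' component means disagree in sign with the "
            "up/down interpretation; labels kept by mean sum",
            RuntimeWarning,
            stacklevel=3,
        )
    return out


def _run_single(
    stats: TestStatTable, config: EMConfig, start_index: int
) -> EMFitResult:
    params = initialize(stats, config.seed, start_index, config.min_var)
    trace = [log_likelihood(stats, params)]
    converged = False
    n_iter = 0
    n_violations = 0
    for it in range(1, config.max_iter + 1):
        post = e_step(stats, params)
        new_params = m_step(stats, post, config.min_var)
        new_ll = log_likelihood(stats, new_params)
        prev_ll = trace[-1]
        if new_ll < prev_ll - ASCENT_SLACK * abs(prev_ll):
            n_violations += 1
            if n_violations == 1:
                warnings.warn(
                    f"restart {start_index}: log-likelihood decreased at "
                    f"iteration {it} ({prev_ll:.6g} -> {new_ll:.6g}); the "
                    "moment-matching updates are not an exact M step",
                    RuntimeWarning,
                    stacklevel=3,
                )
        delta_params = float(
            np.max(np.abs(new_params.as_vector() - params.as_vector()))
        )
        delta_ll = abs(new_ll - prev_ll)
        params = new_params
        trace.append(new_ll)
        n_iter = it
        if delta_params < config.tol_params and delta_ll <= config.tol_loglik:
            converged = True
            break
    return EMFitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        start_index=start_index,
        n_ascent_violations=n_violations,
    )


def fit(stats: TestStatTable, config: EMConfig | None = None) -> EMFitResult:
    """Multi-restart EM fit; returns the restart with the best log-likelihood.

    Thin wrapper over :class:`ReproducibilityMixture`.
    """
    config = config or EMConfig()
    est = ReproducibilityMixture(
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        tol_params=config.tol_params,
        tol_loglik=config.tol_loglik,
        min_var=config.min_var,
        random_state=config.seed,
    )
    est.fit(stats)
    return est.result_


class ReproducibilityMixture(BaseEstimator):
    """Constrained bivariate Gaussian mixture for replicate test statistics.

    Models paired per-gene statistics from two replicate studies as a
    three-component mixture (zero-mean irreproducible, up-regulated,
    down-regulated) with structured covariances, fit by EM with multiple
    random restarts.  The posterior null probability is a local false
    discovery rate; a gene is called reproducible when it falls below
    ``alpha``.

    Parameters
    ----------
    n_starts : int, default 10
        Number of random EM restarts.
    max_iter : int, default 1000
        Maximum EM iterations per restart.
    tol_params, tol_loglik : float
        Joint stopping tolerances (parameter change and log-likelihood
        change; both must hold).
    min_var : float, default 1e-8
        Floor for the three variance parameters.
    random_state : int, default 0
        Seed controlling the restart initializations.
    alpha : float, default 0.05
        Significance level for :meth:`predict`.

    Attributes
    ----------
    params_ : MixtureParams
        Fitted weights, means and variance parameters (label-normalized:
        component 1 up, component 2 down).
    loglik_ : float
        Final log-likelihood of the winning restart.
    n_iter_ : int
        EM iterations used by the winning restart.
    converged_ : bool
        Whether both stopping tolerances were met.
    result_ : EMFitResult
        Full record of the winning restart, including the trace.
    """

    def __init__(
        self,
        n_starts: int = 10,
        max_iter: int = 1000,
        tol_params: float = 1e-4,
        tol_loglik: float = 1e-6,
        min_var: float = 1e-8,
        random_state: int = 0,
        alpha: float = 0.05,
    ):
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol_params = tol_params
        self.tol_loglik = tol_loglik
        self.min_var = min_var
        self.random_state = random_state
        self.alpha = alpha

    @staticmethod
    def _as_table(X: TestStatTable | ArrayLike) -> TestStatTable:
        if isinstance(X, TestStatTable):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                f"X must be a TestStatTable or (n_genes, 2) array, got {arr.shape}"
            )
        ids = [f"g{i}" for i in range(arr.shape[0])]
        return TestStatTable(ids, arr[:, 0], arr[:, 1])

    def fit(self, X: TestStatTable | ArrayLike, y: None = None) -> "ReproducibilityMixture":
        """Fit the mixture to paired statistics (TestStatTable or (n, 2) array)."""
        stats = self._as_table(X)
        config = EMConfig(
            n_starts=self.n_starts,
            max_iter=self.max_iter,
            tol_params=self.tol_params,
            tol_loglik=self.tol_loglik,
            seed=self.random_state,
            min_var=self.min_var,
        )
        results: list[EMFitResult] = []
        failures: list[str] = []
        for start in range(config.n_starts):
            try:
                res = _run_single(stats, config, start)
                results.append(res)
                logger.info(
                    "restart %d: loglik %.6f after %d iterations (converged=%s)",
                    start,
                    res.loglik_trace[-1],
                    res.n_iter,
                    res.converged,
                )
            except ComponentCollapseError as err:
                failures.append(f"restart {start}: {err}")
                logger.info("restart %d collapsed: %s", start, err)
        if not results:
            raise FitFailureError(
                "all EM restarts collapsed:\n" + "\n".join(failures)
            )
        best = max(results, key=lambda r: r.loglik_trace[-1])
        params = _normalize_labels(best.params)
        params = MixtureParams(
            pi=params.pi,
            mu1=params.mu1,
            mu2=params.mu2,
            sigma_g2=params.sigma_g2,
            sigma_G1_2=params.sigma_G1_2,
            sigma_G2_2=params.sigma_G2_2,
            loglik=float(best.loglik_trace[-1]),
            n_iter=best.n_iter,
            converged=best.converged,
        )
        self.params_ = params
        self.loglik_ = float(best.loglik_trace[-1])
        self.n_iter_ = best.n_iter
        self.converged_ = best.converged
        self.result_ = EMFitResult(
            params=params,
            loglik_trace=best.loglik_trace,
            converged=best.converged,
            n_iter=best.n_iter,
            start_index=best.start_index,
            n_ascent_violations=best.n_ascent_violations,
        )
        return self

    def predict_proba(self, X: TestStatTable | ArrayLike) -> NDArray[np.float64]:
        """(n_genes, 3) posterior probabilities (null, up, down)."""
        self._check_fitted()
        return posterior(self._as_table(X), self.params_).probs

    def predict(self, X: TestStatTable | ArrayLike) -> NDArray[np.int_]:
        """Component calls at level ``alpha``: 0 null, 1 up, 2 down."""
        probs = self.predict_proba(X)
        calls = np.zeros(probs.shape[0], dtype=int)
        repro = probs[:, 0] < self.alpha
        calls[repro] = np.where(probs[repro, 1] >= probs[repro, 2], 1, 2)
        return calls

    def score(self, X: TestStatTable | ArrayLike, y: None = None) -> float:
        """Mean per-gene log-likelihood under the fitted parameters."""
        self._check_fitted()
        stats = self._as_table(X)
        return log_likelihood(stats, self.params_) / len(stats)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("this ReproducibilityMixture instance is not fitted")
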