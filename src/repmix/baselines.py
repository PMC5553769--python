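"""Max-p partial-conjunction baseline (Benjamini–Heller specialized to
"reproduced in all studies").

Testing that a signal is present in every one of n studies reduces to
thresholding the largest of the per-study p-values.  Because p-values
discard sign, this rule happily calls genes that are significant in
opposite directions in the two studies — exactly what the mixture model is
designed to catch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .classify import ClassificationResult, _check_alpha
from .model import TestStatTable

__all__ = ["PValuePair", "two_sided_p", "bh_partial_conjunction", "MaxPConjunction"]


@dataclass(frozen=True)
class PValuePair:
    """Per-gene two-sided p-values from the two studies."""

    gene_ids: tuple[str, ...]
    p_1: NDArray[np.float64]
    p_2: NDArray[np.float64]

    def __post_init__(self) -> None:
        for p in (self.p_1, self.p_2):
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _sf(d: NDArray[np.float64], df: float) -> NDArray[np.float64]:
    if np.isinf(df):
        return sps.norm.sf(np.abs(d))
    if df < 1:
        raise ValueError(f"df must be >= 1 (or inf for normal), got {df}")
    return sps.t.sf(np.abs(d), df)


def two_sided_p(stats: TestStatTable, df1: float, df2: float) -> PValuePair:
    """Two-sided p-values per study: p = 2 P(|T| > |d|).

    Reference distribution is t with the given degrees of freedom;
    ``df=inf`` uses the standard normal.
    """
    return PValuePair(
        gene_ids=stats.gene_ids,
        p_1=2.0 * _sf(stats.d1, df1),
        p_2=2.0 * _sf(stats.d2, df2),
    )


def bh_partial_conjunction(
    p: PValuePair,
    alpha: float,
    stats: TestStatTable | None = None,
    adjust: str | None = None,
) -> ClassificationResult:
    """Call a gene reproducible when max(p_1, p_2) < alpha.

    With ``adjust='bh'`` the max-p values are Benjamini–Hochberg adjusted
    before thresholding.  Direction comes from the underlying statistics
    when both agree in sign ('none' otherwise, and always 'none' when no
    statistics are supplied) — the call itself never looks at the signs.
    """
    _check_alpha(alpha)
    maxp = np.maximum(p.p_1, p.p_2)
    if adjust is None:
        call = maxp < alpha
    elif adjust == "bh":
        call = multipletests(maxp, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    if stats is not None:
        if stats.gene_ids != p.gene_ids:
            raise ValueError("statistics and p-values refer to different genes")
        sgn1 = np.sign(stats.d1)
        sgn2 = np.sign(stats.d2)
        agree = (sgn1 == sgn2) & (sgn1 != 0)
        direction = tuple(
            ("up" if s > 0 else "down") if (c and a) else "none"
            for c, a, s in zip(call, agree, sgn1)
        )
    else:
        direction = tuple("none" for _ in range(len(p)))
    return ClassificationResult(
        gene_ids=p.gene_ids,
        score=maxp,
        call=call,
        direction=direction,
        alpha=alpha,
    )


class MaxPConjunction(BaseEstimator):
    """Estimator wrapper for the max-p baseline.

    ``fit`` is a no-op (the rule has no free parameters); ``predict``
    returns boolean reproducibility calls for an (n, 2) array of paired
    statistics, converting each to a two-sided p-value under a t (or
    normal) reference.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level for the max-p threshold.
    df1, df2 : float, default inf
        Degrees of freedom of the per-study reference distributions.
    adjust : {None, 'bh'}
        Optional Benjamini–Hochberg adjustment of the max-p values.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        df1: float = np.inf,
        df2: float = np.inf,
        adjust: str | None = None,
    ):
        self.alpha = alpha
        self.df1 = df1
        self.df2 = df2
        self.adjust = adjust

    def fit(self, X=None, y=None) -> "MaxPConjunction":
        self.is_fitted_ = True
        return self

    def _result(self, X) -> ClassificationResult:
        if isinstance(X, TestStatTable):
            stats = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be an (n, 2) array of paired statistics")
            stats = TestStatTable(
                [f"g{i}" for i in range(arr.shape[0])], arr[:, 0], arr[:, 1]
            )
        p = two_sided_p(stats, self.df1, self.df2)
        return bh_partial_conjunction(p, self.alpha, stats=stats, adjust=self.adjust)

    def predict(self, X) -> NDArray[np.bool_]:
        """Boolean reproducibility calls at level ``alpha``."""
        return self._result(X).call

    def classify(self, X) -> ClassificationResult:
        """Full classification result (scores, calls, directions)."""
        return self._result(X)
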