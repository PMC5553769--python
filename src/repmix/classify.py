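"""Reproducibility calls, rankings, and sign-discordance diagnostics.

A gene is called reproducible when its posterior null probability (local
false discovery rate) satisfies ``p0 < alpha`` strictly; direction is the
larger of the up/down posteriors.  Rankings sort ascending by p0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

from .model import PosteriorTable, TestStatTable

__all__ = ["ClassificationResult", "classify", "top_k", "sign_discordant"]

DIRECTIONS = ("none", "up", "down")


@dataclass(frozen=True)
class ClassificationResult:
    """Per-gene reproducibility calls.

    ``score`` is the significance score the call thresholds (the posterior
    null probability for the mixture method; max-p for the baseline).
    ``direction`` is 'up'/'down' for called genes, 'none' otherwise.
    """

    gene_ids: tuple[str, ...]
    score: NDArray[np.float64]
    call: NDArray[np.bool_]
    direction: tuple[str, ...]
    alpha: float

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def n_called(self) -> int:
        return int(self.call.sum())


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def classify(post: PosteriorTable, alpha: float) -> ClassificationResult:
    """Threshold the posterior null probability at ``alpha`` (strict <)."""
    _check_alpha(alpha)
    call = post.p0 < alpha
    up = post.p1 >= post.p2
    direction = tuple(
        ("up" if u else "down") if c else "none" for c, u in zip(call, up)
    )
    return ClassificationResult(
        gene_ids=post.gene_ids,
        score=post.p0.copy(),
        call=call,
        direction=direction,
        alpha=alpha,
    )


def top_k(post: PosteriorTable, k: int) -> list[str]:
    """The k genes with smallest posterior null probability.

    Ties broken by descending max(p1, p2), then lexicographically by gene
    id, so the ordering is deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(post):
        raise ValueError(f"k={k} exceeds table size {len(post)}")
    strength = np.maximum(post.p1, post.p2)
    order = sorted(
        range(len(post)),
        key=lambda i: (post.p0[i], -strength[i], post.gene_ids[i]),
    )
    return [post.gene_ids[i] for i in order[:k]]


def sign_discordant(
    stats: TestStatTable, selected: Sequence[str]
) -> tuple[list[str], int]:
    """Genes among ``selected`` whose statistics have opposite signs.

    A gene with d1 * d2 < 0 is significant in opposite directions in the
    two studies — the failure mode that p-value-only reproducibility rules
    cannot see.  Zero statistics count as concordant.
    """
    lookup = {g: i for i, g in enumerate(stats.gene_ids)}
    missing = [g for g in selected if g not in lookup]
    if missing:
        raise KeyError(f"unknown gene id(s): {missing}")
    discordant = [
        g for g in selected if stats.d1[lookup[g]] * stats.d2[lookup[g]] < 0
    ]
    return discordant, len(discordant)
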