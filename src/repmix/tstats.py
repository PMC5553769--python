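"""Per-gene two-sample t statistics from two-group expression matrices.

For study i and gene g with group means ``xbar_gi1`` (control) and
``xbar_gi2`` (treatment),

    d_gi = (xbar_gi2 - xbar_gi1) / s_gi,
    s_gi^2 = (1/n_i1 + 1/n_i2) * (SS_1 + SS_2) / (n_i1 + n_i2 - 2),

the classical equal-variance unpaired t statistic with the treatment-minus-
control sign convention.  No small-sample z-score correction is applied;
with very small groups the statistics are t- rather than normal-distributed
and the mixture's unit sampling variance is only approximate (documented
limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import TestStatTable

__all__ = ["ExpressionStudy", "t_statistics", "pair_studies"]


@dataclass(frozen=True)
class ExpressionStudy:
    """A two-group expression study: genes x samples on a normalized scale.

    ``group`` assigns each sample column to 1 (control) or 2 (treatment);
    each group needs at least two samples.
    """

    gene_ids: tuple[str, ...]
    matrix: NDArray[np.float64]
    group: NDArray[np.int_]
    study_id: str = ""

    def __init__(
        self,
        gene_ids: Sequence[str],
        matrix: ArrayLike,
        group: Sequence[int],
        study_id: str = "",
    ):
        ids = tuple(str(g) for g in gene_ids)
        mat = np.asarray(matrix, dtype=float)
        grp = np.asarray(group, dtype=int)
        if mat.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (genes x samples)")
        if mat.shape[0] != len(ids):
            raise ValueError(
                f"{len(ids)} gene ids but matrix has {mat.shape[0]} rows"
            )
        if mat.shape[1] != grp.size:
            raise ValueError(
                f"{grp.size} group labels but matrix has {mat.shape[1]} columns"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(mat)):
            raise ValueError("expression matrix contains missing/non-finite values")
        bad = set(grp.tolist()) - {1, 2}
        if bad:
            raise ValueError(f"group labels must be in {{1, 2}}, found {sorted(bad)}")
        for k in (1, 2):
            if np.sum(grp == k) < 2:
                raise ValueError(f"group {k} has fewer than 2 samples")
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "group", grp)
        object.__setattr__(self, "study_id", str(study_id))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def t_statistics(
    study: ExpressionStudy, drop_degenerate: bool = False
) -> tuple[NDArray[np.float64], tuple[str, ...]]:
    """Equal-variance two-sample t statistic per gene, group 2 minus group 1.

    Parameters
    ----------
    study : ExpressionStudy
    drop_degenerate : bool
        Genes with zero pooled variance raise by default; with this flag
        they are dropped instead and the surviving gene ids are returned.

    Returns
    -------
    d : array of statistics (for the retained genes)
    gene_ids : the retained gene ids, aligned with ``d``
    """
    x1 = study.matrix[:, study.group == 1]
    x2 = study.matrix[:, study.group == 2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = (1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2)
    zero = s2 <= 0
    if np.any(zero):
        if not drop_degenerate:
            gene = study.gene_ids[int(np.flatnonzero(zero)[0])]
            raise ZeroDivisionError(
                f"zero pooled variance for gene {gene!r}; "
                "use drop_degenerate=True to drop such genes"
            )
        keep = ~zero
        ids = tuple(g for g, k in zip(study.gene_ids, keep) if k)
        return (m2[keep] - m1[keep]) / np.sqrt(s2[keep]), ids
    return (m2 - m1) / np.sqrt(s2), study.gene_ids


def pair_studies(
    stats1: ArrayLike,
    stats2: ArrayLike,
    ids1: Sequence[str],
    ids2: Sequence[str],
) -> tuple[TestStatTable, int]:
    """Inner-join two studies' statistics on gene id.

    Returns the paired table (in study-1 order) and the number of genes
    dropped because they were absent from the other study.
    """
    d1 = np.asarray(stats1, dtype=float)
    d2 = np.asarray(stats2, dtype=float)
    ids1 = [str(g) for g in ids1]
    ids2 = [str(g) for g in ids2]
    if len(ids1) != d1.size or len(ids2) != d2.size:
        raise ValueError("ids and statistics lengths differ")
    if len(set(ids1)) != len(ids1) or len(set(ids2)) != len(ids2):
        raise ValueError("duplicate gene ids within a study")
    lookup2 = {g: i for i, g in enumerate(ids2)}
    common = [g for g in ids1 if g in lookup2]
    if not common:
        raise ValueError("no genes in common between the two studies")
    dropped = (len(ids1) - len(common)) + (len(ids2) - len(common))
    idx2 = [lookup2[g] for g in common]
    idx1 = [i for i, g in enumerate(ids1) if g in lookup2]
    return TestStatTable(common, d1[idx1], d2[idx2]), dropped
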