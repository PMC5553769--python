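"""Tabular readers/writers, run manifests, and the packaged gene tables.

All interchange is plain TSV: a statistics table has columns
``gene_id, d1, d2``; an expression matrix has gene ids in the first column
and sample ids as the remaining headers, with a companion metadata TSV
mapping ``sample_id`` to ``group`` in {1, 2}.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .model import PosteriorTable, TestStatTable
from .tstats import ExpressionStudy

__all__ = [
    "read_stats_tsv",
    "write_stats_tsv",
    "read_expression",
    "write_calls_tsv",
    "sign_discordant_bh_fixture",
    "sign_discordant_copula_fixture",
    "RunManifest",
]

# Two replicate idiopathic pulmonary fibrosis microarray studies (peripheral
# blood, IPF vs healthy): genes among the top-500 "reproducible" picks of a
# p-value-only rule whose t statistics point in opposite directions.
# 23 genes selected by the max-p partial-conjunction rule:
_BH_DISCORDANT = """\
A1BG\t3.34\t-3.63
ANKRD39\t3.93\t-3.35
CA4\t-4.4\t4.94
CDK14\t-4.88\t3.34
CHCHD2\t3.5\t-3.65
CXCR2\t-4.67\t3.38
HCG27\t-4.68\t3.29
KAT6A\t-3.48\t3.54
MFSD3\t4.25\t-3.29
MMP9\t-3.51\t5.77
MRPL14\t4.06\t-3.69
MRPL15\t3.99\t-3.38
MRPL55\t3.63\t-3.95
NDUFB7\t3.79\t-3.54
NDUFS3\t3.98\t-3.89
PRPS1\t3.87\t-4.13
RBBP6\t3.66\t-3.67
ROMO1\t3.33\t-3.41
SEPHS1\t4\t-3.44
TANC2\t-3.59\t3.95
TCN1\t-4.69\t3.36
TMEM141\t3.45\t-3.64
TRIM33\t-4.64\t3.47
"""

# 7 genes selected by a rank-based copula mixture rule on the same studies:
_COPULA_DISCORDANT = """\
CA4\t-4.4\t4.94
CDK14\t-4.88\t3.34
CXCR2\t-4.67\t3.38
HCG27\t-4.68\t3.29
MME\t-6.05\t3.25
TCN1\t-4.69\t3.36
TRIM33\t-4.64\t3.47
"""


def _fixture(text: str) -> TestStatTable:
    rows = [line.split("\t") for line in text.strip().splitlines()]
    return TestStatTable(
        [r[0] for r in rows],
        [float(r[1]) for r in rows],
        [float(r[2]) for r in rows],
    )


def sign_discordant_bh_fixture() -> TestStatTable:
    """The 23 sign-discordant genes selected by the max-p baseline."""
    return _fixture(_BH_DISCORDANT)


def sign_discordant_copula_fixture() -> TestStatTable:
    """The 7 sign-discordant genes selected by the copula-mixture comparator."""
    return _fixture(_COPULA_DISCORDANT)


def read_stats_tsv(path: str | Path) -> TestStatTable:
    """Read a gene_id/d1/d2 TSV into a validated TestStatTable."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as err:
        raise ValueError(f"{path}: cannot parse TSV: {err}") from err
    required = {"gene_id", "d1", "d2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        import warnings

        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
    for col in ("d1", "d2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col}, line {line}")
        df[col] = vals
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    return TestStatTable(df["gene_id"].tolist(), df["d1"].to_numpy(), df["d2"].to_numpy())


def write_stats_tsv(stats: TestStatTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": stats.gene_ids, "d1": stats.d1, "d2": stats.d2}
    ).to_csv(path, sep="\t", index=False)


def read_expression(
    path_matrix: str | Path, path_meta: str | Path, study_id: str = ""
) -> ExpressionStudy:
    """Read an expression matrix TSV plus sample metadata into a study.

    Matrix columns are matched to metadata rows by sample id, so column
    order is irrelevant; every sample must appear in both files.
    """
    path_matrix, path_meta = Path(path_matrix), Path(path_meta)
    mat = pd.read_csv(path_matrix, sep="\t", index_col=0)
    meta = pd.read_csv(path_meta, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{path_meta}: missing column {col!r}")
    meta = meta.set_index("sample_id")
    samples = [str(c) for c in mat.columns]
    unmatched = sorted(set(samples) ^ set(meta.index))
    if unmatched:
        raise ValueError(
            f"samples not shared between matrix and metadata: {unmatched}"
        )
    groups = meta.loc[samples, "group"].to_numpy()
    return ExpressionStudy(
        gene_ids=[str(g) for g in mat.index],
        matrix=mat.to_numpy(dtype=float),
        group=groups,
        study_id=study_id or path_matrix.stem,
    )


def write_calls_tsv(
    calls: ClassificationResult,
    path: str | Path,
    stats: TestStatTable | None = None,
    post: PosteriorTable | None = None,
) -> None:
    """Write calls (with statistics/posteriors when available) as TSV."""
    cols: dict[str, object] = {"gene_id": calls.gene_ids}
    if stats is not None:
        cols["d1"] = stats.d1
        cols["d2"] = stats.d2
    if post is not None:
        cols["p0"] = post.p0
        cols["p1"] = post.p1
        cols["p2"] = post.p2
    else:
        cols["score"] = calls.score
    cols["call"] = calls.call.astype(int)
    cols["direction"] = list(calls.direction)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class RunManifest:
    """Provenance record emitted next to every CLI output."""

    command: str
    parameters: dict
    seed: int | None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    package_version: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def checksum(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def write(self, out_path: str | Path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        manifest_path = Path(str(out_path) + ".manifest.json")
        manifest_path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "parameters": self.parameters,
                    "seed": self.seed,
                    "timestamp": self.timestamp,
                    "package_version": self.package_version,
                    "python": platform.python_version(),
                    "input_checksums": self.input_checksums,
                },
                indent=2,
            )
        )
        return manifest_path
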