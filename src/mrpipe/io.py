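"""Readers and writers for the package's plain-text table dialects.

Summary statistics travel as a tab-separated table with header
``SNP CHR BP EA OA EAF BETA SE P N`` and ``.`` for missing values; the LD
reference as a 3-column ``SNP_A SNP_B R2`` table (a square matrix with a
row/column index header is also accepted).  Readers tolerate gzip by suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import SUMSTAT_COLUMNS, GwasSummaryStats, LdReference, MrpipeError

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_ld_reference",
    "write_ld_reference",
]

#: float formatting used everywhere we serialize, so identical inputs and
#: seeds give byte-identical output files
FLOAT_FMT = "%.10g"


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sumstats(path, trait: str = "") -> GwasSummaryStats:
    """Read a summary-statistics TSV (optionally gzipped)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["."], dtype={"SNP": str, "CHR": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise MrpipeError(f"{path}: missing columns {missing}")
    return GwasSummaryStats(df, trait=trait or Path(path).stem)


def write_sumstats(stats: GwasSummaryStats, path) -> None:
    df = stats.table.copy()
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=".")


def read_ld_reference(path, positions: dict[str, tuple[str, int]] | None = None,
                      stats: GwasSummaryStats | None = None) -> LdReference:
    """Read an LD reference from pairs TSV or a square r2 matrix.

    Positions come either from an explicit mapping or from a summary-stats
    table covering the same SNPs (``CHR``/``BP`` columns).
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if positions is None:
        if stats is None:
            raise MrpipeError("LD reference needs positions or a summary-stats table")
        positions = {
            r.SNP: (str(r.CHR), int(r.BP)) for r in stats.table.itertuples()
        }
    if list(df.columns[:3]) == ["SNP_A", "SNP_B", "R2"]:
        return LdReference.from_pairs_frame(df, positions)
    # square-matrix alternative: first column is the row index of SNP ids
    ids = df.iloc[:, 0].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if mat.shape != (len(ids), len(ids)) or list(df.columns[1:]) != ids:
        raise MrpipeError(f"{path}: not a pairs table nor a square r2 matrix")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise MrpipeError(f"{path}: square r2 matrix is not symmetric")
    pairs = {}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if mat[i, j] != 0.0:
                pairs[(a, ids[j])] = mat[i, j]
    return LdReference(pairs, positions)


def write_ld_reference(ld: LdReference, path) -> None:
    ld.to_pairs_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
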