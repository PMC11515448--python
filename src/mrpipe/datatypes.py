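"""Core containers shared across the pipeline.

The substrate of every estimator is a :class:`HarmonizedInstrumentSet` — the
per-SNP quadruples (gamma_hat, se_x, Gamma_hat, se_y) with the exposure and
outcome effects expressed for the same effect allele.  Upstream of it sit the
raw per-trait summary statistics (:class:`GwasSummaryStats`) and the pairwise
LD lookup (:class:`LdReference`); downstream sit the fit objects produced by
the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GwasSummaryStats",
    "LdReference",
    "HarmonizedInstrumentSet",
    "RadialFit",
    "EggerFit",
    "MrEstimate",
    "MrpipeError",
]

#: canonical column order of the summary-statistics table dialect
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class MrpipeError(ValueError):
    """Structured analysis error (maps to CLI exit code 2)."""


def complement(allele: str) -> str:
    """Complementary-strand base for a single nucleotide."""
    return _COMPLEMENT[allele]


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and G/C variants, whose strand is ambiguous."""
    return _COMPLEMENT[ea] == oa


@dataclass
class GwasSummaryStats:
    """One trait's per-variant association records.

    Wraps a DataFrame with columns ``SNP CHR BP EA OA EAF BETA SE P N``:
    identifier, chromosome, 1-based position, effect and other allele,
    effect-allele frequency, log-odds effect with its standard error,
    p-value and sample size.
    """

    table: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise MrpipeError(f"summary-stats table missing columns: {missing}")
        self.table = self.table.loc[:, SUMSTAT_COLUMNS].reset_index(drop=True)
        self._validate()
        self._index = {s: i for i, s in enumerate(self.table["SNP"])}

    def _validate(self) -> None:
        t = self.table
        if t["SNP"].duplicated().any():
            dups = t.loc[t["SNP"].duplicated(), "SNP"].tolist()
            raise MrpipeError(f"duplicate SNP ids: {dups[:5]}")
        if (t["SE"] <= 0).any():
            raise MrpipeError("non-positive SE in summary statistics")
        if ((t["EAF"] <= 0) | (t["EAF"] >= 1)).any():
            raise MrpipeError("EAF outside (0, 1)")
        for col in ("EA", "OA"):
            bad = ~t[col].isin(list(_VALID_ALLELES))
            if bad.any():
                raise MrpipeError(f"invalid {col} alleles: {t.loc[bad, col].unique()}")
        if (t["EA"] == t["OA"]).any():
            raise MrpipeError("EA equals OA for some variants")

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def record(self, snp_id: str) -> pd.Series:
        """Row for one SNP; KeyError if absent."""
        return self.table.iloc[self._index[snp_id]]

    def subset(self, snp_ids) -> "GwasSummaryStats":
        """New table restricted to ``snp_ids``, in the given order."""
        rows = [self._index[s] for s in snp_ids]
        return GwasSummaryStats(self.table.iloc[rows].reset_index(drop=True), self.trait)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["SNP"].tolist()


class LdReference:
    """Symmetric pairwise r-squared lookup with genomic positions.

    Absent pairs are treated as r2 = 0; the diagonal is implicitly 1.
    Positions (chrom, bp) back the clumping window test.
    """

    def __init__(self, pairs: dict[tuple[str, str], float],
                 positions: dict[str, tuple[str, int]]):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), r2 in pairs.items():
            if not 0.0 <= r2 <= 1.0:
                raise MrpipeError(f"r2({a},{b}) = {r2} outside [0, 1]")
            if a != b:
                self._r2[self._key(a, b)] = float(r2)
        self.positions = dict(positions)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def neighbors(self, snp_id: str) -> dict[str, float]:
        """All SNPs with a stored (nonzero) r2 against ``snp_id``."""
        out = {}
        for (a, b), r2 in self._r2.items():
            if a == snp_id:
                out[b] = r2
            elif b == snp_id:
                out[a] = r2
        return out

    def position(self, snp_id: str) -> tuple[str, int]:
        try:
            return self.positions[snp_id]
        except KeyError:
            raise MrpipeError(f"SNP {snp_id!r} absent from LD reference positions") from None

    def to_pairs_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])

    @classmethod
    def from_pairs_frame(cls, df: pd.DataFrame,
                         positions: dict[str, tuple[str, int]]) -> "LdReference":
        pairs = {(r.SNP_A, r.SNP_B): float(r.R2) for r in df.itertuples()}
        return cls(pairs, positions)


@dataclass
class HarmonizedInstrumentSet:
    """Aligned per-SNP effect quadruples — the input to every estimator.

    ``gamma_hat``/``se_x`` are the instrument-exposure associations,
    ``Gamma_hat``/``se_y`` the instrument-outcome associations, with the
    outcome effect expressed for the exposure's effect allele.  Provenance
    flags record allele flips and proxy substitutions; ``drop_log`` lists
    every excluded instrument with a machine-readable reason code.
    """

    snp_ids: list[str]
    gamma_hat: np.ndarray
    se_x: np.ndarray
    Gamma_hat: np.ndarray
    se_y: np.ndarray
    flipped: np.ndarray = None
    proxy_used: np.ndarray = None
    proxy_id: list = None
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        for name in ("gamma_hat", "se_x", "Gamma_hat", "se_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise MrpipeError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise MrpipeError("harmonized set contains non-positive SEs")
        if self.flipped is None:
            self.flipped = np.zeros(n, dtype=bool)
        if self.proxy_used is None:
            self.proxy_used = np.zeros(n, dtype=bool)
        if self.proxy_id is None:
            self.proxy_id = [None] * n
        self.flipped = np.asarray(self.flipped, dtype=bool)
        self.proxy_used = np.asarray(self.proxy_used, dtype=bool)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep) -> "HarmonizedInstrumentSet":
        """Restrict to positional indices ``keep`` (order preserved)."""
        keep = list(keep)
        return HarmonizedInstrumentSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            gamma_hat=self.gamma_hat[keep],
            se_x=self.se_x[keep],
            Gamma_hat=self.Gamma_hat[keep],
            se_y=self.se_y[keep],
            flipped=self.flipped[keep],
            proxy_used=self.proxy_used[keep],
            proxy_id=[self.proxy_id[i] for i in keep],
            drop_log=list(self.drop_log),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "gamma_hat": self.gamma_hat,
                "se_x": self.se_x,
                "Gamma_hat": self.Gamma_hat,
                "se_y": self.se_y,
                "flipped": self.flipped,
                "proxy_used": self.proxy_used,
                "proxy_id": [p if p is not None else "." for p in self.proxy_id],
            }
        )


@dataclass
class RadialFit:
    """Zero-intercept radial IVW fit.

    The causal estimate is the slope of sqrt(W)*ratio on sqrt(W); each SNP's
    Cochran Q contribution ``q_j`` is its squared weighted residual.
    """

    snp_ids: list[str]
    theta_hat: float
    se: float
    ratio: np.ndarray
    weights: np.ndarray
    q_j: np.ndarray
    q_total: float
    df: int
    q_pval: float
    weight_order: str
    n_weight_iterations: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class EggerFit:
    """Radial MR-Egger fit: free intercept indexing directional pleiotropy."""

    snp_ids: list[str]
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    intercept_pval: float
    slope_pval: float
    weights: np.ndarray
    q_prime_j: np.ndarray
    q_prime_total: float
    df: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class MrEstimate:
    """Method-level causal estimate on the log-odds scale with 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    def with_diagnostics(self, **kwargs) -> "MrEstimate":
        d = dict(self.diagnostics)
        d.update(kwargs)
        return replace(self, diagnostics=d)
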