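"""Shared fixtures: a 12-SNP estimator fixture with realistic magnitudes and
a fully hand-designed 30-SNP instrument-filtering scenario."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrpipe.datatypes import GwasSummaryStats, HarmonizedInstrumentSet, LdReference


@pytest.fixture(scope="session")
def twelve_snp_set() -> HarmonizedInstrumentSet:
    """Fixed 12-instrument set shared by all estimator-vs-oracle checks.

    Magnitudes mimic a binary-trait GWAS pair: exposure effects ~0.2-0.9
    with SE ~0.03, outcome effects near theta * gamma with SE ~0.012, plus
    mild heterogeneity.
    """
    rng = np.random.default_rng(20240)
    n = 12
    gamma = rng.uniform(0.2, 0.9, n) * rng.choice([-1.0, 1.0], n)
    se_x = rng.uniform(0.02, 0.04, n)
    se_y = rng.uniform(0.008, 0.016, n)
    theta = 0.05
    Gamma = theta * gamma + rng.normal(0.0, 1.3 * se_y, n)
    return HarmonizedInstrumentSet(
        snp_ids=[f"rs{i:03d}" for i in range(n)],
        gamma_hat=gamma, se_x=se_x, Gamma_hat=Gamma, se_y=se_y,
    )


def _sumstat_row(snp, chrom, bp, ea, oa, eaf, beta, se, p, n=100_000):
    return dict(SNP=snp, CHR=chrom, BP=bp, EA=ea, OA=oa, EAF=eaf,
                BETA=beta, SE=se, P=p, N=n)


@pytest.fixture(scope="session")
def toy_filter_scenario():
    """Hand-designed 30-SNP exposure table, outcome table and LD reference.

    The expected behaviour is fully enumerable:

    * selection at P < 5e-8 keeps s01..s08 (s09 sits exactly at the
      boundary, s10..s30 are non-significant);
    * clumping removes s02, s03 (r2 0.9/0.95 with s01 inside the 10,000 kb
      window) and s07 (r2 0.5 with s06); s04 survives (r2 0.0005 below the
      cutoff) and s05 survives (r2 0.9 with s01 but 29 Mb away);
    * harmonization drops s04 (palindromic A/T, MAF 0.45 > 0.42), keeps s05
      (palindromic G/C, MAF 0.10), proxies s06 through s21 (r2 0.95 > 0.8),
      and drops s08 (best proxy s22 at r2 exactly 0.8, not > 0.8);
    * the surviving set is [s01, s06 (via s21), s05] in p-value order.
    """
    rows = [
        # --- significant, clump-relevant block on chr1 ---
        _sumstat_row("s01", "1", 1_000_000, "A", "G", 0.30, 0.50, 0.030, 1e-20),
        _sumstat_row("s02", "1", 1_050_000, "C", "T", 0.25, 0.45, 0.030, 1e-15),
        _sumstat_row("s03", "1", 1_100_000, "G", "A", 0.28, 0.42, 0.030, 1e-12),
        _sumstat_row("s04", "1", 1_200_000, "A", "T", 0.45, 0.40, 0.030, 1e-10),
        _sumstat_row("s05", "1", 30_000_000, "G", "C", 0.10, 0.38, 0.030, 1e-9),
        # --- chr2 ---
        _sumstat_row("s06", "2", 5_000_000, "T", "C", 0.30, 0.44, 0.030, 1e-11),
        _sumstat_row("s07", "2", 5_100_000, "A", "C", 0.35, 0.36, 0.030, 2e-8),
        _sumstat_row("s08", "2", 40_000_000, "G", "T", 0.20, 0.35, 0.030, 4e-8),
        # --- boundary and non-significant fill ---
        _sumstat_row("s09", "2", 60_000_000, "A", "G", 0.40, 0.30, 0.030, 5e-8),
        _sumstat_row("s10", "3", 1_000_000, "C", "A", 0.22, 0.05, 0.030, 0.5),
    ]
    for i in range(11, 31):
        rows.append(_sumstat_row(f"s{i:02d}", "3", 2_000_000 + i * 1_000_000,
                                 "T", "G", 0.30, 0.10, 0.030, 1e-5))
    exposure = GwasSummaryStats(pd.DataFrame(rows), trait="toy_exposure")

    out_rows = [
        # s01 with alleles swapped: aligned beta must flip to +0.05
        _sumstat_row("s01", "1", 1_000_000, "G", "A", 0.70, -0.05, 0.012, 1e-4),
        _sumstat_row("s02", "1", 1_050_000, "C", "T", 0.25, 0.04, 0.012, 1e-3),
        _sumstat_row("s03", "1", 1_100_000, "G", "A", 0.28, 0.04, 0.012, 1e-3),
        # s04 palindromic, exposure MAF 0.45 > 0.42 -> dropped
        _sumstat_row("s04", "1", 1_200_000, "A", "T", 0.44, 0.03, 0.012, 0.01),
        # s05 palindromic, MAF 0.10/0.12 -> kept, same frequency side
        _sumstat_row("s05", "1", 30_000_000, "G", "C", 0.12, 0.045, 0.012, 1e-4),
        # s06 absent; proxy s21 present (r2 0.95)
        _sumstat_row("s21", "2", 5_050_000, "A", "G", 0.31, 0.039, 0.012, 1e-3),
        # s08 absent; only candidate proxy s22 at r2 exactly 0.8 -> no proxy
        _sumstat_row("s22", "2", 40_050_000, "C", "A", 0.21, 0.02, 0.012, 0.1),
        _sumstat_row("s07", "2", 5_100_000, "A", "C", 0.35, 0.03, 0.012, 0.01),
    ]
    outcome = GwasSummaryStats(pd.DataFrame(out_rows), trait="toy_outcome")

    positions = {r["SNP"]: (r["CHR"], r["BP"]) for r in rows}
    positions["s21"] = ("2", 5_050_000)
    positions["s22"] = ("2", 40_050_000)
    ld = LdReference(
        {
            ("s01", "s02"): 0.90,
            ("s01", "s03"): 0.95,
            ("s02", "s03"): 0.90,
            ("s01", "s04"): 0.0005,
            ("s01", "s05"): 0.90,   # outside the 10,000 kb window
            ("s06", "s07"): 0.50,
            ("s06", "s21"): 0.95,
            ("s08", "s22"): 0.80,   # exactly at the proxy bound: not > 0.8
        },
        positions,
    )
    return exposure, outcome, ld
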