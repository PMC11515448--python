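"""Instrument selection, LD clumping, proxy search, and harmonization.

Selection keeps genome-wide significant variants (P < 5e-8 by default);
clumping greedily retains the most significant variant per LD region
(r2 >= 0.001 within a 10,000 kb window removes a candidate); instruments
absent from the outcome dataset are replaced by the best available proxy
with r2 > 0.8; harmonization aligns the outcome effect to the exposure's
effect allele, resolving allele-order swaps and strand re-encodings, and
drops palindromic variants whose minor allele frequency exceeds 0.42 (below
that, palindromes are aligned by allele frequency).

Boundary conventions: significance is strict '<'; clump removal is '>=' the
r2 cutoff; proxy search is strict '>'; the palindrome cutoff drops strictly
'>' 0.42 (MAF <= 0.42 is retained with frequency alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    GwasSummaryStats,
    HarmonizedInstrumentSet,
    LdReference,
    MrpipeError,
    complement,
    is_palindromic,
)

__all__ = [
    "select_genome_wide",
    "clump",
    "find_proxy",
    "harmonize",
    "HarmonizationOptions",
]

P_GENOME_WIDE = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_KB = 10_000.0
PROXY_R2 = 0.8
MAF_PALINDROMIC_CUTOFF = 0.42

# drop-log reason codes
DROP_MISSING_NO_PROXY = "missing_from_outcome_no_proxy"
DROP_PALINDROMIC_MAF = "palindromic_maf_above_cutoff"
DROP_PALINDROMIC_ALL = "palindromic_drop_all_policy"
DROP_IRRECONCILABLE = "irreconcilable_alleles"


def select_genome_wide(stats: GwasSummaryStats,
                       p_threshold: float = P_GENOME_WIDE) -> list[str]:
    """SNP ids with p-value strictly below the threshold, input order kept."""
    if not 0 < p_threshold < 1:
        raise MrpipeError("p_threshold must be in (0, 1)")
    t = stats.table
    return t.loc[t["P"] < p_threshold, "SNP"].tolist()


def clump(candidates: list[str], stats: GwasSummaryStats, ld: LdReference,
          r2_cutoff: float = CLUMP_R2,
          window_kb: float = CLUMP_WINDOW_KB) -> list[str]:
    """Greedy p-value clumping.

    Repeatedly emit the remaining candidate with the smallest p-value (ties
    broken by lexicographically smaller SNP id) and discard every remaining
    candidate on the same chromosome within +/- ``window_kb`` whose r2 with
    it reaches ``r2_cutoff``.  Returns index SNPs sorted by ascending p.
    """
    if not 0 <= r2_cutoff <= 1:
        raise MrpipeError("r2_cutoff must be in [0, 1]")
    if window_kb <= 0:
        raise MrpipeError("window_kb must be positive")
    for s in candidates:
        if s not in stats:
            raise MrpipeError(f"candidate {s!r} missing from summary statistics")
        ld.position(s)  # raises naming the SNP if absent

    window_bp = window_kb * 1000.0
    remaining = sorted(candidates,
                       key=lambda s: (float(stats.record(s)["P"]), s))
    kept: list[str] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        chrom_i, pos_i = ld.position(index)
        survivors = []
        for s in remaining:
            chrom_s, pos_s = ld.position(s)
            in_window = chrom_s == chrom_i and abs(pos_s - pos_i) <= window_bp
            if in_window and ld.r2(index, s) >= r2_cutoff:
                continue
            survivors.append(s)
        remaining = survivors
    return kept


def find_proxy(snp_id: str, outcome: GwasSummaryStats, ld: LdReference,
               r2_min: float = PROXY_R2) -> str | None:
    """Best outcome-dataset proxy for a missing instrument, or None.

    Among outcome SNPs with r2 strictly above ``r2_min``, returns the one
    with maximal r2 (ties broken by smaller SNP id).
    """
    if snp_id in outcome:
        raise MrpipeError(f"{snp_id!r} present in outcome; proxy not needed")
    best: tuple[float, str] | None = None
    for other, r2 in ld.neighbors(snp_id).items():
        if other not in outcome or r2 <= r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and other < best[1]):
            best = (r2, other)
    return best[1] if best else None


@dataclass
class HarmonizationOptions:
    """Switches for the harmonization policy."""

    maf_palindromic_cutoff: float = MAF_PALINDROMIC_CUTOFF
    #: drop every palindromic variant instead of frequency-aligning those
    #: with unambiguous frequencies
    drop_all_palindromic: bool = False
    proxy_r2: float = PROXY_R2
    use_proxies: bool = True


def _match_class(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """How the outcome allele pair maps onto the exposure pair.

    Returns 'same', 'swap', 'strand', 'strand_swap', or None if the pairs
    cannot be reconciled even after a strand flip.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    c_ea, c_oa = complement(ea_y), complement(oa_y)
    if (c_ea, c_oa) == (ea_x, oa_x):
        return "strand"
    if (c_ea, c_oa) == (oa_x, ea_x):
        return "strand_swap"
    return None


def harmonize(exposure: GwasSummaryStats, outcome: GwasSummaryStats,
              ld: LdReference | None = None,
              options: HarmonizationOptions | None = None,
              maf_palindromic_cutoff: float | None = None) -> HarmonizedInstrumentSet:
    """Align outcome effects to exposure effect alleles.

    For each exposure instrument: substitute a proxy if the variant is
    missing from the outcome (or drop with a logged reason); align the
    outcome beta to the exposure effect allele, negating it and reflecting
    the EAF when the allele order is swapped; resolve complementary-strand
    encodings by flipping strands; apply the palindrome policy (drop when
    MAF > cutoff on either side, otherwise align by frequency).  Every
    exclusion lands in the drop log exactly once with a reason code.
    """
    opts = options or HarmonizationOptions()
    if maf_palindromic_cutoff is not None:
        opts = HarmonizationOptions(
            maf_palindromic_cutoff=maf_palindromic_cutoff,
            drop_all_palindromic=opts.drop_all_palindromic,
            proxy_r2=opts.proxy_r2,
            use_proxies=opts.use_proxies,
        )

    snp_ids: list[str] = []
    gam, sx, Gam, sy = [], [], [], []
    flipped, proxy_used, proxy_ids = [], [], []
    drop_log: list[tuple[str, str]] = []

    for _, x in exposure.table.iterrows():
        snp = x["SNP"]
        proxy = None
        if snp in outcome:
            y = outcome.record(snp)
        elif opts.use_proxies and ld is not None:
            proxy = find_proxy(snp, outcome, ld, opts.proxy_r2)
            if proxy is None:
                drop_log.append((snp, DROP_MISSING_NO_PROXY))
                continue
            y = outcome.record(proxy)
        else:
            drop_log.append((snp, DROP_MISSING_NO_PROXY))
            continue

        ea_x, oa_x = x["EA"], x["OA"]
        beta_y, eaf_y = float(y["BETA"]), float(y["EAF"])

        if proxy is not None:
            # a proxy is a different variant: alleles cannot be matched, so
            # orientation comes from frequency matching against the exposure
            # (unreliable for near-0.5 palindromic proxies, which are dropped)
            if is_palindromic(y["EA"], y["OA"]) and \
                    min(eaf_y, 1.0 - eaf_y) > opts.maf_palindromic_cutoff:
                drop_log.append((snp, DROP_PALINDROMIC_MAF))
                continue
            flip = abs(eaf_y - float(x["EAF"])) > abs((1.0 - eaf_y) - float(x["EAF"]))
            if flip:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
            was_flipped = flip
        elif is_palindromic(ea_x, oa_x):
            if opts.drop_all_palindromic:
                drop_log.append((snp, DROP_PALINDROMIC_ALL))
                continue
            maf_x = min(float(x["EAF"]), 1.0 - float(x["EAF"]))
            maf_y = min(eaf_y, 1.0 - eaf_y)
            if max(maf_x, maf_y) > opts.maf_palindromic_cutoff:
                drop_log.append((snp, DROP_PALINDROMIC_MAF))
                continue
            # strand is unknowable for palindromes; align by frequency:
            # the outcome effect allele is taken to be the one on the same
            # side of 0.5 as the exposure's effect allele
            flip = (float(x["EAF"]) < 0.5) != (eaf_y < 0.5)
            if flip:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
            was_flipped = flip
        else:
            klass = _match_class(ea_x, oa_x, y["EA"], y["OA"])
            if klass is None:
                drop_log.append((snp, DROP_IRRECONCILABLE))
                continue
            was_flipped = klass in ("swap", "strand_swap")
            if was_flipped:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y

        snp_ids.append(snp)
        gam.append(float(x["BETA"]))
        sx.append(float(x["SE"]))
        Gam.append(beta_y)
        sy.append(float(y["SE"]))
        flipped.append(was_flipped)
        proxy_used.append(proxy is not None)
        proxy_ids.append(proxy)

    return HarmonizedInstrumentSet(
        snp_ids=snp_ids,
        gamma_hat=np.array(gam, dtype=float),
        se_x=np.array(sx, dtype=float),
        Gamma_hat=np.array(Gam, dtype=float),
        se_y=np.array(sy, dtype=float),
        flipped=np.array(flipped, dtype=bool),
        proxy_used=np.array(proxy_used, dtype=bool),
        proxy_id=proxy_ids,
        drop_log=drop_log,
    )
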