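"""Pooled-sequencing homozygosity mapping.

A variant heterozygous in the founder tracks the mutant haplotype.  Close
to the causal locus the mutant-haplotype allele is expected at frequency
~1 in the homozygous-mutant pool, ~0.5 in the heterozygote pool and the
founder, and ~0 in the wild-type pool.  Each founder-het variant is
classified against that expectation (concordant / discordant /
uninformative), the genome is tiled in fixed windows, and the fraction of
concordant variants among informative ones per window is the mapping
statistic: windows near the causal site approach 1, the genome-wide
background stays near 0.

Allele frequency is alt/(ref+alt) read counts; variants where any pool
(founder included) misses the per-pool depth minimum are uninformative
and enter neither numerator nor denominator.  Windows with fewer than
``min_variants`` informative variants are flagged non-qualifying and
excluded from ranking (but still reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConcordanceRule", "pool_af", "classify_concordance", "window_scan",
           "rank_candidates", "CONCORDANT", "DISCORDANT", "UNINFORMATIVE"]

CONCORDANT, DISCORDANT, UNINFORMATIVE = 1, 0, -1


@dataclass
class ConcordanceRule:
    """Expected pooled allele-frequency pattern around the causal locus.

    Het-pool and founder ranges are inclusive at both ends ("between 0.4
    and 0.6"); the hom-pool bound is strict > and the wild-type bound
    strict < ("AF > 0.85", "AF < 0.15").
    """
    het_lo: float = 0.4
    het_hi: float = 0.6
    founder_lo: float = 0.4
    founder_hi: float = 0.6
    hom_min: float = 0.85
    wt_max: float = 0.15
    min_depth: int = 30

    def __post_init__(self) -> None:
        for v in (self.het_lo, self.het_hi, self.founder_lo, self.founder_hi,
                  self.hom_min, self.wt_max):
            if not 0 <= v <= 1:
                raise ValueError("AF bounds must be in [0, 1]")
        if self.het_lo > self.het_hi or self.founder_lo > self.founder_hi:
            raise ValueError("AF ranges must be well-ordered")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def pool_af(ref, alt):
    """Allele frequency alt/(ref+alt); NaN where no reads."""
    ref = np.asarray(ref, float)
    alt = np.asarray(alt, float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    return af if af.ndim else float(af)


def classify_concordance(pool_counts: pd.DataFrame,
                         rule: ConcordanceRule | None = None) -> np.ndarray:
    """Classify each founder-het variant as concordant (1), discordant (0)
    or uninformative (-1) against the expected pool AF pattern."""
    rule = rule or ConcordanceRule()
    af, depth_ok = {}, {}
    for p in ("founder", "het", "hom", "wt"):
        ref = pool_counts[f"{p}_ref"].to_numpy()
        alt = pool_counts[f"{p}_alt"].to_numpy()
        af[p] = np.atleast_1d(pool_af(ref, alt))
        depth_ok[p] = (ref + alt) >= rule.min_depth
    informative = np.ones(len(pool_counts), bool)
    for p in ("founder", "het", "hom", "wt"):
        informative &= depth_ok[p] & ~np.isnan(af[p])
    concordant = (
        (af["het"] >= rule.het_lo) & (af["het"] <= rule.het_hi)
        & (af["founder"] >= rule.founder_lo) & (af["founder"] <= rule.founder_hi)
        & (af["hom"] > rule.hom_min)
        & (af["wt"] < rule.wt_max)
    )
    out = np.full(len(pool_counts), UNINFORMATIVE, np.int8)
    out[informative & concordant] = CONCORDANT
    out[informative & ~concordant] = DISCORDANT
    return out


def window_scan(
    pool_counts: pd.DataFrame,
    rule: ConcordanceRule | None = None,
    window_size: int = 10_000,
    min_variants: int = 5,
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile every scaffold in fixed windows and compute the concordant
    fraction per window.

    Input must be sorted by (scaffold, pos).  Windows are half-open
    [k*w, (k+1)*w) anchored at scaffold coordinate 0; when scaffold
    lengths are given the tiling covers the whole scaffold, otherwise it
    extends to the last variant.  Windows with fewer than ``min_variants``
    informative variants have ``qualifying=False`` and a NaN fraction
    when empty.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    status = classify_concordance(pool_counts, rule)
    scaf = pool_counts["scaffold"].to_numpy()
    pos = pool_counts["pos"].to_numpy()
    order_ok = np.all(scaf[:-1] <= scaf[1:]) if len(scaf) else True
    if not order_ok or np.any((scaf[:-1] == scaf[1:]) & (pos[:-1] > pos[1:])):
        raise ValueError("pool counts must be sorted by (scaffold, pos)")
    rows = []
    for name in pd.unique(scaf):
        m = scaf == name
        p = pos[m]
        st = status[m]
        limit = (scaffold_lengths or {}).get(name, int(p.max()) if len(p) else 0)
        n_win = max(1, int(np.ceil(limit / window_size)))
        win = (p - 1) // window_size  # 1-based pos -> 0-based tile index
        if len(win):
            n_win = max(n_win, int(win.max()) + 1)
        inf_c = np.bincount(win[st != UNINFORMATIVE], minlength=n_win)
        con_c = np.bincount(win[st == CONCORDANT], minlength=n_win)
        for k in range(n_win):
            ninf, ncon = int(inf_c[k]), int(con_c[k])
            rows.append({
                "scaffold": name,
                "start": k * window_size,
                "end": (k + 1) * window_size,
                "n_informative": ninf,
                "n_concordant": ncon,
                "fraction": ncon / ninf if ninf else np.nan,
                "qualifying": ninf >= min_variants,
            })
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_informative",
                                       "n_concordant", "fraction", "qualifying"])


def rank_candidates(windows: pd.DataFrame, top_k: int = 10):
    """Rank qualifying windows by concordant fraction.

    Ties break toward the window with more informative variants, then by
    scaffold name, then start.  Returns (ranked top_k DataFrame, histogram
    of the genome-wide fraction distribution as (counts, bin_edges)).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    q = windows[windows["qualifying"]].copy()
    q = q.sort_values(["fraction", "n_informative", "scaffold", "start"],
                      ascending=[False, False, True, True],
                      kind="mergesort").reset_index(drop=True)
    counts, edges = np.histogram(q["fraction"].to_numpy(), bins=20, range=(0, 1))
    return q.head(top_k), (counts, edges)
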