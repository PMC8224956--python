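"""Variant-quality and marker-informativeness filters.

Two filter stages feed the two mapping arms:

* :func:`filter_founder_het` keeps the biallelic variants at which the
  founder is confidently heterozygous (allele balance 0.4-0.6 inclusive,
  DP >= 30, GQ >= 30) on scaffolds of usable length (>= 5 kb) — these are
  the haplotype-tracking markers for pooled homozygosity mapping.
* :func:`filter_association_markers` keeps genotyped markers informative
  for the kinship-corrected scan: minor allele frequency >= 5% and at
  least 10 individuals homozygous for each allele (the stricter reading
  of "fewer than 10 ... homozygous for both ... excluded"; both counts
  are configurable).

Allele balance is computed as alt/(ref+alt) from AD rather than alt/DP,
which is robust to clipped or third-allele reads.  MAF and homozygote
tallies use non-missing calls only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import MISSING, VariantTable

__all__ = ["FilterConfig", "filter_founder_het", "filter_association_markers",
           "mask_low_quality_calls"]


@dataclass
class FilterConfig:
    founder: str = "founder"
    ab_lo: float = 0.4
    ab_hi: float = 0.6
    min_dp: int = 30
    min_gq: int = 30
    min_scaffold_len: int = 5000
    min_maf: float = 0.05
    min_hom: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.ab_lo <= self.ab_hi <= 1:
            raise ValueError("allele-balance range must satisfy 0 <= lo <= hi <= 1")
        for name in ("min_dp", "min_gq", "min_scaffold_len", "min_hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


def filter_founder_het(
    vt: VariantTable,
    cfg: FilterConfig,
    scaffold_lengths: dict[str, int] | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Founder-heterozygosity filter; returns (survivors, removal report).

    A record survives iff it is biallelic, the founder call is het with
    allele balance alt/(ref+alt) within [ab_lo, ab_hi], founder DP and GQ
    meet their minima, and (when scaffold lengths are supplied) the
    scaffold is at least ``min_scaffold_len`` long.  Record order is
    preserved; the report lists one row per removed record with every
    reason it failed.
    """
    j = vt.sample_index(cfg.founder)
    gt = vt.gt[:, j]
    adr = vt.ad_ref[:, j].astype(float)
    ada = vt.ad_alt[:, j].astype(float)
    dp = vt.dp[:, j]
    gq = vt.gq[:, j]

    reasons: dict[str, np.ndarray] = {}
    reasons["multiallelic"] = vt.variants["multiallelic"].to_numpy(bool)
    reasons["founder_not_het"] = gt != 1
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.where((adr == MISSING) | (ada == MISSING), np.nan, adr + ada)
        balance = np.where(total > 0, ada / total, np.nan)
    reasons["allele_balance"] = ~((balance >= cfg.ab_lo) & (balance <= cfg.ab_hi))
    reasons["low_dp"] = (dp == MISSING) | (dp < cfg.min_dp)
    reasons["low_gq"] = (gq == MISSING) | (gq < cfg.min_gq)
    if scaffold_lengths is not None:
        lens = vt.variants["scaffold"].map(scaffold_lengths)
        reasons["short_scaffold"] = (lens.isna() | (lens < cfg.min_scaffold_len)).to_numpy()

    fail = np.zeros(vt.n_variants, bool)
    for m in reasons.values():
        fail |= m
    removed = np.flatnonzero(fail)
    report = pd.DataFrame({
        "scaffold": vt.variants["scaffold"].to_numpy()[removed],
        "pos": vt.variants["pos"].to_numpy()[removed],
        "reasons": [";".join(k for k, m in reasons.items() if m[i]) for i in removed],
    })
    return vt.subset(~fail), report


def mask_low_quality_calls(vt: VariantTable, cfg: FilterConfig) -> VariantTable:
    """Per-sample quality handling for association markers: calls failing
    DP or GQ minima are set to missing (record kept)."""
    bad = (vt.dp == MISSING) | (vt.dp < cfg.min_dp) | \
          (vt.gq == MISSING) | (vt.gq < cfg.min_gq)
    out = vt.subset(np.ones(vt.n_variants, bool))
    out.gt = np.where(bad, MISSING, out.gt).astype(np.int8)
    return out


def filter_association_markers(dosage: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Boolean marker mask for the association scan and kinship matrix.

    ``dosage`` is individuals x markers with NaN for missing calls.
    Retained markers have MAF >= ``min_maf`` and at least ``min_hom``
    hom-ref AND ``min_hom`` hom-alt individuals among non-missing calls.
    """
    dosage = np.asarray(dosage, float)
    if dosage.size == 0:
        raise ValueError("empty genotype matrix")
    with np.errstate(invalid="ignore"):
        called = ~np.isnan(dosage)
        n_called = called.sum(axis=0)
        mean = np.where(n_called > 0, np.nansum(dosage, axis=0), np.nan) / \
            np.where(n_called > 0, n_called, 1)
        p = mean / 2.0
        maf = np.minimum(p, 1 - p)
        hom_ref = np.nansum(dosage == 0, axis=0)
        hom_alt = np.nansum(dosage == 2, axis=0)
    return ((n_called > 0) & (maf >= cfg.min_maf)
            & (hom_ref >= cfg.min_hom) & (hom_alt >= cfg.min_hom))
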