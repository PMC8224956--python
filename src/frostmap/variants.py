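"""In-memory containers for genotype calls and pooled read counts.

``VariantTable`` is a column-oriented store for a multi-sample call set
(one row per variant, aligned numpy arrays per FORMAT field); missing
values are coded -1 throughout.  ``PoolCountsTable`` is a plain DataFrame
of per-pool ref/alt read counts keyed by (scaffold, pos, ref, alt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VariantTable", "POOL_NAMES", "MISSING"]

MISSING = -1

#: canonical pool labels: the founder genome, the heterozygote pool,
#: the homozygous-mutant pool, and the wild-type pool
POOL_NAMES = ("founder", "het", "hom", "wt")


@dataclass
class VariantTable:
    """Genotype calls for ``samples`` at the variants in ``variants``.

    variants: DataFrame with columns scaffold, pos (1-based), ref, alt,
        multiallelic (bool; alt holds a comma-joined list when True).
    gt: dosage of the (first) alt allele in {0, 1, 2}, -1 = missing.
    ad_ref / ad_alt / dp / gq: per-sample ints, -1 = missing.
    """

    variants: pd.DataFrame
    samples: list[str]
    gt: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        n, s = len(self.variants), len(self.samples)
        for name in ("gt", "ad_ref", "ad_alt", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n, s):
                raise ValueError(f"{name}: shape {arr.shape} != ({n}, {s})")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in VariantTable") from None

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[mask],
            ad_ref=self.ad_ref[mask],
            ad_alt=self.ad_alt[mask],
            dp=self.dp[mask],
            gq=self.gq[mask],
        )

    def dosage_matrix(self) -> np.ndarray:
        """individuals x markers dosage matrix, missing as NaN."""
        g = self.gt.T.astype(float)
        g[g == MISSING] = np.nan
        return g

    def keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(zip(v["scaffold"], v["pos"], v["ref"], v["alt"]))
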