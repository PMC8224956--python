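"""Reading and writing the pipeline's file formats.

VCF v4.2 is the exchange format for genotypes (FORMAT ``GT:AD:DP:GQ``)
and pooled read counts (one pseudo-sample per pool, FORMAT ``AD:DP``);
parsing goes through cyvcf2, writing is plain text.  Everything else is
tab-separated tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .variants import MISSING, VariantTable

__all__ = [
    "read_vcf", "write_vcf", "read_pool_vcf", "write_pool_vcf",
    "read_table", "write_table", "read_scaffold_lengths",
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_INT32_MISSING = -2147483648


def _fmt(v: int) -> str:
    return "." if v == MISSING else str(v)


def _header(scaffold_lengths: pd.DataFrame | None, samples: list[str],
            fmt_fields: list[str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=frostmap"]
    if scaffold_lengths is not None:
        for _, row in scaffold_lengths.iterrows():
            lines.append(f"##contig=<ID={row['scaffold']},length={row['length']}>")
    defs = {
        "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "AD": '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    }
    lines += [defs[f] for f in fmt_fields]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return lines


def write_vcf(vt: VariantTable, path, scaffold_lengths: pd.DataFrame | None = None) -> None:
    """Write a multi-sample call set as VCF v4.2 with FORMAT GT:AD:DP:GQ."""
    with open(path, "w") as fh:
        fh.write("\n".join(_header(scaffold_lengths, vt.samples,
                                   ["GT", "AD", "DP", "GQ"])) + "\n")
        v = vt.variants
        for i in range(vt.n_variants):
            # depths beyond the first alt are not tracked; pad AD with '.'
            extra = "," + ",".join("." * str(v.alt.iat[i]).count(",")) \
                if v.multiallelic.iat[i] else ""
            cells = []
            for j in range(len(vt.samples)):
                ad = ("."
                      if vt.ad_ref[i, j] == MISSING and vt.ad_alt[i, j] == MISSING
                      else f"{_fmt(vt.ad_ref[i, j])},{_fmt(vt.ad_alt[i, j])}{extra}")
                cells.append(f"{_GT_STR[int(vt.gt[i, j])]}:{ad}:"
                             f"{_fmt(vt.dp[i, j])}:{_fmt(vt.gq[i, j])}")
            fh.write(f"{v.scaffold.iat[i]}\t{v.pos.iat[i]}\t.\t{v.ref.iat[i]}\t"
                     f"{v.alt.iat[i]}\t.\tPASS\t.\tGT:AD:DP:GQ\t" + "\t".join(cells) + "\n")


def read_vcf(path) -> VariantTable:
    """Parse a VCF into a VariantTable.

    Multi-allelic records are preserved (alt alleles comma-joined, flagged)
    with allele depths taken for the first alt; missing fields stay missing.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has no samples")
    rows, gts, adr, ada, dps, gqs = [], [], [], [], [], []
    for rec in vcf:
        alts = rec.ALT
        if not alts:
            continue
        rows.append({"scaffold": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
                     "alt": ",".join(alts), "multiallelic": len(alts) > 1})
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        t = rec.gt_types
        gts.append(np.select([t == 0, t == 1, t == 3], [0, 1, 2], MISSING))
        ad = rec.format("AD")
        if ad is None:
            adr.append(np.full(len(samples), MISSING))
            ada.append(np.full(len(samples), MISSING))
        else:
            if ad.shape[1] != 1 + len(alts):
                raise ValueError(
                    f"{rec.CHROM}:{rec.POS}: AD arity {ad.shape[1]} inconsistent "
                    f"with {1 + len(alts)} alleles")
            adr.append(np.where(ad[:, 0] < 0, MISSING, ad[:, 0]))
            ada.append(np.where(ad[:, 1] < 0, MISSING, ad[:, 1]))
        dp = rec.format("DP")
        dps.append(np.full(len(samples), MISSING) if dp is None
                   else np.where(dp[:, 0] < 0, MISSING, dp[:, 0]))
        gq = rec.format("GQ")
        gqs.append(np.full(len(samples), MISSING) if gq is None
                   else np.where(gq[:, 0] < 0, MISSING, gq[:, 0]))
    meta = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "multiallelic"])
    stack = (lambda x: np.asarray(x, np.int64).reshape(len(meta), len(samples)))
    return VariantTable(meta, samples, stack(gts).astype(np.int8),
                        stack(adr).astype(np.int32), stack(ada).astype(np.int32),
                        stack(dps).astype(np.int32), stack(gqs).astype(np.int32))


def write_pool_vcf(pool_counts: pd.DataFrame, path,
                   scaffold_lengths: pd.DataFrame | None = None) -> None:
    """Write per-pool read counts as a VCF with one pseudo-sample per pool
    (FORMAT AD:DP; no genotypes are defined for pools)."""
    pools = sorted({c[:-4] for c in pool_counts.columns if c.endswith("_ref")})
    with open(path, "w") as fh:
        fh.write("\n".join(_header(scaffold_lengths, pools, ["AD", "DP"])) + "\n")
        cols = {p: (pool_counts[f"{p}_ref"].to_numpy(),
                    pool_counts[f"{p}_alt"].to_numpy()) for p in pools}
        scaf = pool_counts["scaffold"].to_numpy()
        pos = pool_counts["pos"].to_numpy()
        ref = pool_counts["ref"].to_numpy()
        alt = pool_counts["alt"].to_numpy()
        for i in range(len(pool_counts)):
            cells = [f"{cols[p][0][i]},{cols[p][1][i]}:{cols[p][0][i] + cols[p][1][i]}"
                     for p in pools]
            fh.write(f"{scaf[i]}\t{pos[i]}\t.\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\tAD:DP\t"
                     + "\t".join(cells) + "\n")


def read_pool_vcf(path) -> pd.DataFrame:
    """Parse a pools VCF back into a per-pool counts table."""
    vcf = VCF(str(path))
    pools = list(vcf.samples)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError("pools VCF must carry AD")
        row = {"scaffold": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
               "alt": ",".join(rec.ALT)}
        for j, p in enumerate(pools):
            r, a = int(ad[j, 0]), int(ad[j, 1])
            row[f"{p}_ref"] = max(r, 0) if r != _INT32_MISSING else 0
            row[f"{p}_alt"] = max(a, 0) if a != _INT32_MISSING else 0
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_scaffold_lengths(path) -> dict[str, int]:
    """Scaffold-length table (FASTA index style: name <tab> length [...])."""
    df = pd.read_csv(path, sep="\t")
    if "scaffold" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = ["scaffold", "length"] + [f"c{i}" for i in range(df.shape[1] - 2)]
    return dict(zip(df["scaffold"], df["length"].astype(int)))
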