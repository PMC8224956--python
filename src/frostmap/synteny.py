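"""Synteny-based marker ordering and linkage-disequilibrium decay.

A fragmented draft assembly gives no marker order beyond each scaffold.
Anchor tables mapping scaffold coordinates to a chromosome-scale
reference order the scaffolds: markers are projected onto reference
coordinates by linear interpolation between anchors (extrapolation past
the outermost anchors; a single anchor places the whole scaffold at one
point with unknown orientation; unanchored scaffolds stay unplaced).

Linkage disequilibrium is the squared Pearson correlation of genotype
dosages (composite LD; no phasing required).  The decay statistic is the
Spearman rank correlation between pairwise projected distance and r²,
with a Mantel-style permutation p-value (marker labels of the LD matrix
permuted, preserving the dependence structure among pairs); a negative
correlation with small p indicates decay of LD with synteny distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["project_markers", "ld_matrix", "ld_decay"]


def _project_scaffold(spos: np.ndarray, anchors: pd.DataFrame):
    a = anchors.sort_values("scaffold_pos")
    ax = a["scaffold_pos"].to_numpy(float)
    ay = a["ref_pos"].to_numpy(float)
    if len(a) == 1:
        return np.full(len(spos), ay[0]), "unknown"
    # piecewise-linear interpolation; linear extrapolation from end segments
    proj = np.interp(spos, ax, ay)
    lo = spos < ax[0]
    hi = spos > ax[-1]
    if lo.any():
        slope = (ay[1] - ay[0]) / (ax[1] - ax[0])
        proj[lo] = ay[0] + slope * (spos[lo] - ax[0])
    if hi.any():
        slope = (ay[-1] - ay[-2]) / (ax[-1] - ax[-2])
        proj[hi] = ay[-1] + slope * (spos[hi] - ax[-1])
    slope_all = ay[-1] - ay[0]
    orientation = "+" if slope_all > 0 else ("-" if slope_all < 0 else "unknown")
    return proj, orientation


def project_markers(markers: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    """Project markers (columns: scaffold, pos) onto reference coordinates.

    Returns the markers with added columns ref_chrom, ref_pos (float; NaN
    when unplaced), orientation and placed.  When a scaffold's anchors
    disagree on the reference chromosome, the majority chromosome is used
    and a warning issued.
    """
    out = markers.copy().reset_index(drop=True)
    out["ref_chrom"] = pd.NA
    out["ref_pos"] = np.nan
    out["orientation"] = "unknown"
    out["placed"] = False
    for scaf, grp in out.groupby("scaffold", sort=False):
        a = anchors[anchors["scaffold"] == scaf]
        if a.empty:
            continue
        chrom_counts = a["ref_chrom"].value_counts()
        if len(chrom_counts) > 1:
            warnings.warn(f"scaffold {scaf}: anchors map to multiple reference "
                          f"chromosomes; using majority {chrom_counts.idxmax()}")
        chrom = chrom_counts.idxmax()
        a = a[a["ref_chrom"] == chrom]
        proj, orient = _project_scaffold(grp["pos"].to_numpy(float), a)
        out.loc[grp.index, "ref_chrom"] = chrom
        out.loc[grp.index, "ref_pos"] = proj
        out.loc[grp.index, "orientation"] = orient
        out.loc[grp.index, "placed"] = True
    return out


def ld_matrix(dosage: np.ndarray, marker_index: np.ndarray | None = None) -> np.ndarray:
    """Pairwise r² between markers from dosage vectors.

    Pearson correlation over pairwise-complete observations, squared.
    Entries involving a marker monomorphic among the complete pairs are
    NaN; the diagonal is 1 for polymorphic markers.
    """
    g = np.asarray(dosage, float)
    if marker_index is not None:
        g = g[:, np.asarray(marker_index)]
    if g.shape[1] < 2:
        raise ValueError("need at least 2 markers for LD")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = pd.DataFrame(g).corr(min_periods=2).to_numpy()
    r2 = r ** 2
    # diagonal: 1 where polymorphic, NaN otherwise
    poly = np.nanstd(g, axis=0) > 0
    np.fill_diagonal(r2, np.where(poly, 1.0, np.nan))
    return r2


def ld_decay(
    r2: np.ndarray,
    positions: np.ndarray,
    n_permutations: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Spearman correlation of pairwise distance with r², plus a
    label-permutation (Mantel-style) one-sided p-value for decay.

    ``positions`` are projected reference coordinates (NaN = unplaced;
    those markers are dropped along with markers lacking finite r²).
    Returns dict(statistic, p_value, n_markers, n_pairs); statistic NaN
    with p 1.0 when r² is constant across pairs (no decay signal).
    """
    rng = rng or np.random.default_rng()
    r2 = np.asarray(r2, float)
    pos = np.asarray(positions, float)
    keep = np.isfinite(pos)
    off = ~np.eye(len(r2), dtype=bool)
    keep &= np.array([np.isfinite(r2[i][off[i]]).all() for i in range(len(r2))])
    r2 = r2[np.ix_(keep, keep)]
    pos = pos[keep]
    m = len(pos)
    iu = np.triu_indices(m, 1)
    if len(iu[0]) < 3:
        raise ValueError("need at least 3 placed marker pairs")
    dist = np.abs(pos[iu[0]] - pos[iu[1]])
    vals = r2[iu]
    ok = np.isfinite(vals)
    dist, iu0, iu1, vals = dist[ok], iu[0][ok], iu[1][ok], vals[ok]
    if np.ptp(dist) == 0:
        raise ValueError("all pairwise distances are equal")
    if np.ptp(vals) == 0:
        return {"statistic": np.nan, "p_value": 1.0, "n_markers": m,
                "n_pairs": len(vals), "note": "r2 constant; no decay signal"}
    obs = stats.spearmanr(dist, vals).statistic
    # vectorised Mantel permutations: rank once, correlate rank vectors
    dr = stats.rankdata(dist)
    dr = (dr - dr.mean()) / dr.std()
    perms = np.array([rng.permutation(m) for _ in range(n_permutations)])
    pv = r2[perms[:, iu0], perms[:, iu1]]
    pr = stats.rankdata(pv, axis=1).astype(float)
    pr -= pr.mean(axis=1, keepdims=True)
    sd = pr.std(axis=1)
    rhos = np.where(sd > 0, (pr @ dr) / (len(dr) * np.where(sd > 0, sd, 1.0)), 0.0)
    p = (int(np.sum(rhos <= obs)) + 1) / (n_permutations + 1)
    return {"statistic": float(obs), "p_value": float(p),
            "n_markers": m, "n_pairs": int(len(vals))}
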