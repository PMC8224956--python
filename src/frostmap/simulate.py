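"""Synthetic breeding-colony generator with ground truth.

Emulates the study design behind founder-aware mapping of a spontaneous
semidominant mutation: a heterozygous founder outcrossed to unrelated
dams, carrier F1 intercrossed and backcrossed, a RAD-seq-like genotyping
panel over the colony, and three DNA pools (homozygous mutant /
heterozygote / wild type) plus the founder sequenced as whole genomes.

The genetic model
-----------------
Founder-pool haplotypes carry three classes of background variation:

* *common* variants segregating at Beta-distributed frequencies across all
  founder haplotypes;
* *lineage* variants private to the mutation-bearing founder haplotype
  (the founder comes from a line diverged from both the reference assembly
  and the dam stock, so the haplotype that carries the de novo mutation is
  tagged by a dense set of private markers — the situation that makes
  pooled homozygosity mapping informative);
* *private* variants carried by exactly one haplotype, at a low
  per-haplotype rate.

Meiosis is a no-interference (Poisson) crossover process, uniform along
the genetic map.  Gene dropping is conditioned on the causal transmissions
recorded in the pedigree, so simulated haplotypes and pedigree dosages
agree exactly.

Read-level models: per-site sequencing depth is Poisson with an optional
Gamma-distributed per-site accessibility factor *shared across libraries*
(depth at a site is correlated between pools in real data via
mappability); reads report the wrong allele with a fixed error rate;
genotypes are called by maximum likelihood over {hom-ref, het, hom-alt}
with GQ the phred-scaled gap between the best and second-best genotype
log10-likelihoods, capped at 99.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .genome import GenomeMap, random_genome
from .pedigree import CrossDesign, Individual, PedigreeGraph, build_pedigree
from .variants import MISSING, POOL_NAMES, VariantTable

__all__ = [
    "VariantModel", "RadModel", "PoolModel", "ColonyConfig", "ColonyData",
    "TruthSet", "simulate_colony", "drop_genomes", "sample_radseq_calls",
    "sample_pool_counts", "emit_truth", "call_genotypes",
]

_LOG10_HALF = np.log10(0.5)
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class VariantModel:
    """Densities (variants per bp) of founder-pool background variation."""
    common_density: float = 1 / 400
    common_freq_beta: tuple[float, float] = (0.5, 2.0)
    lineage_density: float = 1 / 200
    private_density: float = 1 / 5000


@dataclass
class RadModel:
    """Reduced-representation genotyping panel over the colony."""
    site_density: float = 1 / 6500
    common_fraction: float = 0.8        # rest are private to one haplotype
    freq_range: tuple[float, float] = (0.1, 0.9)
    mean_depth: float = 60.0            # per-locus depth of RAD loci
    depth_shape: float | None = None    # Gamma shape of per-site depth factor
    error_rate: float = 0.005
    include_causal: bool = True         # causal site is part of the panel


@dataclass
class PoolModel:
    """Pooled whole-genome sequencing of hom / het / wt pools + founder."""
    size_hom: int = 25
    size_het: int = 63
    size_wt: int = 71
    coverage: float = 30.0
    error_rate: float = 0.002
    depth_shape: float | None = 6.0     # shared per-site accessibility factor


@dataclass
class ColonyConfig:
    """Full scenario: genome, colony design, variation, and sequencing."""
    seed: int = 1
    # genome
    n_chromosomes: int = 5
    chrom_length: int = 4_000_000
    morgans_per_chrom: float = 1.25
    scaffolds_per_chrom: int = 40
    min_scaffold_len: int = 5000
    causal_chrom_index: int = 0
    causal_fraction: float = 0.5
    # colony
    design: CrossDesign = field(default_factory=CrossDesign)
    variants: VariantModel = field(default_factory=VariantModel)
    rad: RadModel = field(default_factory=RadModel)
    pools: PoolModel = field(default_factory=PoolModel)
    # genotyped subset: counts per phenotype class (wt, het, hom)
    rad_class_counts: tuple[int, int, int] = (39, 116, 33)
    phenotype_misclassification: float = 0.0
    anchor_fraction: float = 0.7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ColonyConfig":
        d = dict(d)
        for key, sub in (("design", CrossDesign), ("variants", VariantModel),
                         ("rad", RadModel), ("pools", PoolModel)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("rad_class_counts",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for sub, keys in (("variants", ("common_freq_beta",)), ("rad", ("freq_range",))):
            obj = d.get(sub)
            if obj is not None:
                for k in keys:
                    v = getattr(obj, k)
                    if isinstance(v, list):
                        setattr(obj, k, tuple(v))
        return cls(**d)


# ---------------------------------------------------------------------------
# founder-pool haplotype variation
# ---------------------------------------------------------------------------

@dataclass
class ChromVariants:
    """Variant sites on one chromosome with founder-pool haplotype alleles."""
    chrom: str
    positions: np.ndarray   # 0-based chromosome coords, sorted
    haps: np.ndarray        # (n_hap, n_var) int8 alt-allele indicators
    ref: np.ndarray
    alt: np.ndarray
    causal_index: int       # -1 if the causal site is not on this chromosome


def _draw_bases(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    r = rng.integers(0, 4, n)
    a = (r + rng.integers(1, 4, n)) % 4
    return _BASES[r], _BASES[a]


def synthesize_background(
    rng: np.random.Generator, gmap: GenomeMap, model: VariantModel, n_haps: int
) -> dict[str, ChromVariants]:
    """Draw WGS-scale background variation for the founder haplotype pool.

    Haplotype 0 is the mutation-bearing founder haplotype; the causal
    variant itself is inserted at the causal locus, private to it.
    """
    out = {}
    for c in gmap.chromosomes:
        L = c.length_bp
        n_common = rng.poisson(model.common_density * L)
        n_lineage = rng.poisson(model.lineage_density * L)
        n_private = rng.poisson(model.private_density * L, size=n_haps)
        pos_c = rng.integers(0, L, n_common)
        pos_l = rng.integers(0, L, n_lineage)
        pos_p = [rng.integers(0, L, k) for k in n_private]
        freqs = rng.beta(*model.common_freq_beta, n_common)

        pos_all = np.concatenate([pos_c, pos_l, *pos_p])
        kind = np.concatenate(
            [np.zeros(n_common, np.int32) - 1,            # common: -1
             np.full(n_lineage, 0, np.int32),             # lineage: hap 0
             *[np.full(k, h, np.int32) for h, k in enumerate(n_private)]]
        )
        fidx = np.concatenate(
            [np.arange(n_common), np.full(len(pos_all) - n_common, -1)]
        )
        is_causal = np.zeros(len(pos_all), bool)
        if c.name == gmap.causal_chrom:
            keep = pos_all != gmap.causal_pos
            pos_all, kind, fidx, is_causal = (
                pos_all[keep], kind[keep], fidx[keep], is_causal[keep])
            pos_all = np.append(pos_all, gmap.causal_pos)
            kind = np.append(kind, 0)
            fidx = np.append(fidx, -1)
            is_causal = np.append(is_causal, True)

        order = np.argsort(pos_all, kind="stable")
        pos_all, kind, fidx, is_causal = (
            pos_all[order], kind[order], fidx[order], is_causal[order])
        # drop position collisions (keep causal site preferentially)
        dup = np.zeros(len(pos_all), bool)
        dup[1:] = pos_all[1:] == pos_all[:-1]
        if is_causal.any():
            ci = int(np.flatnonzero(is_causal)[0])
            if dup[ci]:
                dup[ci] = False
                dup[ci - 1] = True
        keep = ~dup
        pos_all, kind, fidx, is_causal = (
            pos_all[keep], kind[keep], fidx[keep], is_causal[keep])

        n = len(pos_all)
        H = np.zeros((n_haps, n), np.int8)
        common = kind == -1
        if common.any():
            f = freqs[fidx[common]]
            H[:, common] = (rng.random((n_haps, int(common.sum()))) < f).astype(np.int8)
        priv = ~common
        H[kind[priv], np.flatnonzero(priv)] = 1
        ref, alt = _draw_bases(rng, n)
        causal_index = int(np.flatnonzero(is_causal)[0]) if is_causal.any() else -1
        out[c.name] = ChromVariants(c.name, pos_all.astype(np.int64), H,
                                    ref, alt, causal_index)
    return out


def synthesize_rad_sites(
    rng: np.random.Generator, gmap: GenomeMap, model: RadModel, n_haps: int
) -> dict[str, ChromVariants]:
    """Draw the RAD marker panel: mostly common SNPs, some haplotype-private."""
    out = {}
    for c in gmap.chromosomes:
        L = c.length_bp
        n = rng.poisson(model.site_density * L)
        pos = rng.integers(0, L, n)
        common = rng.random(n) < model.common_fraction
        f = rng.uniform(*model.freq_range, n)
        hap_of = rng.integers(0, n_haps, n)
        if c.name == gmap.causal_chrom and model.include_causal:
            pos = np.append(pos, gmap.causal_pos)
            common = np.append(common, False)
            f = np.append(f, 0.0)
            hap_of = np.append(hap_of, 0)
        order = np.argsort(pos, kind="stable")
        pos, common, f, hap_of = pos[order], common[order], f[order], hap_of[order]
        causal = (pos == gmap.causal_pos) & (~common) & (hap_of == 0) \
            if (c.name == gmap.causal_chrom and model.include_causal) \
            else np.zeros(len(pos), bool)
        dup = np.zeros(len(pos), bool)
        dup[1:] = pos[1:] == pos[:-1]
        if causal.any():
            ci = int(np.flatnonzero(causal)[0])
            if dup[ci]:
                dup[ci], dup[ci - 1] = False, True
        keep = ~dup
        pos, common, f, hap_of, causal = (
            pos[keep], common[keep], f[keep], hap_of[keep], causal[keep])
        n = len(pos)
        H = np.zeros((n_haps, n), np.int8)
        ci = np.flatnonzero(common)
        H[:, ci] = (rng.random((n_haps, len(ci))) < f[ci]).astype(np.int8)
        pi = np.flatnonzero(~common)
        H[hap_of[pi], pi] = 1
        ref, alt = _draw_bases(rng, n)
        causal_index = int(np.flatnonzero(causal)[0]) if causal.any() else -1
        out[c.name] = ChromVariants(c.name, pos.astype(np.int64), H,
                                    ref, alt, causal_index)
    return out


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

# a haplotype mosaic on one chromosome: (segment end positions, source hap ids)
Mosaic = tuple[np.ndarray, np.ndarray]


def _single_segment(L: int, src: int) -> Mosaic:
    return np.array([L], np.int64), np.array([src], np.int64)


def _src_at(mosaic: Mosaic, pos: int) -> int:
    breaks, srcs = mosaic
    return int(srcs[int(np.searchsorted(breaks, pos, side="right"))])


def _compose(pair: tuple[Mosaic, Mosaic], xos: np.ndarray, phase0: int, L: int) -> Mosaic:
    """Gamete mosaic: alternate between the two parental mosaics at crossovers."""
    breaks: list[int] = []
    srcs: list[int] = []
    prev = 0
    ph = phase0
    for cut in list(xos) + [L]:
        if cut > prev:
            b, s = pair[ph]
            i0 = int(np.searchsorted(b, prev, side="right"))
            i1 = int(np.searchsorted(b, cut - 1, side="right"))
            for i in range(i0, i1 + 1):
                end = min(int(b[i]), cut)
                if srcs and srcs[-1] == int(s[i]):
                    breaks[-1] = end
                else:
                    breaks.append(end)
                    srcs.append(int(s[i]))
            prev = cut
        ph ^= 1
    return np.array(breaks, np.int64), np.array(srcs, np.int64)


def _gamete_mosaic(
    rng: np.random.Generator,
    pair: tuple[Mosaic, Mosaic],
    L: int,
    morgans: float,
    causal_pos: int | None,
    need: int | None,
    causal_src: int,
) -> Mosaic:
    """One meiosis.  When ``need`` is given, the gamete is conditioned to
    carry (1) or not carry (0) the causal allele: crossovers are drawn
    unconditionally and the starting phase is chosen to match, which is the
    exact conditional distribution given the transmitted causal allele."""
    if morgans < 0:
        raise ValueError("genetic length must be >= 0")
    k = int(rng.poisson(morgans))
    xos = np.sort(rng.integers(1, L, k)) if k else np.empty(0, np.int64)
    if causal_pos is None or need is None:
        phase0 = int(rng.integers(2))
    else:
        a = [1 if _src_at(m, causal_pos) == causal_src else 0 for m in pair]
        if a[0] == a[1]:
            if a[0] != need:
                raise ValueError("pedigree causal dosage inconsistent with haplotypes")
            phase0 = int(rng.integers(2))
        else:
            parity = int(np.searchsorted(xos, causal_pos, side="right")) % 2
            h_needed = a.index(need)
            phase0 = (h_needed - parity) % 2
    return _compose(pair, xos, phase0, L)


def drop_genomes(
    pedigree: PedigreeGraph,
    gmap: GenomeMap,
    hap_assignment: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> dict[str, dict[str, tuple[Mosaic, Mosaic]]]:
    """Gene-drop founder haplotypes through the pedigree.

    ``hap_assignment`` maps each pedigree founder to its two founder-pool
    haplotype ids (the mutation carrier must hold haplotype 0, which
    carries the causal allele).  Returns per individual, per chromosome,
    the (paternal, maternal) haplotype mosaics.  Transmission of the
    causal allele is conditioned on the pedigree's recorded gametes.
    """
    if not hap_assignment:
        raise ValueError("no founder haplotypes assigned")
    mosaics: dict[str, dict[str, tuple[Mosaic, Mosaic]]] = {}
    for ind in pedigree.founders():
        h = hap_assignment[ind.id]
        if len(set(h)) != 2:
            raise ValueError(f"{ind.id}: needs two distinct founder haplotypes")
        mosaics[ind.id] = {
            c.name: (_single_segment(c.length_bp, h[0]),
                     _single_segment(c.length_bp, h[1]))
            for c in gmap.chromosomes
        }
    founder = pedigree.individuals[pedigree.founder_id]
    if _src_at(mosaics[founder.id][gmap.causal_chrom][0], gmap.causal_pos) != 0:
        raise ValueError("mutation carrier must hold founder haplotype 0")

    for ind in sorted(pedigree.non_founders(), key=lambda i: (i.generation, i.id)):
        per_chrom = {}
        for c in gmap.chromosomes:
            on_causal = c.name == gmap.causal_chrom
            pat = _gamete_mosaic(
                rng, mosaics[ind.sire][c.name], c.length_bp, c.length_morgans,
                gmap.causal_pos if on_causal else None,
                ind.pat_allele if on_causal else None, 0)
            mat = _gamete_mosaic(
                rng, mosaics[ind.dam][c.name], c.length_bp, c.length_morgans,
                gmap.causal_pos if on_causal else None,
                ind.mat_allele if on_causal else None, 0)
            per_chrom[c.name] = (pat, mat)
        mosaics[ind.id] = per_chrom
    return mosaics


def _mosaic_alleles(mosaic: Mosaic, positions: np.ndarray, H: np.ndarray) -> np.ndarray:
    breaks, srcs = mosaic
    out = np.empty(len(positions), np.int8)
    idx = np.searchsorted(positions, breaks, side="left")
    start = 0
    for end, src in zip(idx, srcs):
        if end > start:
            out[start:end] = H[src, start:end]
        start = end
    return out


def genotypes_at(
    ids: list[str],
    mosaics: dict[str, dict[str, tuple[Mosaic, Mosaic]]],
    variants: dict[str, ChromVariants],
    chrom_order: list[str],
) -> np.ndarray:
    """(n_individuals, n_variants) alt-allele dosages from haplotype mosaics."""
    cols = []
    for cname in chrom_order:
        cv = variants[cname]
        block = np.empty((len(ids), len(cv.positions)), np.int8)
        for i, iid in enumerate(ids):
            pat, mat = mosaics[iid][cname]
            block[i] = (_mosaic_alleles(pat, cv.positions, cv.haps)
                        + _mosaic_alleles(mat, cv.positions, cv.haps))
        cols.append(block)
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# sequencing models
# ---------------------------------------------------------------------------

def _depths(rng, mean, shape, size):
    if np.any(np.asarray(mean) < 0):
        raise ValueError("depth must be >= 0")
    lam = np.broadcast_to(np.asarray(mean, float), size).copy()
    if shape is not None:
        if shape <= 0:
            raise ValueError("depth dispersion shape must be > 0")
        lam *= rng.gamma(shape, 1.0 / shape, size)
    return rng.poisson(lam)


def call_genotypes(alt: np.ndarray, ref: np.ndarray, error_rate: float):
    """Maximum-likelihood genotype call from allele read counts.

    Returns (gt, gq): dosage in {0,1,2} (-1 where total depth is 0) and the
    phred-scaled log10-likelihood gap to the runner-up genotype, capped at 99.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    a, r = alt.astype(float), ref.astype(float)
    ln10 = np.log(10.0)
    le = xlogy(1.0, error_rate) / ln10 if error_rate > 0 else -np.inf
    l1e = np.log10(1.0 - error_rate)
    with np.errstate(invalid="ignore"):
        l_rr = np.where(a > 0, a * le, 0.0) + r * l1e
        l_het = (a + r) * _LOG10_HALF
        l_aa = np.where(r > 0, r * le, 0.0) + a * l1e
    liks = np.stack([l_rr, l_het, l_aa], axis=-1)
    order = np.argsort(liks, axis=-1)
    gt = order[..., -1].astype(np.int8)
    best = np.take_along_axis(liks, order[..., -1:], -1)[..., 0]
    second = np.take_along_axis(liks, order[..., -2:-1], -1)[..., 0]
    gap = best - second
    gq = np.where(np.isfinite(gap), np.minimum(np.rint(10 * gap), 99), 99).astype(np.int32)
    depth0 = (a + r) == 0
    gt = np.where(depth0, MISSING, gt).astype(np.int8)
    gq = np.where(depth0, MISSING, gq)
    return gt, gq


def sample_radseq_calls(
    genotypes: np.ndarray,
    rng: np.random.Generator,
    mean_depth: float = 60.0,
    error_rate: float = 0.005,
    depth_shape: float | None = None,
):
    """Simulate genotype calls from true dosages (individuals x sites).

    Depth is Poisson per site/sample (optionally Gamma-overdispersed); each
    read reports the wrong allele with ``error_rate``.  Returns arrays
    (gt, ad_ref, ad_alt, dp, gq) of the same shape as ``genotypes``.
    """
    if mean_depth < 0:
        raise ValueError("mean depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    g = np.asarray(genotypes)
    dp = _depths(rng, mean_depth, depth_shape, g.shape)
    p_alt = np.select([g == 0, g == 1, g == 2],
                      [error_rate, 0.5, 1.0 - error_rate])
    ad_alt = rng.binomial(dp, p_alt)
    ad_ref = dp - ad_alt
    gt, gq = call_genotypes(ad_alt, ad_ref, error_rate)
    return gt, ad_ref.astype(np.int32), ad_alt.astype(np.int32), dp.astype(np.int32), gq


def sample_pool_counts(
    genotypes: np.ndarray,
    pool_assignment: dict[str, np.ndarray],
    rng: np.random.Generator,
    coverage: float = 30.0,
    error_rate: float = 0.002,
    site_factor: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pooled read counts per variant for each pool.

    ``genotypes`` is (individuals x variants) dosage; ``pool_assignment``
    maps pool name -> row indices of its members.  The true pool allele
    frequency is (alt copies)/(2 x pool size); read depth is Poisson
    (``coverage`` scaled by the shared per-site ``site_factor`` when
    given) and alt reads are Binomial with the error-adjusted frequency.
    Returns pool name -> (ref counts, alt counts).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    n_var = genotypes.shape[1]
    lam = np.full(n_var, float(coverage))
    if site_factor is not None:
        lam = lam * site_factor
    out = {}
    for pool, idx in pool_assignment.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"pool {pool!r} is empty")
        freq = genotypes[idx].sum(axis=0) / (2.0 * idx.size)
        p = freq * (1 - error_rate) + (1 - freq) * error_rate
        depth = rng.poisson(lam)
        alt = rng.binomial(depth, p)
        out[pool] = ((depth - alt).astype(np.int32), alt.astype(np.int32))
    return out


def true_pool_frequency(genotypes: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Exact pool allele frequency before read sampling."""
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("pool is empty")
    return genotypes[idx].sum(axis=0) / (2.0 * idx.size)


# ---------------------------------------------------------------------------
# truth and anchors
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth for recovery tests."""
    causal_scaffold: str
    causal_scaffold_pos: int  # 1-based
    causal_chrom: str
    causal_chrom_pos: int     # 0-based
    dosages: pd.Series        # individual -> true causal dosage
    pool_ids: dict[str, list[str]]
    rad_ids: list[str]
    mosaics: dict = field(repr=False, default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for pool, ids in self.pool_ids.items():
            if seen & set(ids):
                raise ValueError(f"pool {pool} overlaps another pool")
            seen |= set(ids)

    def individuals_frame(self) -> pd.DataFrame:
        pool_of = {i: p for p, ids in self.pool_ids.items() for i in ids}
        return pd.DataFrame({
            "id": self.dosages.index,
            "causal_dosage": self.dosages.values,
            "pool": [pool_of.get(i, "") for i in self.dosages.index],
            "rad": [i in set(self.rad_ids) for i in self.dosages.index],
        })


def emit_truth(
    gmap: GenomeMap,
    pedigree: PedigreeGraph,
    mosaics: dict,
    pool_ids: dict[str, list[str]],
    rad_ids: list[str],
    rng: np.random.Generator,
    anchor_fraction: float = 0.7,
) -> tuple[TruthSet, pd.DataFrame]:
    """Package ground truth and emit synteny anchors for a random subset of
    scaffolds (two anchors per anchored scaffold, at ~10% and ~90% of its
    length, mapping scaffold coordinates to source-chromosome coordinates)."""
    if not 0 <= anchor_fraction <= 1:
        raise ValueError("anchor fraction must be in [0, 1]")
    scaf, spos = gmap.causal_scaffold
    dosages = pd.Series(
        {i.id: i.causal_dosage for i in pedigree.individuals.values()}, name="dosage")
    truth = TruthSet(scaf, spos, gmap.causal_chrom, gmap.causal_pos,
                     dosages, pool_ids, rad_ids, mosaics)
    truth.validate()
    rows = []
    for s in gmap.scaffolds:
        if rng.random() >= anchor_fraction:
            continue
        pts = sorted({max(1, round(0.1 * s.length)), min(s.length, round(0.9 * s.length))})
        for p in pts:
            rows.append({
                "scaffold": s.name,
                "scaffold_pos": p,
                "ref_chrom": s.chrom,
                "ref_pos": s.to_chrom_pos(p) + 1,
                "orientation": s.orientation,
            })
    anchors = pd.DataFrame(rows, columns=["scaffold", "scaffold_pos", "ref_chrom",
                                          "ref_pos", "orientation"])
    return truth, anchors


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ColonyData:
    """Everything one simulated study produces."""
    config: ColonyConfig
    gmap: GenomeMap
    pedigree: PedigreeGraph
    truth: TruthSet
    anchors: pd.DataFrame
    phenotypes: pd.DataFrame      # id, sire, dam, sex, generation, phenotype
    rad: VariantTable             # genotyped individuals
    founder_wgs: VariantTable     # single-sample founder calls at WGS sites
    pool_counts: pd.DataFrame     # per-pool ref/alt read counts at WGS sites

    @property
    def scaffold_lengths(self) -> pd.DataFrame:
        return self.gmap.scaffold_lengths()


def _scaffold_meta(gmap: GenomeMap, variants: dict[str, ChromVariants],
                   chrom_order: list[str]):
    """Chromosome-order variant meta mapped to (scaffold, pos); returns the
    meta frame and the permutation that sorts it by (scaffold, pos)."""
    frames = []
    for cname in chrom_order:
        cv = variants[cname]
        scafs = sorted((s for s in gmap.scaffolds if s.chrom == cname),
                       key=lambda s: s.start)
        ends = np.array([s.end for s in scafs])
        si = np.searchsorted(ends, cv.positions, side="right")
        names = np.array([s.name for s in scafs], dtype=object)[si]
        starts = np.array([s.start for s in scafs])[si]
        send = ends[si]
        fwd = np.array([s.orientation == "+" for s in scafs])[si]
        spos = np.where(fwd, cv.positions - starts + 1, send - cv.positions)
        frames.append(pd.DataFrame({
            "scaffold": names, "pos": spos.astype(np.int64),
            "ref": cv.ref, "alt": cv.alt, "multiallelic": False,
        }))
    meta = pd.concat(frames, ignore_index=True)
    order = meta.sort_values(["scaffold", "pos"], kind="mergesort").index.to_numpy()
    return meta.iloc[order].reset_index(drop=True), order


def _sample_classes(rng, by_class: dict[int, list[str]], counts: dict[int, int],
                    what: str) -> list[str]:
    chosen = []
    for dosage, n in counts.items():
        pool = by_class.get(dosage, [])
        if len(pool) < n:
            raise ValueError(
                f"{what}: need {n} individuals with dosage {dosage}, have {len(pool)}")
        chosen.extend(rng.choice(pool, size=n, replace=False).tolist())
    return chosen


def simulate_colony(config: ColonyConfig | None = None) -> ColonyData:
    """Run the full generator for one seeded scenario."""
    cfg = config or ColonyConfig()
    ss = np.random.SeedSequence(cfg.seed)
    (s_gen, s_ped, s_bg, s_drop, s_rad_sites, s_rad_seq,
     s_pool, s_assign, s_anchor, s_pheno) = [np.random.default_rng(s)
                                             for s in ss.spawn(10)]

    gmap = random_genome(
        s_gen, cfg.n_chromosomes, cfg.chrom_length, cfg.morgans_per_chrom,
        cfg.scaffolds_per_chrom, cfg.causal_chrom_index, cfg.causal_fraction,
        cfg.min_scaffold_len)
    chrom_order = [c.name for c in gmap.chromosomes]

    pedigree = build_pedigree(cfg.design, s_ped)
    n_haps = 2 + 2 * cfg.design.n_dams
    hap_assignment = {pedigree.founder_id: (0, 1)}
    for j, ind in enumerate(sorted(
            (i for i in pedigree.founders() if i.id != pedigree.founder_id),
            key=lambda i: i.id)):
        hap_assignment[ind.id] = (2 + 2 * j, 3 + 2 * j)

    background = synthesize_background(s_bg, gmap, cfg.variants, n_haps)
    mosaics = drop_genomes(pedigree, gmap, hap_assignment, s_drop)

    # genotyped subset and pools, drawn per phenotype class
    offspring = pedigree.non_founders()
    by_class: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for i in sorted(offspring, key=lambda i: i.id):
        by_class[i.causal_dosage].append(i.id)
    wt_n, het_n, hom_n = cfg.rad_class_counts
    rad_ids = _sample_classes(s_assign, by_class,
                              {0: wt_n, 1: het_n, 2: hom_n}, "RAD panel")
    pm = cfg.pools
    pool_ids = {
        "hom": _sample_classes(s_assign, {2: by_class[2]}, {2: pm.size_hom}, "hom pool"),
        "het": _sample_classes(s_assign, {1: by_class[1]}, {1: pm.size_het}, "het pool"),
        "wt": _sample_classes(s_assign, {0: by_class[0]}, {0: pm.size_wt}, "wt pool"),
    }

    # RAD genotyping
    rad_sites = synthesize_rad_sites(s_rad_sites, gmap, cfg.rad, n_haps)
    g_rad = genotypes_at(rad_ids, mosaics, rad_sites, chrom_order)
    gt, ad_ref, ad_alt, dp, gq = sample_radseq_calls(
        g_rad, s_rad_seq, cfg.rad.mean_depth, cfg.rad.error_rate, cfg.rad.depth_shape)
    rad_meta, rad_order = _scaffold_meta(gmap, rad_sites, chrom_order)
    rad = VariantTable(rad_meta, list(rad_ids), gt.T[rad_order],
                       ad_ref.T[rad_order], ad_alt.T[rad_order],
                       dp.T[rad_order], gq.T[rad_order])

    # founder WGS + pooled WGS at the background sites
    wgs_meta, wgs_order = _scaffold_meta(gmap, background, chrom_order)
    n_wgs = len(wgs_meta)
    site_factor = (s_pool.gamma(pm.depth_shape, 1.0 / pm.depth_shape, n_wgs)
                   if pm.depth_shape else None)
    founder_dosage = np.concatenate(
        [background[c].haps[0] + background[c].haps[1] for c in chrom_order]
    ).astype(np.int8)[None, :]
    f_lam = pm.coverage * (site_factor if site_factor is not None else 1.0)
    f_dp = s_pool.poisson(np.broadcast_to(f_lam, (1, n_wgs)))
    p_alt = np.select([founder_dosage == 0, founder_dosage == 1, founder_dosage == 2],
                      [pm.error_rate, 0.5, 1.0 - pm.error_rate])
    f_alt = s_pool.binomial(f_dp, p_alt)
    f_ref = f_dp - f_alt
    f_gt, f_gq = call_genotypes(f_alt, f_ref, pm.error_rate)
    founder_wgs = VariantTable(
        wgs_meta, ["founder"], f_gt.T[wgs_order],
        f_ref.T[wgs_order].astype(np.int32), f_alt.T[wgs_order].astype(np.int32),
        f_dp.T[wgs_order].astype(np.int32), f_gq.T[wgs_order])

    member_ids = sorted(set(pool_ids["hom"]) | set(pool_ids["het"]) | set(pool_ids["wt"]))
    g_pool = genotypes_at(member_ids, mosaics, background, chrom_order)
    row_of = {iid: i for i, iid in enumerate(member_ids)}
    assignment = {p: np.array([row_of[i] for i in ids])
                  for p, ids in pool_ids.items()}
    counts = sample_pool_counts(g_pool, assignment, s_pool, pm.coverage,
                                pm.error_rate, site_factor)
    pool_counts = wgs_meta.drop(columns="multiallelic").copy()
    pool_counts["founder_ref"] = f_ref[0][wgs_order]
    pool_counts["founder_alt"] = f_alt[0][wgs_order]
    for p in ("het", "hom", "wt"):
        pool_counts[f"{p}_ref"] = counts[p][0][wgs_order]
        pool_counts[f"{p}_alt"] = counts[p][1][wgs_order]

    truth, anchors = emit_truth(gmap, pedigree, mosaics, pool_ids, rad_ids,
                                s_anchor, cfg.anchor_fraction)

    phen = pedigree.to_frame()
    pheno_codes = phen["dosage"].to_numpy().copy()
    r = cfg.phenotype_misclassification
    if r > 0:
        flip = s_pheno.random(len(pheno_codes)) < r
        shift = s_pheno.integers(1, 3, len(pheno_codes))
        pheno_codes[flip] = (pheno_codes[flip] + shift[flip]) % 3
    phen = phen.drop(columns="dosage")
    phen["phenotype"] = pheno_codes
    return ColonyData(cfg, gmap, pedigree, truth, anchors, phen, rad,
                      founder_wgs, pool_counts)
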