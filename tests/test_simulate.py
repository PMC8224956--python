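import numpy as np
import pandas as pd
import pytest

import frostmap as fm
from frostmap.genome import Chromosome, GenomeMap, Scaffold
from frostmap.pedigree import CrossDesign, build_pedigree
from frostmap.simulate import (_gamete_mosaic, _single_segment, _src_at,
                               call_genotypes, drop_genomes, emit_truth,
                               genotypes_at, sample_pool_counts,
                               sample_radseq_calls, simulate_colony,
                               true_pool_frequency)

from conftest import small_run_config


def _flat_genome(n_chrom=2, length=100_000, morgans=1.0, causal=50_000):
    chroms = [Chromosome(f"chr{i+1}", length, morgans) for i in range(n_chrom)]
    scafs = [Scaffold(f"s{i+1}", c.name, 0, length) for i, c in enumerate(chroms)]
    return GenomeMap(chroms, scafs, "chr1", causal, min_scaffold_len=1)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def test_zero_genetic_length_transmits_intact_haplotypes():
    gmap = _flat_genome(morgans=0.0)
    ped = build_pedigree(CrossDesign(n_dams=2, f1_per_dam=6, n_intercross=1,
                                     f2_per_cross=6, n_backcross=1, bc_per_cross=4),
                         np.random.default_rng(0))
    haps = {"founder": (0, 1), "dam01": (2, 3), "dam02": (4, 5)}
    mos = drop_genomes(ped, gmap, haps, np.random.default_rng(1))
    for ind in ped.non_founders():
        for chrom in ("chr1", "chr2"):
            for m in mos[ind.id][chrom]:
                assert len(m[1]) == 1  # a single intact parental haplotype


def test_crossover_count_matches_poisson_mean():
    """1 Morgan map, 10,000 meioses: mean crossovers per gamete ~ 1.0."""
    rng = np.random.default_rng(5)
    L = 1_000_000
    pair = (_single_segment(L, 0), _single_segment(L, 1))
    n = 10_000
    switches = [len(_gamete_mosaic(rng, pair, L, 1.0, None, None, 0)[1]) - 1
                for _ in range(n)]
    mean = np.mean(switches)
    se = np.sqrt(1.0 / n)  # Poisson variance 1 at rate 1
    assert abs(mean - 1.0) <= 3 * se


def test_mendelian_consistency_and_causal_transmission(small_colony):
    """Every transmitted allele traces to one parental haplotype, and the
    causal dosage implied by the mosaics equals the pedigree dosage."""
    data = small_colony
    ped, gmap, mos = data.pedigree, data.gmap, data.truth.mosaics
    probe = np.linspace(0, gmap.chromosomes[0].length_bp - 1, 23).astype(int)
    for ind in list(ped.non_founders())[::7]:
        for c in gmap.chromosomes:
            for which, parent in ((0, ind.sire), (1, ind.dam)):
                child = mos[ind.id][c.name][which]
                pp = mos[parent][c.name]
                for pos in probe:
                    assert _src_at(child, pos) in {_src_at(pp[0], pos),
                                                   _src_at(pp[1], pos)}
        # causal allele: haplotype 0 carries the mutation
        carried = sum(_src_at(mos[ind.id][gmap.causal_chrom][w], gmap.causal_pos) == 0
                      for w in (0, 1))
        assert carried == ind.causal_dosage


def test_drop_genomes_rejects_bad_inputs():
    gmap = _flat_genome()
    ped = build_pedigree(CrossDesign(n_dams=1, f1_per_dam=1, n_intercross=0,
                                     f2_per_cross=0, n_backcross=0, bc_per_cross=0),
                         np.random.default_rng(0))
    with pytest.raises(ValueError, match="haplotype"):
        drop_genomes(ped, gmap, {}, np.random.default_rng(0))
    with pytest.raises(ValueError, match="distinct"):
        drop_genomes(ped, gmap, {"founder": (0, 0), "dam01": (2, 3)},
                     np.random.default_rng(0))


def test_offspring_of_homozygous_reference_parents_is_homozygous_reference():
    """At a site where no founder haplotype carries the alt allele, every
    descendant is hom-ref; at a site fixed alt, every descendant is hom-alt."""
    from frostmap.simulate import ChromVariants
    gmap = _flat_genome(n_chrom=1, morgans=1.0)
    ped = build_pedigree(CrossDesign(n_dams=2, f1_per_dam=6, n_intercross=2,
                                     f2_per_cross=6, n_backcross=0, bc_per_cross=0),
                         np.random.default_rng(2))
    haps = {"founder": (0, 1), "dam01": (2, 3), "dam02": (4, 5)}
    mos = drop_genomes(ped, gmap, haps, np.random.default_rng(3))
    H = np.zeros((6, 3), np.int8)
    H[:, 1] = 1  # site 1 fixed alt in every haplotype
    cv = {"chr1": ChromVariants("chr1", np.array([10_000, 20_000, 30_000]),
                                H, np.array(list("AAA")), np.array(list("TTT")), -1)}
    ids = [i.id for i in ped.non_founders()]
    g = genotypes_at(ids, mos, cv, ["chr1"])
    assert np.all(g[:, [0, 2]] == 0)
    assert np.all(g[:, 1] == 2)


# ---------------------------------------------------------------------------
# sequencing models
# ---------------------------------------------------------------------------

def test_depth_zero_yields_missing_call(rng):
    gt, ad_ref, ad_alt, dp, gq = sample_radseq_calls(
        np.array([[1]]), rng, mean_depth=0.0, error_rate=0.01)
    assert gt[0, 0] == -1 and dp[0, 0] == 0 and gq[0, 0] == -1


def test_error_free_deep_het_called_het_with_balanced_reads(rng):
    g = np.ones((1, 400), np.int8)
    gt, ad_ref, ad_alt, dp, gq = sample_radseq_calls(g, rng, mean_depth=100.0,
                                                     error_rate=0.0)
    called = gt[dp > 0]
    assert np.all(called == 1)
    ratio = ad_alt[dp > 0] / dp[dp > 0]
    # binomial(100, 1/2) read split
    assert abs(ratio.mean() - 0.5) < 3 * 0.05 / np.sqrt(called.size)


def test_error_free_hom_alt_has_capped_gq(rng):
    g = np.full((1, 50), 2, np.int8)
    gt, *_, gq = sample_radseq_calls(g, rng, mean_depth=100.0, error_rate=0.0)
    assert np.all(gt == 2) and np.all(gq == 99)


def test_genotype_caller_prefers_true_genotype():
    gt, gq = call_genotypes(np.array([0, 15, 30]), np.array([30, 15, 0]), 0.01)
    assert list(gt) == [0, 1, 2]
    assert np.all(gq > 30)


def test_invalid_sequencing_parameters_raise(rng):
    with pytest.raises(ValueError):
        sample_radseq_calls(np.ones((1, 1)), rng, mean_depth=-1)
    with pytest.raises(ValueError):
        sample_radseq_calls(np.ones((1, 1)), rng, error_rate=0.5)
    with pytest.raises(ValueError):
        sample_pool_counts(np.ones((2, 3), np.int8), {"a": np.array([0, 1])},
                           rng, coverage=0.0)
    with pytest.raises(ValueError, match="empty"):
        sample_pool_counts(np.ones((2, 3), np.int8), {"a": np.array([], int)},
                           rng, coverage=30.0)


def test_true_pool_frequency_is_exact_dosage_ratio():
    g = np.array([[2, 1, 0], [2, 0, 0], [1, 1, 2]], np.int8)
    np.testing.assert_allclose(true_pool_frequency(g, [0, 1]),
                               [1.0, 0.25, 0.0])


@pytest.mark.parametrize("dosage,expected", [(2, 1.0), (0, 0.0)])
def test_error_free_fixed_pools_hit_exact_frequencies(rng, dosage, expected):
    """A pool of only dosage-2 (or dosage-0) individuals shows the causal
    allele at exactly 100% (0%) frequency when reads are error-free."""
    g = np.full((10, 200), dosage, np.int8)
    counts = sample_pool_counts(g, {"p": np.arange(10)}, rng, coverage=30.0,
                                error_rate=0.0)
    ref, alt = counts["p"]
    covered = (ref + alt) > 0
    af = alt[covered] / (ref + alt)[covered]
    assert np.all(af == expected)


def test_heterozygote_pool_frequency_near_half(rng):
    g = np.ones((20, 1000), np.int8)
    counts = sample_pool_counts(g, {"p": np.arange(20)}, rng, coverage=30.0,
                                error_rate=0.0)
    ref, alt = counts["p"]
    covered = (ref + alt) > 0
    af = alt[covered] / (ref + alt)[covered]
    se = 0.5 / np.sqrt(30 * covered.sum())  # binomial reads, ~30x per site
    assert abs(af.mean() - 0.5) < 3 * se


# ---------------------------------------------------------------------------
# truth, anchors, determinism
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fraction,expect_all", [(1.0, True), (0.0, False)])
def test_anchor_fraction_extremes(small_colony, fraction, expect_all):
    data = small_colony
    truth, anchors = emit_truth(data.gmap, data.pedigree, data.truth.mosaics,
                                data.truth.pool_ids, data.truth.rad_ids,
                                np.random.default_rng(0), fraction)
    anchored = set(anchors["scaffold"]) if len(anchors) else set()
    if expect_all:
        assert anchored == {s.name for s in data.gmap.scaffolds}
    else:
        assert anchored == set()


def test_anchors_round_trip_through_genome_map(small_colony):
    data = small_colony
    for _, a in data.anchors.iterrows():
        chrom, pos0 = data.gmap.to_chrom_coords(a["scaffold"], a["scaffold_pos"])
        assert chrom == a["ref_chrom"]
        assert pos0 + 1 == a["ref_pos"]


def test_pool_assignments_are_disjoint_and_causal_dosage_consistent(small_colony):
    truth = small_colony.truth
    truth.validate()
    for pool, want in (("hom", 2), ("het", 1), ("wt", 0)):
        assert all(truth.dosages[i] == want for i in truth.pool_ids[pool])


def test_fixed_seed_reproduces_identical_output(tmp_path):
    cfg = small_run_config(seed=33)
    a = simulate_colony(cfg.colony)
    b = simulate_colony(cfg.colony)
    import frostmap.io as fio
    pd.testing.assert_frame_equal(a.pool_counts, b.pool_counts)
    np.testing.assert_array_equal(a.rad.gt, b.rad.gt)
    fio.write_vcf(a.rad, tmp_path / "a.vcf", a.scaffold_lengths)
    fio.write_vcf(b.rad, tmp_path / "b.vcf", b.scaffold_lengths)
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


def test_rad_panel_and_pools_match_design(small_colony):
    data = small_colony
    wt_n, het_n, hom_n = data.config.rad_class_counts
    doses = data.truth.dosages
    rad_doses = doses[data.truth.rad_ids]
    assert (rad_doses == 0).sum() == wt_n
    assert (rad_doses == 1).sum() == het_n
    assert (rad_doses == 2).sum() == hom_n
    pm = data.config.pools
    assert len(data.truth.pool_ids["hom"]) == pm.size_hom
    assert len(data.truth.pool_ids["het"]) == pm.size_het
    assert len(data.truth.pool_ids["wt"]) == pm.size_wt
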