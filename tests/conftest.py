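from pathlib import Path

import numpy as np
import pytest

import frostmap as fm

DATA = Path(__file__).parent / "data"

#: the 12-record founder-filter fixture and its hand-enumerated survivors:
#: records 1-4 pass every rule; the rest each violate exactly one
#: (multiallelic, founder hom-ref, founder missing, balance 0.35,
#: balance 0.65, DP 29, GQ 29, scaffold below 5 kb)
TOY_VCF = DATA / "toy_founder.vcf"
TOY_LENGTHS = DATA / "toy_scaffolds.tsv"
TOY_SURVIVOR_POS = [100, 200, 300, 400]


def small_run_config(seed: int = 11) -> fm.RunConfig:
    """Reduced scenario (3 Mb, small colony) for fast unit tests."""
    colony = fm.ColonyConfig(
        n_chromosomes=3,
        chrom_length=1_000_000,
        morgans_per_chrom=1.0,
        scaffolds_per_chrom=12,
        design=fm.CrossDesign(n_dams=6, f1_per_dam=8, n_intercross=6,
                              f2_per_cross=12, n_backcross=3, bc_per_cross=8),
        rad_class_counts=(10, 25, 10),
        pools=fm.PoolModel(size_hom=10, size_het=20, size_wt=20),
    )
    return fm.RunConfig(seed=seed, colony=colony)


@pytest.fixture(scope="session")
def small_colony() -> fm.ColonyData:
    return fm.simulate_colony(small_run_config().colony)


@pytest.fixture(scope="session")
def small_result() -> fm.PipelineResult:
    return fm.run_pipeline(small_run_config())


@pytest.fixture(scope="session")
def default_result() -> fm.PipelineResult:
    """One full-size default scenario, analysed end to end."""
    return fm.run_pipeline(fm.RunConfig(seed=2))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
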