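import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wgsmap.cross_sim import MUTANT_LABEL, MAPPING_LABEL, cross
from wgsmap.genome import ChromosomeMap, DiploidGenome, GeneticMap


@pytest.fixture(scope="session")
def one_chrom_map():
    return GeneticMap((ChromosomeMap("I", 2_000_000, 50.0),))


@pytest.fixture(scope="session")
def tiny_map():
    return GeneticMap(tuple(
        ChromosomeMap(name, 2_000_000, 50.0) for name in ("I", "II", "III")
    ))


@pytest.fixture(scope="session")
def tiny_f1(tiny_map):
    mut = DiploidGenome.homozygous(tiny_map, MUTANT_LABEL)
    haw = DiploidGenome.homozygous(tiny_map, MAPPING_LABEL)
    return cross(mut, haw, tiny_map, "complete", np.random.default_rng(11))


@pytest.fixture(scope="session")
def one_chrom_f1(one_chrom_map):
    mut = DiploidGenome.homozygous(one_chrom_map, MUTANT_LABEL)
    haw = DiploidGenome.homozygous(one_chrom_map, MAPPING_LABEL)
    return cross(mut, haw, one_chrom_map, "complete", np.random.default_rng(12))
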