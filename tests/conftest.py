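import numpy as np
import pytest

from yrscout import synthgen as sg


@pytest.fixture
def rng():
    return np.random.default_rng(20211118)


@pytest.fixture(scope="session")
def dirs_consensus():
    r = np.random.default_rng(11)
    return sg.make_dirs_like_consensus(sg.FamilySpec.dirs_default("DIRS-T"), r)


@pytest.fixture(scope="session")
def ngaro_consensus():
    r = np.random.default_rng(12)
    return sg.make_ngaro_like_consensus(sg.FamilySpec.ngaro_default("NGARO-T"), r)


def small_world_config(seed: int = 7) -> sg.GeneratorConfig:
    """A compact world for homology/pipeline tests: one DIRS-like and one
    Ngaro-like family on an 80 kb genome, CpG transitions 10x hot."""
    return sg.GeneratorConfig(
        seed=seed,
        genome_length=80_000,
        cpg_factor=10.0,
        families=[sg.FamilySpec.dirs_default("D1"),
                  sg.FamilySpec.ngaro_default("N1")],
        waves=[sg.WaveSpec("D1", n_copies=5, target_K=0.02),
               sg.WaveSpec("N1", n_copies=4, target_K=0.10,
                           intact_fraction=0.75)],
        est_count=15,
    )


@pytest.fixture(scope="session")
def small_world():
    return sg.build_genome(small_world_config())
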