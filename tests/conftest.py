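import numpy as np
import pytest

from pepbind.synthetic import SyntheticSpec, build_corpus, gen_toy_pdb


@pytest.fixture(scope="session")
def toy_pdb_path(tmp_path_factory):
    """A two-chain toy structure: receptor A, peptide B spanning [0,10]^3."""
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    path.write_text(gen_toy_pdb(seed=1, peptide_length=3))
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with docking tracks (12 regions of 30 aa)."""
    spec = SyntheticSpec(n_regions=12, region_length=30, span_range=(3, 8), seed=3)
    return build_corpus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
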