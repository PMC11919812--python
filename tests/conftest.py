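import numpy as np
import pytest

from isopeptide_detect.matcher import SearchConfig
from isopeptide_detect.synthetic import (
    PlantSpec,
    default_template_library,
    make_corpus,
    make_positive,
)


@pytest.fixture(scope="session")
def library():
    return default_template_library()


@pytest.fixture(scope="session")
def search_config():
    return SearchConfig()


@pytest.fixture(scope="session")
def ideal_plant():
    """Noise-free exposed planted bond with its truth record."""
    return make_positive(PlantSpec(noise_sigma=0.0, burial="exposed", seed=101))


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    """The standard evaluation corpus: 20 positives (sigma 0.2 A, buried),
    50 decoys, seed 42."""
    d = tmp_path_factory.mktemp("corpus")
    make_corpus(d, n_pos=20, n_neg=50, seed=42, noise_sigma=0.2)
    return d


@pytest.fixture(scope="session")
def blosum_dict():
    """BLOSUM62 as a plain dict for the independent alignment oracle."""
    from isopeptide_detect.templates import _MATRIX

    alph = _MATRIX.get_alphabet1()
    letters = [str(alph.decode(i)) for i in range(len(alph))]
    arr = _MATRIX.score_matrix()
    return {
        (x, y): int(arr[i, j])
        for i, x in enumerate(letters)
        for j, y in enumerate(letters)
    }


def triad_site(structure, truth):
    """Resolve a truth record to its (lys, catalytic, acceptor) residues."""
    return tuple(
        structure.get_residue((truth["chain"], truth[k], ""))
        for k in ("r1_bond", "r_cat", "r2_bond")
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
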