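import numpy as np
import pytest

from panhab.io import read_newick
from panhab.synthdata import GeneratorConfig, generate_dataset, simulate_tree


@pytest.fixture
def small_tree():
    """3-tip tree with hand-checkable distances."""
    return read_newick("((A:0.5,B:0.5):0.2,C:0.7);")


@pytest.fixture
def quartet_tree():
    return read_newick("((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5);")


def star_newick(n: int, length: float = 1.0) -> str:
    return "(" + ",".join(f"T{i}:{length}" for i in range(n)) + ");"


@pytest.fixture
def star_tree():
    return read_newick(star_newick(30))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One full default synthetic dataset, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_dataset(GeneratorConfig(seed=1), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def default_dataset(default_bundle):
    """The default bundle loaded into memory."""
    from panhab.io import read_annotations, read_matrix, read_metadata, read_newick

    outdir, truth = default_bundle
    return {
        "matrix": read_matrix(outdir / "matrix.tsv"),
        "metadata": read_metadata(outdir / "metadata.tsv"),
        "tree": read_newick(outdir / "tree.nwk"),
        "annotations": read_annotations(outdir / "annotations.tsv"),
        "truth": truth,
        "dir": outdir,
    }


def random_binary_tree(n_tips: int, seed: int):
    """Small random tree for property tests."""
    return simulate_tree(n_tips, 1.0, 0.0, seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
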