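import numpy as np
import pytest

from protokaryo.core_io import Segmentation
from protokaryo.simulate import EvolutionConfig, simulate


@pytest.fixture(scope="session")
def clade_1r():
    """Small clade: non-duplicated reference + two post-1R species."""
    cfg = EvolutionConfig(
        k_anc=2,
        genes_per_chromosome=100,
        branches={
            "ref": [],
            "spA": [("tetraploidize",)],
            "spB": [("tetraploidize",)],
        },
        roles={"ref": "reference", "spA": "post_wgd", "spB": "post_wgd"},
        retention={"ref": 1.0, "spA": 0.8, "spB": 0.8},
        seed=1,
    )
    gene_table, pairs, truth = simulate(cfg)
    return gene_table, pairs, truth


@pytest.fixture(scope="session")
def clade_1r3x():
    """Clade with tetraploidization followed by triplication (sixfold)."""
    cfg = EvolutionConfig(
        k_anc=3,
        genes_per_chromosome=80,
        branches={
            "ref": [],
            "lampA": [("tetraploidize",), ("hexaploidize",), ("invert", 1.0)],
            "lampB": [("tetraploidize",), ("hexaploidize",), ("invert", 1.0)],
        },
        roles={"ref": "reference", "lampA": "post_wgd", "lampB": "post_wgd"},
        retention={"ref": 1.0, "lampA": 0.75, "lampB": 0.75},
        seed=3,
    )
    gene_table, pairs, truth = simulate(cfg)
    return gene_table, pairs, truth


@pytest.fixture()
def scaffold_segmentation():
    def make(gene_table, species):
        return Segmentation.from_scaffolds(gene_table, species)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
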