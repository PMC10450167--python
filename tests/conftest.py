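import numpy as np
import pytest

from nucassign.classifier import TrainingConfig, train_classifier
from nucassign.fixtures import (DuplexSpec, MapSimulationParams, make_duplex,
                                simulate_map, training_set)


@pytest.fixture(scope="session")
def em_classifier():
    """Classifier trained on synthetic 3-A descriptors (shared, seeded)."""
    data = training_set(n_per_class=200, resolutions=(3.0,), noise_sd=0.1, seed=2)
    return train_classifier(data, TrainingConfig(epochs=80, seed=0), modality="EM")


@pytest.fixture(scope="session")
def duplex10():
    return make_duplex(DuplexSpec(sequence="GGAUCCGAUC", form="A_RNA"))


@pytest.fixture(scope="session")
def duplex10_map(duplex10):
    return simulate_map(duplex10, MapSimulationParams(resolution=3.0, seed=0))


def perturb_structure(structure, noise_sd, seed):
    """Copy of a structure with Gaussian coordinate noise added."""
    import copy
    st = copy.deepcopy(structure)
    rng = np.random.default_rng(seed)
    for chain in st.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(0.0, noise_sd, 3)
            res.rebuild_index()
    return st


def rigid_move_structure(structure, rot, trans):
    import copy
    st = copy.deepcopy(structure)
    for chain in st.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.xyz = rot @ atom.xyz + trans
            res.rebuild_index()
    return st
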