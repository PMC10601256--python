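import numpy as np
import pytest

from triplexlens import scenarios, synthtraj
from triplexlens.topology import default_params
from triplexlens.triplexcode import SequenceRecord, align_windows


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def small_alignment():
    """All-match 6-level alignment (purine AAAA.., RNA UUUU..)."""
    rna = SequenceRecord("rna6", "UUUUUU", "rna")
    dna = SequenceRecord("dna6", "AAAAAA", "dna")
    return align_windows(rna, 1, dna, 1, 6)


@pytest.fixture(scope="session")
def mixed_alignment():
    """6-level alignment with one mismatch (level 3: G opposite dG)."""
    rna = SequenceRecord("rna6m", "UUGUCU", "rna")
    dna = SequenceRecord("dna6m", "AAGAGA", "dna")
    return align_windows(rna, 1, dna, 1, 6)


@pytest.fixture(scope="session")
def small_system(small_alignment, params):
    topology, reference = synthtraj.build_ideal_triplex(
        small_alignment, params=params
    )
    return topology, reference


@pytest.fixture(scope="session")
def mixed_system(mixed_alignment, params):
    topology, reference = synthtraj.build_ideal_triplex(
        mixed_alignment, params=params
    )
    return topology, reference


@pytest.fixture(scope="session")
def static_trajectory(small_system):
    """Zero-noise, occupancy-1 trajectory: every frame identical."""
    topology, reference = small_system
    pairs = [synthtraj.PlantedPair(i, "B", i, 1.0) for i in range(1, 7)]
    traj, truth = synthtraj.synthesize_trajectory(
        topology, reference, n_frames=5, dt=1.0, noise_sigma=0.0,
        occupancies=pairs, seed=11,
    )
    return topology, traj, truth


@pytest.fixture(scope="session")
def stable_bundle():
    return scenarios.generate_scenario("stable_A", seed=5, n_frames=120)
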