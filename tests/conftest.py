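import numpy as np
import pytest

from flavopot.structure import parse_structure
from flavopot.synthetic import (
    CofactorSpec,
    PlantedDatasetSpec,
    ResiduePlacement,
    StructureSpec,
    generate_planted_dataset,
    generate_structure,
)


@pytest.fixture(scope="session")
def banded_structure():
    """FMN structure with residues in known shells: 3 inside 8 Å, 2 mid, 5 far."""
    placements = (
        [ResiduePlacement(name, d) for name, d in
         [("ARG", 4.5), ("GLN", 5.5), ("HIS", 6.0)]]
        + [ResiduePlacement(name, d) for name, d in [("ASP", 10.0), ("TRP", 11.0)]]
        + [ResiduePlacement(name, d) for name, d in
           [("SER", 22.0), ("LEU", 23.0), ("TYR", 24.0), ("LYS", 25.0), ("GLU", 26.0)]]
    )
    spec = StructureSpec(placements=placements, seed=42)
    pdb_text, truth = generate_structure(spec)
    return pdb_text, truth, spec


@pytest.fixture(scope="session")
def parsed_banded(banded_structure):
    pdb_text, truth, _ = banded_structure
    return parse_structure(pdb_text, "banded"), truth


@pytest.fixture(scope="session")
def planted():
    """Planted sparse-signal dataset at the study conditions (n=141, sd 20 mV)."""
    return generate_planted_dataset(PlantedDatasetSpec(seed=7))


def random_structure(seed: int, n_inner: int = 4, n_outer: int = 6):
    """A random small FMN structure for oracle comparisons."""
    rng = np.random.default_rng(seed)
    names = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
             "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
             "TYR", "VAL"]
    placements = [
        ResiduePlacement(names[rng.integers(20)], float(rng.uniform(4, 12)))
        for _ in range(n_inner)
    ] + [
        ResiduePlacement(names[rng.integers(20)], float(rng.uniform(14, 28)))
        for _ in range(n_outer)
    ]
    spec = StructureSpec(placements=placements, seed=seed)
    pdb_text, truth = generate_structure(spec)
    return parse_structure(pdb_text), truth
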