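import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from taglessppi.iodata import ElutionDataset, Multiplex, ProteinRecord


def build_dataset(
    multiplexes: dict[str, tuple[str, list[str]]],
    abundance: dict[tuple[str, str], list[float]],
    peptides: dict[tuple[str, str], int] | None = None,
    annotations: dict[str, ProteinRecord] | None = None,
) -> ElutionDataset:
    """Terse dataset builder: multiplexes maps id -> (dimension, fraction ids);
    peptide counts default to 1."""
    mxs = {
        mid: Multiplex(multiplex_id=mid, dimension=dim, fraction_ids=tuple(fids))
        for mid, (dim, fids) in multiplexes.items()
    }
    ab = {k: np.asarray(v, dtype=float) for k, v in abundance.items()}
    pep = {k: 1 for k in ab}
    if peptides:
        pep.update(peptides)
    proteins = dict(annotations or {})
    for pid, _ in ab:
        proteins.setdefault(pid, ProteinRecord(protein_id=pid))
    ds = ElutionDataset(
        proteins=proteins, multiplexes=mxs, abundance=ab, peptides=pep
    )
    ds.validate()
    return ds


@pytest.fixture
def two_multiplex_dataset() -> ElutionDataset:
    """Three proteins over one SEC and one HIC multiplex; A and B co-elute."""
    return build_dataset(
        multiplexes={
            "S1": ("SEC", ["f1", "f2", "f3", "f4"]),
            "H1": ("HIC", ["g1", "g2", "g3", "g4"]),
        },
        abundance={
            ("A", "S1"): [1.0, 0.5, 0.1, 0.0],
            ("B", "S1"): [0.9, 0.6, 0.05, 0.01],
            ("C", "S1"): [0.0, 0.1, 0.5, 1.0],
            ("A", "H1"): [0.2, 1.0, 0.3, 0.0],
            ("B", "H1"): [0.1, 0.9, 0.4, 0.05],
        },
        peptides={("A", "S1"): 4, ("B", "S1"): 6, ("C", "S1"): 2,
                  ("A", "H1"): 8, ("B", "H1"): 6},
    )


@pytest.fixture(scope="session")
def small_simulation():
    """One moderate synthetic experiment shared by read-only tests."""
    from taglessppi.synthetic import SimulationConfig, simulate_experiment

    config = SimulationConfig(n_proteins=150, n_complexes=20, seed=42)
    return config, simulate_experiment(config)
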