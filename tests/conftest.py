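"""Shared fixtures: tiny hand-built PDB texts and synthetic bundles."""

from __future__ import annotations

import pytest

from paraclust import SpatialClustering, SyntheticSpec, generate_bundle


def atom_line(serial, resname, chain, resseq, x, y, z, altloc=" ", occ=1.0):
    return (
        f"ATOM  {serial:>5d}  CA {altloc}{resname:>3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {'C':>2s}"
    )


@pytest.fixture
def toy_pdb():
    """Three Cα atoms, chain A."""
    lines = [
        atom_line(1, "ALA", "A", 1, 1.0, 2.0, 3.0),
        atom_line(2, "CYS", "A", 2, 4.0, 5.0, 6.0),
        atom_line(3, "ASP", "A", 3, 7.0, 8.0, 9.0),
        "TER", "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb():
    """One residue with alternate Cα locations A and B."""
    lines = [
        atom_line(1, "ALA", "A", 1, 1.0, 1.0, 1.0, altloc="A", occ=0.4),
        atom_line(2, "ALA", "A", 1, 9.0, 9.0, 9.0, altloc="B", occ=0.6),
        atom_line(3, "GLY", "A", 2, 2.0, 2.0, 2.0),
        "TER", "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_model_pdb():
    """Two-model NMR-style file with different coordinates per model."""
    lines = ["MODEL        1",
             atom_line(1, "ALA", "A", 1, 1.0, 0.0, 0.0),
             atom_line(2, "GLY", "A", 2, 2.0, 0.0, 0.0),
             "ENDMDL",
             "MODEL        2",
             atom_line(1, "ALA", "A", 1, -1.0, 0.0, 5.0),
             atom_line(2, "GLY", "A", 2, -2.0, 0.0, 5.0),
             "ENDMDL",
             "END"]
    return "\n".join(lines) + "\n"


@pytest.fixture
def null_bundle():
    """Default-sized null bundle (no spatial clustering)."""
    return generate_bundle(SyntheticSpec(seed=1))


@pytest.fixture
def clustered_bundle():
    """Tightly clustered bundle: foci at opposite chain ends, 2 Å decay."""
    spec = SyntheticSpec(
        seed=2, clustering=SpatialClustering(focus_a=1, focus_b=142,
                                             decay_length=2.0)
    )
    return generate_bundle(spec)
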