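"""Shared fixtures: toy structures, decoy cohorts and variant pools.

All fixture data is generated programmatically; nothing is downloaded or
read from disk except files the tests themselves write to tmp_path.
"""

import numpy as np
import pytest

from nbselect import fixtures as fx
from nbselect.structio import AtomRecord, ChainModel, ComplexModel, Residue

# Handcrafted 1-model PDB text: chains A and B, 5 CA atoms each.
TOY_PDB = "\n".join(
    ["MODEL        1"]
    + [
        f"ATOM  {i + 1:>5}  CA  ALA {ch}{i % 5 + 1:>4}    "
        f"{float(3 * i):8.3f}{1.500:8.3f}{-2.250:8.3f}  1.00  0.00           C"
        for ch, base in (("A", 0), ("B", 5))
        for i in range(base, base + 5)
    ]
    + ["ENDMDL", "END", ""]
)


@pytest.fixture
def toy_pdb_path(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def make_atom(serial, xyz, element="C", res_seq=None, chain_id="A", atom_name="CA"):
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        element=element,
        res_name="ALA",
        res_seq=res_seq if res_seq is not None else serial,
        chain_id=chain_id,
        xyz=np.asarray(xyz, dtype=float),
    )


def chain_from_coords(coords, chain_id="A", atom_name="CA", elements=None):
    residues = []
    for i, xyz in enumerate(coords):
        el = elements[i] if elements is not None else "C"
        residues.append(
            Residue(
                "ALA",
                i + 1,
                [make_atom(i + 1, xyz, element=el, res_seq=i + 1, chain_id=chain_id, atom_name=atom_name)],
            )
        )
    return ChainModel(chain_id=chain_id, residues=residues)


@pytest.fixture(scope="session")
def mutable_positions():
    loop = fx.DEFAULT_LOOPDEF
    return (
        list(range(loop.cdr1[0], loop.cdr1[1] + 1))
        + list(range(loop.cdr2[0], loop.cdr2[1] + 1))
        + list(range(loop.cdr3[0], loop.cdr3[1] + 1))
    )


@pytest.fixture(scope="session")
def maturation_pool(mutable_positions):
    """1600-record pool with exactly 89 unique sequences in 6 score-structured
    sequence families (the canonical maturation fixture)."""
    return fx.gen_variant_pool(
        fx.NANOBODY_TEMPLATE,
        mutable_positions,
        n=1600,
        seed=7,
        n_unique=89,
        n_families=6,
    )
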