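"""Structure I/O and geometry primitives.

Atomic coordinates are held in lightweight dataclasses (:class:`AtomRecord`,
:class:`ChainModel`, :class:`ComplexModel`) that the decision stages of the
pipeline share.  The primitives here — Kabsch superposition, selection RMSD,
steric clash counting, Shrake–Rupley solvent accessibility and chain
molecular weight — are the measurements every downstream filter is built on.

Conventions
-----------
* Coordinates are in Ångström; PDB author residue numbering is kept as-is and
  all residue ranges are inclusive on both ends.
* Clash counting is heavy-atom only (hydrogens are ignored) with element van
  der Waals radii C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å and a 0.4 Å
  overlap threshold; the clashscore is normalized per 1000 atoms of the
  *first* atom set (the pose being scored).
* SASA uses a deterministic Fibonacci sphere of 960 points per atom and a
  1.4 Å water probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils import seq1 as _seq1
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Residue",
    "ChainModel",
    "ComplexModel",
    "AtomSelection",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
    "selection_rmsd",
    "clash_metrics",
    "shrake_rupley_sasa",
    "buried_sasa",
    "chain_molecular_weight",
]

#: Heavy-atom van der Waals radii (Å) used for clash and SASA computations.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

_HYDROGENS = {"H", "D"}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class AtomRecord:
    """One atom of a PDB model."""

    serial: int
    atom_name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: np.ndarray
    model_no: int = 1

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: xyz must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element is empty")


@dataclass
class Residue:
    res_name: str
    res_seq: int
    atoms: list[AtomRecord] = field(default_factory=list)


@dataclass
class ChainModel:
    """One chain: ordered residues with strictly increasing author numbering."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = [r.res_seq for r in self.residues]
        if any(b <= a for a, b in zip(seqs, seqs[1:])):
            raise ValueError(f"chain {self.chain_id}: res_seq not strictly increasing")

    @property
    def sequence(self) -> str:
        """One-letter sequence derived from residue names ('X' for unknowns)."""
        return "".join(
            _seq1(r.res_name.capitalize(), undef_code="X") for r in self.residues
        )

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def get_residue(self, res_seq: int) -> Residue:
        for r in self.residues:
            if r.res_seq == res_seq:
                return r
        raise KeyError(f"residue {res_seq} not found in chain {self.chain_id}")


@dataclass
class ComplexModel:
    """Named chain groups (ligand/receptor/competitor/scaffold) of one model."""

    groups: dict[str, list[ChainModel]]
    model_no: int = 1

    def group_atoms(self, group: str) -> list[AtomRecord]:
        if group not in self.groups:
            raise KeyError(f"group {group!r} not present (have {sorted(self.groups)})")
        return [a for ch in self.groups[group] for a in ch.atoms]

    def group_chain(self, group: str) -> ChainModel:
        chains = self.groups[group]
        if len(chains) != 1:
            raise ValueError(f"group {group!r} has {len(chains)} chains, expected 1")
        return chains[0]

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for g in self.groups.values() for ch in g for a in ch.atoms]


@dataclass
class AtomSelection:
    """Residue ranges (inclusive) plus an atom-name filter.

    ``res_ranges`` is a list of ``(first, last)`` author-numbering pairs;
    ``atom_names=None`` selects every atom of the selected residues.
    """

    res_ranges: Sequence[tuple[int, int]]
    atom_names: tuple[str, ...] | None = ("CA",)

    def resolve(self, chain: ChainModel) -> list[AtomRecord]:
        out: list[AtomRecord] = []
        for res in chain.residues:
            if any(lo <= res.res_seq <= hi for lo, hi in self.res_ranges):
                for atom in res.atoms:
                    if self.atom_names is None or atom.atom_name in self.atom_names:
                        out.append(atom)
        return out


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def _chain_from_gemmi(chain: gemmi.Chain, model_no: int) -> ChainModel:
    residues = []
    for res in chain:
        atoms = [
            AtomRecord(
                serial=atom.serial,
                atom_name=atom.name,
                element=atom.element.name,
                res_name=res.name,
                res_seq=res.seqid.num,
                chain_id=chain.name,
                xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                model_no=model_no,
            )
            for atom in res
        ]
        residues.append(Residue(res_name=res.name, res_seq=res.seqid.num, atoms=atoms))
    return ChainModel(chain_id=chain.name, residues=residues)


def read_pdb(path, group_spec: Mapping[str, str]) -> list[ComplexModel]:
    """Read a (possibly multi-model) PDB file into one ComplexModel per MODEL.

    ``group_spec`` maps chain ids to group names, e.g.
    ``{"A": "ligand", "B": "receptor"}``.  Chains absent from the file raise a
    ValueError naming the chain; chains absent from the spec are ignored.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    models: list[ComplexModel] = []
    for model in st:
        model_no = int(model.num)
        present = {ch.name for ch in model}
        missing = sorted(set(group_spec) - present)
        if missing:
            raise ValueError(
                f"chain(s) {', '.join(missing)} listed in group_spec are missing "
                f"from model {model_no} of {path}"
            )
        groups: dict[str, list[ChainModel]] = {}
        for ch in model:
            group = group_spec.get(ch.name)
            if group is None:
                continue
            groups.setdefault(group, []).append(_chain_from_gemmi(ch, model_no))
        models.append(ComplexModel(groups=groups, model_no=model_no))
    if not models:
        raise ValueError(f"no models found in {path}")
    return models


def write_pdb(models: Sequence[ComplexModel], path) -> None:
    """Write ComplexModels as a multi-model PDB file (one MODEL per entry)."""
    st = gemmi.Structure()
    st.name = "nbselect"
    for cm in models:
        gm = gemmi.Model(cm.model_no)
        for chains in cm.groups.values():
            for chain in chains:
                gc = gemmi.Chain(chain.chain_id)
                for res in chain.residues:
                    gr = gemmi.Residue()
                    gr.name = res.res_name
                    gr.seqid = gemmi.SeqId(res.res_seq, " ")
                    for atom in res.atoms:
                        ga = gemmi.Atom()
                        ga.name = atom.atom_name
                        ga.element = gemmi.Element(atom.element)
                        ga.serial = atom.serial
                        ga.pos = gemmi.Position(*atom.xyz)
                        gr.add_atom(ga)
                    gc.add_residue(gr)
                gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _as_coords(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        arr = np.asarray(x, dtype=float)
    else:
        arr = np.array([a.xyz for a in x], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array or atom list")
    return arr


def kabsch_superpose(mobile, reference) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.  The
    rotation is proper (det = +1).  Requires at least 3 non-degenerate points.
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if mob.shape != ref.shape:
        raise ValueError(f"point counts differ: {mob.shape[0]} vs {ref.shape[0]}")
    if mob.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinear (rank < 2) reference leaves the rotation under-determined
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference point set")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - mob.mean(axis=0) @ rot.T
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def selection_rmsd(chain_a: ChainModel, chain_b: ChainModel, selection: AtomSelection) -> float:
    """Plain (unsuperposed) RMSD over paired atoms of a selection."""
    atoms_a = selection.resolve(chain_a)
    atoms_b = selection.resolve(chain_b)
    if not atoms_a or not atoms_b:
        raise ValueError("selection resolves to 0 atoms")
    if len(atoms_a) != len(atoms_b):
        raise ValueError(
            f"selection lengths differ: {len(atoms_a)} vs {len(atoms_b)}"
        )
    a = _as_coords(atoms_a)
    b = _as_coords(atoms_b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if a.element.upper() not in _HYDROGENS]


def _radii(atoms: Sequence[AtomRecord]) -> np.ndarray:
    unknown = sorted({a.element.upper() for a in atoms} - set(VDW_RADII))
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {', '.join(unknown)}")
    return np.array([VDW_RADII[a.element.upper()] for a in atoms])


def clash_metrics(
    atoms_a: Sequence[AtomRecord],
    atoms_b: Sequence[AtomRecord],
    overlap_threshold: float = 0.4,
) -> tuple[int, float]:
    """Inter-set steric clash count and clashscore.

    A clash is an inter-set heavy-atom pair closer than
    ``r_vdw(i) + r_vdw(j) - overlap_threshold``.  The clashscore normalizes
    the count per 1000 atoms of ``atoms_a`` (the pose being scored).
    """
    heavy_a, heavy_b = _heavy(atoms_a), _heavy(atoms_b)
    if not heavy_a or not heavy_b:
        raise ValueError("clash_metrics requires two nonempty heavy-atom sets")
    ra, rb = _radii(heavy_a), _radii(heavy_b)
    ca, cb = _as_coords(heavy_a), _as_coords(heavy_b)
    max_cut = ra.max() + rb.max() - overlap_threshold
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    count = 0
    for i, neighbors in enumerate(tree_a.query_ball_tree(tree_b, r=max_cut)):
        if not neighbors:
            continue
        d = np.linalg.norm(cb[neighbors] - ca[i], axis=1)
        cut = ra[i] + rb[neighbors] - overlap_threshold
        count += int(np.sum(d < cut))
    clashscore = 1000.0 * count / len(heavy_a)
    return count, clashscore


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    atoms: Sequence[AtomRecord], probe: float = 1.4, n_points: int = 960
) -> float:
    """Total solvent-accessible surface area (Å²) of a heavy-atom set."""
    heavy = _heavy(atoms)
    if not heavy:
        raise ValueError("SASA requires a nonempty heavy-atom set")
    coords = _as_coords(heavy)
    radii = _radii(heavy) + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    total = 0.0
    max_r = radii.max()
    for i, (center, r) in enumerate(zip(coords, radii)):
        pts = center + r * sphere
        neighbors = [j for j in tree.query_ball_point(center, r + max_r) if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            exposed = np.all(d >= radii[neighbors][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * r * r
    return float(total)


def buried_sasa(
    atoms_a: Sequence[AtomRecord],
    atoms_b: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface area buried on complex formation: SASA(A)+SASA(B)−SASA(A∪B)."""
    if not atoms_a or not atoms_b:
        raise ValueError("buried_sasa requires two nonempty groups")
    sasa_a = shrake_rupley_sasa(atoms_a, probe, n_points)
    sasa_b = shrake_rupley_sasa(atoms_b, probe, n_points)
    sasa_ab = shrake_rupley_sasa(list(atoms_a) + list(atoms_b), probe, n_points)
    return sasa_a + sasa_b - sasa_ab


def chain_molecular_weight(sequence: str) -> float:
    """Average molecular weight (Da) of a peptide: residue masses + one water."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted(set(sequence.upper()) - _STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue letter(s): {', '.join(bad)}")
    return float(_bio_molecular_weight(sequence.upper(), seq_type="protein"))
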