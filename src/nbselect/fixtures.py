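"""Seed-deterministic synthetic data generators.

Every decision stage of the pipeline is testable without engine runs or
downloads: these generators emulate (a) per-pose design-decoy ensembles with
funnel-shaped or flat RMSD-vs-energy structure, (b) toy atom clouds with an
exact planted clash count, (c) pools of point-mutated sequence variants with
attached scores, and (d) toy trajectories with scheduled loop displacements.

Each generator takes an explicit integer seed and owns a single
``numpy.random.default_rng`` stream; the same spec plus seed reproduces the
same output exactly.  The generated energies and scores are statistical
stand-ins with the documented distributions, not physical predictions.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import DesignDecoy, LandscapeEnsemble
from .mdrmsd import LoopDefinition
from .structio import AtomRecord, ChainModel, ComplexModel, Residue, VDW_RADII

__all__ = [
    "NANOBODY_TEMPLATE",
    "DEFAULT_LOOPDEF",
    "gen_decoy_ensemble",
    "gen_clash_complex",
    "gen_variant_pool",
    "gen_toy_trajectory",
    "make_toy_chain",
]

#: 120-residue nanobody-like template sequence (VHH framework with three
#: CDR-like loop stretches); synthetic, used only as a mutation scaffold.
NANOBODY_TEMPLATE = (
    "QVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYY"
    "ADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAKDRGYSSGWYRDYWGQGTLVTVS"
)

#: Loop ranges (1-based positions on the template) standing in for CDR1/2/3,
#: with the framework taken as the stretches between them.
DEFAULT_LOOPDEF = LoopDefinition(
    cdr1=(26, 35),
    cdr2=(50, 59),
    cdr3=(97, 109),
    framework=((1, 25), (36, 49), (60, 96), (110, 120)),
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _funnel_params(params: Mapping | None) -> dict:
    defaults = dict(sigma_r=2.0, r_max=8.0, depth=10.0, width=1.5, tau=1.0, base=0.0)
    if params:
        unknown = set(params) - set(defaults)
        if unknown:
            raise ValueError(f"unknown generator parameter(s): {sorted(unknown)}")
        defaults.update(params)
    if defaults["sigma_r"] <= 0 or defaults["r_max"] <= 0 or defaults["tau"] < 0:
        raise ValueError("sigma_r, r_max must be positive; tau nonnegative")
    return defaults


def _mutate(rng: np.random.Generator, template: str, positions: Sequence[int], k: int) -> str:
    """Apply k random substitutions at 1-based positions drawn from ``positions``."""
    seq = list(template)
    chosen = rng.choice(np.asarray(positions), size=min(k, len(positions)), replace=False)
    for pos in np.atleast_1d(chosen):
        current = seq[pos - 1]
        options = [aa for aa in _AA if aa != current]
        seq[pos - 1] = options[rng.integers(len(options))]
    return "".join(seq)


def gen_decoy_ensemble(
    kind: str,
    n: int,
    seed: int,
    pose_id: str = "pose-1",
    params: Mapping | None = None,
    with_sequences: bool = False,
    template: str = NANOBODY_TEMPLATE,
    mutable_positions: Sequence[int] | None = None,
) -> LandscapeEnsemble:
    """Generate a funnel-shaped or flat design-decoy ensemble.

    ``funnel`` kind: rmsd ~ |Normal(0, σ_r)| truncated to [0, r_max];
    ddg = b − depth·exp(−(rmsd/width)²) + Normal(0, τ).
    ``flat`` kind: rmsd ~ Uniform(0, r_max); ddg ~ Normal(b, τ), independent
    of rmsd.  Defaults: σ_r = 2, r_max = 8, depth = 10, width = 1.5, τ = 1,
    b = 0.  Buried SASA is drawn Normal(950, 120) Å² (clipped ≥ 400) and an
    MM/PBSA stand-in correlated with ddg is attached via ``to_frame``-style
    consumers downstream.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in {"funnel", "flat"}:
        raise ValueError(f"unknown ensemble kind {kind!r}")
    p = _funnel_params(params)
    rng = np.random.default_rng(seed)
    if kind == "funnel":
        rmsd = np.minimum(np.abs(rng.normal(0.0, p["sigma_r"], size=n)), p["r_max"])
        ddg = (
            p["base"]
            - p["depth"] * np.exp(-((rmsd / p["width"]) ** 2))
            + rng.normal(0.0, p["tau"], size=n)
        )
    else:
        rmsd = rng.uniform(0.0, p["r_max"], size=n)
        ddg = rng.normal(p["base"], p["tau"], size=n)
    sasa = np.clip(rng.normal(950.0, 120.0, size=n), 400.0, None)
    if mutable_positions is None:
        mutable_positions = list(range(DEFAULT_LOOPDEF.cdr1[0], DEFAULT_LOOPDEF.cdr1[1] + 1)) + \
            list(range(DEFAULT_LOOPDEF.cdr2[0], DEFAULT_LOOPDEF.cdr2[1] + 1)) + \
            list(range(DEFAULT_LOOPDEF.cdr3[0], DEFAULT_LOOPDEF.cdr3[1] + 1))
    decoys = []
    for i in range(n):
        seq = (
            _mutate(rng, template, mutable_positions, k=int(rng.integers(1, 4)))
            if with_sequences
            else ""
        )
        decoys.append(
            DesignDecoy(
                design_id=f"{pose_id}_d{i:05d}",
                pose_id=pose_id,
                rmsd_to_initial=float(rmsd[i]),
                ddg_binding=float(ddg[i]),
                sequence=seq,
                buried_sasa=float(sasa[i]),
            )
        )
    return LandscapeEnsemble(pose_id=pose_id, decoys=decoys)


def make_toy_chain(
    n_res: int,
    chain_id: str = "A",
    spacing: float = 8.0,
    element: str = "C",
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> ChainModel:
    """A pseudo-chain of single-atom (Cα) residues on a cubic lattice.

    Lattice spacing 8 Å guarantees no internal contacts at heavy-atom vdW
    radii (max contact cutoff 2·1.8 − 0.4 = 3.2 Å).
    """
    side = int(np.ceil(n_res ** (1.0 / 3.0)))
    residues = []
    origin = np.asarray(origin, dtype=float)
    for i in range(n_res):
        ix, iy, iz = i % side, (i // side) % side, i // (side * side)
        xyz = origin + spacing * np.array([ix, iy, iz], dtype=float)
        residues.append(
            Residue(
                res_name="ALA",
                res_seq=i + 1,
                atoms=[
                    AtomRecord(
                        serial=i + 1,
                        atom_name="CA",
                        element=element,
                        res_name="ALA",
                        res_seq=i + 1,
                        chain_id=chain_id,
                        xyz=xyz,
                    )
                ],
            )
        )
    return ChainModel(chain_id=chain_id, residues=residues)


def gen_clash_complex(
    n_atoms: int,
    planted_clashes: int,
    seed: int,
    n_competitor: int = 50,
    overlap: float = 0.5,
) -> ComplexModel:
    """Ligand lattice plus a competitor cloud with an exact planted clash count.

    Exactly ``planted_clashes`` competitor atoms sit at distance
    ``r_i + r_j − overlap`` (default overlap 0.5 Å ≥ the 0.4 Å clash
    threshold) from distinct ligand atoms; all other competitor atoms are
    ≥ 8 Å away from every ligand atom.
    """
    if planted_clashes > min(n_atoms, n_competitor):
        raise ValueError("planted_clashes exceeds available atoms")
    rng = np.random.default_rng(seed)
    ligand = make_toy_chain(n_atoms, chain_id="L")
    lig_xyz = np.array([a.xyz for a in ligand.atoms])
    targets = rng.choice(n_atoms, size=planted_clashes, replace=False)
    r = VDW_RADII["C"]
    comp_coords = []
    for t in targets:
        # offset along -x: the nearest other lattice atom is >= 8 A away in
        # +x/+y/+z, so only the targeted pair falls under the clash cutoff
        comp_coords.append(lig_xyz[t] + np.array([-(2 * r - overlap), 0.0, 0.0]))
    far_origin = lig_xyz.max(axis=0) + 50.0
    n_far = n_competitor - planted_clashes
    if n_far > 0:
        far_chain = make_toy_chain(n_far, chain_id="X", origin=far_origin)
        comp_coords.extend(a.xyz for a in far_chain.atoms)
    residues = [
        Residue(
            res_name="ALA",
            res_seq=i + 1,
            atoms=[
                AtomRecord(
                    serial=i + 1,
                    atom_name="CA",
                    element="C",
                    res_name="ALA",
                    res_seq=i + 1,
                    chain_id="C",
                    xyz=xyz,
                )
            ],
        )
        for i, xyz in enumerate(comp_coords)
    ]
    competitor = ChainModel(chain_id="C", residues=residues)
    return ComplexModel(groups={"ligand": [ligand], "competitor": [competitor]})


def _spread_family_cores(
    rng: np.random.Generator,
    template: str,
    positions: Sequence[int],
    n_families: int,
    core_size: int = 5,
    n_candidates_factor: int = 6,
) -> list[dict]:
    """Pick family core-mutation sets that are far apart in sequence space.

    Candidate cores (``core_size`` random substitutions each) are featurized
    and projected onto two principal components; a greedy max-min selection
    keeps the ``n_families`` most mutually distant cores, so density
    clustering of the resulting pool can resolve every family.
    """
    from .maturation import featurize_sequences, project_pca

    n_cand = max(n_families * n_candidates_factor, n_families + 1)
    cores: list[dict] = []
    seqs: list[str] = []
    for _ in range(n_cand):
        core_pos = rng.choice(np.asarray(positions), size=core_size, replace=False)
        core = {}
        seq = list(template)
        for pos in core_pos:
            options = [aa for aa in _AA if aa != template[pos - 1]]
            aa = options[rng.integers(len(options))]
            core[int(pos)] = aa
            seq[pos - 1] = aa
        cores.append(core)
        seqs.append("".join(seq))
    coords = project_pca(featurize_sequences(seqs), n_components=2)
    chosen = [0]
    while len(chosen) < n_families:
        d = np.min(
            np.linalg.norm(coords[:, None, :] - coords[chosen][None, :, :], axis=2),
            axis=1,
        )
        d[chosen] = -1.0
        chosen.append(int(np.argmax(d)))
    return [cores[i] for i in chosen]


def gen_variant_pool(
    template: str,
    mutable_positions: Sequence[int],
    n: int,
    seed: int,
    duplicates_fraction: float = 0.0,
    n_unique: int | None = None,
    n_families: int = 0,
    reference_flexddg: float = 0.0,
    score_correlation: float = 0.6,
) -> pd.DataFrame:
    """Pool of point-mutated sequence variants with synthetic scores.

    Unique variants are single/double mutants of ``template`` restricted to
    ``mutable_positions``.  ``n_unique`` fixes the exact unique-sequence
    count (e.g. 1600 records with 89 unique); otherwise it is derived from
    ``duplicates_fraction``.  With ``n_families > 0`` each unique variant
    carries a family-specific core of five mutations (cores chosen mutually
    distant in descriptor space) plus one extra mutation, giving the pool a
    clusterable sequence-space structure, and
    family-specific score offsets make the best scores concentrate in the
    first two families.  ``mmpbsa`` and ``delta_flexddg`` share a latent
    factor giving rank correlation ≈ ``score_correlation``; ``ddg`` is an
    independent Normal(−25, 5).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not mutable_positions:
        raise ValueError("no mutable positions")
    if n_unique is None:
        n_unique = max(1, int(round(n * (1.0 - duplicates_fraction))))
    if n_unique > n:
        raise ValueError("n_unique cannot exceed n")
    rng = np.random.default_rng(seed)
    positions = list(mutable_positions)
    families: list[dict] = []
    if n_families > 0:
        if len(positions) < 5:
            raise ValueError("not enough mutable positions for family structure")
        families = _spread_family_cores(rng, template, positions, n_families)
    unique_seqs: list[str] = []
    family_of: list[int] = []
    seen = set()
    guard = 0
    while len(unique_seqs) < n_unique:
        guard += 1
        if guard > 100 * n_unique:
            raise RuntimeError("could not generate enough unique variants")
        if families:
            fam = int(rng.integers(len(families)))
            seq = list(template)
            for pos, aa in families[fam].items():
                seq[pos - 1] = aa
            seq = _mutate(rng, "".join(seq), positions, k=1)
        else:
            fam = -1
            seq = _mutate(rng, template, positions, k=int(rng.integers(1, 3)))
        if seq not in seen:
            seen.add(seq)
            unique_seqs.append(seq)
            family_of.append(fam)
    # distribute n records over the unique sequences (every unique appears)
    counts = np.ones(n_unique, dtype=int)
    extra = rng.multinomial(n - n_unique, np.full(n_unique, 1.0 / n_unique))
    counts += extra
    rows = []
    variations = [f"var{i + 1:02d}" for i in range(16)]
    for uid, (seq, fam, count) in enumerate(zip(unique_seqs, family_of, counts)):
        latent = rng.normal()
        # families 0 and 1 carry strongly favorable score offsets so the
        # dual-score stage concentrates its picks in those two families
        fam_shift = -40.0 if fam in (0, 1) else 0.0
        # shared-latent loading sqrt(rho) on both scores gives corr = rho
        a = np.sqrt(score_correlation)
        mmpbsa = -50.0 + fam_shift + 10.0 * (a * latent + np.sqrt(1 - a**2) * rng.normal())
        dflex = (-6.0 if fam in (0, 1) else 0.0) + 1.5 * (
            a * latent + np.sqrt(1 - a**2) * rng.normal()
        )
        for c in range(count):
            rows.append(
                {
                    "variant_id": f"v{uid:04d}_{c}",
                    "sequence": seq,
                    "variation_id": variations[int(rng.integers(len(variations)))],
                    "family": fam,
                    "ddg": rng.normal(-25.0, 5.0),
                    "mmpbsa": mmpbsa + rng.normal(0.0, 0.5),
                    "flexddg": reference_flexddg + dflex + rng.normal(0.0, 0.1),
                }
            )
    df = pd.DataFrame(rows)
    df["delta_flexddg"] = df["flexddg"] - reference_flexddg
    return df


def gen_toy_trajectory(
    reference: ChainModel,
    loopdef: LoopDefinition,
    displacement_schedule: Mapping[str, Sequence[float]],
    seed: int,
    noise: float = 0.0,
    rigid_motion: bool = False,
) -> list[ChainModel]:
    """Toy trajectory: framework fixed, loops displaced per schedule.

    ``displacement_schedule`` maps loop names (``CDR1``/``CDR2``/``CDR3``)
    to per-frame displacement magnitudes (Å); all schedules must share one
    length, which sets the frame count.  Displacements are rigid
    translations of the loop along a fixed random unit vector per loop, plus
    optional isotropic per-atom noise; ``rigid_motion`` additionally applies
    a random global rotation+translation to every frame (which framework
    superposition must cancel).
    """
    schedules = {k: np.asarray(v, dtype=float) for k, v in displacement_schedule.items()}
    unknown = set(schedules) - set(loopdef.loops)
    if unknown:
        raise ValueError(f"unknown loop(s) in schedule: {sorted(unknown)}")
    lengths = {len(v) for v in schedules.values()}
    if len(lengths) != 1:
        raise ValueError("all displacement schedules must have the same length")
    n_frames = lengths.pop()
    rng = np.random.default_rng(seed)
    directions = {}
    for loop in schedules:
        v = rng.normal(size=3)
        directions[loop] = v / np.linalg.norm(v)
    loop_residues = {
        loop: set(range(lo, hi + 1)) for loop, (lo, hi) in loopdef.loops.items()
    }
    frames = []
    for f in range(n_frames):
        if rigid_motion:
            a = rng.normal(size=3)
            a /= np.linalg.norm(a)
            theta = rng.uniform(0, 2 * np.pi)
            k = np.array(
                [[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]]
            )
            rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
            trans = rng.uniform(-20, 20, size=3)
        else:
            rot, trans = np.eye(3), np.zeros(3)
        residues = []
        for res in reference.residues:
            atoms = []
            for atom in res.atoms:
                xyz = atom.xyz.copy()
                for loop, sched in schedules.items():
                    if res.res_seq in loop_residues[loop]:
                        xyz = xyz + sched[f] * directions[loop]
                if noise > 0:
                    xyz = xyz + rng.normal(0.0, noise, size=3)
                xyz = xyz @ rot.T + trans
                atoms.append(replace(atom, xyz=xyz, model_no=f + 1))
            residues.append(Residue(res.res_name, res.res_seq, atoms))
        frames.append(ChainModel(chain_id=reference.chain_id, residues=residues))
    return frames
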