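"""Stage orchestration, configuration and run manifests.

Each pipeline stage reads its inputs from paths in a single YAML config,
writes its outputs under an output directory, and records a machine-readable
manifest (hashed inputs, parameters, in/out counts, package version) so a
run can be audited and reproduced.  All thresholds default to the pipeline's
published operating points but live in the config, never hard-coded in the
stage logic.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curation, fixtures, landscape, maturation, mdrmsd, selection, triage
from .mdrmsd import LoopDefinition
from .structio import read_pdb, write_pdb

__all__ = ["STAGES", "load_config", "run_stage"]

STAGES = (
    "curate",
    "triage",
    "landscape",
    "select-round1",
    "maturation",
    "seqspace",
    "md-rmsd",
    "simulate",
)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: dict, *keys: str) -> list:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ValueError(f"config missing required key(s): {', '.join(missing)}")
    return [cfg[k] for k in keys]


def _loopdef(cfg: dict) -> LoopDefinition:
    lcfg = cfg.get("loops")
    if lcfg is None:
        return fixtures.DEFAULT_LOOPDEF
    return LoopDefinition(
        cdr1=tuple(lcfg["cdr1"]),
        cdr2=tuple(lcfg["cdr2"]),
        cdr3=tuple(lcfg["cdr3"]),
        framework=tuple(tuple(r) for r in lcfg.get("framework", ())),
        atom_names=tuple(lcfg.get("atom_names", ("CA",))),
    )


def _write_manifest(
    out_dir: Path, stage: str, cfg: dict, inputs: list[Path], counts: dict
) -> dict:
    manifest = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "package_version": _pkg_version("nbselect"),
        "parameters": cfg,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "counts": counts,
    }
    with open(out_dir / f"{stage.replace('-', '_')}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_stage(stage: str, cfg: dict, out_dir, seed: int = 0) -> dict:
    """Run one named stage; returns its manifest.

    Raises ValueError for unknown stages or schema-invalid configs; no
    partial outputs are written on config errors (inputs are validated
    before any output file is opened).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {', '.join(STAGES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = {
        "curate": _run_curate,
        "triage": _run_triage,
        "landscape": _run_landscape,
        "select-round1": _run_select_round1,
        "maturation": _run_maturation,
        "seqspace": _run_seqspace,
        "md-rmsd": _run_md_rmsd,
        "simulate": _run_simulate,
    }[stage]
    return handler(cfg, out_dir, seed)


def _run_curate(cfg: dict, out_dir: Path, seed: int) -> dict:
    (metadata_path,) = _require(cfg, "metadata")
    df = curation.read_metadata_tsv(metadata_path)
    curator = curation.ChainCurator(**cfg.get("curation", {}))
    kept = curator.fit(df).transform(df)
    kept.to_csv(out_dir / "curated_chains.tsv", sep="\t", index=False)
    records = curation.dataframe_to_records(kept)
    curation.write_fasta(records, out_dir / "curated_chains.fasta")
    return _write_manifest(
        out_dir, "curate", cfg, [Path(metadata_path)],
        {"n_in": len(df), "n_retained": len(kept)},
    )


def _run_triage(cfg: dict, out_dir: Path, seed: int) -> dict:
    poses_path, competitor_path = _require(cfg, "poses", "competitor")
    scaffold_path = cfg.get("scaffold", competitor_path)
    thresholds = triage.TriageThresholds(**cfg.get("thresholds", {}))
    group_spec = cfg.get("group_spec", {"L": "ligand", "C": "competitor"})
    pose_models = read_pdb(poses_path, group_spec)
    competitor_atoms = read_pdb(competitor_path, group_spec)[0].group_atoms("competitor")
    scaffold_atoms = (
        read_pdb(scaffold_path, {"S": "scaffold"})[0].group_atoms("scaffold")
        if "scaffold" in cfg
        else competitor_atoms
    )
    poses = [
        triage.DockedPose(pose_id=f"pose-{m.model_no}", nanobody=m.group_chain("ligand"))
        for m in pose_models
    ]
    retained, report = triage.triage_poses(
        poses, competitor_atoms, scaffold_atoms, thresholds
    )
    report.to_csv(out_dir / "triage_report.tsv", sep="\t", index=False)
    return _write_manifest(
        out_dir, "triage", cfg, [Path(poses_path), Path(competitor_path)],
        {"n_in": len(poses), "n_retained": len(retained)},
    )


def _run_landscape(cfg: dict, out_dir: Path, seed: int) -> dict:
    (decoys_path,) = _require(cfg, "decoys")
    cohort = landscape.read_decoy_tsv(decoys_path)
    filt = landscape.FunnelFilter(**cfg.get("funnel", {}))
    filt.fit(cohort)
    filt.verdicts_.to_csv(out_dir / "funnel_verdicts.tsv", sep="\t", index=False)
    scores = pd.DataFrame(
        {
            "pose_id": [e.pose_id for e in cohort],
            "funnel_score": [
                landscape.funnel_score(e) if e.n >= 5 else float("nan")
                for e in cohort
            ],
        }
    )
    scores.to_csv(out_dir / "funnel_scores.tsv", sep="\t", index=False)
    return _write_manifest(
        out_dir, "landscape", cfg, [Path(decoys_path)],
        {"n_in": len(cohort), "n_retained": len(filt.retained_ids_)},
    )


def _run_select_round1(cfg: dict, out_dir: Path, seed: int) -> dict:
    (decoys_path,) = _require(cfg, "decoys")
    pool_df = pd.read_csv(decoys_path, sep="\t")
    # restrict the default scheme to ranking columns the table actually has
    full = selection.default_scheme(cfg.get("target_count", 16))
    sets = [
        cs
        for cs in full.criteria_sets
        if all(col in pool_df.columns for col, _ in cs.keys)
        and all(col in pool_df.columns for col in cs.filters)
    ]
    if not sets:
        raise ValueError("decoy table has none of the scheme's ranking columns")
    scheme = selection.SelectionScheme(sets, target_count=full.target_count)
    sel = selection.Round1Selector(
        k=cfg.get("k", 20),
        min_sasa=cfg.get("min_sasa", 800.0),
        scheme=scheme,
        target_count=cfg.get("target_count", 16),
    )
    sel.fit(pool_df)
    sel.candidates_.to_csv(out_dir / "round1_candidates.tsv", sep="\t", index=False)
    with open(out_dir / "round1_candidates.fasta", "w") as fh:
        for row in sel.candidates_.itertuples(index=False):
            fh.write(f">{row.design_id}\n{row.sequence}\n")
    return _write_manifest(
        out_dir, "select-round1", cfg, [Path(decoys_path)],
        {
            "n_in": len(pool_df),
            "n_pooled": len(sel.pool_),
            "n_candidates": len(sel.candidates_),
        },
    )


def _run_maturation(cfg: dict, out_dir: Path, seed: int) -> dict:
    (variants_path,) = _require(cfg, "variants")
    pool = pd.read_csv(variants_path, sep="\t")
    k = cfg.get("retain_k", 100)
    if "variation_id" in pool.columns and cfg.get("retain_lowest", True):
        pool = maturation.retain_lowest_k(pool, k)
    unique = maturation.dedupe_variants(pool)
    model = maturation.SequenceSpace(
        min_cluster_size=cfg.get("min_cluster_size", 5)
    ).fit(unique["sequence"].tolist())
    final = maturation.maturation_select(
        unique,
        model,
        n_score=cfg.get("n_score", 20),
        n_diversity=cfg.get("n_diversity", 3),
        excluded_clusters=cfg.get("excluded_clusters", ()),
    )
    unique.to_csv(out_dir / "nonredundant_variants.tsv", sep="\t", index=False)
    final.to_csv(out_dir / "maturation_candidates.tsv", sep="\t", index=False)
    with open(out_dir / "maturation_candidates.fasta", "w") as fh:
        for i, row in enumerate(final.itertuples(index=False)):
            fh.write(f">candidate_{i + 1}|{row.provenance}\n{row.sequence}\n")
    return _write_manifest(
        out_dir, "maturation", cfg, [Path(variants_path)],
        {
            "n_in": len(pool),
            "n_unique": len(unique),
            "n_candidates": len(final),
        },
    )


def _run_seqspace(cfg: dict, out_dir: Path, seed: int) -> dict:
    (variants_path,) = _require(cfg, "variants")
    pool = pd.read_csv(variants_path, sep="\t")
    unique = maturation.dedupe_variants(pool)
    model = maturation.SequenceSpace(
        min_cluster_size=cfg.get("min_cluster_size", 5)
    ).fit(unique["sequence"].tolist())
    out = unique.copy()
    out["pc1"] = model.coords_[:, 0]
    out["pc2"] = model.coords_[:, 1]
    out["cluster"] = model.labels_
    out.to_csv(out_dir / "sequence_space.tsv", sep="\t", index=False)
    return _write_manifest(
        out_dir, "seqspace", cfg, [Path(variants_path)],
        {
            "n_in": len(pool),
            "n_unique": len(unique),
            "n_clusters": len(model.centroids_),
        },
    )


def _run_md_rmsd(cfg: dict, out_dir: Path, seed: int) -> dict:
    trajectories, reference_path = _require(cfg, "trajectories", "reference")
    loopdef = _loopdef(cfg)
    group_spec = cfg.get("group_spec", {"A": "ligand"})
    reference = read_pdb(reference_path, group_spec)[0].group_chain("ligand")
    interval = cfg.get("interval_ps", 100.0)
    traces = []
    paths = [Path(p) for p in trajectories]
    for i, path in enumerate(paths):
        frames = [m.group_chain("ligand") for m in read_pdb(path, group_spec)]
        times = mdrmsd.snapshot_schedule(interval * len(frames), interval)
        traces.append(
            mdrmsd.cdr_rmsd_trace(
                frames, reference, loopdef, times=times, run_id=f"run{i + 1}"
            )
        )
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(
        out_dir / "rmsd_traces.tsv", sep="\t", index=False
    )
    agg = mdrmsd.aggregate_runs(traces, n_expected=cfg.get("n_runs", 5))
    agg.to_csv(out_dir / "rmsd_aggregate.tsv", sep="\t", index=False)
    return _write_manifest(
        out_dir, "md-rmsd", cfg, paths + [Path(reference_path)],
        {"n_runs": len(traces), "n_frames": len(traces[0].times)},
    )


def _run_simulate(cfg: dict, out_dir: Path, seed: int) -> dict:
    """Write synthetic fixtures (decoy tables, clash complexes, variant pools,
    trajectories) from a spec config, for exercising the other stages."""
    (kind,) = _require(cfg, "kind")
    counts: dict = {}
    if kind in {"funnel", "flat"}:
        n_poses = cfg.get("n_poses", 13)
        n = cfg.get("n_decoys", 200)
        ensembles = [
            fixtures.gen_decoy_ensemble(
                kind, n, seed=seed + i, pose_id=f"pose-{i + 1}",
                with_sequences=cfg.get("with_sequences", False),
            )
            for i in range(n_poses)
        ]
        landscape.write_decoy_tsv(ensembles, out_dir / "decoys.tsv")
        counts = {"n_poses": n_poses, "n_decoys": n_poses * n}
    elif kind == "clash_complex":
        cm = fixtures.gen_clash_complex(
            cfg.get("n_atoms", 100), cfg.get("planted_clashes", 3), seed
        )
        write_pdb([cm], out_dir / "clash_complex.pdb")
        counts = {"n_ligand_atoms": len(cm.group_atoms("ligand"))}
    elif kind == "variant_pool":
        df = fixtures.gen_variant_pool(
            cfg.get("template", fixtures.NANOBODY_TEMPLATE),
            cfg.get("mutable_positions", list(range(26, 36)) + list(range(50, 60)) + list(range(97, 110))),
            cfg.get("n", 1600),
            seed=seed,
            n_unique=cfg.get("n_unique"),
            n_families=cfg.get("n_families", 0),
        )
        df.to_csv(out_dir / "variants.tsv", sep="\t", index=False)
        counts = {"n": len(df), "n_unique": df["sequence"].nunique()}
    elif kind == "trajectory":
        chain = fixtures.make_toy_chain(cfg.get("n_res", 120), spacing=3.8)
        loopdef = _loopdef(cfg)
        n_frames = cfg.get("n_frames", 100)
        schedule = {"CDR3": np.where(np.arange(n_frames) >= n_frames // 2, 3.0, 0.0)}
        frames = fixtures.gen_toy_trajectory(chain, loopdef, schedule, seed=seed)
        from .structio import ComplexModel

        write_pdb(
            [ComplexModel(groups={"ligand": [f]}, model_no=i + 1) for i, f in enumerate(frames)],
            out_dir / "trajectory.pdb",
        )
        write_pdb([ComplexModel(groups={"ligand": [chain]})], out_dir / "reference.pdb")
        counts = {"n_frames": n_frames}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return _write_manifest(out_dir, "simulate", cfg, [], counts)
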