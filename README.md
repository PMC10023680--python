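# nbselect

Decision stages of a computational nanobody (VHH) dock-and-design campaign,
implemented as a tested, engine-agnostic pipeline.

A dock-and-design workflow targets a small antigen domain — here the kind of
problem posed by the Ras-binding domain (RBD) of ELMO1, whose natural partner
is the GTPase RhoG — by docking a library of curated nanobody scaffolds onto
the antigen, redesigning the CDR loops of promising poses, and selecting a
small panel of candidates for experimental binding assays.  The heavy
engines (PatchDock, RosettaDock/RosettaScripts, GROMACS, MM/PBSA, FlexddG)
produce poses, design decoys, score tables and trajectories; **nbselect**
implements everything *between* the engines — the curation, triage,
landscape analysis and selection logic that decides what moves forward:

* **curation** — filter candidate nanobody chains: X-ray < 2.5 Å, complete
  CDRs, camelid species, molecular weight < 20 kDa, sequence-unique.
* **triage** — reduce docked poses to "compatible" poses with a heavy-atom
  clashscore (atom pairs overlapping ≥ 0.4 Å, per 1000 pose atoms): overlap
  with the competitor GTPase ≥ 30 (the design must compete with the natural
  partner), steric hindrance with the scaffold domain < 10, all three CDRs
  in epitope contact, CDR1/CDR2 anchor-distance constraint.
* **landscape** — represent each pose's design ensemble as an RMSD-vs-ΔΔG
  binding-energy landscape and keep funnel-shaped ones: > 50 designs, RMSD
  and ΔΔG spreads in the top half of the cohort, and the energy-minimum
  design localized below the mean RMSD.  A closed-form funnel score in
  [0, 10] combines depth, localization and slope (Spearman ρ of RMSD vs
  ΔΔG) as a quantitative stand-in for visual landscape assessment.
* **selection** — pool the lowest-20 ΔΔG designs per pose (13 poses → 260),
  discard interfaces burying < 800 Å², and cycle through 12 heterogeneous
  criteria sets until 16 sequence-non-redundant candidates are picked.
* **maturation** — expand 4 binary design parameters into 16 variations,
  retain the lowest-100 ΔΔG variants each (→ 1600), deduplicate, reference
  FlexddG scores to the parent hit (ΔFlexddG), embed all variants in a 2-D
  sequence space (66 physicochemical descriptors per residue position →
  first two principal components → HDBSCAN clusters), and pick 20 dual-score
  winners plus 3 cluster-centroid representatives (→ 23 candidates).
* **mdrmsd** — MD post-processing: snapshot schedules (50 × 200 ps,
  100 × 100 ps over 10 ns), framework-Cα superposition, per-CDR backbone
  RMSD traces, mean ± range aggregation over n = 5 runs, and one-tailed
  pooled-variance t-tests of loop flexibility.
* **fixtures** — seed-deterministic synthetic generators (funnel/flat decoy
  ensembles, clash-planted atom clouds, mutant pools with planted structure,
  toy trajectories) that make every stage testable without any engine.

Tabular decision stages are scikit-learn-style estimators
(`ChainCurator`, `FunnelFilter`, `Round1Selector`, `SequenceSpace`) with
`fit`/`transform`/`get_params`; geometry primitives (Kabsch superposition,
clash counting, Shrake–Rupley SASA) are plain functions in
`nbselect.structio`.

## Worked example

```python
from nbselect import fixtures as fx
from nbselect.landscape import FunnelFilter, funnel_score
from nbselect.maturation import SequenceSpace, dedupe_variants, maturation_select

# four funnel-shaped pose ensembles and one flat one
cohort = [fx.gen_decoy_ensemble("funnel", 200, seed=i, pose_id=f"pose-{i+1}")
          for i in range(4)]
cohort.append(fx.gen_decoy_ensemble("flat", 200, seed=9, pose_id="pose-flat"))
filt = FunnelFilter().fit(cohort)
print("retained poses:", filt.retained_ids_)
for e in cohort:
    print(f"{e.pose_id}: funnel score {funnel_score(e):.2f}")

# maturation: 1600-record pool, 89 unique variants, 20 + 3 final candidates
mut = list(range(26, 36)) + list(range(50, 60)) + list(range(97, 110))
pool = fx.gen_variant_pool(fx.NANOBODY_TEMPLATE, mut, n=1600, seed=7,
                           n_unique=89, n_families=6)
unique = dedupe_variants(pool)
model = SequenceSpace(min_cluster_size=5).fit(unique["sequence"].tolist())
final = maturation_select(unique, model, n_score=20, n_diversity=3)
print(f"{len(pool)} records -> {len(unique)} unique -> {len(final)} candidates")
```

prints

```
retained poses: ['pose-2', 'pose-4']
pose-1: funnel score 7.99
pose-2: funnel score 8.16
pose-3: funnel score 8.40
pose-4: funnel score 8.34
pose-flat: funnel score 5.26
1600 records -> 89 unique -> 23 candidates
```

All five ensembles score by shape (the flat one clearly lower); the cohort-
relative spread criteria then keep only the poses whose landscapes are both
wide and deep *relative to the cohort*, which is stricter than the score
alone.  The maturation pool deduplicates to 89 unique variants, and the
two-stage pick returns 20 score-based plus 3 diversity candidates.

The same stages are scriptable from a shell via the `nbselect` CLI
(`simulate`, `curate`, `triage`, `landscape`, `select-round1`, `maturation`,
`seqspace`, `md-rmsd`), each taking `--config cfg.yaml --out-dir out --seed N`
and writing TSV/FASTA/PDB outputs plus a JSON run manifest.

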