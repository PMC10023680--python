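# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the numerical decisions a user may want to audit or override.

## Geometry primitives (`structio`)

**Clashscore.** A clash is an inter-set heavy-atom pair whose distance is
below `r_vdw(i) + r_vdw(j) − 0.4 Å`, with element radii C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 Å.  The clashscore normalizes the clash count per
1000 atoms of the *first* set — the pose being scored — so the triage
thresholds (≥ 30 against the competitor, < 10 against the scaffold) read as
"clashes per 1000 pose atoms".  This is a heavy-atom variant of the usual
all-atom contact score: crystal-derived inputs lack hydrogens and the
pipeline deliberately avoids a protonation engine.  Consequences: absolute
values are not interchangeable with hydrogen-aware implementations, and the
30/10 defaults are operating points, not physical constants — both the
radii table and the 0.4 Å overlap threshold are arguments.

**SASA.** Shrake–Rupley quadrature with a deterministic golden-spiral
(Fibonacci) point set, 960 points per atom, probe 1.4 Å (water).  The
deterministic point set makes every SASA value exactly reproducible.
Verified against closed forms: an isolated sphere is within 1% of
`4π(r+1.4)²` and a two-sphere overlap within 2% of the spherical-cap
formula.  Buried interface area is `SASA(A) + SASA(B) − SASA(A∪B)`,
nonnegative up to quadrature noise.

**Superposition.** Kabsch via SVD with a determinant correction, so the
returned rotation is always proper.  Fewer than 3 points or a collinear
reference raises (the rotation would be under-determined).  Superposition
for loop-RMSD traces anchors on the *framework* Cα atoms only: fitting on
the loop under measurement would absorb exactly the motion being
quantified.

**Molecular weight.** Average residue masses plus one water (18.02 Da),
matching hand sums (GG → 132.12 Da, A → 89.09 Da).  Used by curation's
< 20 kDa criterion.

**Coordinates.** PDB author numbering is kept as-is; every residue range in
the package is inclusive on both ends.  Multi-model PDB is the trajectory
format; mmCIF and hydrogen placement are out of scope.

## Curation

The five chain filters (X-ray, resolution strictly < 2.5 Å, complete CDRs,
camelid species by case-insensitive taxon match, MW strictly < 20 kDa) are
applied record-wise, then exact-sequence deduplication keeps the first
occurrence in input order.  Curation is idempotent and monotone: loosening
any single threshold can only grow the retained set.  Sequence redundancy
is exact identity; a similarity-threshold notion of redundancy would need a
clustering step that is deliberately not included.

## Triage

A pose is compatible iff competitor-overlap clashscore ≥ 30 AND scaffold
clashscore < 10 AND (optionally) all three CDRs have a heavy atom within
5.0 Å of the antigen.  The 5.0 Å contact cutoff is a conventional
heavy-atom contact distance and is config-exposed.  The CDR1/CDR2
anchor-residue check (Cα of residues 38 and 60 within 12 Å of the nearest
epitope atom) is a post-hoc geometric surrogate for the two-point distance
constraint an antibody-mode docking engine imposes during sampling; the
engine-side constraint is not reproducible downstream, but its geometric
intent is.  The per-pose report is exhaustive — every input pose appears
with all its scores regardless of retention — so discard reasons are always
auditable.

## Landscape selection

Per ensemble, the statistics are: sample (n−1) standard deviations of RMSD
and ΔΔG, and the RMSD of the minimum-ΔΔG decoy (ΔΔG ties broken toward the
lower RMSD).  The four funnel criteria: (1) n > 50 designs; (2) RMSD spread
≥ the cohort median; (3) ΔΔG spread ≥ the cohort median; (4) minimum-ΔΔG
RMSD < mean RMSD.  "Top half" is inclusive (≥ median) and the medians are
computed over criterion-(1) survivors only, because the count filter is
logically prior: an ensemble too small to characterize should not shift the
cohort's spread baseline.  Population-vs-sample std is a judgment call;
sample std was chosen and matters only at small n.

**Funnel score.**  `score = (10/3)·(f_depth + f_loc + f_slope)` with

* `f_depth = clamp01((median(ΔΔG) − min(ΔΔG)) / (max(ΔΔG) − min(ΔΔG)))`,
  defined as 0 for a zero-range (flat) ensemble;
* `f_loc = 1` if the minimum-ΔΔG decoy sits at RMSD ≤ 2 Å, otherwise
  `exp(−(RMSD − 2))`.  The 2 Å constant reflects the typical width of the
  steep native energy drop;
* `f_slope = clamp01(ρ)`, ρ = Spearman correlation of (RMSD, ΔΔG) over
  decoys with RMSD < 5 Å.  The sign convention is that a funnel — energy
  *falling* as RMSD falls — has *positive* rank correlation and scores
  high; 0 if fewer than 3 decoys are in range or either variable is
  constant.

The three components are equally weighted and all constants (2 Å, 5 Å,
weights) are arguments.  The score is a deterministic surrogate for visual
landscape assessment: it is monotone in funnel depth, invariant to decoy
relabeling, and separates the synthetic funnel and flat generators at
threshold 5 with ≈ 92% accuracy (measured over 200 seeded ensembles).  The
residual error is one-sided: a flat ensemble whose energy minimum lands at
low RMSD by chance (probability ≈ ¼ under the flat generator) collects the
full localization credit, so roughly one flat ensemble in six or seven
scores above 5.  Ensembles with funnel structure essentially never score
below it.

## Round-1 selection

Lowest-k pooling takes the k = 20 smallest-ΔΔG decoys per pose (ties:
RMSD, then design id); the buried-SASA filter discards < 800 Å² interfaces
(exactly 800 passes); the cycled pick iterates an ordered list of criteria
sets, each visit picking the top-ranked not-yet-picked design whose
sequence is new — redundant designs are skipped but not consumed, so a
later set could still pick a different design of the same rank.  The
shipped default scheme is the cross product of three rankings (ΔΔG ↑,
MM/PBSA ↑, funnel score ↓) and four hard-filter variants (none,
SASA ≥ 900, funnel score ≥ 5, MM/PBSA below the pool median), giving 12
sets.  The mechanism — diversification by cycling heterogeneously biased
rankings — is the point; the specific contents are configuration and can be
replaced wholesale via `SelectionScheme`.  All tie-breaking is
lexicographic (keys, RMSD, design id), so the stage is deterministic for a
fixed pool order.

## Affinity maturation

The parameter grid is the Cartesian product of four binary axes (force the
two hit-defining CDR mutations or not; design all CDRs or only CDR1/CDR2;
start from the parent scaffold or the first-round hit; design shell 10 or
12 Å), expanded in declaration order, off before on — 16 variations.  Per
variation the lowest-100 ΔΔG variants are retained; deduplication is on
exact sequence with the lowest-ΔΔG duplicate as representative.
ΔFlexddG = variant − reference, so negative means predicted improvement;
the sign is an argument because score conventions differ between engines.

**Sequence space.**  Each variant maps to the position-major concatenation
of a 66-vector per residue (66·L columns), is centered and projected onto
the first two principal components (component signs fixed so the
largest-magnitude loading is positive — a deterministic convention, since
SVD signs are otherwise arbitrary), and clustered with HDBSCAN
(`min_cluster_size` = 5 by default; noise = −1).  The clustering backend is
deterministic — no randomized initialization — so featurize → project →
cluster is a pure function of the inputs.

**Descriptor table.**  The shipped 20 × 66 table is a *synthetic stand-in*
(`descriptors.synthetic_descriptor_table`): six standardized real
physicochemical axes (Kyte–Doolittle hydropathy, side-chain volume, residue
mass, net charge, aromaticity, polarity) plus 60 seeded standardized
mixtures of those axes with orthogonal noise.  It preserves what the
embedding needs — fixed width, full rank, realistic inter-scale
correlation — but its columns are not the published descriptor collections
(Cruciani, Kidera, z-scales, FASGAI, T-scales, VHSE, ProtFP, ST-scales,
BLOSUM indices, MS-WHIM); users with those tables can pass any DataFrame
indexed by amino acid with 66 numeric columns and the rest of the stage is
unchanged.  Cluster *shapes* obtained with the stand-in are therefore
illustrative, while counts, determinism and the selection mechanics are
exact.

**Final selection.**  Stage 1 alternates between the MM/PBSA ranking and
the ΔFlexddG ranking (both ascending), taking the best remaining unique
sequence from each in turn until 20 picks — an explicit "best in either or
both scorings" rule.  Stage 2 adds the variant nearest each cluster
centroid for up to 3 clusters not yet represented by stage 1, largest
clusters first, skipping user-excluded clusters (cluster identities are
figure-level choices, so exclusion is always explicit configuration).  When
the score picks happen to touch most clusters and fewer unrepresented ones
remain than the quota, the stage tops up with the nearest unpicked member
of the least-represented clusters — the quota expresses a diversity budget,
not a hard constraint on cluster novelty.  Default total: 23.

## MD post-processing

Snapshot schedules exclude t₀, so a 10 ns run sampled every 200 ps yields
exactly 50 snapshots and every 100 ps yields 100.  Loop RMSD is computed
per frame after framework-Cα Kabsch superposition; the atom filter defaults
to Cα-only ("backbone Cα"), with an N/Cα/C/O backbone mode available.
Traces from independent runs (default n = 5) aggregate to mean and
[min, max] envelope per time point.  Flexibility comparison uses the
two-sample Student t-test with pooled variance, one-tailed in the stated
direction; Welch would be the safer default under variance heterogeneity
but pooled is the convention followed here and the choice is exposed.  Two
identical degenerate samples return (t = 0, p = 0.5) rather than NaN.

## Synthetic generators

Every generator takes an explicit seed and owns one `default_rng` stream;
identical spec + seed reproduces byte-identical output.

* *Decoy ensembles* — funnel kind: RMSD ~ |N(0, 2)| truncated to [0, 8] Å,
  ΔΔG = −10·exp(−(RMSD/1.5)²) + N(0, 1); flat kind: RMSD ~ U(0, 8),
  ΔΔG ~ N(0, 1) independent of RMSD.  These depths and widths emulate the
  documented size of native funnel landscapes relative to scoring noise.
  Buried SASA ~ N(950, 120) Å² so the 800 Å² filter bites on a realistic
  ~10% of designs.
* *Clash complexes* — ligand atoms on an 8 Å lattice (no internal
  contacts); exactly k competitor atoms planted at overlap 0.5 Å from
  distinct ligand atoms, all others ≥ 8 Å away, so the clash count is k by
  construction (3 planted among 100 pose atoms ⇒ clashscore exactly 30).
* *Variant pools* — single/double mutants restricted to the loop-position
  whitelist; an exact unique-sequence count can be requested (1600 records
  with 89 unique is the canonical case).  Family mode plants 5-mutation
  cores chosen mutually distant in the descriptor 2-PC plane plus one extra
  mutation per member, giving density-resolvable sequence clusters; the
  first two families carry strongly favorable MM/PBSA and ΔFlexddG offsets
  so score-based picks concentrate there and other clusters remain for the
  diversity stage.  MM/PBSA and ΔFlexddG share a latent factor with
  loading √ρ each, giving correlation ρ = 0.6.
* *Toy trajectories* — framework atoms fixed, loop atoms rigidly translated
  per schedule along a fixed random direction (+ optional per-atom noise
  and per-frame global rigid motion, which framework superposition must
  cancel to < 1e-6 Å).

What the generators do *not* emulate: physical energies (scores are
statistical stand-ins), rotamer-level structure, correlated engine failure
modes, or the composition of real docking decoy sets.  Passing tests
therefore demonstrate that the decision logic is correct and deterministic
under controlled structure — not that the thresholds would select the same
poses on real engine output.

## Problem sizes

The acceptance script uses the study's stated stage sizes where they are
cheap (13 × 5000 designs, 16 × lowest-100, 1600/89 pools, 100 + 100
ensembles for the separation measurement) and reduced synthetic sources
where only the arithmetic matters (300 generated variants per grid
variation before the lowest-100 cut).  The whole script runs in a few
seconds on one CPU.

## Known limitations

* Clashscore values are heavy-atom and not numerically comparable to
  hydrogen-aware contact scores; the 30/10 triage thresholds may need
  recalibration against any other implementation.
* The funnel score's localization term saturates at RMSD ≤ 2 Å; landscapes
  whose minimum sits just beyond it decay exponentially, which is a
  modeling choice, not a fitted constant.
* The 12 default criteria sets and the alternating dual-score rule are
  documented reconstructions of selection-scheme mechanisms whose exact
  published contents are configuration-level detail; both are fully
  overridable.
* Exact-identity sequence dedup may undercount redundancy relative to a
  similarity-threshold definition.
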