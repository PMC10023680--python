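"""Affinity-maturation design selection and sequence-space analysis.

Starting from a first-round hit, the design engine is run under all
combinations of four binary design parameters (16 parametric variations);
from each variation the lowest-100 ddg variants are retained (1600 records),
deduplicated on exact sequence, and re-scored with MM/PBSA and FlexddG.
ΔFlexddG references every variant's FlexddG to the parent hit (negative =
predicted improvement).  Final candidates are picked in two stages:

1. *score stage* — alternate between the MM/PBSA ranking and the ΔFlexddG
   ranking, taking the best remaining unique sequence from each in turn,
   until ``n_score`` (default 20) candidates are picked ("best in either or
   both" scorings);
2. *diversity stage* — embed all unique variants in a 2-D sequence space
   (66 physicochemical descriptors per position → first two principal
   components), cluster by density (HDBSCAN), and add the variant nearest to
   the centroid of each cluster not yet represented (up to ``n_diversity``,
   default 3, excluding user-specified clusters), giving 20 + 3 = 23
   candidates by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import HDBSCAN

from .descriptors import N_DESCRIPTORS, synthetic_descriptor_table

__all__ = [
    "DesignParameterGrid",
    "VariantRecord",
    "expand_grid",
    "retain_lowest_k",
    "dedupe_variants",
    "delta_flexddg",
    "featurize_sequences",
    "project_pca",
    "cluster_density",
    "nearest_to_centroid",
    "maturation_select",
    "validate_mutation_positions",
    "SequenceSpace",
]


@dataclass
class DesignParameterGrid:
    """Four binary design-parameter axes (order as declared; off < on)."""

    axes: dict[str, tuple] = field(
        default_factory=lambda: {
            "force_L29_K59": ("off", "on"),
            "cdr_scope": ("H1_H2_only", "all_CDRs"),
            "start_structure": ("parent_5LMW", "Nb01"),
            "design_shell": ("10A", "12A"),
        }
    )


def expand_grid(grid: DesignParameterGrid | dict | None = None) -> list[dict]:
    """Cartesian product of all grid axes, in deterministic declaration order."""
    if isinstance(grid, DesignParameterGrid):
        axes = grid.axes
    elif grid is None:
        axes = DesignParameterGrid().axes
    else:
        axes = grid
    names = list(axes)
    configs = []
    for i, combo in enumerate(itertools.product(*(axes[n] for n in names)), start=1):
        cfg = dict(zip(names, combo))
        cfg["variation_id"] = f"var{i:02d}"
        configs.append(cfg)
    return configs


@dataclass
class VariantRecord:
    """A designed sequence variant with its engine scores."""

    sequence: str
    variation_id: str
    ddg_binding: float
    mmpbsa: float = float("nan")
    flexddg: float = float("nan")
    delta_flexddg: float = float("nan")
    variant_id: str = ""


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "sequence": [v.sequence for v in variants],
            "variation_id": [v.variation_id for v in variants],
            "ddg": [v.ddg_binding for v in variants],
            "mmpbsa": [v.mmpbsa for v in variants],
            "flexddg": [v.flexddg for v in variants],
            "delta_flexddg": [v.delta_flexddg for v in variants],
        }
    )


def retain_lowest_k(
    per_variation: dict[str, pd.DataFrame] | pd.DataFrame, k: int = 100
) -> pd.DataFrame:
    """Per design variation, keep the k lowest-ddg variants; pool the rest.

    16 variations × k=100 gives the canonical 1600-record maturation pool.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(per_variation, pd.DataFrame):
        groups = list(per_variation.groupby("variation_id", sort=False))
    else:
        groups = list(per_variation.items())
    frames = []
    for vid, df in groups:
        if len(df) < k:
            warnings.warn(f"variation {vid}: only {len(df)} variants (< k={k})")
        frames.append(
            df.sort_values(["ddg", "sequence"], kind="mergesort").head(k)
        )
    return pd.concat(frames, ignore_index=True)


def dedupe_variants(pool: pd.DataFrame) -> pd.DataFrame:
    """Unique on exact sequence; representative = lowest-ddg duplicate."""
    if pool.empty:
        return pool.copy()
    unique = (
        pool.sort_values(["ddg", "sequence"], kind="mergesort")
        .drop_duplicates("sequence", keep="first")
        .reset_index(drop=True)
    )
    return unique


def delta_flexddg(variant_flexddg: float, reference_flexddg: float) -> float:
    """FlexddG change vs the reference design (negative = predicted improvement)."""
    if not np.isfinite(reference_flexddg):
        raise ValueError("missing or non-finite reference FlexddG")
    if not np.isfinite(variant_flexddg):
        raise ValueError("missing or non-finite variant FlexddG")
    return float(variant_flexddg - reference_flexddg)


# ---------------------------------------------------------------------------
# Sequence-space featurization, projection, clustering
# ---------------------------------------------------------------------------


def featurize_sequences(
    sequences: Sequence[str], descriptor_table: pd.DataFrame | None = None
) -> np.ndarray:
    """Concatenate the per-residue descriptor vectors position-major.

    Every sequence of length L maps to a row of length ``66·L``; column
    order is (position 1 descriptors..., position 2 descriptors..., ...).
    """
    table = descriptor_table if descriptor_table is not None else synthetic_descriptor_table()
    if table.shape[1] != N_DESCRIPTORS:
        raise ValueError(f"descriptor table must have {N_DESCRIPTORS} columns")
    if not sequences:
        raise ValueError("no sequences to featurize")
    length = len(sequences[0])
    values = table.to_numpy()
    index = {aa: i for i, aa in enumerate(table.index)}
    rows = np.empty((len(sequences), length * N_DESCRIPTORS))
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, expected {length}"
            )
        try:
            rows[i] = values[[index[aa] for aa in seq]].ravel()
        except KeyError as exc:
            raise ValueError(f"sequence {i}: unknown residue {exc.args[0]!r}") from exc
    return rows


def project_pca(matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Project onto the top principal components with a deterministic sign.

    Columns are centered; each component's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("zero-variance matrix")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:n_components]
    signs = np.sign(components[np.arange(len(components)), np.argmax(np.abs(components), axis=1)])
    components = components * signs[:, None]
    return centered @ components.T


def cluster_density(
    coords: np.ndarray, min_cluster_size: int = 5
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Density clustering (HDBSCAN) of the 2-D projection.

    Returns ``(labels, centroids)`` with noise labelled −1 and centroid =
    mean coordinates of each cluster's members.  The backend is
    deterministic (no randomized initialization).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < min_cluster_size:
        warnings.warn(
            f"only {len(coords)} points (< min_cluster_size={min_cluster_size}); "
            "labelling all as noise"
        )
        return np.full(len(coords), -1), {}
    if np.allclose(coords, coords[0]):  # degenerate: all points identical
        labels = np.zeros(len(coords), dtype=int)
        return labels, {0: coords[0].copy()}
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(coords)
    centroids = {
        int(lab): coords[labels == lab].mean(axis=0)
        for lab in np.unique(labels)
        if lab != -1
    }
    return labels, centroids


def nearest_to_centroid(
    coords: np.ndarray,
    labels: np.ndarray,
    centroids: dict[int, np.ndarray],
    cluster_label: int,
) -> int:
    """Index of the cluster member closest to its centroid (tie → lowest index)."""
    if cluster_label == -1:
        raise ValueError("noise label (-1) has no centroid")
    if cluster_label not in centroids:
        raise KeyError(f"no cluster labelled {cluster_label}")
    members = np.flatnonzero(labels == cluster_label)
    d = np.linalg.norm(coords[members] - centroids[cluster_label], axis=1)
    return int(members[np.argmin(d)])


class SequenceSpace(BaseEstimator, TransformerMixin):
    """Sequence-space model: descriptors → 2-PC projection → density clusters.

    Fitted attributes: ``matrix_`` (variants × 66·L descriptors),
    ``coords_`` (variants × 2), ``labels_`` (−1 = noise), ``centroids_``.
    """

    def __init__(
        self,
        descriptor_table: pd.DataFrame | None = None,
        n_components: int = 2,
        min_cluster_size: int = 5,
    ):
        self.descriptor_table = descriptor_table
        self.n_components = n_components
        self.min_cluster_size = min_cluster_size

    def fit(self, sequences: Sequence[str], y=None):
        self.matrix_ = featurize_sequences(list(sequences), self.descriptor_table)
        self.coords_ = project_pca(self.matrix_, self.n_components)
        self.labels_, self.centroids_ = cluster_density(
            self.coords_, self.min_cluster_size
        )
        return self

    def transform(self, sequences: Sequence[str] | None = None) -> np.ndarray:
        if sequences is None:
            return self.coords_
        matrix = featurize_sequences(list(sequences), self.descriptor_table)
        # re-project onto the fitted components
        centered_fit = self.matrix_ - self.matrix_.mean(axis=0)
        u, s, vt = np.linalg.svd(centered_fit, full_matrices=False)
        comps = vt[: self.n_components]
        signs = np.sign(comps[np.arange(len(comps)), np.argmax(np.abs(comps), axis=1)])
        comps = comps * signs[:, None]
        return (matrix - self.matrix_.mean(axis=0)) @ comps.T

    def fit_transform(self, sequences, y=None):
        return self.fit(sequences).transform()


# ---------------------------------------------------------------------------
# Final candidate selection
# ---------------------------------------------------------------------------


def maturation_select(
    variants: pd.DataFrame,
    model: SequenceSpace | None = None,
    n_score: int = 20,
    n_diversity: int = 3,
    excluded_clusters: Sequence[int] = (),
) -> pd.DataFrame:
    """Two-stage final selection: alternating dual-score picks + cluster picks.

    Stage 1 alternates between the MM/PBSA and ΔFlexddG rankings (both
    ascending: lower = better) taking the best remaining unique sequence from
    each until ``n_score`` picks.  Stage 2 adds the nearest-to-centroid
    variant of up to ``n_diversity`` non-excluded clusters not represented by
    stage 1 (largest clusters first); if fewer unrepresented clusters exist,
    it tops up with the nearest unpicked member of the least-represented
    clusters so the diversity quota is met whenever unpicked sequences
    remain.  ``provenance`` records each pick.  The model must have been fit
    on the variant sequences in the same row order as ``variants``.
    """
    if variants.empty:
        raise ValueError("empty variant pool")
    for col in ("sequence", "mmpbsa", "delta_flexddg"):
        if col not in variants.columns:
            raise ValueError(f"variant table missing column {col!r}")
    pool = variants.reset_index(drop=True)
    rank_mm = pool.sort_values(
        ["mmpbsa", "delta_flexddg", "sequence"], kind="mergesort"
    ).index.tolist()
    rank_fx = pool.sort_values(
        ["delta_flexddg", "mmpbsa", "sequence"], kind="mergesort"
    ).index.tolist()
    picked_idx: list[int] = []
    provenance: list[str] = []
    picked_seqs: set[str] = set()
    rankings = itertools.cycle([("mmpbsa", rank_mm), ("delta_flexddg", rank_fx)])
    pointers = {"mmpbsa": 0, "delta_flexddg": 0}
    stalled = 0
    while len(picked_idx) < n_score and stalled < 2:
        name, order = next(rankings)
        ptr = pointers[name]
        while ptr < len(order) and pool.loc[order[ptr], "sequence"] in picked_seqs:
            ptr += 1
        pointers[name] = ptr
        if ptr >= len(order):
            stalled += 1
            continue
        stalled = 0
        idx = order[ptr]
        picked_idx.append(idx)
        picked_seqs.add(pool.loc[idx, "sequence"])
        provenance.append(f"score:{name}")
    if len(picked_idx) < n_score:
        warnings.warn(
            f"only {len(picked_idx)} unique sequences available for the "
            f"score stage (requested {n_score})"
        )
    if model is not None and n_diversity > 0:
        labels = model.labels_
        centroids = model.centroids_
        excluded = set(excluded_clusters)
        represented = {int(labels[i]) for i in picked_idx if labels[i] != -1}
        by_size = sorted(centroids, key=lambda l: (-(labels == l).sum(), l))
        # one pick per cluster not yet represented, largest first; if fewer
        # such clusters exist than n_diversity, top up with the next-nearest
        # unpicked member of the least-represented clusters so the diversity
        # quota is still met
        pick_counts = {lab: int(np.sum(labels[picked_idx] == lab)) for lab in by_size}
        queue = [lab for lab in by_size if lab not in represented and lab not in excluded]
        queue += sorted(
            (lab for lab in by_size if lab in represented and lab not in excluded),
            key=lambda l: (pick_counts[l], l),
        )
        added = 0
        for lab in queue:
            if added >= n_diversity:
                break
            members = np.flatnonzero(labels == lab)
            d = np.linalg.norm(model.coords_[members] - centroids[lab], axis=1)
            for idx in members[np.argsort(d, kind="stable")]:
                if pool.loc[idx, "sequence"] not in picked_seqs:
                    picked_idx.append(int(idx))
                    picked_seqs.add(pool.loc[idx, "sequence"])
                    provenance.append(f"cluster:{lab}")
                    added += 1
                    break
        if added < n_diversity:
            warnings.warn(
                f"only {added} cluster picks available for the diversity "
                f"stage (requested {n_diversity})"
            )
    out = pool.loc[picked_idx].copy()
    out["provenance"] = provenance
    return out.reset_index(drop=True)


def validate_mutation_positions(
    variant: str, template: str, allowed_positions: Sequence[int]
) -> tuple[bool, list[int]]:
    """Check that all variant/template differences lie in a position whitelist.

    Positions are 1-based.  This is how the avoid-mutating-beta-strands rule
    is represented: the whitelist is the loop (CDR) positions.
    """
    if len(variant) != len(template):
        raise ValueError(
            f"length mismatch: variant {len(variant)} vs template {len(template)}"
        )
    allowed = set(allowed_positions)
    offending = [
        i + 1
        for i, (v, t) in enumerate(zip(variant, template))
        if v != t and (i + 1) not in allowed
    ]
    return not offending, offending
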