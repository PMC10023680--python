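"""First-round design selection.

From each selected pose's design ensemble the lowest-k (default 20) decoys
by ddg are pooled; designs burying less than 800 Å² of interface are
discarded; the remainder is reduced to a fixed number (default 16) of
sequence-non-redundant final candidates by cycling through an ordered list
of heterogeneous criteria sets — each set ranks the pool by its own keys
(ddg, MM/PBSA, funnel score, …) and may impose hard filters, and each visit
picks the top not-yet-picked design whose sequence is new.  Cycling across
differently-biased criteria sets is what diversifies the final panel.

Tie-breaking everywhere is lexicographic on (ranking keys, rmsd, design_id),
so the whole stage is deterministic for a fixed pool order and scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .landscape import LandscapeEnsemble

__all__ = [
    "CriteriaSet",
    "SelectionScheme",
    "default_scheme",
    "per_pose_lowest_k",
    "sasa_filter",
    "cycled_pick",
    "Round1Selector",
]


@dataclass
class CriteriaSet:
    """One ranking recipe: ordered sort keys plus optional hard filters.

    ``keys`` is a list of ``(column, ascending)`` pairs; ``filters`` maps a
    column to a ``(op, value)`` pair with op in {">=", "<=", ">", "<"}.  A
    value of ``"median"`` is resolved against the current pool.
    """

    set_id: int
    keys: list[tuple[str, bool]]
    filters: dict[str, tuple[str, float | str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError(f"criteria set {self.set_id}: needs at least one key")


@dataclass
class SelectionScheme:
    criteria_sets: list[CriteriaSet]
    target_count: int = 16

    def __post_init__(self) -> None:
        if self.target_count < 1:
            raise ValueError("target_count must be >= 1")
        if not self.criteria_sets:
            raise ValueError("scheme needs at least one criteria set")


def default_scheme(target_count: int = 16) -> SelectionScheme:
    """Default 12-set scheme: {ddg, mmpbsa, funnel_score} × 4 filter variants.

    The published selection used 12 criteria sets combining binding-energy
    ranks, MM/PBSA estimates and landscape assessment; their exact contents
    are configuration, not ground truth.  This default preserves the
    mechanism — cycling heterogeneous rankings — and is fully overridable.
    """
    rankings = [
        [("ddg", True)],
        [("mmpbsa", True)],
        [("funnel_score", False)],
    ]
    filter_variants: list[dict] = [
        {},
        {"sasa": (">=", 900.0)},
        {"funnel_score": (">=", 5.0)},
        {"mmpbsa": ("<=", "median")},
    ]
    sets = []
    set_id = 1
    for filt in filter_variants:
        for keys in rankings:
            sets.append(CriteriaSet(set_id=set_id, keys=list(keys), filters=dict(filt)))
            set_id += 1
    return SelectionScheme(criteria_sets=sets, target_count=target_count)


def per_pose_lowest_k(
    ensembles: Sequence[LandscapeEnsemble] | pd.DataFrame, k: int = 20
) -> pd.DataFrame:
    """Pool the k lowest-ddg decoys of every pose (ties → rmsd, design_id).

    Accepts a list of ensembles or an already-tabulated decoy DataFrame with
    a ``pose_id`` column (extra score columns are carried through).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(ensembles, pd.DataFrame):
        groups = [(pid, grp) for pid, grp in ensembles.groupby("pose_id", sort=False)]
    else:
        groups = [(e.pose_id, e.to_frame()) for e in ensembles]
    frames = []
    for pose_id, df in groups:
        if len(df) < k:
            warnings.warn(
                f"pose {pose_id}: only {len(df)} decoys (< k={k}); keeping all"
            )
        df = df.sort_values(
            ["ddg", "rmsd", "design_id"], kind="mergesort"
        ).head(k)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["design_id", "pose_id", "sequence", "rmsd", "ddg", "sasa", "total_score"]
        )
    return pd.concat(frames, ignore_index=True)


def sasa_filter(designs: pd.DataFrame, min_sasa: float = 800.0) -> pd.DataFrame:
    """Discard designs whose buried interface SASA is below ``min_sasa``.

    The boundary is kept: exactly 800 Å² passes ("less than 800" discarded).
    """
    if designs.empty:
        return designs.copy()
    if "sasa" not in designs.columns:
        raise ValueError("designs table has no 'sasa' column")
    bad = designs["sasa"].isna()
    if bad.any():
        names = designs.loc[bad, "design_id"].tolist()
        raise ValueError(f"missing buried SASA for design(s): {names}")
    return designs[designs["sasa"] >= min_sasa].reset_index(drop=True)


def _apply_filters(pool: pd.DataFrame, cset: CriteriaSet) -> pd.DataFrame:
    out = pool
    for col, (op, value) in cset.filters.items():
        if col not in out.columns:
            raise ValueError(f"criteria set {cset.set_id}: column {col!r} missing")
        if isinstance(value, str) and value == "median":
            value = float(pool[col].median())
        series = out[col]
        if op == ">=":
            out = out[series >= value]
        elif op == "<=":
            out = out[series <= value]
        elif op == ">":
            out = out[series > value]
        elif op == "<":
            out = out[series < value]
        else:
            raise ValueError(f"unknown filter op {op!r}")
    return out


def cycled_pick(pool: pd.DataFrame, scheme: SelectionScheme) -> pd.DataFrame:
    """Cycle through criteria sets, picking one new-sequence design per visit.

    Returns the picked designs in pick order, with a ``picked_by_set``
    column.  Stops at ``scheme.target_count`` or when a full cycle yields no
    pick (pool exhausted of non-redundant sequences).
    """
    if pool.empty:
        raise ValueError("empty design pool")
    for cset in scheme.criteria_sets:
        for col, _ in cset.keys:
            if col not in pool.columns:
                raise ValueError(
                    f"criteria set {cset.set_id}: ranking column {col!r} missing"
                )
    picked_rows = []
    picked_ids: set = set()
    picked_seqs: set = set()
    while len(picked_rows) < scheme.target_count:
        progressed = False
        for cset in scheme.criteria_sets:
            if len(picked_rows) >= scheme.target_count:
                break
            candidates = pool[
                ~pool["design_id"].isin(picked_ids)
                & ~pool["sequence"].isin(picked_seqs)
            ]
            candidates = _apply_filters(candidates, cset)
            if candidates.empty:
                continue
            sort_cols = [c for c, _ in cset.keys]
            ascending = [a for _, a in cset.keys]
            for tie_col in ("rmsd", "design_id"):
                if tie_col in candidates.columns and tie_col not in sort_cols:
                    sort_cols.append(tie_col)
                    ascending.append(True)
            top = candidates.sort_values(
                sort_cols, ascending=ascending, kind="mergesort"
            ).iloc[0]
            row = top.to_dict()
            row["picked_by_set"] = cset.set_id
            picked_rows.append(row)
            picked_ids.add(top["design_id"])
            picked_seqs.add(top["sequence"])
            progressed = True
        if not progressed:
            warnings.warn(
                f"pool exhausted after {len(picked_rows)} non-redundant picks "
                f"(target {scheme.target_count})"
            )
            break
    return pd.DataFrame(picked_rows).reset_index(drop=True)


class Round1Selector(BaseEstimator):
    """Sklearn-style wrapper for the full round-1 selection stage.

    ``fit`` runs lowest-k pooling, the buried-SASA filter, and cycled
    multi-criteria picking; the final candidates are in ``candidates_`` and
    the intermediate pool in ``pool_``.
    """

    def __init__(
        self,
        k: int = 20,
        min_sasa: float = 800.0,
        scheme: SelectionScheme | None = None,
        target_count: int = 16,
    ):
        self.k = k
        self.min_sasa = min_sasa
        self.scheme = scheme
        self.target_count = target_count

    def fit(self, ensembles: Sequence[LandscapeEnsemble] | pd.DataFrame, y=None):
        scheme = self.scheme or default_scheme(self.target_count)
        pool = per_pose_lowest_k(ensembles, self.k)
        pool = sasa_filter(pool, self.min_sasa)
        self.pool_ = pool
        self.candidates_ = cycled_pick(pool, scheme)
        return self

    def transform(self, ensembles=None) -> pd.DataFrame:
        return self.candidates_

    def fit_transform(self, ensembles, y=None):
        return self.fit(ensembles).transform()
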