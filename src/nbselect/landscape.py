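"""Binding-energy-landscape representation and funnel selection.

For each compatible docked pose, the design engine samples an ensemble of
design decoys, each with a backbone RMSD to the initial pose and an
interface binding-energy change (ddg).  A native-like pose shows a
funnel-shaped RMSD-vs-ddg landscape: energy falls as the decoys approach the
initial pose.  This module applies the four funnel criteria used to select
poses and computes a closed-form funnel score in [0, 10] that stands in for
visual landscape assessment.

Funnel criteria (a pose passes only if all four hold):

1. more than ``min_designs`` decoys were generated (strict >, default 50);
2. the ensemble's RMSD standard deviation is within the highest 50% of the
   cohort (≥ cohort median), i.e. the landscape is not too narrow;
3. the ddg standard deviation is within the highest 50% (≥ median), i.e. the
   landscape is not too shallow;
4. the decoy with the minimum ddg lies at an RMSD below the ensemble's mean
   RMSD, i.e. the energy minimum localizes near the initial pose.

Cohort medians for (2) and (3) are computed over the ensembles that pass
criterion (1).  Standard deviations are sample (n−1) values.

The funnel score is ``(10/3)·(f_depth + f_loc + f_slope)`` where

* ``f_depth = clamp01((median(ddg) − min(ddg)) / (max(ddg) − min(ddg)))`` —
  funnel depth relative to the energy spread (0 for a flat landscape);
* ``f_loc = 1`` if the minimum-ddg decoy sits at RMSD ≤ 2 Å, decaying as
  ``exp(−(rmsd − 2))`` beyond — the energy minimum must localize near the
  reference pose;
* ``f_slope = clamp01(ρ)`` with ρ the Spearman correlation of (rmsd, ddg)
  over decoys with RMSD < 5 Å — positive rank correlation means the energy
  falls toward low RMSD, the funnel signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "DesignDecoy",
    "LandscapeEnsemble",
    "FunnelCriteria",
    "ensemble_stats",
    "funnel_filter",
    "funnel_score",
    "FunnelFilter",
    "read_decoy_tsv",
    "write_decoy_tsv",
]


@dataclass
class DesignDecoy:
    """One dock-and-design decoy with its engine scores."""

    design_id: str
    pose_id: str
    rmsd_to_initial: float  # backbone RMSD vs the initial pose, Å
    ddg_binding: float  # interface binding energy change, engine units
    sequence: str = ""
    buried_sasa: float = float("nan")  # Å²
    total_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.rmsd_to_initial < 0:
            raise ValueError(f"{self.design_id}: negative rmsd")


@dataclass
class LandscapeEnsemble:
    """All design decoys sampled from one initial pose."""

    pose_id: str
    decoys: list[DesignDecoy]

    def __post_init__(self) -> None:
        for d in self.decoys:
            if d.pose_id != self.pose_id:
                raise ValueError(
                    f"decoy {d.design_id} has pose_id {d.pose_id!r}, "
                    f"ensemble is {self.pose_id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.decoys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "design_id": [d.design_id for d in self.decoys],
                "pose_id": self.pose_id,
                "sequence": [d.sequence for d in self.decoys],
                "rmsd": [d.rmsd_to_initial for d in self.decoys],
                "ddg": [d.ddg_binding for d in self.decoys],
                "sasa": [d.buried_sasa for d in self.decoys],
                "total_score": [d.total_score for d in self.decoys],
            }
        )


@dataclass
class FunnelCriteria:
    min_designs: int = 50  # criterion 1 is strict >
    spread_percentile: float = 0.50
    require_localization: bool = True  # criterion 4

    def __post_init__(self) -> None:
        if not 0 < self.spread_percentile < 1:
            raise ValueError("spread_percentile must be in (0, 1)")


def ensemble_stats(ensemble: LandscapeEnsemble) -> dict[str, float]:
    """Summary statistics of one landscape ensemble.

    ``rmsd_at_min_ddg`` is the RMSD of the minimum-ddg decoy; ddg ties are
    broken by the lowest RMSD.
    """
    if ensemble.n == 0:
        raise ValueError(f"ensemble {ensemble.pose_id}: no decoys")
    rmsd = np.array([d.rmsd_to_initial for d in ensemble.decoys])
    ddg = np.array([d.ddg_binding for d in ensemble.decoys])
    order = np.lexsort((rmsd, ddg))  # primary: ddg, tie-break: rmsd
    best = order[0]
    return {
        "n": ensemble.n,
        "rmsd_mean": float(rmsd.mean()),
        "rmsd_std": float(rmsd.std(ddof=1)) if ensemble.n > 1 else 0.0,
        "ddg_std": float(ddg.std(ddof=1)) if ensemble.n > 1 else 0.0,
        "rmsd_at_min_ddg": float(rmsd[best]),
        "min_ddg": float(ddg[best]),
    }


def funnel_filter(
    cohort: Sequence[LandscapeEnsemble], criteria: FunnelCriteria | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the four funnel criteria across a cohort of pose ensembles.

    Returns the retained pose ids and a per-pose verdict table recording
    every criterion.  The spread medians (criteria 2 and 3) are computed over
    the ensembles that pass criterion 1.
    """
    if not cohort:
        raise ValueError("empty cohort")
    criteria = criteria or FunnelCriteria()
    stats_rows = {e.pose_id: ensemble_stats(e) for e in cohort}
    pass1 = {pid: s["n"] > criteria.min_designs for pid, s in stats_rows.items()}
    survivors = [pid for pid, ok in pass1.items() if ok]
    if not survivors:
        warnings.warn("no ensemble passes the minimum-design-count criterion")
        median_rmsd_std = median_ddg_std = np.nan
    else:
        q = 1.0 - criteria.spread_percentile
        median_rmsd_std = float(
            np.quantile([stats_rows[p]["rmsd_std"] for p in survivors], q)
        )
        median_ddg_std = float(
            np.quantile([stats_rows[p]["ddg_std"] for p in survivors], q)
        )
    rows = []
    retained = []
    for e in cohort:
        s = stats_rows[e.pose_id]
        c1 = pass1[e.pose_id]
        c2 = bool(c1 and s["rmsd_std"] >= median_rmsd_std)
        c3 = bool(c1 and s["ddg_std"] >= median_ddg_std)
        c4 = bool(s["rmsd_at_min_ddg"] < s["rmsd_mean"])
        keep = c1 and c2 and c3 and (c4 or not criteria.require_localization)
        rows.append(
            {
                "pose_id": e.pose_id,
                **s,
                "c1_count": c1,
                "c2_rmsd_spread": c2,
                "c3_ddg_spread": c3,
                "c4_localized": c4,
                "retained": keep,
            }
        )
        if keep:
            retained.append(e.pose_id)
    return retained, pd.DataFrame(rows)


def _clamp01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def funnel_score(
    ensemble: LandscapeEnsemble,
    loc_rmsd: float = 2.0,
    slope_rmsd_max: float = 5.0,
) -> float:
    """Closed-form funnel score in [0, 10] (higher = more funnel-like).

    Equal-weight sum of depth, localization and slope components (see module
    docstring), scaled by 10/3.  Requires at least 5 decoys.
    """
    if ensemble.n < 5:
        raise ValueError("funnel_score needs at least 5 decoys")
    rmsd = np.array([d.rmsd_to_initial for d in ensemble.decoys])
    ddg = np.array([d.ddg_binding for d in ensemble.decoys])
    rng = float(ddg.max() - ddg.min())
    if rng == 0.0:
        f_depth = 0.0
    else:
        f_depth = _clamp01((float(np.median(ddg)) - float(ddg.min())) / rng)
    s = ensemble_stats(ensemble)
    r_min = s["rmsd_at_min_ddg"]
    f_loc = 1.0 if r_min <= loc_rmsd else float(np.exp(-(r_min - loc_rmsd)))
    near = rmsd < slope_rmsd_max
    if near.sum() >= 3 and len(set(rmsd[near])) > 1 and len(set(ddg[near])) > 1:
        rho = stats.spearmanr(rmsd[near], ddg[near]).statistic
        f_slope = _clamp01(rho) if np.isfinite(rho) else 0.0
    else:
        f_slope = 0.0
    return (10.0 / 3.0) * (f_depth + f_loc + f_slope)


class FunnelFilter(BaseEstimator):
    """Sklearn-style cohort filter for funnel-shaped landscapes.

    ``fit`` learns the cohort-relative spread medians; ``transform`` returns
    the retained ensembles.  The per-pose verdict table is available as
    ``verdicts_`` after fitting.
    """

    def __init__(
        self,
        min_designs: int = 50,
        spread_percentile: float = 0.50,
        require_localization: bool = True,
    ):
        self.min_designs = min_designs
        self.spread_percentile = spread_percentile
        self.require_localization = require_localization

    def fit(self, cohort: Sequence[LandscapeEnsemble], y=None):
        criteria = FunnelCriteria(
            min_designs=self.min_designs,
            spread_percentile=self.spread_percentile,
            require_localization=self.require_localization,
        )
        self.retained_ids_, self.verdicts_ = funnel_filter(cohort, criteria)
        return self

    def transform(
        self, cohort: Sequence[LandscapeEnsemble]
    ) -> list[LandscapeEnsemble]:
        retained = set(self.retained_ids_)
        return [e for e in cohort if e.pose_id in retained]

    def fit_transform(self, cohort, y=None):
        return self.fit(cohort).transform(cohort)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_DECOY_COLUMNS = ["design_id", "pose_id", "sequence", "rmsd", "ddg", "sasa", "total_score"]


def write_decoy_tsv(ensembles: Sequence[LandscapeEnsemble], path) -> None:
    pd.concat([e.to_frame() for e in ensembles], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_decoy_tsv(path) -> list[LandscapeEnsemble]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_DECOY_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"decoy table missing column(s): {sorted(missing)}")
    ensembles = []
    for pose_id, grp in df.groupby("pose_id", sort=False):
        decoys = [
            DesignDecoy(
                design_id=str(r.design_id),
                pose_id=str(pose_id),
                sequence="" if pd.isna(r.sequence) else str(r.sequence),
                rmsd_to_initial=float(r.rmsd),
                ddg_binding=float(r.ddg),
                buried_sasa=float(getattr(r, "sasa", float("nan"))),
                total_score=float(getattr(r, "total_score", float("nan"))),
            )
            for r in grp.itertuples(index=False)
        ]
        ensembles.append(LandscapeEnsemble(pose_id=str(pose_id), decoys=decoys))
    return ensembles
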