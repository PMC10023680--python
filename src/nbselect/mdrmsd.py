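"""MD post-processing: CDR loop flexibility from trajectory snapshots.

Given multi-model PDB trajectories of the unbound nanobody, this module
extracts snapshot schedules, superposes each frame onto a reference using
the framework Cα atoms (so that loop motion is not absorbed by the fit),
computes per-CDR backbone-Cα RMSD traces, aggregates independent production
runs as mean plus min/max range, and tests loop-flexibility differences with
a one-tailed two-sample Student t-test (pooled variance).

The superposition anchor is deliberately the framework, not the loop under
measurement: fitting on the loop itself would hide exactly the flexibility
being quantified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structio import (
    AtomSelection,
    ChainModel,
    ComplexModel,
    kabsch_superpose,
    selection_rmsd,
)

__all__ = [
    "LoopDefinition",
    "RmsdTrace",
    "snapshot_schedule",
    "cdr_rmsd_trace",
    "aggregate_runs",
    "compare_flexibility",
]

#: Backbone atom names for the full-backbone RMSD mode.
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class LoopDefinition:
    """CDR and framework residue ranges (inclusive, author numbering).

    ``atom_names`` is the atom filter used for superposition and RMSD;
    the default is Cα-only (``("CA",)``); pass :data:`BACKBONE_ATOMS` for the
    full-backbone variant.
    """

    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]
    framework: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        cdr_res = set()
        for lo, hi in (self.cdr1, self.cdr2, self.cdr3):
            cdr_res.update(range(lo, hi + 1))
        fw_res = set()
        for lo, hi in self.framework:
            fw_res.update(range(lo, hi + 1))
        if cdr_res & fw_res:
            raise ValueError("CDR and framework residue ranges overlap")

    @property
    def loops(self) -> dict[str, tuple[int, int]]:
        return {"CDR1": self.cdr1, "CDR2": self.cdr2, "CDR3": self.cdr3}

    def loop_selection(self, loop: str) -> AtomSelection:
        return AtomSelection([self.loops[loop]], self.atom_names)

    def framework_selection(self) -> AtomSelection:
        if not self.framework:
            raise ValueError("no framework ranges defined")
        return AtomSelection(list(self.framework), self.atom_names)


@dataclass
class RmsdTrace:
    """Per-loop backbone RMSD time series for one MD run."""

    run_id: str
    times: np.ndarray  # ps
    rmsd: dict[str, np.ndarray]  # loop name -> Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for loop, values in self.rmsd.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{loop}: trace length differs from times")
            if np.any(arr < 0):
                raise ValueError(f"{loop}: negative RMSD")
            self.rmsd[loop] = arr

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, **self.rmsd}).assign(
            run_id=self.run_id
        )


def snapshot_schedule(
    t_end: float, interval: float, include_t0: bool = False
) -> np.ndarray:
    """Snapshot times (ps): interval, 2·interval, …, t_end.

    With the default ``include_t0=False`` a 10 ns run sampled every 200 ps
    yields exactly 50 snapshots, and every 100 ps yields 100.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if t_end < interval:
        raise ValueError("t_end must be at least one interval")
    n = int(np.floor(t_end / interval + 1e-9))
    if abs(n * interval - t_end) > 1e-9 * max(1.0, t_end):
        warnings.warn(
            f"t_end={t_end} is not a multiple of interval={interval}; "
            f"scheduling up to {n * interval}",
            stacklevel=2,
        )
    times = interval * np.arange(1, n + 1)
    if include_t0:
        times = np.concatenate([[0.0], times])
    return times


def _as_chain(frame, group: str) -> ChainModel:
    if isinstance(frame, ComplexModel):
        return frame.group_chain(group)
    return frame


def _check_topology(chain: ChainModel, reference: ChainModel) -> None:
    ref_res = [(r.res_seq, r.res_name) for r in reference.residues]
    frm_res = [(r.res_seq, r.res_name) for r in chain.residues]
    if ref_res != frm_res:
        for a, b in zip(ref_res, frm_res):
            if a != b:
                raise ValueError(
                    f"topology mismatch at residue {a[0]} ({a[1]} vs {b[1]})"
                )
        raise ValueError(
            f"topology mismatch: {len(ref_res)} vs {len(frm_res)} residues"
        )


def cdr_rmsd_trace(
    trajectory: Sequence[ChainModel | ComplexModel],
    reference: ChainModel | ComplexModel,
    loopdef: LoopDefinition,
    times: np.ndarray | None = None,
    run_id: str = "run",
    group: str = "ligand",
) -> RmsdTrace:
    """Per-CDR RMSD trace after framework-Cα superposition of each frame."""
    ref_chain = _as_chain(reference, group)
    fw_sel = loopdef.framework_selection()
    ref_fw = np.array([a.xyz for a in fw_sel.resolve(ref_chain)])
    if times is None:
        times = np.arange(1, len(trajectory) + 1, dtype=float)
    traces: dict[str, list[float]] = {loop: [] for loop in loopdef.loops}
    for frame in trajectory:
        chain = _as_chain(frame, group)
        _check_topology(chain, ref_chain)
        frm_fw = np.array([a.xyz for a in fw_sel.resolve(chain)])
        rot, trans, _ = kabsch_superpose(frm_fw, ref_fw)
        fitted = _transform_chain(chain, rot, trans)
        for loop in loopdef.loops:
            sel = loopdef.loop_selection(loop)
            traces[loop].append(selection_rmsd(fitted, ref_chain, sel))
    return RmsdTrace(
        run_id=run_id,
        times=np.asarray(times, dtype=float),
        rmsd={loop: np.array(v) for loop, v in traces.items()},
    )


def _transform_chain(chain: ChainModel, rot: np.ndarray, trans: np.ndarray) -> ChainModel:
    from dataclasses import replace

    residues = []
    for res in chain.residues:
        atoms = [
            replace(a, xyz=a.xyz @ rot.T + trans) for a in res.atoms
        ]
        residues.append(type(res)(res.res_name, res.res_seq, atoms))
    return ChainModel(chain_id=chain.chain_id, residues=residues)


def aggregate_runs(traces: Sequence[RmsdTrace], n_expected: int = 5) -> pd.DataFrame:
    """Per-time mean and [min, max] envelope per loop over independent runs.

    Mirrors the convention of reporting the mean and the range over n = 5
    independent production runs.
    """
    if not traces:
        raise ValueError("no traces to aggregate")
    if len(traces) != n_expected:
        warnings.warn(
            f"aggregating {len(traces)} runs (expected {n_expected})", stacklevel=2
        )
    times = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError(f"time grid of run {tr.run_id} differs")
    rows = []
    for loop in traces[0].rmsd:
        stack = np.vstack([tr.rmsd[loop] for tr in traces])
        rows.append(
            pd.DataFrame(
                {
                    "loop": loop,
                    "time_ps": times,
                    "mean": stack.mean(axis=0),
                    "min": stack.min(axis=0),
                    "max": stack.max(axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def compare_flexibility(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-tailed independent two-sample Student t-test (pooled variance).

    ``alternative="greater"`` tests whether sample A is more flexible (larger
    RMSD) than sample B.  Two identical degenerate samples return
    ``(0.0, 0.5)`` by convention.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if alternative not in {"greater", "less"}:
        raise ValueError("alternative must be 'greater' or 'less'")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 0.5
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(t), float(p)
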