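"""Per-residue physicochemical descriptor table (synthetic stand-in).

The sequence-space featurization concatenates, per residue position, a
vector of 66 amino-acid descriptors.  Published descriptor collections of
that size (Cruciani properties, Kidera factors, z-scales, FASGAI, T-scales,
VHSE, ProtFP, ST-scales, BLOSUM indices, MS-WHIM) are tabulated in external
software that is not bundled here, so this module ships a *synthetic*
66-column stand-in built deterministically from a small set of real
physicochemical axes — Kyte–Doolittle hydropathy, residue side-chain
volume, residue mass, net charge at neutral pH, aromaticity and a
polarity indicator — mixed with seeded, standardized pseudo-scales.  The
stand-in preserves what the featurization needs: a fixed 20 × 66 table with
realistic inter-scale correlation structure and full rank.

Any user-supplied table (a DataFrame indexed by one-letter amino acid with
66 numeric columns, e.g. the published collections) can be passed to
``featurize_sequences`` in its place.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = ["AMINO_ACIDS", "N_DESCRIPTORS", "synthetic_descriptor_table"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_DESCRIPTORS = 66

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
# mean side-chain volumes, A^3
_VOL = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
# average residue masses, Da
_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14, "Q": 128.13,
    "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16, "L": 113.16, "K": 128.17,
    "M": 131.19, "F": 147.18, "P": 97.12, "S": 87.08, "T": 101.10, "W": 186.21,
    "Y": 163.18, "V": 99.13,
}
_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS} | {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_AROMATIC = {aa: 0.0 for aa in AMINO_ACIDS} | {"F": 1.0, "W": 1.0, "Y": 1.0, "H": 0.5}
_POLAR = {aa: 0.0 for aa in AMINO_ACIDS} | {
    aa: 1.0 for aa in "STNQCYHKRDE"
}

_TABLE_SEED = 660  # fixed: the table is a versioned artifact, not a dial


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


@lru_cache(maxsize=1)
def synthetic_descriptor_table() -> pd.DataFrame:
    """Deterministic synthetic 20 × 66 amino-acid descriptor table.

    Columns ``sd01``–``sd66``; rows indexed by one-letter amino acid.  The
    first six columns are standardized real physicochemical axes; the rest
    are seeded random mixtures of those axes with orthogonal noise
    (weights 0.6 / 0.4), standardized per column.
    """
    base = np.column_stack(
        [
            _standardize(np.array([d[aa] for aa in AMINO_ACIDS]))
            for d in (_KD, _VOL, _MASS, _CHARGE, _AROMATIC, _POLAR)
        ]
    )
    rng = np.random.default_rng(_TABLE_SEED)
    cols = [base[:, i] for i in range(base.shape[1])]
    while len(cols) < N_DESCRIPTORS:
        weights = rng.normal(size=base.shape[1])
        mix = base @ weights / np.linalg.norm(weights)
        noise = rng.normal(size=base.shape[0])
        cols.append(_standardize(0.6 * mix + 0.4 * noise))
    table = pd.DataFrame(
        np.column_stack(cols[:N_DESCRIPTORS]),
        index=list(AMINO_ACIDS),
        columns=[f"sd{i + 1:02d}" for i in range(N_DESCRIPTORS)],
    )
    table.index.name = "aa"
    return table
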