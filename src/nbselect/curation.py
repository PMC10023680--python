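"""Candidate nanobody chain curation.

Before docking, candidate chains harvested from structure databases are
filtered down to high-quality, sequence-unique camelid nanobodies:

1. X-ray crystal structures only,
2. resolution better than 2.5 Å,
3. all three CDR loops fully resolved,
4. camelid species only,
5. chain molecular weight under 20 kDa,

followed by exact-sequence deduplication (first occurrence kept, in input
order).  Species matching is case-insensitive on the provided taxon strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .structio import chain_molecular_weight

__all__ = [
    "CAMELID_SPECIES",
    "ChainMetadata",
    "CurationCriteria",
    "curate_chains",
    "ChainCurator",
    "read_metadata_tsv",
    "write_fasta",
]

#: Allowed camelid taxa (matched case-insensitively).
CAMELID_SPECIES = (
    "Camelidae",
    "Camelus Dromedarius",
    "Lama",
    "Lama Glama",
    "Vicugna Pacos",
)


@dataclass
class ChainMetadata:
    pdb_id: str
    chain_id: str
    method: str
    species: str
    sequence: str
    resolution: float | None = None
    cdr_complete: tuple[bool, bool, bool] = (True, True, True)


@dataclass
class CurationCriteria:
    max_resolution: float = 2.5  # strict <
    max_weight: float = 20000.0  # Da, strict <
    allowed_species: tuple[str, ...] = CAMELID_SPECIES
    require_xray: bool = True
    require_complete_cdrs: bool = True
    dedupe: bool = True


def _passes(rec: ChainMetadata, criteria: CurationCriteria) -> bool:
    if criteria.require_xray:
        if rec.method.strip().lower() not in {"x-ray", "xray", "x-ray diffraction"}:
            return False
        if rec.resolution is None:
            warnings.warn(
                f"{rec.pdb_id}:{rec.chain_id} is X-ray but has no resolution; "
                "treated as failing the resolution criterion",
                stacklevel=3,
            )
            return False
    if rec.resolution is not None and not rec.resolution > 0:
        raise ValueError(f"{rec.pdb_id}:{rec.chain_id}: resolution must be > 0")
    if rec.resolution is not None and rec.resolution >= criteria.max_resolution:
        return False
    if criteria.require_complete_cdrs and not all(rec.cdr_complete):
        return False
    allowed = {s.lower() for s in criteria.allowed_species}
    if rec.species.strip().lower() not in allowed:
        return False
    if chain_molecular_weight(rec.sequence) >= criteria.max_weight:
        return False
    return True


def curate_chains(
    records: list[ChainMetadata], criteria: CurationCriteria | None = None
) -> list[ChainMetadata]:
    """Apply the five curation criteria, then deduplicate on exact sequence."""
    if not records:
        raise ValueError("no records to curate")
    criteria = criteria or CurationCriteria()
    kept = [r for r in records if _passes(r, criteria)]
    if not criteria.dedupe:
        return kept
    seen: set[str] = set()
    unique: list[ChainMetadata] = []
    for rec in kept:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            unique.append(rec)
    return unique


class ChainCurator(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the curation filter to a DataFrame.

    Expects columns ``pdb_id, chain_id, method, resolution, species, sequence,
    cdr1_complete, cdr2_complete, cdr3_complete``.
    """

    def __init__(
        self,
        max_resolution: float = 2.5,
        max_weight: float = 20000.0,
        allowed_species: tuple[str, ...] = CAMELID_SPECIES,
        require_xray: bool = True,
        require_complete_cdrs: bool = True,
        dedupe: bool = True,
    ):
        self.max_resolution = max_resolution
        self.max_weight = max_weight
        self.allowed_species = allowed_species
        self.require_xray = require_xray
        self.require_complete_cdrs = require_complete_cdrs
        self.dedupe = dedupe

    def _criteria(self) -> CurationCriteria:
        return CurationCriteria(
            max_resolution=self.max_resolution,
            max_weight=self.max_weight,
            allowed_species=tuple(self.allowed_species),
            require_xray=self.require_xray,
            require_complete_cdrs=self.require_complete_cdrs,
            dedupe=self.dedupe,
        )

    def fit(self, X: pd.DataFrame, y=None):
        self.n_input_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        records = dataframe_to_records(X)
        kept = curate_chains(records, self._criteria())
        kept_keys = {(r.pdb_id, r.chain_id) for r in kept}
        mask = [
            (row.pdb_id, row.chain_id) in kept_keys for row in X.itertuples(index=False)
        ]
        return X.loc[mask].reset_index(drop=True)


def dataframe_to_records(df: pd.DataFrame) -> list[ChainMetadata]:
    records = []
    for row in df.itertuples(index=False):
        resolution = getattr(row, "resolution", None)
        if resolution is not None and pd.isna(resolution):
            resolution = None
        records.append(
            ChainMetadata(
                pdb_id=str(row.pdb_id),
                chain_id=str(row.chain_id),
                method=str(row.method),
                species=str(row.species),
                sequence=str(row.sequence),
                resolution=None if resolution is None else float(resolution),
                cdr_complete=(
                    bool(row.cdr1_complete),
                    bool(row.cdr2_complete),
                    bool(row.cdr3_complete),
                ),
            )
        )
    return records


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a chain-metadata table (TSV with the ChainCurator columns)."""
    return pd.read_csv(path, sep="\t")


def write_fasta(records: list[ChainMetadata], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.pdb_id}_{rec.chain_id}\n{rec.sequence}\n")
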