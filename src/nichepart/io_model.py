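"""Domain types, delimited-text I/O, and run configuration.

The pipeline operates on four tables, all plain TSV/CSV with a header row:

* a detection table (samples x MOTUs, read counts or binary occurrence),
* sample metadata (colony, predator species, collection date, sample type),
* per-MOTU taxonomic assignments (identity/coverage scores, taxonomy path,
  curation flags),
* prey trait and colony habitat-composition tables used by the trait stage.

Everything downstream consumes the typed containers defined here.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SPECIES",
    "SEASONS",
    "SAMPLE_TYPES",
    "ASSIGNED_RANKS",
    "CURATION_FLAGS",
    "RunConfig",
    "DetectionTable",
    "MotuAssignment",
    "assign_season",
    "read_detection_table",
    "write_detection_table",
    "read_assignments",
    "write_assignments",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_habitat_table",
    "write_habitat_table",
    "file_digest",
]

#: The three sympatric long-eared bat (Plecotus) predators.
SPECIES = ("auritus", "austriacus", "macrobullaris")

#: Seasons of the maternity-roost activity period, in calendar order.
SEASONS = ("spring", "summer", "autumn")

SAMPLE_TYPES = ("community", "smaller")

ASSIGNED_RANKS = ("species", "genus", "family", "order", "unassigned")

#: Curation flags a MOTU assignment may carry; flagged MOTUs never enter the
#: curated detection table.
CURATION_FLAGS = ("contaminant", "coprophage", "secondary_prey", "predator_dna")

#: Six habitat classes describing colony surroundings (compositional).
HABITAT_CLASSES = (
    "urbanized",
    "wetlands_water",
    "lawns_isolated_trees",
    "grasslands_prairies",
    "forest_shrub",
    "farmland",
)


@dataclass
class RunConfig:
    """Thresholds, permutation counts and seeds shared across the pipeline.

    Parameters
    ----------
    per_sample_rel_abundance : float
        Within-sample relative-abundance cutoff; cells carrying strictly less
        than this fraction of the sample's total reads are zeroed.  Default
        1e-4 (0.1 per mille), matching the recovery-bias magnitude reported
        for metabarcoding mock communities.
    min_reads_per_motu : int
        MOTUs with a data-set-wide read total strictly below this are
        dropped.  Default 5.
    species_identity, species_coverage : float
        BLAST score thresholds (percent) for species-level assignment.
    genus_identity, family_identity : float
        Lower identity tiers for genus- and family-level assignment.
    n_permutations : int
        Permutations for every randomization test (production default 9999).
    alpha : float
        Significance level.
    rng_seed : int
        Seed recorded in every run report.
    season_boundaries : tuple
        Four (month, day) pairs delimiting the half-open season intervals
        [start, summer), [summer, autumn), [autumn, end).
    """

    per_sample_rel_abundance: float = 1e-4
    min_reads_per_motu: int = 5
    species_identity: float = 99.0
    species_coverage: float = 98.0
    genus_identity: float = 96.0
    family_identity: float = 90.0
    n_permutations: int = 9999
    alpha: float = 0.05
    rng_seed: int = 0
    sampling_year: int = 2015
    season_boundaries: tuple = ((4, 15), (6, 15), (8, 15), (10, 16))
    chao2_bias_corrected: bool = False
    wpoo_weighting: bool = True
    distance_sqrt: bool = False
    alr_reference: str = "farmland"

    def __post_init__(self) -> None:
        if not 0.0 < self.per_sample_rel_abundance < 1.0:
            raise ValueError("per_sample_rel_abundance must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if len(self.season_boundaries) != 4:
            raise ValueError("season_boundaries needs 4 (month, day) pairs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_boundaries"] = [list(b) for b in self.season_boundaries]
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "season_boundaries" in raw:
            raw["season_boundaries"] = tuple(
                tuple(b) for b in raw["season_boundaries"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def assign_season(date: _dt.date, config: RunConfig | None = None) -> str:
    """Map a collection date to spring, summer or autumn.

    The sampling window runs mid-April to mid-October; seasons are the
    half-open intervals [Apr 15, Jun 15) spring, [Jun 15, Aug 15) summer and
    [Aug 15, Oct 16) autumn by default.  Dates outside the window raise
    ``ValueError``.
    """
    config = config or RunConfig()
    y = date.year
    b = [_dt.date(y, m, d) for m, d in config.season_boundaries]
    if not (b[0] <= date < b[3]):
        raise ValueError(
            f"date {date.isoformat()} outside the sampling window "
            f"[{b[0].isoformat()}, {b[3].isoformat()})"
        )
    if date < b[1]:
        return "spring"
    if date < b[2]:
        return "summer"
    return "autumn"


@dataclass
class DetectionTable:
    """Samples x MOTUs read counts (or binary occurrence) with metadata.

    ``counts`` is indexed by sample_id with one column per MOTU;
    ``meta`` is indexed by sample_id with columns colony_id, species, date,
    season and sample_type.  Rows of both frames are aligned.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate sample_id(s): {list(dups)}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate MOTU column(s): {list(dups)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        missing = self.counts.index.difference(self.meta.index)
        if len(missing):
            raise KeyError(
                f"sample(s) missing from metadata: {sorted(missing)}"
            )
        self.meta = self.meta.loc[self.counts.index]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def motu_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def is_binary(self) -> bool:
        vals = self.counts.to_numpy()
        return bool(((vals == 0) | (vals == 1)).all())

    def subset(self, sample_ids: Sequence[str]) -> "DetectionTable":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.counts.index)
        if len(missing):
            raise KeyError(f"unknown sample(s): {sorted(missing)}")
        return DetectionTable(
            self.counts.loc[ids].copy(), self.meta.loc[ids].copy()
        )

    def copy(self) -> "DetectionTable":
        return DetectionTable(self.counts.copy(), self.meta.copy())


@dataclass(frozen=True)
class MotuAssignment:
    """Best-hit summary and taxonomy for one MOTU."""

    motu_id: str
    best_identity: float
    best_coverage: float
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""
    assigned_rank: str = "unassigned"
    n_best_hits: int = 1
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, v in (("identity", self.best_identity),
                        ("coverage", self.best_coverage)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"best_{name} {v} outside [0, 100]")
        bad = set(self.flags) - set(CURATION_FLAGS) - {"no_match"}
        if bad:
            raise ValueError(f"unknown flag(s): {sorted(bad)}")


# ---------------------------------------------------------------------------
# Readers / writers.  All tables are UTF-8 delimited text with a header row;
# the delimiter is sniffed from the extension (.csv -> comma, else tab).
# ---------------------------------------------------------------------------

def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_detection_table(
    path: str | Path, metadata_path: str | Path
) -> DetectionTable:
    """Read a samples x MOTUs table and join its sample metadata.

    The detection file's first column is the sample_id; the metadata file
    must cover every sample row (a missing sample is a hard error naming it).
    """
    counts = pd.read_csv(path, sep=_sep(path), index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    meta = read_sample_metadata(metadata_path)
    return DetectionTable(counts, meta)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=_sep(path), index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique()
        raise ValueError(f"duplicate sample_id(s) in metadata: {list(dups)}")
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"]).dt.date
        if "season" not in meta.columns:
            meta["season"] = [assign_season(d) for d in meta["date"]]
    return meta


def write_detection_table(
    table: DetectionTable, path: str | Path, metadata_path: str | Path
) -> None:
    table.counts.to_csv(path, sep=_sep(path), index_label="sample_id")
    table.meta.to_csv(metadata_path, sep=_sep(metadata_path),
                      index_label="sample_id")


def read_assignments(path: str | Path) -> dict[str, MotuAssignment]:
    """Read per-MOTU assignment records keyed by motu_id.

    Flags are a semicolon-separated list in the ``flags`` column (empty for
    none).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str).fillna("")
    out: dict[str, MotuAssignment] = {}
    for _, row in df.iterrows():
        rec = MotuAssignment(
            motu_id=row["motu_id"],
            best_identity=float(row["best_identity"]),
            best_coverage=float(row["best_coverage"]),
            order=row.get("order", ""),
            family=row.get("family", ""),
            genus=row.get("genus", ""),
            species=row.get("species", ""),
            assigned_rank=row.get("assigned_rank", "unassigned") or "unassigned",
            n_best_hits=int(row.get("n_best_hits", "1") or 1),
            flags=frozenset(f for f in row.get("flags", "").split(";") if f),
        )
        if rec.motu_id in out:
            raise ValueError(f"duplicate motu_id {rec.motu_id}")
        out[rec.motu_id] = rec
    return out


def write_assignments(
    assignments: Mapping[str, MotuAssignment], path: str | Path
) -> None:
    rows = []
    for rec in assignments.values():
        d = dataclasses.asdict(rec)
        d["flags"] = ";".join(sorted(rec.flags))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_trait_matrix(path: str | Path) -> pd.DataFrame:
    """Prey x trait matrix: binary habitat traits, ordinal size (1-3) and a
    binary night-flying flag."""
    q = pd.read_csv(path, sep=_sep(path), index_col=0)
    q.index = q.index.astype(str)
    validate_trait_matrix(q)
    return q


def validate_trait_matrix(q: pd.DataFrame) -> None:
    for col in q.columns:
        vals = set(q[col].unique())
        if col == "size":
            if not vals <= {1, 2, 3}:
                raise ValueError(f"size values outside {{1,2,3}}: {vals}")
        elif not vals <= {0, 1}:
            raise ValueError(f"non-binary trait column {col!r}: {vals}")


def write_trait_matrix(q: pd.DataFrame, path: str | Path) -> None:
    q.to_csv(path, sep=_sep(path), index_label="prey_id")


def read_habitat_table(path: str | Path, *, atol: float = 1e-9) -> pd.DataFrame:
    """Colony x habitat-class proportions; each row must sum to 1."""
    h = pd.read_csv(path, sep=_sep(path), index_col=0)
    h.index = h.index.astype(str)
    validate_habitat_table(h, atol=atol)
    return h


def validate_habitat_table(h: pd.DataFrame, *, atol: float = 1e-9) -> None:
    sums = h.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > atol]
    if len(bad):
        raise ValueError(
            f"habitat rows not summing to 1: {dict(bad.round(6))}"
        )
    if (h.to_numpy() < 0).any():
        raise ValueError("negative habitat proportions")


def write_habitat_table(h: pd.DataFrame, path: str | Path) -> None:
    h.to_csv(path, sep=_sep(path), index_label="colony_id")


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run-report input provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
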