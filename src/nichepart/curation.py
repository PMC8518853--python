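"""Curation of raw MOTU detection tables.

Three rules turn a raw read-count table into the curated prey data set:

1. within each sample, cells carrying strictly less than a relative-abundance
   threshold (default 0.1 per mille) of that sample's total reads are zeroed,
   and MOTUs with a data-set-wide total strictly below a minimum read count
   (default 5) are dropped;
2. MOTUs flagged as reference-database misses, predator DNA, environmental
   contaminants, coprophages or secondary prey are excluded;
3. the surviving counts are reduced to binary occurrence for all diet
   statistics.

Taxonomic rank assignment follows tiered identity/coverage thresholds:
species at >=98% coverage and >=99% identity, genus above 96% identity,
family above 90%; ambiguous multi-taxon best hits demote one rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import CURATION_FLAGS, DetectionTable, MotuAssignment, RunConfig

__all__ = [
    "CurationReport",
    "filter_low_abundance",
    "assign_taxonomy",
    "apply_exclusions",
    "to_occurrence",
    "curate",
]

#: First-matching rule precedence for attribution in the curation report.
RULE_ORDER = (
    "no_match",
    "predator_dna",
    "contaminant",
    "coprophage",
    "secondary_prey",
    "low_abundance",
)


@dataclass
class CurationReport:
    """Accounting of what curation removed and why.

    ``removed_by_rule`` attributes every removed MOTU to exactly one rule
    (first match in :data:`RULE_ORDER`); removed + retained equals the input
    MOTU count.
    """

    n_motus_input: int = 0
    n_motus_retained: int = 0
    removed_by_rule: dict = field(
        default_factory=lambda: {r: 0 for r in RULE_ORDER}
    )
    reads_before: dict = field(default_factory=dict)
    reads_after: dict = field(default_factory=dict)
    cells_zeroed_low_abundance: int = 0
    samples_dropped: list = field(default_factory=list)
    empty_samples_after: list = field(default_factory=list)

    @property
    def n_motus_removed(self) -> int:
        return sum(self.removed_by_rule.values())

    def check(self) -> None:
        if self.n_motus_removed + self.n_motus_retained != self.n_motus_input:
            raise AssertionError("curation accounting does not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_motus_input": self.n_motus_input,
            "n_motus_retained": self.n_motus_retained,
            "n_motus_removed": self.n_motus_removed,
            "removed_by_rule": dict(self.removed_by_rule),
            "cells_zeroed_low_abundance": self.cells_zeroed_low_abundance,
            "reads_before_total": int(sum(self.reads_before.values())),
            "reads_after_total": int(sum(self.reads_after.values())),
            "samples_dropped": list(self.samples_dropped),
            "empty_samples_after": list(self.empty_samples_after),
        }


def filter_low_abundance(
    table: DetectionTable,
    rel_threshold: float = 1e-4,
    min_reads: int = 5,
    report: CurationReport | None = None,
    sample_totals: pd.Series | None = None,
) -> DetectionTable:
    """Zero sub-threshold cells and drop rare MOTUs.

    Within each sample, cells with count strictly less than
    ``rel_threshold`` times that sample's total reads are zeroed ("less
    than" is strict: a cell exactly at the cutoff is retained).  MOTUs whose
    data-set-wide total is strictly below ``min_reads`` are dropped, as are
    columns left all-zero.  Samples with zero total reads are dropped with a
    warning.

    ``sample_totals`` fixes the per-sample denominators; by default the
    table's own row totals are used.  Passing the raw (pre-exclusion) totals
    reproduces the sequencing-stage filter, where the cutoff is taken
    against everything a sample yielded, and makes the filter commute with
    flag-based column exclusions.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if table.counts.empty:
        raise ValueError("empty detection table")
    counts = table.counts.astype(np.int64).copy()
    meta = table.meta.copy()

    totals = (
        sample_totals.loc[counts.index]
        if sample_totals is not None
        else counts.sum(axis=1)
    )
    empty = totals[totals == 0].index
    if len(empty):
        warnings.warn(
            f"dropping sample(s) with zero reads: {sorted(empty)}",
            stacklevel=2,
        )
        counts = counts.drop(index=empty)
        meta = meta.drop(index=empty)
        totals = totals.drop(index=empty)
        if report is not None:
            report.samples_dropped.extend(sorted(empty))

    if report is not None:
        report.reads_before = {s: int(t) for s, t in totals.items()}

    # per-sample cutoff; strict "<" semantics
    cutoff = totals.to_numpy()[:, None] * rel_threshold
    vals = counts.to_numpy()
    below = (vals > 0) & (vals < cutoff)
    vals = np.where(below, 0, vals)
    counts = pd.DataFrame(vals, index=counts.index, columns=counts.columns)

    motu_totals = counts.sum(axis=0)
    keep = motu_totals[(motu_totals >= min_reads) & (motu_totals > 0)].index
    dropped = counts.columns.difference(keep)
    counts = counts[keep]

    if report is not None:
        report.cells_zeroed_low_abundance += int(below.sum())
        report.removed_by_rule["low_abundance"] += len(dropped)
        report.reads_after = {
            s: int(t) for s, t in counts.sum(axis=1).items()
        }
        report.empty_samples_after = sorted(
            counts.index[counts.sum(axis=1) == 0]
        )
    return DetectionTable(counts, meta)


def assign_taxonomy(
    best_identity: float,
    best_coverage: float,
    n_best_hits: int = 1,
    config: RunConfig | None = None,
) -> str:
    """Tiered rank assignment from BLAST-style identity/coverage scores.

    species if coverage >= 98 and identity >= 99; else genus if identity
    > 96; else family if identity > 90; else unassigned.  An ambiguous
    multi-taxon best hit (``n_best_hits > 1``) demotes the call one rank
    (species -> genus, genus -> family, family -> order).
    """
    cfg = config or RunConfig()
    for name, v in (("identity", best_identity), ("coverage", best_coverage)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} {v} outside [0, 100]")
    if best_coverage >= cfg.species_coverage and best_identity >= cfg.species_identity:
        rank = "species"
    elif best_identity > cfg.genus_identity:
        rank = "genus"
    elif best_identity > cfg.family_identity:
        rank = "family"
    else:
        return "unassigned"
    if n_best_hits > 1:
        demote = {"species": "genus", "genus": "family", "family": "order"}
        rank = demote[rank]
    return rank


def apply_exclusions(
    table: DetectionTable,
    assignments: Mapping[str, MotuAssignment],
    report: CurationReport | None = None,
) -> tuple[DetectionTable, CurationReport]:
    """Drop flagged MOTU columns, attributing each removal to one rule.

    A MOTU with no reference match (``no_match`` flag or unassigned rank
    with zero identity) is removed first; then predator DNA, contaminants,
    coprophages and secondary prey, in that order.  Every table column must
    have an assignment record.
    """
    report = report or CurationReport()
    missing = [m for m in table.motu_ids if m not in assignments]
    if missing:
        raise KeyError(f"MOTU(s) lacking assignment records: {missing}")

    drop: list[str] = []
    for motu in table.motu_ids:
        rec = assignments[motu]
        flags = set(rec.flags)
        if rec.assigned_rank == "unassigned" and rec.best_identity == 0.0:
            flags.add("no_match")
        for rule in RULE_ORDER[:-1]:  # all except low_abundance
            if rule in flags:
                report.removed_by_rule[rule] += 1
                drop.append(motu)
                break
    counts = table.counts.drop(columns=drop)
    return DetectionTable(counts, table.meta.copy()), report


def to_occurrence(table: DetectionTable) -> DetectionTable:
    """Reduce counts to binary presence/absence (idempotent)."""
    occ = (table.counts > 0).astype(np.int64)
    return DetectionTable(occ, table.meta.copy())


def curate(
    table: DetectionTable,
    assignments: Mapping[str, MotuAssignment],
    config: RunConfig | None = None,
) -> tuple[DetectionTable, DetectionTable, CurationReport]:
    """Full curation: exclusions, abundance filtering, occurrence reduction.

    Returns ``(curated_counts, occurrence, report)``.  Exclusion rules and
    the abundance filter are cell/column-local, so their order does not
    affect the retained table; exclusions run first so that the report
    attributes each removal to the earliest rule in :data:`RULE_ORDER`.
    """
    cfg = config or RunConfig()
    report = CurationReport(n_motus_input=table.counts.shape[1])
    raw_totals = table.counts.sum(axis=1)
    excluded, report = apply_exclusions(table, assignments, report)
    filtered = filter_low_abundance(
        excluded,
        rel_threshold=cfg.per_sample_rel_abundance,
        min_reads=cfg.min_reads_per_motu,
        report=report,
        sample_totals=raw_totals,
    )
    report.n_motus_retained = filtered.counts.shape[1]
    report.check()
    return filtered, to_occurrence(filtered), report
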