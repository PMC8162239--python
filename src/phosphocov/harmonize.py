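"""Normalize raw identifiers to current, reference-taxon primary accessions.

Resources annotate proteins with a mix of current primaries, superseded
(secondary) accessions, retired (obsolete) accessions, isoform-suffixed
accessions, and identifiers from other species.  "Updating" an identifier
means: strip any isoform suffix, convert secondary accessions to their
primary, drop obsolete and non-reference-taxon identifiers, and drop
anything the catalog does not know.  Every distinct input lands in exactly
one report bucket, so the report partitions the input.

When a foreign identifier maps to several candidate accessions, the
one-to-one selection rule applies: prefer reviewed entries, then the
longest canonical sequence, breaking remaining ties by the
lexicographically smallest accession (a determinism choice).

Site positions are deliberately NOT renumbered when an isoform-suffixed
annotation is reassigned to its base accession; the consistency stage
surfaces any resulting coordinate damage as a mismatch or offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd

from .types import (
    Accession,
    AnnotationSet,
    Phosphosite,
    SequenceCatalog,
    ValidationError,
)


class UpdateOutcome(str, Enum):
    PRIMARY = "primary"
    SECONDARY_MAPPED = "secondary_mapped"
    OBSOLETE_DROPPED = "obsolete_dropped"
    TAXON_DROPPED = "taxon_dropped"
    UNKNOWN_DROPPED = "unknown_dropped"


@dataclass
class HarmonizationReport:
    """Bucketed fate of every distinct identifier seen during harmonization."""

    kept_primary: set[str] = field(default_factory=set)
    mapped_secondary: dict[str, str] = field(default_factory=dict)
    dropped_obsolete: set[str] = field(default_factory=set)
    dropped_taxon: set[str] = field(default_factory=set)
    dropped_unmappable: set[str] = field(default_factory=set)
    isoforms_stripped: int = 0
    n_sites_dropped: int = 0

    @property
    def kept(self) -> set[str]:
        """Output bases that survived harmonization."""
        return self.kept_primary | set(self.mapped_secondary.values())

    @property
    def n_inputs(self) -> int:
        return (
            len(self.kept_primary)
            + len(self.mapped_secondary)
            + len(self.dropped_obsolete)
            + len(self.dropped_taxon)
            + len(self.dropped_unmappable)
        )

    def bucket_counts(self) -> dict[str, int]:
        return {
            UpdateOutcome.PRIMARY.value: len(self.kept_primary),
            UpdateOutcome.SECONDARY_MAPPED.value: len(self.mapped_secondary),
            UpdateOutcome.OBSOLETE_DROPPED.value: len(self.dropped_obsolete),
            UpdateOutcome.TAXON_DROPPED.value: len(self.dropped_taxon),
            UpdateOutcome.UNKNOWN_DROPPED.value: len(self.dropped_unmappable),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for acc in sorted(self.kept_primary):
            rows.append((acc, UpdateOutcome.PRIMARY.value, acc))
        for acc in sorted(self.mapped_secondary):
            rows.append(
                (acc, UpdateOutcome.SECONDARY_MAPPED.value, self.mapped_secondary[acc])
            )
        for bucket, outcome in (
            (self.dropped_obsolete, UpdateOutcome.OBSOLETE_DROPPED),
            (self.dropped_taxon, UpdateOutcome.TAXON_DROPPED),
            (self.dropped_unmappable, UpdateOutcome.UNKNOWN_DROPPED),
        ):
            for acc in sorted(bucket):
                rows.append((acc, outcome.value, ""))
        return pd.DataFrame(rows, columns=["input", "outcome", "output"])


def strip_isoform(acc: str) -> str:
    """Discard a trailing isoform suffix: ``P04637-2`` becomes ``P04637``."""
    return Accession.parse(acc).base


def update_accession(
    base: str, catalog: SequenceCatalog
) -> tuple[UpdateOutcome, str | None]:
    """Classify a base accession against the catalog and map it if possible.

    Returns the outcome together with the current primary accession (for
    kept outcomes) or ``None`` (for drops).  Secondary accessions whose
    primary belongs to another taxon are dropped on taxon grounds.
    """
    if base in catalog.records:
        if catalog.records[base].taxon == catalog.reference_taxon:
            return UpdateOutcome.PRIMARY, base
        return UpdateOutcome.TAXON_DROPPED, None
    if base in catalog.secondary_to_primary:
        primary = catalog.secondary_to_primary[base]
        if catalog.records[primary].taxon == catalog.reference_taxon:
            return UpdateOutcome.SECONDARY_MAPPED, primary
        return UpdateOutcome.TAXON_DROPPED, None
    if base in catalog.obsolete:
        return UpdateOutcome.OBSOLETE_DROPPED, None
    return UpdateOutcome.UNKNOWN_DROPPED, None


def resolve_foreign_id(
    candidates: Iterable[str], catalog: SequenceCatalog
) -> str | None:
    """Pick exactly one accession from a multi-mapping, or none.

    Selection rule: restrict to reviewed entries when any exist, then take
    the longest canonical sequence, then the lexicographically smallest
    accession.  Candidates must already be primary records in the catalog;
    unknown candidates are ignored.
    """
    pool = sorted(c for c in set(candidates) if c in catalog.records)
    if not pool:
        return None
    reviewed = [c for c in pool if catalog.records[c].reviewed]
    if reviewed:
        pool = reviewed
    return min(pool, key=lambda c: (-len(catalog.records[c].canonical), c))


def harmonize_annotation_set(
    raw: AnnotationSet, catalog: SequenceCatalog
) -> tuple[AnnotationSet, HarmonizationReport]:
    """Harmonize one resource's protein and site sets against the catalog.

    Isoform suffixes are stripped before the update (secondary/obsolete
    status is defined on bases); sites follow the fate of their accession.
    Harmonizing an already-harmonized set is the identity.
    """
    report = HarmonizationReport()
    raw_ids = set(raw.proteins) | {s.accession for s in raw.sites}

    stripped_of: dict[str, str | None] = {}
    for rid in sorted(raw_ids):
        try:
            acc = Accession.parse(rid)
        except ValidationError:
            stripped_of[rid] = None
            report.dropped_unmappable.add(rid)
            continue
        if acc.isoform_index is not None:
            report.isoforms_stripped += 1
        stripped_of[rid] = acc.base

    mapping: dict[str, str | None] = {}
    for base in sorted({b for b in stripped_of.values() if b is not None}):
        outcome, out = update_accession(base, catalog)
        mapping[base] = out
        if outcome is UpdateOutcome.PRIMARY:
            report.kept_primary.add(base)
        elif outcome is UpdateOutcome.SECONDARY_MAPPED:
            assert out is not None
            report.mapped_secondary[base] = out
        elif outcome is UpdateOutcome.OBSOLETE_DROPPED:
            report.dropped_obsolete.add(base)
        elif outcome is UpdateOutcome.TAXON_DROPPED:
            report.dropped_taxon.add(base)
        else:
            report.dropped_unmappable.add(base)

    def resolve(rid: str) -> str | None:
        base = stripped_of[rid]
        return None if base is None else mapping[base]

    out_set = AnnotationSet(name=raw.name)
    for rid in raw.proteins:
        target = resolve(rid)
        if target is not None:
            out_set.proteins.add(target)
    for site in raw.sites:
        target = resolve(site.accession)
        if target is None:
            report.n_sites_dropped += 1
        else:
            out_set.sites.add(Phosphosite(target, site.residue, site.position))
    return out_set, report
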