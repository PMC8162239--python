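"""Classify phosphosite annotations against catalog sequences.

Each annotation is checked against the canonical sequence and, failing
that, the isoform sequences of its protein:

* ``canonical_match`` — the annotated residue sits at the annotated
  position in the canonical sequence;
* ``isoform_match``  — it sits at that position in an isoform instead;
* ``mismatch``       — a *different* phosphorylatable residue occupies the
  position (any other letter falls through to the offset search);
* ``offset``         — the nearest exact occurrence of the annotated
  residue lies at a recorded signed distance (annotated − matched, so
  initiator-Met cleavage shows up as −1);
* ``unmatched``      — position beyond the sequence or residue absent.

Category precedence: canonical match > isoform match > canonical mismatch
> canonical offset > isoform mismatch/offset (only when the annotated
residue is wholly absent from the canonical sequence) > unmatched.  When a
position exceeds the canonical length no canonical mismatch/offset search
is performed.  Offset distance ties are broken toward the negative signed
offset, the direction produced by initiator-methionine cleavage.

The summary mirrors the audit's headline table: consistent count and
percentage (isoform matches excluded from the numerator), isoform match
count, mismatch count, an offset-magnitude histogram binned 1 / 2 / 3 / +
(everything ≥ 4), and the unmatched count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .types import AnnotationSet, Phosphosite, SequenceCatalog, SequenceRecord, site_sort_key

#: Residues considered phosphorylatable by default (His is excluded but the
#: set is configurable for users who want to audit pHis annotations).
DEFAULT_PHOSPHO_RESIDUES = frozenset({"S", "T", "Y"})

OFFSET_BINS = ("1", "2", "3", "+")


class Category(str, Enum):
    CANONICAL_MATCH = "canonical_match"
    ISOFORM_MATCH = "isoform_match"
    MISMATCH = "mismatch"
    OFFSET = "offset"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class SiteClassification:
    site: Phosphosite
    category: Category
    matched_in: str | None = None  # "canonical", an isoform id, or None
    matched_position: int | None = None
    signed_offset: int | None = None
    magnitude_bin: str | None = None


def offset_bin(signed_offset: int) -> str:
    """Histogram bin for an offset magnitude: "1", "2", "3" or "+" (>= 4)."""
    magnitude = abs(signed_offset)
    return str(magnitude) if magnitude < 4 else "+"


def residue_at(sequence: str, position: int) -> str | None:
    """The 1-based residue at ``position``, or None beyond the sequence."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if position > len(sequence):
        return None
    return sequence[position - 1]


def nearest_occurrence(
    sequence: str, residue: str, position: int
) -> tuple[int, int] | None:
    """Closest exact occurrence of ``residue`` to ``position``.

    Returns ``(matched_position, signed_offset)`` with
    ``signed_offset = annotated − matched``; on a distance tie the
    occurrence downstream of the annotation wins (negative signed offset).
    Returns None when the residue is absent from the sequence.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    best: tuple[int, int] | None = None  # (distance, matched position)
    for idx, letter in enumerate(sequence, 1):
        if letter != residue:
            continue
        distance = abs(position - idx)
        if best is None or distance < best[0] or (distance == best[0] and idx > best[1]):
            best = (distance, idx)
    if best is None:
        return None
    return best[1], position - best[1]


def classify_site(
    site: Phosphosite,
    record: SequenceRecord,
    residues: frozenset[str] = DEFAULT_PHOSPHO_RESIDUES,
) -> SiteClassification:
    """Classify one annotation against its protein's sequences."""
    canonical = record.canonical
    target = site.residue
    position = site.position

    if residue_at(canonical, position) == target:
        return SiteClassification(
            site,
            Category.CANONICAL_MATCH,
            matched_in="canonical",
            matched_position=position,
            signed_offset=0,
        )

    for iso_id, iso_seq in record.isoforms.items():
        if residue_at(iso_seq, position) == target:
            return SiteClassification(
                site,
                Category.ISOFORM_MATCH,
                matched_in=iso_id,
                matched_position=position,
                signed_offset=0,
            )

    if position <= len(canonical):
        occupant = canonical[position - 1]
        if occupant in residues and occupant != target:
            return SiteClassification(site, Category.MISMATCH)
        found = nearest_occurrence(canonical, target, position)
        if found is not None:
            matched, signed = found
            return SiteClassification(
                site,
                Category.OFFSET,
                matched_in="canonical",
                matched_position=matched,
                signed_offset=signed,
                magnitude_bin=offset_bin(signed),
            )

    # Isoform mismatch/offset only when the annotated residue is wholly
    # absent from the canonical sequence (otherwise a canonical offset or
    # the beyond-length unmatched rule already applied).
    if target not in canonical:
        for iso_id, iso_seq in record.isoforms.items():
            occupant = residue_at(iso_seq, position)
            if occupant is not None and occupant in residues and occupant != target:
                return SiteClassification(site, Category.MISMATCH)
        for iso_id, iso_seq in record.isoforms.items():
            found = nearest_occurrence(iso_seq, target, position)
            if found is not None:
                matched, signed = found
                return SiteClassification(
                    site,
                    Category.OFFSET,
                    matched_in=iso_id,
                    matched_position=matched,
                    signed_offset=signed,
                    magnitude_bin=offset_bin(signed),
                )

    return SiteClassification(site, Category.UNMATCHED)


def classify_annotation_set(
    aset: AnnotationSet,
    catalog: SequenceCatalog,
    residues: frozenset[str] = DEFAULT_PHOSPHO_RESIDUES,
) -> list[SiteClassification]:
    """Classify every site of a harmonized annotation set, in stable order."""
    out = []
    for site in sorted(aset.sites, key=site_sort_key):
        record = catalog.records.get(site.accession)
        if record is None:
            raise KeyError(
                f"accession {site.accession} not in catalog; harmonize the set first"
            )
        out.append(classify_site(site, record, residues))
    return out


@dataclass
class ConsistencySummary:
    """Tally of classification categories for one annotation set."""

    n_sites: int = 0
    n_consistent: int = 0
    pct_consistent: float = 0.0
    n_isoform: int = 0
    n_mismatch: int = 0
    offset_histogram: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in OFFSET_BINS}
    )
    n_unmatched: int = 0

    def to_row(self, name: str = "") -> dict[str, object]:
        row: dict[str, object] = {
            "set": name,
            "n_sites": self.n_sites,
            "n_consistent": self.n_consistent,
            "pct_consistent": round(100.0 * self.pct_consistent, 2),
            "n_isoform": self.n_isoform,
            "n_mismatch": self.n_mismatch,
        }
        for b in OFFSET_BINS:
            row[f"offset_{'plus' if b == '+' else b}"] = self.offset_histogram[b]
        row["n_unmatched"] = self.n_unmatched
        return row


def summarize(classifications: Iterable[SiteClassification]) -> ConsistencySummary:
    """Tally classifications; the categories partition the site count.

    The consistent percentage excludes isoform matches from its numerator
    but counts every classified site (isoform, mismatch, offset, unmatched
    included) in its denominator.  An empty input yields an all-zero
    summary with the percentage defined as zero.
    """
    summary = ConsistencySummary()
    for clf in classifications:
        summary.n_sites += 1
        if clf.category is Category.CANONICAL_MATCH:
            summary.n_consistent += 1
        elif clf.category is Category.ISOFORM_MATCH:
            summary.n_isoform += 1
        elif clf.category is Category.MISMATCH:
            summary.n_mismatch += 1
        elif clf.category is Category.OFFSET:
            assert clf.magnitude_bin is not None
            summary.offset_histogram[clf.magnitude_bin] += 1
        else:
            summary.n_unmatched += 1
    if summary.n_sites:
        summary.pct_consistent = summary.n_consistent / summary.n_sites
    return summary


def classifications_to_frame(
    classifications: Sequence[SiteClassification],
) -> pd.DataFrame:
    rows = [
        {
            "accession": c.site.accession,
            "residue": c.site.residue,
            "position": c.site.position,
            "category": c.category.value,
            "matched_in": c.matched_in or "",
            "matched_position": "" if c.matched_position is None else c.matched_position,
            "signed_offset": "" if c.signed_offset is None else c.signed_offset,
            "bin": c.magnitude_bin or "",
        }
        for c in classifications
    ]
    columns = [
        "accession",
        "residue",
        "position",
        "category",
        "matched_in",
        "matched_position",
        "signed_offset",
        "bin",
    ]
    return pd.DataFrame(rows, columns=columns)
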