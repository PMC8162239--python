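"""Core domain objects shared by every pipeline stage.

The pipeline audits phosphosite annotations from signalling and PTM
databases against a reference protein-sequence catalog (a UniProt-style
proteome).  These classes are the common currency: parsed accessions,
sequence records with isoforms, the catalog with secondary/obsolete
identifier maps, and the site / annotation-set / experimental-record
containers that the downstream set algebra operates on.

Positions are 1-based inclusive throughout, following the UniProt
convention used by every resource the pipeline ingests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: The 20 proteinogenic amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters allowed in catalog sequences (X = unknown residue).
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

#: UniProt accession shape: a letter followed by 5 or 9 alphanumerics.
#: The pattern is configurable wherever accessions are parsed so synthetic
#: or non-UniProt dialects can be accommodated.
DEFAULT_ACCESSION_PATTERN = re.compile(r"[A-Za-z][A-Za-z0-9]{5}(?:[A-Za-z0-9]{4})?")


class ValidationError(ValueError):
    """An object violated one of its structural invariants."""


@dataclass(frozen=True)
class Accession:
    """A protein accession, optionally carrying an isoform suffix.

    The rendered form is ``base`` when no isoform index is present, else
    ``base-<index>`` (e.g. ``P04637-2`` for isoform 2 of P04637).
    """

    base: str
    isoform_index: int | None = None

    def __post_init__(self) -> None:
        if self.isoform_index is not None and self.isoform_index < 1:
            raise ValidationError(
                f"isoform index must be >= 1, got {self.isoform_index}"
            )

    def render(self) -> str:
        if self.isoform_index is None:
            return self.base
        return f"{self.base}-{self.isoform_index}"

    @classmethod
    def parse(
        cls,
        text: str,
        pattern: re.Pattern[str] = DEFAULT_ACCESSION_PATTERN,
    ) -> "Accession":
        """Parse a rendered accession, recovering base and isoform index.

        Raises :class:`ValidationError` when the base does not match
        ``pattern`` or the isoform suffix is malformed.
        """
        base, sep, suffix = text.partition("-")
        if not pattern.fullmatch(base):
            raise ValidationError(
                f"accession {text!r} does not match the expected pattern"
            )
        if not sep:
            return cls(base)
        if not suffix.isdigit() or int(suffix) < 1:
            raise ValidationError(
                f"accession {text!r} has a malformed isoform suffix"
            )
        return cls(base, int(suffix))


@dataclass
class SequenceRecord:
    """One catalog entry: a canonical sequence plus its isoforms.

    ``isoforms`` maps isoform identifiers (rendered accessions such as
    ``P04637-2``) to their sequences, in catalog order; that order is the
    search order used by the consistency classifier.
    """

    accession: str
    canonical: str
    reviewed: bool = True
    taxon: int = 9606
    isoforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValidationError(f"{self.accession}: canonical sequence is empty")
        for name, seq in [(self.accession, self.canonical), *self.isoforms.items()]:
            bad = set(seq) - SEQUENCE_ALPHABET
            if bad:
                raise ValidationError(
                    f"{name}: sequence contains invalid letters {sorted(bad)}"
                )
        if self.accession in self.isoforms:
            raise ValidationError(
                f"{self.accession}: isoform id equals the canonical id"
            )


@dataclass
class SequenceCatalog:
    """The reference proteome stand-in.

    ``records`` maps primary base accessions to their sequence records;
    ``secondary_to_primary`` maps superseded accessions to current
    primaries; ``obsolete`` holds retired accessions.  All downstream
    harmonization decisions are made against this object.
    """

    records: dict[str, SequenceRecord] = field(default_factory=dict)
    secondary_to_primary: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    reference_taxon: int = 9606

    def validate(self) -> "SequenceCatalog":
        overlap = self.secondary_to_primary.keys() & self.records.keys()
        if overlap:
            raise ValidationError(
                f"accessions both secondary and primary: {sorted(overlap)[:5]}"
            )
        overlap = self.obsolete & self.records.keys()
        if overlap:
            raise ValidationError(
                f"accessions both obsolete and primary: {sorted(overlap)[:5]}"
            )
        unknown = {
            p for p in self.secondary_to_primary.values() if p not in self.records
        }
        if unknown:
            raise ValidationError(
                f"secondary accessions map to unknown primaries: {sorted(unknown)[:5]}"
            )
        return self

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, base: str) -> bool:
        return base in self.records


@dataclass(frozen=True, order=True)
class Phosphosite:
    """A single reported phosphorylated residue.

    Identity across databases is the exact (accession, residue, position)
    triple; no sequence-window standardization is attempted.
    """

    accession: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if len(self.residue) != 1 or not self.residue.isalpha() or not self.residue.isupper():
            raise ValidationError(
                f"residue must be a single uppercase letter, got {self.residue!r}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")


def site_sort_key(site: Phosphosite) -> tuple[str, int, str]:
    """Deterministic ordering used for all site output tables."""
    return (site.accession, site.position, site.residue)


@dataclass
class AnnotationSet:
    """One resource's extracted content: a protein set and a site set."""

    name: str
    proteins: set[str] = field(default_factory=set)
    sites: set[Phosphosite] = field(default_factory=set)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.name == other.name
            and self.proteins == other.proteins
            and self.sites == other.sites
        )


@dataclass(frozen=True)
class ExperimentalRecord:
    """A measured phosphosite tied to a publication (PMID).

    ``samples`` is the full set of sample labels (cell lines) attached to
    the PMID; when a PMID carries more than one label it is impossible to
    tell which measurement came from which sample, so the labels travel
    together on every record of that PMID.
    """

    site: Phosphosite
    pmid: str
    samples: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValidationError("experimental record has no PMID")
        if not self.samples:
            raise ValidationError(f"PMID {self.pmid}: empty sample set")
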