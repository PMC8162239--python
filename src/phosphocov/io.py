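"""Readers and writers for the pipeline's external formats.

Formats handled here:

* UniProt-style FASTA (``>sp|ACC|NAME`` / ``>tr|ACC|NAME`` headers, isoform
  entries as ``>sp|ACC-2|NAME``) plus an identifier-status TSV
  (accession / status / maps_to / taxon) — together they define a
  :class:`~phosphocov.types.SequenceCatalog`.
* Annotation TSVs (accession / residue / position; empty residue+position
  rows contribute only proteins) — :class:`~phosphocov.types.AnnotationSet`.
* Experimental TSVs (accession / residue / position / pmid / sample) —
  lists of :class:`~phosphocov.types.ExperimentalRecord`.
* Result tables: every summary is written as a TSV with a JSON mirror,
  deterministically ordered so repeated runs are byte-identical.

Row-level problems never crash a reader: bad rows land in a
:class:`RejectReport` with the input line number and a reason, and
``accepted + rejected == input rows`` always holds.
"""

from __future__ import annotations

import csv
import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .types import (
    DEFAULT_ACCESSION_PATTERN,
    Accession,
    AnnotationSet,
    ExperimentalRecord,
    Phosphosite,
    SequenceCatalog,
    SequenceRecord,
    ValidationError,
    site_sort_key,
)


class ParseError(ValueError):
    """A file could not be parsed; the message names file and line."""


@dataclass(frozen=True)
class Reject:
    line: int | None
    field: str
    reason: str


@dataclass
class RejectReport:
    """Row-level rejections plus non-fatal warnings from one read."""

    rejects: list[Reject] = field(default_factory=list)
    warnings: list[Reject] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"line": r.line, "field": r.field, "reason": r.reason, "severity": sev}
            for sev, items in (("reject", self.rejects), ("warning", self.warnings))
            for r in items
        ]
        return pd.DataFrame(rows, columns=["line", "field", "reason", "severity"])


_HEADER_RE = re.compile(r"(sp|tr)\|([A-Za-z0-9-]+)\|(\S+)")


def _header_line_numbers(path: Path) -> list[int]:
    numbers = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith(">"):
                numbers.append(lineno)
    return numbers


def read_catalog(
    fasta_path: str | Path,
    id_table_path: str | Path,
    reference_taxon: int = 9606,
    accession_pattern: re.Pattern[str] = DEFAULT_ACCESSION_PATTERN,
) -> SequenceCatalog:
    """Assemble a sequence catalog from a FASTA file and an ID-status table.

    Isoform entries (``ACC-2`` etc.) are attached to their base record and
    never emitted as standalone records; the ``sp``/``tr`` database tag
    sets the reviewed flag.  The ID table supplies per-accession taxa and
    the secondary/obsolete maps.
    """
    fasta_path = Path(fasta_path)
    id_table_path = Path(id_table_path)

    lines = _header_line_numbers(fasta_path)
    canonical_entries: dict[str, tuple[bool, str]] = {}
    isoform_entries: list[tuple[str, str, str]] = []  # (base, iso id, seq)
    for idx, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta")):
        lineno = lines[idx]
        match = _HEADER_RE.fullmatch(rec.id)
        if match is None:
            raise ParseError(
                f"{fasta_path}:{lineno}: malformed FASTA header {rec.description!r}"
            )
        tag, acc_text = match.group(1), match.group(2)
        try:
            acc = Accession.parse(acc_text, pattern=accession_pattern)
        except ValidationError as exc:
            raise ParseError(f"{fasta_path}:{lineno}: {exc}") from exc
        seq = str(rec.seq).upper()
        if acc.isoform_index is None:
            if acc.base in canonical_entries:
                raise ParseError(
                    f"{fasta_path}:{lineno}: duplicate canonical entry {acc.base}"
                )
            canonical_entries[acc.base] = (tag == "sp", seq)
        else:
            isoform_entries.append((acc.base, acc.render(), seq))

    records: dict[str, SequenceRecord] = {}
    for base, (reviewed, seq) in canonical_entries.items():
        records[base] = SequenceRecord(
            accession=base, canonical=seq, reviewed=reviewed, taxon=reference_taxon
        )
    for base, iso_id, seq in isoform_entries:
        if base not in records:
            raise ParseError(
                f"{fasta_path}: isoform {iso_id} has no canonical entry {base}"
            )
        if iso_id in records[base].isoforms:
            raise ParseError(f"{fasta_path}: duplicate isoform entry {iso_id}")
        records[base].isoforms[iso_id] = seq

    secondary: dict[str, str] = {}
    obsolete: set[str] = set()
    with open(id_table_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "status", "maps_to", "taxon"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{id_table_path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            acc = (row["accession"] or "").strip()
            status = (row["status"] or "").strip()
            if status == "primary":
                if acc not in records:
                    raise ValidationError(
                        f"{id_table_path}: primary accession {acc} absent from FASTA"
                    )
                taxon = (row["taxon"] or "").strip()
                if taxon:
                    records[acc].taxon = int(taxon)
            elif status == "secondary":
                secondary[acc] = (row["maps_to"] or "").strip()
            elif status == "obsolete":
                obsolete.add(acc)
            else:
                raise ParseError(
                    f"{id_table_path}:{reader.line_num}: unknown status {status!r}"
                )

    catalog = SequenceCatalog(
        records=records,
        secondary_to_primary=secondary,
        obsolete=obsolete,
        reference_taxon=reference_taxon,
    )
    return catalog.validate()


def _wrap(seq: str, width: int = 60) -> Iterable[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_catalog(
    catalog: SequenceCatalog,
    fasta_path: str | Path,
    id_table_path: str | Path,
) -> None:
    """Write a catalog back to FASTA + ID table (inverse of read_catalog)."""
    with open(fasta_path, "w") as handle:
        for base in sorted(catalog.records):
            rec = catalog.records[base]
            tag = "sp" if rec.reviewed else "tr"
            handle.write(f">{tag}|{base}|{base}\n")
            for chunk in _wrap(rec.canonical):
                handle.write(chunk + "\n")
            for iso_id, seq in rec.isoforms.items():
                handle.write(f">{tag}|{iso_id}|{base}\n")
                for chunk in _wrap(seq):
                    handle.write(chunk + "\n")
    with open(id_table_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "status", "maps_to", "taxon"])
        for base in sorted(catalog.records):
            writer.writerow([base, "primary", "", catalog.records[base].taxon])
        for acc in sorted(catalog.secondary_to_primary):
            writer.writerow(
                [acc, "secondary", catalog.secondary_to_primary[acc], ""]
            )
        for acc in sorted(catalog.obsolete):
            writer.writerow([acc, "obsolete", "", ""])


def read_annotation_set(
    tsv_path: str | Path, name: str
) -> tuple[AnnotationSet, RejectReport]:
    """Read one resource's annotation TSV (accession/residue/position).

    Duplicate site triples collapse silently; rows whose residue and
    position are both empty contribute only to the protein set.  Sites
    sharing an (accession, position) but disagreeing on the residue letter
    are kept but surfaced as warnings in the report.
    """
    aset = AnnotationSet(name=name)
    report = RejectReport()
    with open(tsv_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "residue", "position"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{tsv_path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            acc = (row["accession"] or "").strip()
            residue = (row["residue"] or "").strip()
            pos_text = (row["position"] or "").strip()
            if not acc:
                report.rejects.append(Reject(line, "accession", "missing accession"))
                continue
            if not residue and not pos_text:
                aset.proteins.add(acc)
                continue
            if not residue:
                report.rejects.append(
                    Reject(line, "residue", "missing residue for site row")
                )
                continue
            if not pos_text:
                report.rejects.append(
                    Reject(line, "position", "missing position for site row")
                )
                continue
            try:
                position = int(pos_text)
            except ValueError:
                report.rejects.append(
                    Reject(line, "position", f"non-integer position {pos_text!r}")
                )
                continue
            if position < 1:
                report.rejects.append(
                    Reject(line, "position", f"position {position} < 1")
                )
                continue
            residue = residue.upper()
            if len(residue) != 1 or not residue.isalpha():
                report.rejects.append(
                    Reject(line, "residue", f"invalid residue {row['residue']!r}")
                )
                continue
            aset.proteins.add(acc)
            aset.sites.add(Phosphosite(acc, residue, position))

    by_slot: dict[tuple[str, int], set[str]] = defaultdict(set)
    for site in aset.sites:
        by_slot[(site.accession, site.position)].add(site.residue)
    for (acc, pos), letters in sorted(by_slot.items()):
        if len(letters) > 1:
            report.warnings.append(
                Reject(
                    None,
                    "residue",
                    f"conflicting residues {sorted(letters)} at {acc} position {pos}",
                )
            )
    return aset, report


def write_annotation_set(aset: AnnotationSet, tsv_path: str | Path) -> None:
    """Write an annotation set as a TSV readable by read_annotation_set."""
    covered = {site.accession for site in aset.sites}
    with open(tsv_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "residue", "position"])
        for acc in sorted(aset.proteins - covered):
            writer.writerow([acc, "", ""])
        for site in sorted(aset.sites, key=site_sort_key):
            writer.writerow([site.accession, site.residue, site.position])


def read_experimental(
    tsv_path: str | Path,
) -> tuple[list[ExperimentalRecord], RejectReport]:
    """Read a qPhos-style experimental table.

    One input row per (site, pmid, sample) pairing; rows sharing a PMID
    have their sample labels merged so every record carrying that PMID
    sees the full label set.  Rows without a PMID or sample are rejected.
    """
    report = RejectReport()
    pmid_samples: dict[str, set[str]] = defaultdict(set)
    pairs: set[tuple[Phosphosite, str]] = set()
    with open(tsv_path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"accession", "residue", "position", "pmid", "sample"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{tsv_path}: expected columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            pmid = (row["pmid"] or "").strip()
            sample = (row["sample"] or "").strip()
            acc = (row["accession"] or "").strip()
            residue = (row["residue"] or "").strip().upper()
            pos_text = (row["position"] or "").strip()
            if not pmid:
                report.rejects.append(Reject(line, "pmid", "missing pmid"))
                continue
            if not sample:
                report.rejects.append(Reject(line, "sample", "missing sample"))
                continue
            if not acc:
                report.rejects.append(Reject(line, "accession", "missing accession"))
                continue
            try:
                position = int(pos_text)
            except ValueError:
                report.rejects.append(
                    Reject(line, "position", f"non-integer position {pos_text!r}")
                )
                continue
            if position < 1 or len(residue) != 1 or not residue.isalpha():
                report.rejects.append(
                    Reject(line, "site", "invalid residue/position for site")
                )
                continue
            pmid_samples[pmid].add(sample)
            pairs.add((Phosphosite(acc, residue, position), pmid))

    records = [
        ExperimentalRecord(site, pmid, frozenset(pmid_samples[pmid]))
        for site, pmid in sorted(pairs, key=lambda p: (site_sort_key(p[0]), p[1]))
    ]
    return records, report


def write_experimental(
    records: Iterable[ExperimentalRecord], tsv_path: str | Path
) -> None:
    """Write experimental records, one row per (site, pmid, sample)."""
    rows = sorted(
        (r.site.accession, r.site.residue, r.site.position, r.pmid, sample)
        for r in records
        for sample in r.samples
    )
    with open(tsv_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["accession", "residue", "position", "pmid", "sample"])
        writer.writerows(rows)


def write_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write each named table as a TSV plus a JSON mirror.

    Column order and row order are taken as given (callers sort), so the
    same input always yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name]
        tsv = out / f"{name}.tsv"
        df.to_csv(tsv, sep="\t", index=False, lineterminator="\n")
        payload = {
            "columns": list(df.columns),
            "rows": json.loads(df.to_json(orient="values")) if len(df) else [],
        }
        mirror = out / f"{name}.json"
        mirror.write_text(json.dumps(payload, sort_keys=False) + "\n")
        written.extend([tsv, mirror])
    return written
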