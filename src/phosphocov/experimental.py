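"""Coverage of experimental (qPhos-style) phosphoproteomics by databases.

Experimental records tie measured phosphosites to publications (PMIDs)
tagged with sample labels (cell lines).  When a PMID carries several
labels it is impossible to tell which measurement came from which sample,
so those PMIDs are excluded wholesale before any per-sample statistic is
computed.  Samples are ranked by their number of distinct publications,
and per-sample measured sets (proteins derived from the sites' accessions,
or the site triples themselves) are intersected with each database.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Hashable, Sequence

import pandas as pd

from .types import AnnotationSet, ExperimentalRecord
from .coverage import CoverageCell


def filter_single_sample(
    records: Sequence[ExperimentalRecord],
) -> tuple[list[ExperimentalRecord], list[ExperimentalRecord]]:
    """Split records into single-sample-PMID keeps and multi-sample excludes."""
    kept, excluded = [], []
    for record in records:
        (kept if len(record.samples) == 1 else excluded).append(record)
    return kept, excluded


def rank_samples(
    records: Sequence[ExperimentalRecord],
) -> list[tuple[str, int]]:
    """Samples ordered by distinct-PMID count (desc), ties by name (asc).

    Records must already be single-sample filtered.
    """
    pmids: dict[str, set[str]] = defaultdict(set)
    for record in records:
        if len(record.samples) != 1:
            raise ValueError(
                f"PMID {record.pmid} carries multiple samples; filter first"
            )
        (label,) = record.samples
        pmids[label].add(record.pmid)
    return sorted(
        ((label, len(ids)) for label, ids in pmids.items()),
        key=lambda pair: (-pair[1], pair[0]),
    )


@dataclass
class SampleCoverageMatrix:
    """Per-sample coverage by each database.

    Rows are samples in rank order; proportions are relative to the
    sample's own measured set.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    sample_sizes: dict[str, int]

    def cell(self, sample: str, database: str) -> CoverageCell:
        return CoverageCell(
            int(self.counts.loc[sample, database]),
            float(self.proportions.loc[sample, database]),
        )


def sample_coverage(
    records: Sequence[ExperimentalRecord],
    databases: Sequence[AnnotationSet],
    level: str = "protein",
    top_k: int | None = None,
) -> SampleCoverageMatrix:
    """Intersect each sample's measured set with each database.

    At protein level a protein counts as measured in a sample iff at least
    one of its sites was; at site level the exact (accession, residue,
    position) triple must agree.  ``top_k`` restricts the rows to the
    top-ranked samples.
    """
    if level not in ("protein", "site"):
        raise ValueError(f"level must be 'protein' or 'site', got {level!r}")

    order = [label for label, _ in rank_samples(records)]
    if top_k is not None:
        order = order[:top_k]

    measured: dict[str, set[Hashable]] = {label: set() for label in order}
    for record in records:
        (label,) = record.samples
        if label not in measured:
            continue
        element = record.site.accession if level == "protein" else record.site
        measured[label].add(element)

    db_names = [db.name for db in databases]
    counts = pd.DataFrame(0, index=order, columns=db_names, dtype=int)
    props = pd.DataFrame(0.0, index=order, columns=db_names, dtype=float)
    for db in databases:
        elements = db.proteins if level == "protein" else db.sites
        for label in order:
            n = len(measured[label] & set(elements))
            counts.loc[label, db.name] = n
            props.loc[label, db.name] = (
                n / len(measured[label]) if measured[label] else 0.0
            )
    sizes = {label: len(measured[label]) for label in order}
    return SampleCoverageMatrix(counts, props, sizes)
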