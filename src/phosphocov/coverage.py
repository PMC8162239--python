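"""Set algebra over harmonized protein and site sets.

Everything here operates on named sets of hashable elements — base
accessions at protein level, (accession, residue, position) triples at
site level — and produces the count tables that coverage heatmaps and
UpSet plots are drawn from: pairwise intersection matrices with
proportions relative to a reference set, exclusive (UpSet-style)
intersections that partition the union, per-set unique elements, and set
difference matrices in both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Hashable, Mapping

import pandas as pd


@dataclass(frozen=True)
class CoverageCell:
    count: int
    proportion_of_reference: float


@dataclass
class CoverageMatrix:
    """Pairwise intersections: rows = reference sets, columns = queries."""

    counts: pd.DataFrame
    proportions: pd.DataFrame

    def cell(self, reference: str, query: str) -> CoverageCell:
        return CoverageCell(
            int(self.counts.loc[reference, query]),
            float(self.proportions.loc[reference, query]),
        )


def pairwise_matrix(
    query_sets: Mapping[str, AbstractSet[Hashable]],
    reference_sets: Mapping[str, AbstractSet[Hashable]],
) -> CoverageMatrix:
    """Intersection counts and coverage proportions for every (ref, query).

    The proportion in cell (r, q) is |r ∩ q| / |r|, i.e. how much of the
    reference set the query covers; an empty reference yields 0.
    """
    ref_names = sorted(reference_sets)
    query_names = sorted(query_sets)
    counts = pd.DataFrame(0, index=ref_names, columns=query_names, dtype=int)
    props = pd.DataFrame(0.0, index=ref_names, columns=query_names, dtype=float)
    for r in ref_names:
        ref = reference_sets[r]
        for q in query_names:
            n = len(ref & set(query_sets[q]))
            counts.loc[r, q] = n
            props.loc[r, q] = n / len(ref) if ref else 0.0
    return CoverageMatrix(counts, props)


def signature_label(signature: AbstractSet[str]) -> str:
    return "&".join(sorted(signature))


@dataclass
class ExclusiveIntersectionTable:
    """UpSet-style exclusive intersections.

    ``entries`` maps each non-empty membership signature (the exact subset
    of set names an element belongs to) to the number of such elements;
    the counts partition the union, so they always sum to
    ``universe_size``.
    """

    entries: dict[frozenset[str], int]
    universe_size: int

    def to_frame(self, min_count: int = 0) -> pd.DataFrame:
        rows = [
            {"signature": signature_label(sig), "degree": len(sig), "count": n}
            for sig, n in self.entries.items()
            if n >= min_count
        ]
        rows.sort(key=lambda r: (-r["count"], r["signature"]))
        return pd.DataFrame(rows, columns=["signature", "degree", "count"])


def exclusive_intersections(
    named_sets: Mapping[str, AbstractSet[Hashable]],
) -> ExclusiveIntersectionTable:
    """Assign every element of the union to its exact membership signature."""
    if not named_sets:
        raise ValueError("at least one named set is required")
    names = sorted(named_sets)
    entries: dict[frozenset[str], int] = {}
    universe: set[Hashable] = set()
    for name in names:
        universe |= set(named_sets[name])
    for element in universe:
        sig = frozenset(n for n in names if element in named_sets[n])
        entries[sig] = entries.get(sig, 0) + 1
    table = ExclusiveIntersectionTable(entries, len(universe))
    assert sum(table.entries.values()) == table.universe_size
    return table


def unique_elements(
    name: str, named_sets: Mapping[str, AbstractSet[Hashable]]
) -> set[Hashable]:
    """Elements present in the named set and in no other set."""
    if name not in named_sets:
        raise KeyError(f"unknown set name {name!r}")
    out = set(named_sets[name])
    for other, elements in named_sets.items():
        if other != name:
            out -= set(elements)
    return out


@dataclass
class DifferenceMatrix:
    """|reference \\ query| and the transposed |query \\ reference| counts."""

    reference_minus_query: pd.DataFrame  # rows = references, cols = queries
    query_minus_reference: pd.DataFrame  # rows = queries, cols = references


def difference_matrix(
    query_sets: Mapping[str, AbstractSet[Hashable]],
    reference_sets: Mapping[str, AbstractSet[Hashable]],
) -> DifferenceMatrix:
    ref_names = sorted(reference_sets)
    query_names = sorted(query_sets)
    rmq = pd.DataFrame(0, index=ref_names, columns=query_names, dtype=int)
    qmr = pd.DataFrame(0, index=query_names, columns=ref_names, dtype=int)
    for r in ref_names:
        ref = set(reference_sets[r])
        for q in query_names:
            query = set(query_sets[q])
            rmq.loc[r, q] = len(ref - query)
            qmr.loc[q, r] = len(query - ref)
    return DifferenceMatrix(rmq, qmr)


def matrix_to_frame(df: pd.DataFrame, index_name: str = "set") -> pd.DataFrame:
    """Reshape a named-index matrix into a flat, writeable table."""
    out = df.copy()
    out.insert(0, index_name, out.index)
    return out.reset_index(drop=True)
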