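"""Over-representation analysis of protein sets against term maps.

The standard ORA formulation: for a query of size n drawn from a
background of size N, a term with K background members and k query hits
has upper-tail hypergeometric probability P[X >= k].  Benjamini–Hochberg
adjusted values are reported alongside the raw p so both readings are
available.  Term maps arrive pre-flattened (no ontology propagation) as
two-column TSV (term, accession) or GMT files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Hashable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # query hits
    K: int  # background hits
    n: int  # query size
    N: int  # background size
    p: float  # hypergeometric upper-tail probability
    q: float  # Benjamini-Hochberg adjusted value
    significant: bool


def ora(
    query: AbstractSet[Hashable],
    background: AbstractSet[Hashable],
    term_map: Mapping[str, AbstractSet[Hashable]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Term member sets are restricted to the background before testing.
    Results are sorted by (p, term); ``significant`` flags q <= alpha.
    Raises ValueError when the query is not a subset of the background.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"query contains elements outside the background: {sorted(map(str, stray))[:5]}"
        )
    if not term_map:
        return []

    N, n = len(background), len(query)
    terms = sorted(term_map)
    stats = []
    for term in terms:
        members = set(term_map[term]) & background
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        stats.append((term, k, K, min(p, 1.0)))

    qvals = multipletests([p for _, _, _, p in stats], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, k, K, n, N, p, max(p, float(q)), bool(q <= alpha))
        for (term, k, K, p), q in zip(stats, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term": r.term,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p", "q", "significant"])


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a term→proteins map from GMT or two-column (term, accession) TSV."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as handle:
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                terms.setdefault(parts[0], set()).update(
                    p for p in parts[2:] if p
                )
        return terms
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"term", "accession"} <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns ['term', 'accession'], got {reader.fieldnames}"
            )
        for row in reader:
            term = (row["term"] or "").strip()
            acc = (row["accession"] or "").strip()
            if term and acc:
                terms.setdefault(term, set()).add(acc)
    return terms
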