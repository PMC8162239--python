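# Methods

## The audit model

`phosphocov` treats a phosphosite annotation as the exact triple
(base accession, residue letter, 1-based position). No sequence-window
(±7-mer) standardization or realignment is attempted: two databases agree
on a site only when the triples are identical after identifier
harmonization. This is deliberate — the audit measures what resources
*record*, not what could be reconciled.

### Identifier harmonization

An identifier is updated in three steps, in this order:

1. **Isoform stripping.** `P04637-2 → P04637`. Stripping precedes the
   update because secondary/obsolete status is defined on base accessions.
   Site positions are *not* renumbered when an isoform annotation is
   reassigned to its base; any coordinate damage is surfaced downstream as
   a mismatch or offset rather than silently corrected.
2. **Update.** Primary accessions of the reference taxon are kept;
   secondary accessions map to their primary (dropped if the primary is
   foreign); obsolete, foreign-taxon and unknown identifiers are dropped.
   Every distinct stripped input lands in exactly one report bucket, so
   `Σ buckets = distinct inputs` is checkable on every run.
3. **One-to-one resolution** (for foreign-namespace multi-mappings):
   reviewed candidates beat unreviewed; among those, the longest canonical
   sequence wins; remaining ties go to the lexicographically smallest
   accession. The tie-break is a determinism choice — nothing in the
   underlying procedure prescribes one — and is stable across runs and
   platforms.

Identifiers that do not parse as accessions at all are routed to the
`unknown_dropped` bucket rather than raising, so a single malformed row
cannot abort a resource-scale run.

### Consistency classification

For a site (r, p) on a record with canonical sequence C and isoforms
I₁, I₂, … (in catalog order), the category is decided by precedence:

1. `canonical_match` — C[p] = r.
2. `isoform_match` — Iₖ[p] = r for the first such isoform.
3. `mismatch` — C[p] is a *different* member of the phosphorylatable set
   (default {S, T, Y}, configurable). Any other occupant falls through to
   the offset search; "mismatch" is reserved for plausible-but-wrong
   phospho-residues.
4. `offset` — the nearest occurrence of r in C, with signed offset
   `p − p_matched`. Distance ties prefer the *downstream* occurrence
   (negative signed offset), because initiator-methionine cleavage — the
   dominant known cause of systematic shifts — produces exactly that
   direction. Magnitudes are binned 1 / 2 / 3 / + (≥ 4) for summaries;
   signed values are retained per site.
5. Isoform mismatch, then isoform offset — searched only when r is wholly
   absent from the canonical sequence (both report the same `mismatch` /
   `offset` categories, with the isoform identity in `matched_in`).
6. `unmatched`. A position beyond the canonical length triggers no
   canonical mismatch/offset search at all: with no isoform match it is
   unmatched outright.

The precedence ordering at steps 3–5 is a documented design decision: the
classifier keeps headline-table reportability (isoform *matches* are a
category of their own) while still honouring the isoform search for
residues the canonical sequence cannot explain.

The summary percentage `n_consistent / n_sites` counts only canonical
matches in the numerator and *all* classified sites (isoform matches,
mismatches, offsets, unmatched) in the denominator; an empty input defines
the percentage as zero.

### Coverage, experimental mapping, enrichment

Coverage statistics are plain set algebra with two conventions: pairwise
proportions are always relative to the *reference* (row) set, and
exclusive (UpSet) intersections assign each element of the union to its
exact membership signature, so the counts partition the union — an
identity asserted on every call. A minimum-count display filter exists for
UpSet output tables only; stored entries are never filtered.

Experimental mapping excludes multi-sample PMIDs wholesale (when a
publication is tagged with several cell lines it is impossible to
attribute individual measurements), ranks samples by distinct-PMID count
(ties by name), and derives per-sample protein sets from the sites'
accessions — a protein is "measured" in a sample iff at least one of its
sites is. Site-level coverage demands exact triple equality, which is why
a well-covered phosphoprotein can still contribute zero site-level hits.

Enrichment is the standard one-sided hypergeometric upper tail,
`P[X ≥ k]` for `X ~ Hypergeom(N, K, n)`, over user-supplied flattened
term maps (no ontology propagation). Benjamini–Hochberg adjusted values
are reported alongside raw p so either threshold convention can be
applied; with a single tested term q = p.

## The synthetic world

The generator exists to make every stage's output checkable *exactly*
against planted truth, not to mimic biological sequence composition.
Sequences are i.i.d. uniform over the 20-letter alphabet; all randomness
flows from one mandatory integer seed through `random.Random` integer
draws only, so output is identical across platforms.

Defaults state the audited world at desk scale:

| parameter | default | why |
|---|---|---|
| identifier universe | 1,000 | large enough for exact 10%/5%/5% splits, small enough for sub-second runs |
| secondary / obsolete / foreign fractions | 0.10 / 0.05 / 0.05 | the planted harmonization mixture |
| sequence lengths | 100–600 | brackets typical protein lengths; min length hosts the largest planted offset window |
| isoforms per record | 0–2 | enough to exercise isoform search order |
| planted categories | 60 match / 10 isoform / 5 mismatch / 20 offsets / 5 unmatched | the planted consistency mixture; offsets are five each of magnitudes 1, 2, 3, 7, mixed signs |
| membership vector | five resources' unique counts 26,423 / 3,980 / 3,059 / 638 / 599 plus 42 elements common to all five | the published site-level exclusive-intersection structure |
| experimental | six cell lines, 30/24/18/14/10/6 PMIDs, 25 sites per PMID, 30% multi-sample | a scaled-down stand-in for a corpus of ~190 publications; descending counts make the ranking unambiguous |

Fractions are defined over an identifier universe of exactly `n_proteins`
tokens (secondaries, obsoletes and foreign primaries are carved *out of*
the universe, not added to it), so recovered bucket fractions equal the
planted fractions exactly rather than approximately.

`plant_sites` places one site per reference-taxon record and *edits* the
generated sequences to enforce each category's defining constraint **and**
the absence of every higher-precedence classification: offsets clear the
whole tie window (radius |m|) of the target residue before placing the
single nearest occurrence on the planted side; the annotated position gets
a non-phosphorylatable occupant; isoforms long enough to reach the
position are blocked; unmatched sites guarantee the residue exists in the
canonical so the isoform fallback never fires. A final verification pass
re-classifies every planted site and raises on any disagreement — planted
recovery is exact by construction, and a green recovery test establishes
classifier/generator agreement under the documented precedence, **not**
robustness to real-world annotation pathologies (orthologue transfers,
windowed remappings, compositional bias), which the generator does not
emulate.

## Numerical and degenerate-input choices

* Empty reference set → coverage proportion 0 (not NaN); empty
  classification input → all-zero summary with pct 0.
* `nearest_occurrence` is an exact linear scan (sequences are ≤ a few
  thousand residues; no indexing structure is warranted).
* ORA p-values are clamped to [0, 1] and q = max(p, BH) to guard
  floating-point round-trip at the tail.
* Report bundles are byte-deterministic: all tables are written in sorted
  order with fixed float rounding, and the manifest contains checksums and
  versions, no timestamps.
* A documented caveat: "appending residues never changes in-range
  classifications" holds only when the appended letters do not introduce a
  nearer occurrence of the annotated residue; position-decided categories
  (match, isoform match, mismatch) are unconditionally stable. The
  property tests assert exactly this corrected form.

## Known limitations

* No sequence-window standardization or automated annotation repair —
  out of scope by design; the audit reports inconsistency, it does not fix it.
* Isoform search order is catalog order; a site matching several isoforms
  reports the first.
* The generator cannot plant more sites than there are reference-taxon
  records (one site per record keeps constraints non-interacting); it
  raises rather than degrade.
* GO-style term maps must arrive pre-flattened; no DAG propagation.
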