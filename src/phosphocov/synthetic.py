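"""Synthetic catalogs, annotation sets, memberships and experimental tables.

Every pipeline stage is testable without downloads: each generator plants
an explicit ground truth (harmonization outcome per identifier,
consistency category per site, membership signature per element, sample
labels per PMID) that the corresponding stage must recover *exactly*, not
statistically.  Generation draws integers only from a seeded
``random.Random``, so output is fully deterministic per seed across
platforms.

Defaults encode the audited world at desk scale: harmonization fractions
0.10 secondary / 0.05 obsolete / 0.05 foreign-taxon over an identifier
universe of 1,000; 100 planted sites split 60 canonical matches, 10
isoform matches, 5 mismatches, 20 offsets (5 each of magnitudes 1, 2, 3
and 7, both signs), 5 unmatched; a five-database membership vector using
the published unique/global-intersection counts (HPRD 26,423, PSP-KS
3,980, BioGRID 3,059, SIGNOR 638, Reactome 599, 42 common to all five);
and six cell lines with descending publication counts, 30% of PMIDs
multi-sample.

Sequences are i.i.d. uniform over the 20-letter alphabet — the planted
constraints need structure, not compositional realism.  ``plant_sites``
edits the generated sequences in place to enforce each planted category
under the classifier's documented precedence, then re-classifies every
planted site and fails loudly on any disagreement.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .consistency import DEFAULT_PHOSPHO_RESIDUES, classify_site
from .types import (
    AMINO_ACIDS,
    AnnotationSet,
    ExperimentalRecord,
    Phosphosite,
    SequenceCatalog,
    SequenceRecord,
    site_sort_key,
)

FOREIGN_TAXON = 10090  # mouse, the stand-in for any non-reference species

#: Non-phosphorylatable filler letters used when clearing planted windows.
_BLOCKER = "A"
_CLEARER = "L"

DEFAULT_CATEGORY_COUNTS: dict[str, int] = {
    "canonical_match": 60,
    "isoform_match": 10,
    "mismatch": 5,
    "unmatched": 5,
}

#: Twenty planted signed offsets: five each of magnitudes 1, 2, 3 and 7.
DEFAULT_OFFSETS: tuple[int, ...] = (
    1, -1, 1, -1, -1,
    2, -2, 2, -2, 2,
    3, -3, 3, -3, -3,
    7, -7, 7, -7, 7,
)

DEFAULT_MEMBERSHIP: dict[tuple[str, ...], int] = {
    ("HPRD",): 26423,
    ("PSP-KS",): 3980,
    ("BioGRID",): 3059,
    ("SIGNOR",): 638,
    ("Reactome",): 599,
    ("BioGRID", "HPRD", "PSP-KS", "Reactome", "SIGNOR"): 42,
}


@dataclass
class SampleSpec:
    """Shape of the synthetic experimental table.

    The six labels are the audit's top cell lines; publication counts
    descend so the ranking is unambiguous (a desk-scale stand-in for the
    real corpus of 191 publications across 484 conditions).
    """

    labels: tuple[str, ...] = (
        "HeLa",
        "HEK293",
        "HeLa S3",
        "Jurkat",
        "MCF-7",
        "MCF-10A",
    )
    pmids_per_sample: tuple[int, ...] = (30, 24, 18, 14, 10, 6)
    sites_per_pmid: int = 25
    multi_sample_fraction: float = 0.3


@dataclass
class SyntheticSpec:
    """Full description of one synthetic world; the seed is mandatory."""

    seed: int
    n_proteins: int = 1000
    length_range: tuple[int, int] = (100, 600)
    isoform_count_range: tuple[int, int] = (0, 2)
    fraction_secondary: float = 0.10
    fraction_obsolete: float = 0.05
    fraction_foreign_taxon: float = 0.05
    fraction_unreviewed: float = 0.25
    category_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    offsets: tuple[int, ...] = DEFAULT_OFFSETS
    membership_vector: dict[tuple[str, ...], int] = field(
        default_factory=lambda: dict(DEFAULT_MEMBERSHIP)
    )
    samples: SampleSpec = field(default_factory=SampleSpec)

    def validate(self) -> "SyntheticSpec":
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        for name in ("fraction_secondary", "fraction_obsolete",
                     "fraction_foreign_taxon", "fraction_unreviewed"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid length_range {self.length_range}")
        if any(c < 0 for c in self.category_counts.values()):
            raise ValueError("category counts must be >= 0")
        if any(m == 0 for m in self.offsets):
            raise ValueError("planted offsets must be non-zero")
        max_mag = max((abs(m) for m in self.offsets), default=0)
        if self.offsets and lo < 2 * max_mag + 2:
            raise ValueError(
                f"minimum sequence length {lo} cannot host offsets of "
                f"magnitude {max_mag}"
            )
        if not 0.0 <= self.samples.multi_sample_fraction <= 1.0:
            raise ValueError("multi_sample_fraction must be in [0, 1]")
        if len(self.samples.labels) != len(self.samples.pmids_per_sample):
            raise ValueError("labels and pmids_per_sample lengths differ")
        if self.samples.multi_sample_fraction > 0 and len(self.samples.labels) < 2:
            raise ValueError("multi-sample PMIDs need at least two labels")
        return self


@dataclass(frozen=True)
class PlantedSite:
    category: str
    signed_offset: int | None = None


@dataclass
class SyntheticTruth:
    """Planted labels against which every stage's output is checked."""

    harmonization: dict[str, str] = field(default_factory=dict)
    site_categories: dict[Phosphosite, PlantedSite] = field(default_factory=dict)
    membership: dict[str, frozenset[str]] = field(default_factory=dict)
    pmid_samples: dict[str, frozenset[str]] = field(default_factory=dict)
    sample_sites: dict[str, set[Phosphosite]] = field(default_factory=dict)

    def harmonization_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for outcome in self.harmonization.values():
            counts[outcome] = counts.get(outcome, 0) + 1
        return counts

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for planted in self.site_categories.values():
            counts[planted.category] = counts.get(planted.category, 0) + 1
        return counts

    def membership_vector(self) -> dict[frozenset[str], int]:
        vector: dict[frozenset[str], int] = {}
        for sig in self.membership.values():
            vector[sig] = vector.get(sig, 0) + 1
        return vector


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(AMINO_ACIDS[rng.randrange(20)] for _ in range(length))


def make_catalog(spec: SyntheticSpec) -> tuple[SequenceCatalog, SyntheticTruth]:
    """Generate a catalog whose identifier universe has exactly the planted
    harmonization composition.

    The universe holds ``n_proteins`` identifiers: round(f·n) secondary,
    obsolete and foreign-taxon tokens, the remainder human primaries —
    so bucket fractions recovered by harmonization equal the planted
    fractions exactly, not approximately.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    truth = SyntheticTruth()
    n = spec.n_proteins
    n_secondary = round(spec.fraction_secondary * n)
    n_obsolete = round(spec.fraction_obsolete * n)
    n_foreign = round(spec.fraction_foreign_taxon * n)
    n_human = n - n_secondary - n_obsolete - n_foreign
    if n_human < 0:
        raise ValueError("planted fractions exceed the identifier universe")
    if n_secondary > 0 and n_human == 0:
        raise ValueError("secondary accessions need human primaries to map to")

    lo, hi = spec.length_range
    iso_lo, iso_hi = spec.isoform_count_range
    records: dict[str, SequenceRecord] = {}
    human_bases: list[str] = []
    n_unreviewed = round(spec.fraction_unreviewed * n_human)

    for i in range(n_human + n_foreign):
        foreign = i >= n_human
        base = f"F{i - n_human:05d}" if foreign else f"P{i:05d}"
        canonical = _random_sequence(rng, rng.randrange(lo, hi + 1))
        isoforms = {}
        for j in range(2, 2 + rng.randrange(iso_lo, iso_hi + 1)):
            isoforms[f"{base}-{j}"] = _random_sequence(rng, rng.randrange(lo, hi + 1))
        reviewed = foreign or i >= n_unreviewed  # first human block is tr
        records[base] = SequenceRecord(
            accession=base,
            canonical=canonical,
            reviewed=reviewed,
            taxon=FOREIGN_TAXON if foreign else 9606,
            isoforms=isoforms,
        )
        if foreign:
            truth.harmonization[base] = "taxon_dropped"
        else:
            human_bases.append(base)
            truth.harmonization[base] = "primary"

    secondary: dict[str, str] = {}
    for i in range(n_secondary):
        acc = f"S{i:05d}"
        secondary[acc] = human_bases[rng.randrange(len(human_bases))]
        truth.harmonization[acc] = "secondary_mapped"
    obsolete: set[str] = set()
    for i in range(n_obsolete):
        acc = f"O{i:05d}"
        obsolete.add(acc)
        truth.harmonization[acc] = "obsolete_dropped"

    catalog = SequenceCatalog(
        records=records,
        secondary_to_primary=secondary,
        obsolete=obsolete,
        reference_taxon=9606,
    )
    return catalog.validate(), truth


def _plant_one(
    rng: random.Random,
    record: SequenceRecord,
    category: str,
    signed_offset: int | None,
    residue_pool: Sequence[str],
    residues: frozenset[str],
) -> Phosphosite:
    """Edit one record's sequences so a fresh site classifies as planted."""
    target = residue_pool[rng.randrange(len(residue_pool))]
    canon = list(record.canonical)
    length = len(canon)

    def write_back() -> None:
        record.canonical = "".join(canon)

    def block_isoforms_at(position: int) -> None:
        for iso_id, seq in record.isoforms.items():
            if len(seq) >= position:
                chars = list(seq)
                chars[position - 1] = _BLOCKER
                record.isoforms[iso_id] = "".join(chars)

    if category == "canonical_match":
        position = rng.randrange(1, length + 1)
        canon[position - 1] = target
        write_back()
        return Phosphosite(record.accession, target, position)

    if category == "isoform_match":
        position = rng.randrange(1, length + 1)
        canon[position - 1] = _BLOCKER
        write_back()
        if not record.isoforms:
            record.isoforms[f"{record.accession}-2"] = record.canonical
        iso_id = next(iter(record.isoforms))
        seq = record.isoforms[iso_id]
        if len(seq) < position:
            seq = seq + _random_sequence(rng, position - len(seq))
        chars = list(seq)
        chars[position - 1] = target
        record.isoforms[iso_id] = "".join(chars)
        return Phosphosite(record.accession, target, position)

    if category == "mismatch":
        position = rng.randrange(1, length + 1)
        others = [r for r in residue_pool if r != target]
        canon[position - 1] = others[rng.randrange(len(others))]
        write_back()
        block_isoforms_at(position)
        return Phosphosite(record.accession, target, position)

    if category == "offset":
        assert signed_offset is not None and signed_offset != 0
        magnitude = abs(signed_offset)
        if length < 2 * magnitude + 2:
            raise ValueError(
                f"{record.accession}: sequence of length {length} cannot host "
                f"an offset of magnitude {magnitude}"
            )
        position = rng.randrange(magnitude + 1, length - magnitude + 1)
        # Clear the whole tie window of the target residue, then place the
        # single nearest occurrence on the planted side.
        for x in range(position - magnitude, position + magnitude + 1):
            if canon[x - 1] == target:
                canon[x - 1] = _CLEARER
        canon[position - 1] = _BLOCKER  # not the target, not phosphorylatable
        matched = position - signed_offset
        canon[matched - 1] = target
        write_back()
        block_isoforms_at(position)
        return Phosphosite(record.accession, target, position)

    if category == "unmatched":
        position = length + rng.randrange(1, 51)
        if target not in canon:
            # Guarantee the canonical holds the residue somewhere so the
            # isoform fallback search is never triggered.
            canon[rng.randrange(length)] = target
            write_back()
        block_isoforms_at(position)
        return Phosphosite(record.accession, target, position)

    raise ValueError(f"unknown planted category {category!r}")


def plant_sites(
    catalog: SequenceCatalog,
    category_counts: Mapping[str, object],
    seed: int,
    residues: frozenset[str] = DEFAULT_PHOSPHO_RESIDUES,
) -> tuple[AnnotationSet, SyntheticTruth]:
    """Plant one phosphosite per reference-taxon record, by category.

    ``category_counts`` maps category names to counts; the ``"offset"``
    key instead carries a sequence of signed offsets, one planted site
    each.  The catalog's sequences are edited in place to enforce every
    constraint; a final verification pass re-classifies all planted sites
    and raises if any disagrees with its label.
    """
    rng = random.Random(seed)
    counts = dict(category_counts)
    offsets = list(counts.pop("offset", ()) or ())  # type: ignore[arg-type]
    jobs: list[tuple[str, int | None]] = []
    for cat in ("canonical_match", "isoform_match", "mismatch", "unmatched"):
        jobs.extend([(cat, None)] * int(counts.pop(cat, 0)))  # type: ignore[call-overload]
    if counts:
        raise ValueError(f"unknown planted categories {sorted(counts)}")
    jobs.extend(("offset", int(m)) for m in offsets)

    eligible = sorted(
        base
        for base, rec in catalog.records.items()
        if rec.taxon == catalog.reference_taxon
    )
    if len(jobs) > len(eligible):
        raise ValueError(
            f"cannot plant {len(jobs)} sites on {len(eligible)} "
            "reference-taxon records (one site per record)"
        )
    rng.shuffle(jobs)
    chosen = rng.sample(eligible, len(jobs))
    residue_pool = sorted(residues)

    truth = SyntheticTruth()
    sites: set[Phosphosite] = set()
    for base, (category, signed) in zip(chosen, jobs):
        site = _plant_one(
            rng, catalog.records[base], category, signed, residue_pool, residues
        )
        sites.add(site)
        planted_offset = 0 if category in ("canonical_match", "isoform_match") else signed
        truth.site_categories[site] = PlantedSite(category, planted_offset)

    for site, planted in truth.site_categories.items():
        clf = classify_site(site, catalog.records[site.accession], residues)
        offset_ok = (
            planted.category != "offset" or clf.signed_offset == planted.signed_offset
        )
        if clf.category.value != planted.category or not offset_ok:
            raise RuntimeError(
                f"planted-site verification failed for {site}: planted "
                f"{planted}, classified {clf.category.value} "
                f"(signed offset {clf.signed_offset})"
            )

    aset = AnnotationSet(
        name="planted",
        proteins={s.accession for s in sites},
        sites=sites,
    )
    return aset, truth


def make_membership(
    names: Sequence[str],
    membership_vector: Mapping[tuple[str, ...], int],
    seed: int = 0,
) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """Build named sets realizing an exclusive-intersection vector exactly.

    Each signature receives exactly its planted number of fresh elements,
    so running ``exclusive_intersections`` on the output reproduces the
    vector verbatim.  Generation is deterministic regardless of seed (the
    parameter exists for interface symmetry).
    """
    del seed
    name_set = set(names)
    sets: dict[str, set[str]] = {name: set() for name in names}
    truth = SyntheticTruth()
    counter = 0
    for key in sorted(membership_vector, key=lambda sig: tuple(sorted(sig))):
        signature = frozenset(key)
        if not signature or not signature <= name_set:
            raise ValueError(
                f"signature {sorted(key)} is not a non-empty subset of names"
            )
        for _ in range(membership_vector[key]):
            element = f"M{counter:06d}"
            counter += 1
            for name in signature:
                sets[name].add(element)
            truth.membership[element] = signature
    return sets, truth


def make_experimental(
    sample_spec: SampleSpec,
    site_pool: Sequence[Phosphosite],
    seed: int,
) -> tuple[list[ExperimentalRecord], SyntheticTruth]:
    """Generate PMID-tagged experimental records with planted sample labels.

    Exactly round(multi_sample_fraction · total PMIDs) publications carry
    a second sample label; the rest are single-sample, and their per-sample
    site sets are recorded in the truth.
    """
    if not site_pool:
        raise ValueError("site pool must be non-empty")
    rng = random.Random(seed)
    pool = sorted(set(site_pool), key=site_sort_key)
    labels = list(sample_spec.labels)

    pmids: list[tuple[str, str]] = []
    counter = 0
    for label, count in zip(labels, sample_spec.pmids_per_sample):
        for _ in range(count):
            pmids.append((f"PM{counter:06d}", label))
            counter += 1

    n_multi = round(sample_spec.multi_sample_fraction * len(pmids))
    if n_multi > 0 and len(labels) < 2:
        raise ValueError("multi-sample PMIDs need at least two labels")
    multi_indices = set(rng.sample(range(len(pmids)), n_multi))

    truth = SyntheticTruth()
    records: list[ExperimentalRecord] = []
    per_pmid = min(sample_spec.sites_per_pmid, len(pool))
    for index, (pmid, label) in enumerate(pmids):
        samples = {label}
        if index in multi_indices:
            others = [l for l in labels if l != label]
            samples.add(others[rng.randrange(len(others))])
        chosen = rng.sample(pool, per_pmid)
        tag = frozenset(samples)
        truth.pmid_samples[pmid] = tag
        for site in chosen:
            records.append(ExperimentalRecord(site, pmid, tag))
        if len(samples) == 1:
            truth.sample_sites.setdefault(label, set()).update(chosen)
    return records, truth


@dataclass
class SimulationBundle:
    """Everything one seed produces, with merged ground truth."""

    spec: SyntheticSpec
    catalog: SequenceCatalog
    planted: AnnotationSet
    raw_ids: AnnotationSet
    membership_sets: dict[str, set[str]]
    experimental: list[ExperimentalRecord]
    truth: SyntheticTruth


def simulate(spec: SyntheticSpec) -> SimulationBundle:
    """Run every generator off one master seed and merge the truths.

    ``raw_ids`` is the protein set covering the whole identifier universe
    (primaries, secondaries, obsolete, foreign) whose harmonization report
    must reproduce the planted bucket counts exactly.
    """
    spec.validate()
    master = random.Random(spec.seed)
    seeds = [master.randrange(2**31) for _ in range(3)]

    catalog, truth = make_catalog(spec)
    planted, site_truth = plant_sites(
        catalog,
        {**spec.category_counts, "offset": spec.offsets},
        seeds[0],
    )
    truth.site_categories = site_truth.site_categories

    names = sorted({n for sig in spec.membership_vector for n in sig})
    membership_sets, member_truth = make_membership(
        names, spec.membership_vector, seeds[1]
    )
    truth.membership = member_truth.membership

    records, exp_truth = make_experimental(
        spec.samples, sorted(planted.sites, key=site_sort_key), seeds[2]
    )
    truth.pmid_samples = exp_truth.pmid_samples
    truth.sample_sites = exp_truth.sample_sites

    raw_ids = AnnotationSet(name="raw_ids", proteins=set(truth.harmonization))
    return SimulationBundle(
        spec, catalog, planted, raw_ids, membership_sets, records, truth
    )
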