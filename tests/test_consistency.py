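
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphocov.consistency import (
    Category,
    classify_site,
    nearest_occurrence,
    offset_bin,
    residue_at,
    summarize,
)
from phosphocov.synthetic import SyntheticSpec, make_catalog, plant_sites
from phosphocov.types import AMINO_ACIDS, Phosphosite, SequenceRecord


def scan_oracle(sequence, residue, position):
    """Independent linear scan: min distance, ties to the larger position."""
    hits = [i for i, c in enumerate(sequence, 1) if c == residue]
    if not hits:
        return None
    matched = min(hits, key=lambda i: (abs(position - i), -i))
    return matched, position - matched


def test_residue_at_basics():
    assert residue_at("MSTY", 2) == "S"
    assert residue_at("MSTY", 9) is None
    with pytest.raises(ValueError):
        residue_at("MSTY", 0)


def test_residue_at_agrees_with_direct_indexing(rng):
    for _ in range(1000):
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randrange(1, 40)))
        pos = rng.randrange(1, len(seq) + 10)
        expected = seq[pos - 1] if pos <= len(seq) else None
        assert residue_at(seq, pos) == expected


def test_nearest_occurrence_worked_example():
    # Serine annotated at 495, nearest serine at 490: offset of 5.
    seq = ["A"] * 520
    seq[489] = "S"
    assert nearest_occurrence("".join(seq), "S", 495) == (490, 5)


def test_nearest_occurrence_met_cleavage_sign():
    # Annotation on Met-cleaved coordinates: matched one downstream, offset -1.
    seq = "M" + "A" * 8 + "S" + "A" * 10  # S at canonical position 10
    assert nearest_occurrence(seq, "S", 9) == (10, -1)


def test_nearest_occurrence_tie_prefers_negative_offset():
    seq = "SAS"  # S at 1 and 3, annotation at 2: both at distance 1
    assert nearest_occurrence(seq, "S", 2) == (3, -1)


def test_nearest_occurrence_matches_scan_oracle(rng):
    """Equality with the brute-force scan, including tie-rich alphabets."""
    for trial in range(2000):
        alphabet = "SA" if trial % 2 else AMINO_ACIDS
        seq = "".join(rng.choice(alphabet) for _ in range(rng.randrange(1, 60)))
        pos = rng.randrange(1, len(seq) + 5)
        assert nearest_occurrence(seq, "S", pos) == scan_oracle(seq, "S", pos)


def record(canonical, **isoforms):
    return SequenceRecord("P00001", canonical, isoforms=isoforms)


def site(residue, position):
    return Phosphosite("P00001", residue, position)


def test_classify_canonical_match_at_128():
    rec = record("A" * 127 + "T" + "A" * 60)
    clf = classify_site(site("T", 128), rec)
    assert clf.category is Category.CANONICAL_MATCH
    assert clf.matched_in == "canonical" and clf.signed_offset == 0


def test_classify_mismatch_tyrosine_for_threonine_at_362():
    rec = record("A" * 361 + "Y" + "A" * 40)
    clf = classify_site(site("T", 362), rec)
    assert clf.category is Category.MISMATCH


def test_classify_offset_of_five_bins_plus():
    seq = ["A"] * 520
    seq[489] = "S"
    clf = classify_site(site("S", 495), record("".join(seq)))
    assert clf.category is Category.OFFSET
    assert clf.signed_offset == 5 and clf.magnitude_bin == "+"
    assert clf.matched_position == 490


def test_classify_beyond_length_is_unmatched_without_canonical_search():
    # Canonical holds serines, but 999 exceeds its length and no isoform
    # reaches it: unmatched, no canonical offset search.
    rec = record("S" * 400, **{"P00001-2": "S" * 100})
    clf = classify_site(site("S", 999), rec)
    assert clf.category is Category.UNMATCHED
    assert clf.signed_offset is None and clf.matched_in is None


def test_classify_isoform_match():
    iso = "A" * 9 + "S" + "A" * 10
    rec = record("A" * 20, **{"P00001-2": iso})
    clf = classify_site(site("S", 10), rec)
    assert clf.category is Category.ISOFORM_MATCH
    assert clf.matched_in == "P00001-2" and clf.matched_position == 10


def test_classify_isoform_match_beats_canonical_mismatch_and_offset():
    # Canonical has T at the position and a nearby S, but an isoform holds
    # the annotated S at the exact position: isoform match wins.
    canonical = "A" * 9 + "T" + "S" + "A" * 9
    iso = "A" * 9 + "S" + "A" * 10
    rec = record(canonical, **{"P00001-2": iso})
    assert classify_site(site("S", 10), rec).category is Category.ISOFORM_MATCH


def test_classify_isoform_mismatch_only_when_absent_from_canonical():
    # S absent from the canonical entirely; the isoform has T at the
    # position, a phosphorylatable stand-in: mismatch via the isoform.
    rec = record("A" * 20, **{"P00001-2": "A" * 9 + "T" + "A" * 10})
    assert classify_site(site("S", 10), rec).category is Category.MISMATCH


def test_classify_isoform_offset_when_absent_from_canonical():
    rec = record("A" * 20, **{"P00001-2": "A" * 11 + "S" + "A" * 8})
    clf = classify_site(site("S", 10), rec)
    assert clf.category is Category.OFFSET
    assert clf.matched_in == "P00001-2" and clf.signed_offset == -2


def test_non_phospho_occupant_falls_through_to_offset():
    # L at the annotated position is not phosphorylatable: offset, not mismatch.
    seq = ["A"] * 30
    seq[9] = "L"
    seq[12] = "S"
    clf = classify_site(site("S", 10), record("".join(seq)))
    assert clf.category is Category.OFFSET and clf.signed_offset == -3


@pytest.mark.parametrize("signed,expected", [(1, "1"), (-2, "2"), (3, "3"), (4, "+"), (-7, "+")])
def test_offset_bins(signed, expected):
    assert offset_bin(signed) == expected


def test_summarize_worked_example_trio():
    """The three Protein-X annotations: one match, one mismatch, one offset 5."""
    match_rec = record("A" * 127 + "T" + "A" * 400)
    mismatch_rec = record("A" * 361 + "Y" + "A" * 160)
    offset_seq = ["A"] * 520
    offset_seq[489] = "S"
    offset_rec = record("".join(offset_seq))
    summary = summarize(
        [
            classify_site(site("T", 128), match_rec),
            classify_site(site("T", 362), mismatch_rec),
            classify_site(site("S", 495), offset_rec),
        ]
    )
    assert summary.n_sites == 3
    assert summary.n_consistent == 1
    assert summary.n_mismatch == 1
    assert summary.offset_histogram == {"1": 0, "2": 0, "3": 0, "+": 1}
    assert summary.pct_consistent == pytest.approx(1 / 3)


def test_summarize_empty_is_all_zero():
    summary = summarize([])
    assert summary.n_sites == 0 and summary.pct_consistent == 0.0


def test_planted_mixture_recovered_exactly_seed_42():
    """60/10/5/20/5 planted categories are tallied back without error."""
    catalog, _ = make_catalog(SyntheticSpec(seed=42, n_proteins=200))
    counts = {
        "canonical_match": 60,
        "isoform_match": 10,
        "mismatch": 5,
        "unmatched": 5,
        "offset": [1, -1, 2, -2, 3, -3, 7, -7] * 2 + [1, 2, 3, 7],
    }
    aset, truth = plant_sites(catalog, counts, seed=42)
    summary = summarize(
        classify_site(s, catalog.records[s.accession]) for s in aset.sites
    )
    assert summary.n_sites == 100
    assert summary.n_consistent == 60
    assert summary.n_isoform == 10
    assert summary.n_mismatch == 5
    assert summary.n_unmatched == 5
    assert summary.offset_histogram == {"1": 5, "2": 5, "3": 5, "+": 5}
    assert truth.category_counts()["offset"] == 20


sequences = st.text(alphabet="ASTYL", min_size=5, max_size=60)


@given(
    seq=sequences,
    residue=st.sampled_from("STY"),
    position=st.integers(1, 60),
    tail=st.text(alphabet="AL", min_size=1, max_size=30),
)
def test_appending_non_target_residues_never_changes_classification(
    seq, residue, position, tail
):
    """Extending the canonical with letters other than the annotated residue
    leaves any in-range site's classification untouched."""
    if position > len(seq):
        position = len(seq)
    rec_before = SequenceRecord("P00001", seq)
    rec_after = SequenceRecord("P00001", seq + tail)
    s = Phosphosite("P00001", residue, position)
    before = classify_site(s, rec_before)
    after = classify_site(s, rec_after)
    assert before.category == after.category
    assert before.signed_offset == after.signed_offset


@given(
    seq=sequences,
    residue=st.sampled_from("STY"),
    position=st.integers(1, 60),
    tail=st.text(alphabet="ASTYL", min_size=1, max_size=30),
)
def test_position_decided_categories_survive_any_extension(
    seq, residue, position, tail
):
    """Match/isoform-match/mismatch are decided at the annotated position and
    cannot be disturbed by anything appended after the end."""
    if position > len(seq):
        position = len(seq)
    s = Phosphosite("P00001", residue, position)
    before = classify_site(s, SequenceRecord("P00001", seq))
    if before.category in (
        Category.CANONICAL_MATCH,
        Category.ISOFORM_MATCH,
        Category.MISMATCH,
    ):
        after = classify_site(s, SequenceRecord("P00001", seq + tail))
        assert after.category == before.category


def test_classification_partition_on_random_sites(rng):
    """Every site lands in exactly one category; counts sum to n_sites."""
    catalog, _ = make_catalog(SyntheticSpec(seed=9, n_proteins=40))
    bases = sorted(catalog.records)
    classifications = []
    for _ in range(500):
        base = bases[rng.randrange(len(bases))]
        s = Phosphosite(base, rng.choice("STY"), rng.randrange(1, 700))
        classifications.append(classify_site(s, catalog.records[base]))
    summary = summarize(classifications)
    total = (
        summary.n_consistent
        + summary.n_isoform
        + summary.n_mismatch
        + sum(summary.offset_histogram.values())
        + summary.n_unmatched
    )
    assert total == summary.n_sites == 500
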