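
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosphocov.harmonize import (
    UpdateOutcome,
    harmonize_annotation_set,
    resolve_foreign_id,
    strip_isoform,
    update_accession,
)
from phosphocov.synthetic import SyntheticSpec, make_catalog
from phosphocov.types import Accession, AnnotationSet, Phosphosite

accession_bases = st.from_regex(r"[A-Z][A-Z0-9]{5}", fullmatch=True)


@pytest.mark.parametrize(
    "raw,expected", [("P04637-2", "P04637"), ("P04637", "P04637"), ("Q9Y6K9-12", "Q9Y6K9")]
)
def test_strip_isoform(raw, expected):
    assert strip_isoform(raw) == expected


@given(base=accession_bases, index=st.integers(1, 99))
def test_strip_inverts_render_for_any_isoform(base, index):
    assert strip_isoform(Accession(base, index).render()) == base


@pytest.mark.parametrize(
    "base,outcome,target",
    [
        ("P11111", UpdateOutcome.PRIMARY, "P11111"),
        ("S11111", UpdateOutcome.SECONDARY_MAPPED, "P11111"),
        ("O11111", UpdateOutcome.OBSOLETE_DROPPED, None),
        ("P99999", UpdateOutcome.TAXON_DROPPED, None),
        ("Z98765", UpdateOutcome.UNKNOWN_DROPPED, None),
    ],
)
def test_update_accession_outcomes(small_catalog, base, outcome, target):
    assert update_accession(base, small_catalog) == (outcome, target)


@pytest.mark.parametrize(
    "candidates,expected",
    [
        ({"P11111", "Q33333"}, "P11111"),  # reviewed beats longer unreviewed
        ({"P11111", "P22222"}, "P22222"),  # both reviewed: longest wins
        ({"P55555", "P44444"}, "P44444"),  # all unreviewed: longest wins
        (set(), None),
    ],
)
def test_resolve_foreign_id_rule(small_catalog, candidates, expected):
    assert resolve_foreign_id(candidates, small_catalog) == expected


def test_resolve_foreign_id_matches_exhaustive_rule(small_catalog, rng):
    """The selection matches an independently coded reviewed/longest/name rule."""

    def oracle(candidates):
        known = [c for c in candidates if c in small_catalog.records]
        if not known:
            return None
        reviewed = [c for c in known if small_catalog.records[c].reviewed]
        pool = reviewed or known
        best = None
        for c in pool:
            length = len(small_catalog.records[c].canonical)
            if (
                best is None
                or length > best[0]
                or (length == best[0] and c < best[1])
            ):
                best = (length, c)
        return best[1]

    universe = sorted(small_catalog.records) + ["Z00001", "Z00002"]
    for _ in range(300):
        candidates = set(rng.sample(universe, rng.randrange(0, len(universe) + 1)))
        assert resolve_foreign_id(candidates, small_catalog) == oracle(candidates)


def test_obsolete_protein_cascades_its_sites(small_catalog):
    raw = AnnotationSet(
        name="db",
        proteins={"O11111"},
        sites={
            Phosphosite("O11111", "S", 1),
            Phosphosite("O11111", "T", 2),
            Phosphosite("O11111", "Y", 3),
        },
    )
    out, report = harmonize_annotation_set(raw, small_catalog)
    assert out.proteins == set() and out.sites == set()
    assert report.dropped_obsolete == {"O11111"}
    assert report.n_sites_dropped == 3


def test_isoform_site_reassigned_to_base(small_catalog):
    raw = AnnotationSet(name="db", sites={Phosphosite("P11111-2", "S", 10)})
    out, report = harmonize_annotation_set(raw, small_catalog)
    assert out.sites == {Phosphosite("P11111", "S", 10)}
    assert report.isoforms_stripped == 1


def test_secondary_site_rekeyed_and_merged(small_catalog):
    raw = AnnotationSet(
        name="db",
        sites={Phosphosite("S11111", "S", 10), Phosphosite("P11111", "S", 10)},
    )
    out, _ = harmonize_annotation_set(raw, small_catalog)
    assert out.sites == {Phosphosite("P11111", "S", 10)}


def test_planted_fraction_recovery_seed_17():
    """Report bucket fractions equal the planted 10/5/5% exactly."""
    spec = SyntheticSpec(
        seed=17,
        n_proteins=1000,
        fraction_secondary=0.10,
        fraction_obsolete=0.05,
        fraction_foreign_taxon=0.05,
    )
    catalog, truth = make_catalog(spec)
    raw = AnnotationSet(name="raw", proteins=set(truth.harmonization))
    _, report = harmonize_annotation_set(raw, catalog)
    counts = report.bucket_counts()
    n = spec.n_proteins
    assert counts["secondary_mapped"] / n == spec.fraction_secondary
    assert counts["obsolete_dropped"] / n == spec.fraction_obsolete
    assert counts["taxon_dropped"] / n == spec.fraction_foreign_taxon
    assert counts == truth.harmonization_counts() | {"unknown_dropped": 0}


def test_harmonization_is_idempotent(small_catalog):
    raw = AnnotationSet(
        name="db",
        proteins={"P11111", "S11111", "O11111", "P99999", "Z00009"},
        sites={Phosphosite("S11111", "S", 4), Phosphosite("P22222-3", "T", 8)},
    )
    once, _ = harmonize_annotation_set(raw, small_catalog)
    twice, report = harmonize_annotation_set(once, small_catalog)
    assert twice == once
    assert report.mapped_secondary == {} and report.n_sites_dropped == 0


@given(
    ids=st.sets(
        st.one_of(
            st.sampled_from(
                ["P11111", "P22222", "S11111", "O11111", "P99999", "Z00001"]
            ),
            st.from_regex(r"[A-Z][A-Z0-9]{5}(-[1-9])?", fullmatch=True),
            st.sampled_from(["not-an-accession", "x", "P1"]),
        ),
        max_size=20,
    )
)
def test_every_identifier_lands_in_exactly_one_bucket(small_catalog, ids):
    """Conservation: report buckets partition the distinct stripped inputs."""
    raw = AnnotationSet(name="db", proteins=set(ids))
    _, report = harmonize_annotation_set(raw, small_catalog)

    distinct = set()
    for rid in ids:
        try:
            distinct.add(Accession.parse(rid).base)
        except Exception:
            distinct.add(rid)
    buckets = [
        report.kept_primary,
        set(report.mapped_secondary),
        report.dropped_obsolete,
        report.dropped_taxon,
        report.dropped_unmappable,
    ]
    assert report.n_inputs == len(distinct)
    union = set().union(*buckets)
    assert union == distinct
    assert sum(len(b) for b in buckets) == len(distinct)
    assert set(report.mapped_secondary.values()) <= report.kept
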