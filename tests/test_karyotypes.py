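"""Karyotype formula parsing, arm-ratio classes and derived traits."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoevol.karyotypes import (
    KaryotypeParseError,
    classify_arm_ratio,
    format_formula,
    fundamental_number,
    load_fixture,
    parse_formula,
    trait_table,
    traits_from_counts,
)


@pytest.mark.parametrize("text,expected", [
    ("12 m + 6sm + 4st", {"m": 12, "sm": 6, "st": 4, "t": 0}),
    ("2 m + 6sm + 16st + 14 t", {"m": 2, "sm": 6, "st": 16, "t": 14}),
    ("20 m", {"m": 20, "sm": 0, "st": 0, "t": 0}),
    ("10a + 2m", {"m": 2, "sm": 0, "st": 0, "t": 10}),  # acrocentric -> t
])
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


@pytest.mark.parametrize("text", ["12x + 3m", "", "  ", "m + 3sm", "3.5m"])
def test_parse_formula_rejects_malformed(text):
    with pytest.raises(KaryotypeParseError):
        parse_formula(text)


@given(counts=st.fixed_dictionaries(
    {c: st.integers(min_value=0, max_value=40) for c in ("m", "sm", "st", "t")}))
@settings(max_examples=50, deadline=None)
def test_format_parse_round_trip(counts):
    if sum(counts.values()) == 0:
        with pytest.raises(KaryotypeParseError):
            format_formula(counts)
    else:
        assert parse_formula(format_formula(counts)) == counts


@pytest.mark.parametrize("counts,expected", [
    # Acromyrmex balzani row: 12m + 10sm + 14st + 2t
    ({"m": 12, "sm": 10, "st": 14, "t": 2},
     dict(n=19, nm=6, nsm=5, nst=7, nt=1, fn=74)),
    # Amoimyrmex striatus row: 20m + 2sm
    ({"m": 20, "sm": 2, "st": 0, "t": 0},
     dict(n=11, nm=10, nsm=1, nst=0, nt=0, fn=44)),
])
def test_traits_from_counts(counts, expected):
    assert traits_from_counts(counts).as_dict() == expected


def test_traits_from_counts_edge_cases():
    with pytest.raises(ValueError):
        traits_from_counts({"m": 0, "sm": 0, "st": 0, "t": 0})
    with pytest.raises(ValueError):  # odd class count in strict mode
        traits_from_counts({"m": 3, "sm": 1, "st": 0, "t": 0})
    tv = traits_from_counts({"m": 3, "sm": 1, "st": 0, "t": 0}, strict=False)
    assert tv.n == 2


@pytest.mark.parametrize("long,short,expected", [
    (1.0, 1.0, "m"),
    (1.69, 1.0, "m"),
    (2.0, 1.0, "sm"),
    (3.0, 1.0, "st"),
    (6.9, 1.0, "st"),
    (7.0, 1.0, "t"),
    (5.0, 0.0, "t"),
])
def test_classify_arm_ratio(long, short, expected):
    assert classify_arm_ratio(long, short) == expected


def test_classify_arm_ratio_rejects_invalid():
    with pytest.raises(ValueError):
        classify_arm_ratio(1.0, 2.0)
    with pytest.raises(ValueError):
        classify_arm_ratio(0.0, 0.0)


class TestFixture:
    def test_row_counts(self):
        records = load_fixture()
        assert len(records) == 33
        assert sum(r.group == "leafcutting" for r in records) == 30
        assert sum(r.group == "outgroup" for r in records) == 3

    def test_duplicate_species_records(self):
        records = load_fixture()
        ambiguus = [r for r in records if r.taxon == "Acromyrmex ambiguus"]
        assert len(ambiguus) == 2
        assert ambiguus[0].formula != ambiguus[1].formula

    def test_formula_sums_to_2n_everywhere(self):
        # enforced by the KaryotypeRecord invariant at load time; assert
        # explicitly over the whole table
        for rec in load_fixture():
            assert sum(rec.formula.values()) == rec.diploid_2n
            assert rec.diploid_2n == 2 * rec.haploid_n

    def test_trait_identity_over_fixture(self):
        for rec in load_fixture():
            tv = rec.traits
            assert tv.nm + tv.nsm + tv.nst + tv.nt == tv.n

    def test_inconsistent_fn_rows_are_flagged(self):
        flagged = {(r.taxon, r.locality) for r in load_fixture()
                   if not r.fn_consistent}
        # four Atta rows print fn=40 where the two-armed-st convention
        # gives 44; the Brazilian A. ambiguus record prints 68 vs 72
        assert flagged == {
            ("Atta bisphaerica", "Brazil"),
            ("Atta colombica", "Panama"),
            ("Atta laevigata", "Brazil"),
            ("Atta sexdens", "Brazil"),
            ("Acromyrmex ambiguus", "Brazil"),
        }
        for rec in load_fixture():
            if rec.fn_consistent:
                assert rec.fn_printed == fundamental_number(rec.formula)

    def test_preferred_table_unique_per_species(self):
        table = trait_table()
        assert not table["taxon"].duplicated().any()
        # 27 leafcutting species + 3 outgroups, duplicates collapsed
        assert len(table) == 30 - 5 + 3

    def test_log_transform_handles_zero_counts(self):
        table = trait_table(log_transform=True)
        assert (table[["n", "nm", "nsm", "nst", "nt", "fn"]] >= 0).all().all()
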