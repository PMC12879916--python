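import pytest
from hypothesis import given
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass
from pyteomics import parser as pyteomics_parser

from selenospec.constants import MODIFICATIONS
from selenospec.peptide_match import (
    Peptide,
    PeptideMatchResult,
    ProteinRecord,
    TierThresholds,
    coverage_and_tier,
    digest,
    fragment_ladder,
    match_masses,
    peptide_mass,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def pep(seq, start=1, mods=()):
    return Peptide(seq, start, start + len(seq) - 1, 0, tuple(mods))


# --- digestion --------------------------------------------------------------


def test_trypsin_does_not_cleave_before_proline():
    out = digest(ProteinRecord("toy", "AKRPGR"), max_missed=0)
    assert [(p.sequence, p.start, p.end) for p in out] == [("AK", 1, 2), ("RPGR", 3, 6)]


def test_sequence_without_cleavage_sites_is_one_peptide():
    out = digest(ProteinRecord("toy", "ACDEFG"), max_missed=0)
    assert len(out) == 1 and out[0].sequence == "ACDEFG"


def test_missed_cleavage_enumeration():
    out = digest(ProteinRecord("toy", "AKR"), max_missed=1)
    assert {(p.sequence, p.missed_cleavages) for p in out} == {
        ("AK", 0),
        ("R", 0),
        ("AKR", 1),
    }


@given(st.text(alphabet=AA, min_size=1, max_size=60))
def test_zero_missed_peptides_tile_the_parent(seq):
    protein = ProteinRecord("p", seq)
    frags = [p for p in digest(protein, max_missed=2) if p.missed_cleavages == 0]
    assert "".join(p.sequence for p in frags) == seq
    pos = 1
    for p in frags:
        assert p.start == pos
        pos = p.end + 1


# W and M excluded: the expasy rule carries the rare WKP/MRP exception
# clauses this digest deliberately omits (plain Keil rule)
@given(st.text(alphabet="ACDEFGHIKLNPQRSTVY", min_size=1, max_size=60))
def test_cleavage_sets_match_pyteomics(seq):
    ours = {p.sequence for p in digest(ProteinRecord("p", seq), max_missed=2)}
    theirs = pyteomics_parser.cleave(seq, pyteomics_parser.expasy_rules["trypsin"], 2)
    assert ours == set(theirs)


# --- masses -----------------------------------------------------------------


def test_glycine_monoisotopic_mass():
    assert peptide_mass(pep("G")) == pytest.approx(75.03203, abs=1e-5)


def test_carbamidomethyl_shift_is_additive():
    bare = peptide_mass(pep("ACDK"))
    modded = peptide_mass(pep("ACDK", mods=[(2, "carbamidomethyl")]))
    assert modded - bare == pytest.approx(57.02146, abs=1e-9)


def test_dehydroalanine_shift_on_selenocysteine():
    bare = peptide_mass(pep("GUK"))
    modded = peptide_mass(pep("GUK", mods=[(2, "dehydroalanine")]))
    assert modded - bare == pytest.approx(-81.93218, abs=1e-9)


@given(st.text(alphabet=AA, min_size=1, max_size=30))
def test_monoisotopic_masses_match_pyteomics(seq):
    ours = peptide_mass(pep(seq))
    theirs = pyteomics_mass.calculate_mass(sequence=seq)
    assert ours == pytest.approx(theirs, abs=2e-4)


def test_unknown_mass_kind_and_misplaced_mod_fail():
    with pytest.raises(ValueError, match="kind"):
        peptide_mass(pep("GG"), kind="exact")
    with pytest.raises(ValueError, match="carbamidomethyl"):
        peptide_mass(pep("GG", mods=[(1, "carbamidomethyl")]))


# --- matching and coverage --------------------------------------------------


def masses_of(seqs):
    return [peptide_mass(pep(s)) for s in seqs]


def test_self_match_reaches_full_coverage():
    """Control-standard analogue: observing every digest mass covers 100 %."""
    protein = ProteinRecord("ctl", "ACDEFGKLMNQSTVWYKGHIDEK")
    peptides = digest(protein, max_missed=0)
    observed = [peptide_mass(p) for p in peptides]
    result = match_masses(protein, peptides, observed, fixed_mods=(), variable_mods=())
    assert result.coverage_fraction == pytest.approx(1.0)
    assert result.tier == "confirmed"


def test_shifted_masses_do_not_match():
    protein = ProteinRecord("ctl", "ACDEFGKLMNQSTVWYK")
    peptides = digest(protein, max_missed=0)
    observed = [peptide_mass(p) * (1 + 40e-6) for p in peptides]  # 2x the 20 ppm tol
    result = match_masses(protein, peptides, observed, fixed_mods=(), variable_mods=())
    assert result.matches == []
    assert result.coverage_fraction == 0.0


def test_empty_observed_list_is_zero_coverage_not_error():
    protein = ProteinRecord("p", "ACDEFGK")
    result = match_masses(protein, digest(protein), [])
    assert result.coverage_fraction == 0.0
    assert result.tier == "not_confirmed"


def test_each_observed_mass_used_at_most_once():
    protein = ProteinRecord("p", "ACDEFGKACDEFGK")  # two identical fragments
    peptides = digest(protein, max_missed=0)
    one_mass = [peptide_mass(pep("ACDEFGK"), "mono")]
    result = match_masses(protein, peptides, one_mass, fixed_mods=(), variable_mods=())
    assert len(result.matches) == 1


def test_synthetic_85mer_reports_8824_percent(synthetic_selenow):
    """75 of 85 residues spanned by matched peptides -> 88.24 %, confirmed."""
    sequence, observed_segments = synthetic_selenow
    protein = ProteinRecord("SELENOW-like", sequence)
    peptides = digest(protein, max_missed=0)
    observed = [
        pyteomics_mass.calculate_mass(sequence=s)
        + sum(57.02146 for aa in s if aa == "C")
        for s in observed_segments
    ]
    result = match_masses(protein, peptides, observed)
    assert result.coverage_fraction == pytest.approx(75 / 85)
    assert result.coverage_percent == 88.24
    assert result.tier == "confirmed"


def test_coverage_counts_interval_union_once():
    result = PeptideMatchResult(protein_id="p", protein_length=20)
    result.matches = [
        type("M", (), {"peptide": pep("A" * 10, start=1)})(),
        type("M", (), {"peptide": pep("A" * 11, start=5)})(),
    ]
    out = coverage_and_tier(result)
    assert out.coverage_fraction == pytest.approx(15 / 20)


@pytest.mark.parametrize(
    "pct,tier",
    [
        (59.0, "not_confirmed"),
        (60.0, "partially_confirmed"),
        (75.0, "partially_confirmed"),
        (84.9, "partially_confirmed"),
        (85.0, "confirmed"),
        (88.24, "confirmed"),
    ],
)
def test_tier_thresholds(pct, tier):
    length = 10000
    covered = int(round(pct / 100 * length))
    result = PeptideMatchResult(protein_id="p", protein_length=length)
    result.matches = [type("M", (), {"peptide": pep("A" * covered, start=1)})()]
    assert coverage_and_tier(result).tier == tier


def test_tier_thresholds_must_be_ordered():
    with pytest.raises(ValueError):
        TierThresholds(not_confirmed_below=90.0, confirmed_at=85.0)


def test_coverage_monotone_in_observed_set(synthetic_selenow):
    sequence, observed_segments = synthetic_selenow
    protein = ProteinRecord("p", sequence)
    peptides = digest(protein, max_missed=0)
    masses = [peptide_mass(pep(s)) for s in observed_segments]
    prev = -1.0
    for k in range(len(masses) + 1):
        cov = match_masses(
            protein, peptides, masses[:k], fixed_mods=(), variable_mods=()
        ).coverage_fraction
        assert cov >= prev
        prev = cov


# --- fragment ladders -------------------------------------------------------


def test_y1_of_diglycine():
    _, y = fragment_ladder(pep("GG"), charge=1)
    assert y[0] == pytest.approx(76.03931, abs=2e-5)


@given(st.text(alphabet=AA, min_size=2, max_size=20))
def test_fragment_mass_conservation(seq):
    """b_{n-1} + y_1 - proton reconstructs the precursor + proton."""
    p = pep(seq)
    b, y = fragment_ladder(p, charge=1)
    precursor = peptide_mass(p)
    assert b[-1] + y[0] == pytest.approx(precursor + 2 * 1.00727646688, abs=1e-6)


def test_doubly_charged_series():
    p = pep("ACDEFGHIK")
    b1, y1 = fragment_ladder(p, charge=1)
    b2, y2 = fragment_ladder(p, charge=2)
    proton = 1.00727646688
    for m1, m2 in zip(b1 + y1, b2 + y2):
        neutral = m1 - proton
        assert m2 == pytest.approx((neutral + 2 * proton) / 2, abs=1e-9)
    with pytest.raises(ValueError):
        fragment_ladder(p, charge=0)
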