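"""Mass arithmetic, tryptic digestion, branched-peptide fragments, matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isopepgraft.fixtures import make_spectrum_fixture
from isopepgraft.msverify import (
    NH3_MONO,
    PROTON_MASS,
    WATER_MONO,
    PeakList,
    ProteinSequence,
    SequenceError,
    crosslinked_candidates,
    digest,
    isopeptide_mass_delta,
    match_spectrum,
    peptide_mass,
    read_fasta,
    read_peak_list,
    theoretical_fragments,
)

# Independent residue monoisotopic masses, from standard atomic masses
# (C 12, H 1.0078250319, N 14.0030740052, O 15.9949146221, S 31.97207069).
_H, _C, _N, _O, _S = 1.0078250319, 12.0, 14.0030740052, 15.9949146221, 31.97207069
ORACLE_RESIDUE = {
    "G": 2 * _C + 3 * _H + _N + _O,
    "A": 3 * _C + 5 * _H + _N + _O,
    "S": 3 * _C + 5 * _H + _N + 2 * _O,
    "P": 5 * _C + 7 * _H + _N + _O,
    "V": 5 * _C + 9 * _H + _N + _O,
    "T": 4 * _C + 7 * _H + _N + 2 * _O,
    "L": 6 * _C + 11 * _H + _N + _O,
    "I": 6 * _C + 11 * _H + _N + _O,
    "N": 4 * _C + 6 * _H + 2 * _N + 2 * _O,
    "D": 4 * _C + 5 * _H + _N + 3 * _O,
    "Q": 5 * _C + 8 * _H + 2 * _N + 2 * _O,
    "K": 6 * _C + 12 * _H + 2 * _N + _O,
    "E": 5 * _C + 7 * _H + _N + 3 * _O,
    "M": 5 * _C + 9 * _H + _N + _O + _S,
    "H": 6 * _C + 7 * _H + 3 * _N + _O,
    "F": 9 * _C + 9 * _H + _N + _O,
    "R": 6 * _C + 12 * _H + 4 * _N + _O,
    "C": 3 * _C + 5 * _H + _N + _O + _S,
    "W": 11 * _C + 10 * _H + 2 * _N + _O,
    "Y": 9 * _C + 9 * _H + _N + 2 * _O,
}
ORACLE_WATER = 2 * _H + _O
ORACLE_NH3 = _N + 3 * _H

seqs = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def test_glycine_mass_from_elemental_oracle():
    """mass('G') equals residue 57.02146 plus one water (75.032 Da)."""
    assert peptide_mass("G") == pytest.approx(ORACLE_RESIDUE["G"] + ORACLE_WATER, abs=1e-4)
    assert peptide_mass("G") == pytest.approx(75.032, abs=1e-3)


def test_empty_and_invalid_sequences_rejected():
    with pytest.raises(SequenceError):
        peptide_mass("")
    with pytest.raises(SequenceError, match="position 3"):
        peptide_mass("GAX")
    with pytest.raises(SequenceError):
        peptide_mass("GA", kind="nominal")


@given(s1=seqs, s2=seqs)
@settings(max_examples=50, deadline=None)
def test_mass_concatenation_identity(s1, s2):
    """mass(s1+s2) = mass(s1) + mass(s2) − water, for any sequences."""
    assert peptide_mass(s1 + s2) == pytest.approx(
        peptide_mass(s1) + peptide_mass(s2) - WATER_MONO, abs=1e-9
    )


@given(s=seqs)
@settings(max_examples=30, deadline=None)
def test_mass_matches_elemental_oracle(s):
    oracle = sum(ORACLE_RESIDUE[aa] for aa in s) + ORACLE_WATER
    assert peptide_mass(s) == pytest.approx(oracle, abs=1e-3)


def test_isopeptide_delta_is_minus_ammonia():
    """Bond formation loses one NH3: −17.02655 Da mono, ~−17.031 average."""
    assert isopeptide_mass_delta() == pytest.approx(-ORACLE_NH3, abs=1e-4)
    assert isopeptide_mass_delta("monoisotopic") == pytest.approx(-17.02655, abs=1e-5)
    assert isopeptide_mass_delta("average") == pytest.approx(-17.031, abs=1e-3)
    assert round(-isopeptide_mass_delta()) == 17


@given(s=seqs)
@settings(max_examples=20, deadline=None)
def test_bonded_mass_definition(s):
    """bonded = unbonded + delta for any sequence."""
    bonded = peptide_mass(s) + isopeptide_mass_delta()
    assert bonded - peptide_mass(s) == pytest.approx(-NH3_MONO, abs=1e-12)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def test_digest_hand_cases():
    assert [(p.sequence, p.start, p.end) for p in digest("AKAR", max_missed=0)] == [
        ("AK", 1, 2), ("AR", 3, 4),
    ]
    # no cleavage before proline
    assert [(p.sequence,) for p in digest("AKPR", max_missed=0)] == [("AKPR",)]
    # no K/R at all: the whole chain
    assert [(p.sequence,) for p in digest("AGSTV", max_missed=5)] == [("AGSTV",)]


def test_digest_missed_cleavages():
    peps = digest("AKAR", max_missed=1)
    assert {(p.sequence, p.missed_cleavages) for p in peps} == {
        ("AK", 0), ("AR", 0), ("AKAR", 1),
    }


@given(s=seqs, missed=st.integers(min_value=0, max_value=3))
@settings(max_examples=100, deadline=None)
def test_digest_partition_identity(s, missed):
    """0-missed peptides are disjoint and concatenate back to the input."""
    peps = [p for p in digest(s, max_missed=missed) if p.missed_cleavages == 0]
    assert "".join(p.sequence for p in peps) == s
    covered = []
    for p in peps:
        assert s[p.start - 1: p.end] == p.sequence
        covered.extend(range(p.start, p.end + 1))
    assert covered == list(range(1, len(s) + 1))


def test_blocked_site_never_cleaved():
    """Blocking a K suppresses its cut and never increases the peptide count."""
    s = "AKARAK"
    free = digest(s, max_missed=0)
    blocked = digest(s, max_missed=0, blocked_sites={2})
    assert len(blocked) <= len(free)
    assert all(not (p.start <= 2 < p.end + 1 and p.end == 2) for p in blocked)
    assert [(p.sequence,) for p in blocked] == [("AKAR",), ("AK",)]
    with pytest.raises(SequenceError, match="blocked site"):
        digest(s, blocked_sites={1})  # position 1 is A


# ---------------------------------------------------------------------------
# Crosslinked candidates
# ---------------------------------------------------------------------------

def test_crosslink_pair_mass_identity():
    """AKAR+ANAR concatenated, link K2-N6: the branched pair weighs
    m(AKAR)+m(ANAR)−NH3 and the loop-linked form is one water lighter."""
    cands = crosslinked_candidates("AKARANAR", 2, 6, max_missed=1)
    pair = next(c for c in cands if not c.is_loop and c.alpha.sequence == "AKAR")
    assert pair.beta.sequence == "ANAR"
    assert pair.neutral_mass == pytest.approx(
        peptide_mass("AKAR") + peptide_mass("ANAR") - NH3_MONO, abs=1e-6
    )
    loop = next(c for c in cands if c.is_loop)
    assert loop.alpha.sequence == "AKARANAR"
    assert loop.neutral_mass == pytest.approx(
        peptide_mass("AKAR") + peptide_mass("ANAR") - WATER_MONO - NH3_MONO, abs=1e-6
    )


def test_all_candidates_contain_the_link_sites():
    seq = "GGKAAARLLNDDRKAA"
    cands = crosslinked_candidates(seq, 3, 10)
    assert cands
    for c in cands:
        assert c.alpha.contains(3)
        assert c.alpha.sequence[c.link_alpha_pos - 1] == "K"
        if c.is_loop:
            assert c.alpha.contains(10)
        else:
            assert c.beta.contains(10)
            assert c.beta.sequence[c.link_beta_pos - 1] == "N"
            # alpha and beta never overlap in the parent
            assert c.alpha.end < c.beta.start or c.beta.end < c.alpha.start
        # neutral-mass identity holds to 1e-6 Da
        expected = peptide_mass(c.alpha.sequence) - NH3_MONO
        if not c.is_loop:
            expected += peptide_mass(c.beta.sequence)
        else:
            pass
        assert c.neutral_mass == pytest.approx(expected, abs=1e-6)


def test_adjacent_sites_in_one_peptide_yield_loop_only():
    """Link sites inside a single tryptic peptide: loop-linked, no pair."""
    cands = crosslinked_candidates("AKNAR", 2, 3, max_missed=0)
    assert len(cands) == 1
    assert cands[0].is_loop
    assert cands[0].alpha.sequence == "AKNAR"


def test_bad_link_sites_rejected():
    with pytest.raises(SequenceError, match="not K"):
        crosslinked_candidates("AAAA", 1, 2)
    with pytest.raises(SequenceError, match="not N or D"):
        crosslinked_candidates("AKAA", 2, 3)


# ---------------------------------------------------------------------------
# Fragment ions
# ---------------------------------------------------------------------------

def bruteforce_fragments(xp):
    """Independent enumeration summing residue masses explicitly."""
    out = {}
    for chain_name, pep, link_pos, partner in (
        ("alpha", xp.alpha, xp.link_alpha_pos, xp.beta),
        ("beta", xp.beta, xp.link_beta_pos, xp.alpha),
    ):
        seq = pep.sequence
        partner_mass = sum(ORACLE_RESIDUE[aa] for aa in partner.sequence) + ORACLE_WATER - ORACLE_NH3
        for i in range(1, len(seq)):
            b_neutral = sum(ORACLE_RESIDUE[aa] for aa in seq[:i])
            y_neutral = sum(ORACLE_RESIDUE[aa] for aa in seq[i:]) + ORACLE_WATER
            if link_pos <= i:
                b_neutral += partner_mass
            else:
                y_neutral += partner_mass
            for z in (1, 2):
                out[(chain_name, "b", i, z)] = (b_neutral + z * PROTON_MASS) / z
                out[(chain_name, "y", len(seq) - i, z)] = (y_neutral + z * PROTON_MASS) / z
    return out


def test_fragment_enumeration_matches_bruteforce():
    """Full 4+3-residue branched pair agrees with the explicit-sum oracle."""
    cands = crosslinked_candidates("AKARLNR", 2, 6, max_missed=0)
    xp = next(c for c in cands if not c.is_loop)
    assert (len(xp.alpha), len(xp.beta)) == (4, 3)
    oracle = bruteforce_fragments(xp)
    ions = theoretical_fragments(xp)
    assert len(ions) == len(oracle)
    for ion in ions:
        key = (ion.chain, ion.series, ion.index, ion.charge)
        assert ion.mz == pytest.approx(oracle[key], abs=1e-3), key


def test_fragment_complementarity_identity():
    """Neutral b_i + y_(n−i) recovers the chain mass plus the partner mass
    on exactly one side."""
    cands = crosslinked_candidates("AKARLNR", 2, 6, max_missed=0)
    xp = next(c for c in cands if not c.is_loop)
    ions = {(i.chain, i.series, i.index): i for i in theoretical_fragments(xp, charges=(1,))}
    for chain, pep, partner in (("alpha", xp.alpha, xp.beta), ("beta", xp.beta, xp.alpha)):
        n = len(pep)
        chain_mass = peptide_mass(pep.sequence)
        partner_mass = peptide_mass(partner.sequence) - NH3_MONO
        for i in range(1, n):
            b = ions[(chain, "b", i)]
            y = ions[(chain, "y", n - i)]
            total = (b.mz - PROTON_MASS) + (y.mz - PROTON_MASS)
            assert total == pytest.approx(chain_mass + partner_mass, abs=1e-9)
            assert b.includes_link != y.includes_link  # link on exactly one side


def test_link_site_fragment_carries_partner():
    """With the link on residue 1 of the alpha chain, b1 carries the whole
    partner chain but y1 does not."""
    cands = crosslinked_candidates("KAREANR", 1, 6, max_missed=0)
    xp = next(c for c in cands if not c.is_loop and len(c.alpha) == 3)
    # alpha = KAR, link at 1: b1 includes link, y1 does not
    ions = {(i.series, i.index): i for i in theoretical_fragments(xp, charges=(1,))
            if i.chain == "alpha"}
    assert ions[("b", 1)].includes_link
    assert not ions[("y", 1)].includes_link
    beta_mass = peptide_mass(xp.beta.sequence) - NH3_MONO
    expected_b1 = ORACLE_RESIDUE["K"] + beta_mass + PROTON_MASS
    assert ions[("b", 1)].mz == pytest.approx(expected_b1, abs=1e-3)


def test_loop_linked_fragments_skip_ring_cleavages():
    cands = crosslinked_candidates("AKNAR", 2, 3, max_missed=0)
    ions = theoretical_fragments(cands[0], charges=(1,))
    # cleavage inside the ring (between residues 2 and 3) must be absent
    assert all(not (i.series == "b" and i.index == 2) for i in ions)
    for ion in ions:
        assert ion.includes_link in (True, False)


# ---------------------------------------------------------------------------
# Spectrum matching
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def branched_pair():
    cands = crosslinked_candidates("AGLKVAREDLNSTK", 4, 11, max_missed=0)
    return next(c for c in cands if not c.is_loop)


def test_exact_peaks_full_coverage(branched_pair):
    ions = theoretical_fragments(branched_pair)
    peaks = PeakList(peaks=[(i.mz, 100.0) for i in ions])
    result = match_spectrum(ions, peaks, tol_ppm=20)
    assert result.coverage == 1.0
    assert all(abs(err) < 1e-9 for _, _, err in result.matched)


def test_shifted_peaks_zero_coverage(branched_pair):
    ions = theoretical_fragments(branched_pair)
    peaks = PeakList(peaks=[(i.mz * (1 + 100e-6), 100.0) for i in ions])
    result = match_spectrum(ions, peaks, tol_ppm=20)
    assert result.coverage == 0.0


def test_empty_peaklist_valid(branched_pair):
    ions = theoretical_fragments(branched_pair)
    result = match_spectrum(ions, PeakList(peaks=[]), tol_ppm=20)
    assert result.coverage == 0.0
    assert result.matched == []


def test_planted_subset_recovered_among_decoys(branched_pair):
    """With decoys present, matching recovers exactly the planted ions."""
    peaks, truth = make_spectrum_fixture(branched_pair, n_decoys=50, noise_ppm=5, seed=3)
    ions = theoretical_fragments(branched_pair)
    result = match_spectrum(ions, peaks, tol_ppm=10)
    assert result.coverage == 1.0
    matched_mz = sorted(peak[0] for _, peak, _ in result.matched)
    planted_mz = sorted(p["mz_observed"] for p in truth["planted"])
    assert np.allclose(matched_mz, planted_mz, atol=1e-9)
    # each peak used at most once
    assert len({id(peak) for _, peak, _ in result.matched}) == len(result.matched)
    assert all(abs(err) <= 10 for _, _, err in result.matched)


def test_peaklist_invariants():
    pl = PeakList(peaks=[(300.0, 1.0), (100.0, 2.0)])
    assert [mz for mz, _ in pl.peaks] == [100.0, 300.0]
    with pytest.raises(SequenceError):
        PeakList(peaks=[(-5.0, 1.0)])
    with pytest.raises(SequenceError):
        PeakList(peaks=[(5.0, -1.0)])


def test_file_io(tmp_path):
    fasta = tmp_path / "seq.fa"
    fasta.write_text(">prot1 test\nAGLKVAR\nEDLNSTK\n")
    seqs_ = read_fasta(fasta)
    assert seqs_[0].id == "prot1"
    assert seqs_[0].residues == "AGLKVAREDLNSTK"

    peaks_file = tmp_path / "peaks.txt"
    peaks_file.write_text("# mz intensity\n500.25\t120\n800.5 30\n1000.1,5\n")
    pl = read_peak_list(peaks_file)
    assert len(pl) == 3
    assert pl.peaks[0] == (500.25, 120.0)


def test_protein_sequence_alphabet():
    with pytest.raises(SequenceError, match="position 2"):
        ProteinSequence("x", "AB")
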