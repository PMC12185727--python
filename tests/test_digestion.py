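"""FASTA I/O, in-silico digestion, peptide masses, candidates and decoys."""

import random

import pytest
from pyteomics import mass as pyteomics_mass

from xlstub.chem import CARBAMIDOMETHYL_MASS, RESIDUE_MASS, WATER_MASS
from xlstub.digestion import (
    DECOY_PREFIX,
    PeptideSpec,
    ProteinRecord,
    digest,
    enumerate_candidates,
    generate_decoys,
    link_positions,
    peptide_mass,
    read_fasta,
)

# ---------------------------------------------------------------------------
# FASTA


def test_read_fasta_single_record(tmp_path):
    path = tmp_path / "one.fasta"
    path.write_text(">P1 test protein\nPEPTIDEK\n")
    records = read_fasta(path)
    assert len(records) == 1
    assert records[0].accession == "P1"
    assert records[0].sequence == "PEPTIDEK"


def test_read_fasta_wrapped_lines_concatenate(tmp_path):
    seq = "MKWVTFISLLLLFSSAYSRGVFRRDTHKSEIAHRFKDLGEEHFKGLVLIAFSQYLQQCPF"
    path = tmp_path / "wrapped.fasta"
    path.write_text(">P2 wrapped\n" + seq[:30] + "\n" + seq[30:] + "\n")
    assert read_fasta(path)[0].sequence == seq


def test_read_fasta_preserves_order(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(">B second-alphabetically-first\nAAAK\n>A first\nCCCK\n")
    assert [r.accession for r in read_fasta(path)] == ["B", "A"]


def test_read_fasta_rejects_digits_with_line_number(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">P1\nPEPTIDEK\nPE9TIDE\n")
    with pytest.raises(ValueError, match="line 3"):
        read_fasta(path)


def test_read_fasta_rejects_empty_file(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_fasta(path)


# ---------------------------------------------------------------------------
# Digestion


def _sequences(peptides):
    return {(p.sequence, p.start) for p in peptides}


def test_tryptic_digest_of_the_single_peptide_standard():
    protein = ProteinRecord("XLPEP1", "", "WGGGGRKSSAAR")
    zero = digest(protein, "trypsin", 0, length_range=None)
    assert _sequences(zero) == {("WGGGGR", 1), ("K", 7), ("SSAAR", 8)}
    one = digest(protein, "trypsin", 1, length_range=None)
    assert {("WGGGGRK", 1), ("KSSAAR", 7)} <= _sequences(one)


def test_trypsin_does_not_cleave_before_proline():
    protein = ProteinRecord("P", "", "KPR")
    assert _sequences(digest(protein, "trypsin", 0, None)) == {("KPR", 1)}


def test_lysc_cleaves_lysine_even_before_proline():
    protein = ProteinRecord("P", "", "AKPGGK")
    assert _sequences(digest(protein, "lysC", 0, None)) == {("AK", 1), ("PGGK", 3)}


def test_zero_missed_cleavage_peptides_reconstruct_protein():
    protein = ProteinRecord("P", "", "MKWVTFISLLKRPFKDLGEEHFKGLVK")
    peptides = sorted(
        digest(protein, "trypsin", 0, length_range=None), key=lambda p: p.start
    )
    assert "".join(p.sequence for p in peptides) == protein.sequence
    assert all(p.missed_cleavages == 0 for p in peptides)


def test_ambiguous_residue_peptides_are_dropped():
    protein = ProteinRecord("P", "", "AAAKXXXKGGGK")
    peptides = digest(protein, "trypsin", 0, length_range=None)
    assert all("X" not in p.sequence for p in peptides)


def _brute_force_digest(sequence, enzyme, max_mc):
    """Independent oracle: direct scan over all cleavage-site spans."""
    if enzyme == "trypsin":
        sites = [
            i for i in range(len(sequence) - 1)
            if sequence[i] in "KR" and sequence[i + 1] != "P"
        ]
    else:
        sites = [i for i in range(len(sequence) - 1) if sequence[i] == "K"]
    bounds = [-1] + sites + [len(sequence) - 1]
    out = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + max_mc + 2, len(bounds))):
            out.add((sequence[bounds[a] + 1 : bounds[b] + 1], bounds[a] + 2, b - a - 1))
    return out


@pytest.mark.parametrize("enzyme", ["trypsin", "lysC"])
@pytest.mark.parametrize("max_mc", [0, 1, 2])
def test_digest_matches_brute_force_oracle(enzyme, max_mc):
    rng = random.Random(1234)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(200):
        seq = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 80)))
        protein = ProteinRecord("P", "", seq)
        got = {
            (p.sequence, p.start, p.missed_cleavages)
            for p in digest(protein, enzyme, max_mc, length_range=None)
        }
        assert got == _brute_force_digest(seq, enzyme, max_mc)


# ---------------------------------------------------------------------------
# Peptide mass


def _spec(seq, cam=False, **kwargs):
    mods = tuple(
        (i + 1, CARBAMIDOMETHYL_MASS) for i, r in enumerate(seq) if cam and r == "C"
    )
    return PeptideSpec(seq, "P", 1, 0, fixed_mods=mods, **kwargs)


def test_peptide_mass_examples(dispaso):
    assert peptide_mass(_spec("G")) == pytest.approx(75.03203, abs=1e-5)
    assert peptide_mass(_spec("GG")) == pytest.approx(132.05349, abs=1e-5)
    expected_k = 128.09496 + 18.01056 + dispaso.monolink_mass
    assert peptide_mass(_spec("K"), extra_mods=dispaso.monolink_mass) == pytest.approx(
        expected_k, abs=1e-4
    )


def test_carbamidomethyl_applied_through_fixed_mods():
    plain = peptide_mass(_spec("ACDK"))
    alkylated = peptide_mass(_spec("ACDK", cam=True))
    assert alkylated - plain == pytest.approx(57.02146, abs=1e-5)


def test_non_canonical_residue_rejected():
    with pytest.raises(ValueError, match="non-canonical"):
        peptide_mass(PeptideSpec("AXA", "P", 1, 0))


def test_peptide_mass_matches_pyteomics_oracle():
    """1,000 random peptides against the independent pyteomics residue table."""
    rng = random.Random(99)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(1000):
        seq = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 40)))
        ours = peptide_mass(_spec(seq))
        reference = pyteomics_mass.fast_mass(seq, ion_type="M", charge=0)
        assert abs(ours - reference) < 1e-6


def test_residue_table_plus_water_equals_peptide_mass():
    seq = "KSSAAR"
    expected = sum(RESIDUE_MASS[r] for r in seq) + WATER_MASS
    assert peptide_mass(_spec(seq)) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Link sites and candidate enumeration


def test_link_positions_exclude_enzymatic_cterm_lysine(dispaso):
    # K at the peptide C-terminus is not linkable unless protein C-terminal
    internal = PeptideSpec("AKGGR", "P", 1, 0)
    assert link_positions(internal, dispaso) == [2]
    cterm_k = PeptideSpec("AGGK", "P", 1, 0)
    assert link_positions(cterm_k, dispaso) == []
    protein_cterm = PeptideSpec("AGGK", "P", 10, 0, protein_cterm=True)
    assert link_positions(protein_cterm, dispaso) == [4]


def test_protein_nterm_is_linkable_unless_acetylated(dispaso):
    nterm = PeptideSpec("AGGR", "P", 1, 0, protein_nterm=True)
    assert link_positions(nterm, dispaso) == [1]
    acetylated = PeptideSpec("AGGR", "P", 1, 0, protein_nterm=True, nterm_acetyl=True)
    assert link_positions(acetylated, dispaso) == []


def test_symmetric_kssaar_crosslink_candidate(dispaso):
    pep = PeptideSpec("KSSAAR", "XLPEP1", 7, 1, protein_cterm=True)
    precursor = 2 * peptide_mass(pep) + dispaso.bridge_mass
    candidates = enumerate_candidates([pep, pep], dispaso, precursor, tol_ppm=5)
    assert len(candidates) == 1
    cand = candidates[0]
    assert cand.type == "crosslink"
    assert (cand.pos_alpha, cand.pos_beta) == (1, 1)
    assert cand.site_alpha() == ("XLPEP1", 7)
    assert cand.site_beta() == ("XLPEP1", 7)


def test_zero_precursor_mass_gives_empty_candidates(dispaso):
    pep = PeptideSpec("KSSAAR", "P", 1, 0)
    assert enumerate_candidates([pep], dispaso, 0.0) == []


def test_peptides_without_link_sites_are_excluded(dispaso):
    no_k = PeptideSpec("GGSSAAR", "P", 5, 0)
    precursor = 2 * peptide_mass(no_k) + dispaso.bridge_mass
    assert enumerate_candidates([no_k, no_k], dispaso, precursor) == []


def test_candidate_completeness_on_synthetic_library(dispaso):
    """Every planted mass-consistent crosslink appears among the candidates."""
    rng = random.Random(7)
    alphabet = "ACDEFGHILMNPQSTVWY"  # K inserted explicitly
    peptides = []
    for i in range(30):
        core = "".join(rng.choice(alphabet) for _ in range(rng.randint(4, 10)))
        pos = rng.randint(1, len(core))
        seq = core[: pos - 1] + "K" + core[pos - 1 :] + "R"
        peptides.append(PeptideSpec(seq, f"P{i}", 1, 0))
    for _ in range(25):
        pep_a, pep_b = rng.sample(peptides, 2)
        precursor = peptide_mass(pep_a) + peptide_mass(pep_b) + dispaso.bridge_mass
        candidates = enumerate_candidates(peptides, dispaso, precursor, tol_ppm=5)
        found = {
            frozenset((c.alpha.accession, c.beta.accession))
            for c in candidates
            if c.type == "crosslink"
        }
        assert frozenset((pep_a.accession, pep_b.accession)) in found


def test_monolink_and_looplink_candidates(dispaso):
    pep = PeptideSpec("AKGGKGR", "P", 1, 0)
    mono_prec = peptide_mass(pep) + dispaso.monolink_mass
    monos = enumerate_candidates(
        [pep], dispaso, mono_prec, types=("monolink",)
    )
    assert {c.pos_alpha for c in monos} == {2, 5}
    loop_prec = peptide_mass(pep) + dispaso.bridge_mass
    loops = enumerate_candidates([pep], dispaso, loop_prec, types=("looplink",))
    assert len(loops) == 1
    assert (loops[0].pos_alpha, loops[0].pos_beta) == (2, 5)


# ---------------------------------------------------------------------------
# Decoys


def test_decoy_reversal_and_prefix():
    targets = [ProteinRecord("P1", "", "PEPTIDEK")]
    decoys = generate_decoys(targets)
    assert decoys[0].sequence == "KEDITPEP"
    assert decoys[0].accession == DECOY_PREFIX + "P1"


def test_palindromic_decoy_still_flagged_as_decoy():
    targets = [ProteinRecord("P1", "", "ABLKKLBA".replace("B", "G"))]
    decoys = generate_decoys(targets)
    assert decoys[0].sequence == targets[0].sequence[::-1]
    peptides = digest(decoys[0], "trypsin", 0, None)
    assert all(p.decoy for p in peptides)


def test_decoy_generation_is_a_bijection():
    targets = [ProteinRecord(f"P{i}", "", "AAGK" * (i + 2)) for i in range(5)]
    decoys = generate_decoys(targets)
    assert len(decoys) == len(targets)
    assert {d.accession for d in decoys}.isdisjoint({t.accession for t in targets})
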