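"""Doublet detection, ion matching, CSM scoring, FDR estimation, full search."""

import math

import pytest

from xlstub.chem import RESIDUE_MASS, WATER_MASS
from xlstub.digestion import CandidateLink, PeptideSpec, ProteinRecord, peptide_mass
from xlstub.linkers import enumerate_doublet_distances
from xlstub.search import (
    CSM,
    SearchConfig,
    detect_doublets,
    estimate_fdr,
    group_residue_pairs,
    match_ions,
    pair_doublets_to_precursor,
    prefilter_linear,
    score_csm,
    search_run,
    theoretical_ions,
)
from xlstub.digestion import PeptideIndex
from xlstub.simulate import SimulationConfig, simulate_dataset
from xlstub.spectra import MS2Spectrum, Peak, mass_to_mz

A_SA_DELTA = 49.98264  # alkene / sulfenic-acid doublet distance


def _doublet(dispaso, did):
    return [d for d in enumerate_doublet_distances(dispaso) if d.id == did]


def _spectrum(peaks, precursor_mz=600.0, charge=3, sid="s"):
    return MS2Spectrum(sid, 1, precursor_mz, charge, peaks=peaks)


# ---------------------------------------------------------------------------
# detect_doublets


def test_detect_planted_doublet_at_charge_one(dispaso):
    spectrum = _spectrum([Peak(400.0, 100.0), Peak(400.0 + A_SA_DELTA, 90.0)])
    matches = detect_doublets(spectrum, _doublet(dispaso, "D2"), dispaso)
    singly = [m for m in matches if m.charge == 1]
    assert len(singly) == 1
    match = singly[0]
    assert (match.light_index, match.heavy_index) == (0, 1)
    # inferred mass = neutral(light) - alkene stub
    expected = 400.0 - 1.00727646688 - dispaso.fragment("alkene").mass
    assert match.inferred_peptide_mass == pytest.approx(expected, abs=1e-6)


def test_detect_planted_doublet_at_charge_two(dispaso):
    spectrum = _spectrum([Peak(400.0, 100.0), Peak(400.0 + A_SA_DELTA / 2, 90.0)])
    matches = detect_doublets(
        spectrum, _doublet(dispaso, "D2"), dispaso, max_fragment_charge=2
    )
    assert any(m.charge == 2 for m in matches)


def test_no_pair_within_tolerance_gives_empty(dispaso):
    spectrum = _spectrum([Peak(400.0, 100.0), Peak(400.0 + A_SA_DELTA + 0.3, 90.0)])
    assert detect_doublets(spectrum, _doublet(dispaso, "D2"), dispaso) == []


def test_empty_spectrum_gives_empty(dispaso):
    spectrum = _spectrum([])
    assert detect_doublets(
        spectrum, enumerate_doublet_distances(dispaso), dispaso
    ) == []


def test_low_intensity_peaks_ignored(dispaso):
    spectrum = _spectrum(
        [Peak(300.0, 10000.0), Peak(400.0, 1.0), Peak(400.0 + A_SA_DELTA, 1.0)]
    )
    assert detect_doublets(
        spectrum, _doublet(dispaso, "D2"), dispaso, min_relative_intensity=0.005
    ) == []


# ---------------------------------------------------------------------------
# pair_doublets_to_precursor


def test_two_consistent_doublets_pair_to_precursor(dispaso):
    mass_a, mass_b = 800.0, 1100.0
    precursor = mass_a + mass_b + dispaso.bridge_mass
    alkene = dispaso.fragment("alkene").mass
    peaks = []
    for pep_mass in (mass_a, mass_b):
        light = mass_to_mz(pep_mass + alkene, 1)
        peaks += [Peak(light, 50.0), Peak(light + A_SA_DELTA, 45.0)]
    spectrum = _spectrum(sorted(peaks, key=lambda p: p.mz))
    matches = detect_doublets(
        spectrum, _doublet(dispaso, "D2"), dispaso, max_fragment_charge=1
    )
    pairs = pair_doublets_to_precursor(matches, dispaso, precursor)
    full = [p for p in pairs if not p.single_doublet_fallback]
    assert len(full) == 1
    assert full[0].mass_alpha == pytest.approx(mass_a, abs=1e-4)
    assert full[0].mass_beta == pytest.approx(mass_b, abs=1e-4)


def test_inconsistent_masses_yield_no_full_pair(dispaso):
    mass_a, mass_b = 800.0, 1100.0
    precursor = mass_a + mass_b + dispaso.bridge_mass + 5.0  # off by 5 Da
    alkene = dispaso.fragment("alkene").mass
    peaks = []
    for pep_mass in (mass_a, mass_b):
        light = mass_to_mz(pep_mass + alkene, 1)
        peaks += [Peak(light, 50.0), Peak(light + A_SA_DELTA, 45.0)]
    spectrum = _spectrum(sorted(peaks, key=lambda p: p.mz))
    matches = detect_doublets(
        spectrum, _doublet(dispaso, "D2"), dispaso, max_fragment_charge=1
    )
    pairs = pair_doublets_to_precursor(matches, dispaso, precursor)
    assert all(p.single_doublet_fallback for p in pairs)


def test_single_doublet_fallback_flagged(dispaso):
    mass_a = 900.0
    precursor = 2222.2
    alkene = dispaso.fragment("alkene").mass
    light = mass_to_mz(mass_a + alkene, 1)
    spectrum = _spectrum([Peak(light, 50.0), Peak(light + A_SA_DELTA, 45.0)])
    matches = detect_doublets(
        spectrum, _doublet(dispaso, "D2"), dispaso, max_fragment_charge=1
    )
    pairs = pair_doublets_to_precursor(matches, dispaso, precursor)
    assert pairs
    assert all(p.single_doublet_fallback for p in pairs)
    assert pairs[0].mass_beta == pytest.approx(
        precursor - dispaso.bridge_mass - mass_a, abs=1e-4
    )


# ---------------------------------------------------------------------------
# theoretical_ions


def test_stub_location_in_ion_series(dispaso):
    peptide = PeptideSpec("KSSAAR", "P", 7, 1)
    alkene = dispaso.fragment("alkene").mass
    ions = {i.label: i.mz for i in theoretical_ions(peptide, alkene, 1, max_charge=1)}
    proton = 1.00727646688
    # y5 = SSAAR, no stub
    y5 = sum(RESIDUE_MASS[r] for r in "SSAAR") + WATER_MASS + proton
    assert ions["y5+1"] == pytest.approx(y5, abs=1e-6)
    # b2 = KS + stub
    b2 = RESIDUE_MASS["K"] + RESIDUE_MASS["S"] + alkene + proton
    assert ions["b2+1"] == pytest.approx(b2, abs=1e-6)


def test_zero_stub_reduces_to_plain_series():
    peptide = PeptideSpec("KSSAAR", "P", 1, 0)
    with_stub = theoretical_ions(peptide, 0.0, 1, max_charge=2)
    without = theoretical_ions(peptide, 0.0, None, max_charge=2)
    assert [(i.label, i.mz) for i in with_stub] == [(i.label, i.mz) for i in without]


def test_dipeptide_has_one_ion_pair_per_charge():
    peptide = PeptideSpec("GK", "P", 1, 0)
    ions = theoretical_ions(peptide, 0.0, None, max_charge=2)
    labels = {i.label for i in ions}
    assert labels == {"b1+1", "b1+2", "y1+1", "y1+2"}


def test_ion_series_matches_residue_sum_oracle():
    peptide = PeptideSpec("LTDKGGR", "P", 1, 0)
    stub = 103.9932
    pos = 4
    proton = 1.00727646688
    ions = {i.label: i.mz for i in theoretical_ions(peptide, stub, pos, max_charge=1)}
    seq = peptide.sequence
    for i in range(1, len(seq)):
        b = sum(RESIDUE_MASS[r] for r in seq[:i]) + (stub if pos <= i else 0) + proton
        y = (
            sum(RESIDUE_MASS[r] for r in seq[-i:])
            + WATER_MASS
            + (stub if pos > len(seq) - i else 0)
            + proton
        )
        assert ions[f"b{i}+1"] == pytest.approx(b, abs=1e-6)
        assert ions[f"y{i}+1"] == pytest.approx(y, abs=1e-6)


# ---------------------------------------------------------------------------
# match_ions


def test_exact_theoretical_peaks_match_fully():
    peptide = PeptideSpec("KSSAAR", "P", 1, 0)
    ions = theoretical_ions(peptide, 54.01056, 1, max_charge=1)
    spectrum = _spectrum([Peak(i.mz, 10.0) for i in ions])
    result = match_ions(spectrum, ions)
    assert result.n_matched == result.n_theoretical == len(ions)
    assert result.matched_intensity_fraction == pytest.approx(1.0)


def test_empty_spectrum_matches_nothing():
    peptide = PeptideSpec("KSSAAR", "P", 1, 0)
    ions = theoretical_ions(peptide, 0.0, None)
    assert match_ions(_spectrum([]), ions).n_matched == 0


def test_each_peak_used_at_most_once_tie_to_lower_mz_ion():
    from xlstub.search import TheoreticalIon

    peak = Peak(500.0, 10.0)
    ions = [
        TheoreticalIon("low", 500.0 - 0.001, 1),
        TheoreticalIon("high", 500.0 + 0.001, 1),
    ]
    result = match_ions(_spectrum([peak]), ions, fragment_tol_ppm=10.0)
    assert result.n_matched == 1
    assert result.assignments[0][0] == "low"


# ---------------------------------------------------------------------------
# score_csm


def test_zero_matches_score_zero():
    assert score_csm(0, 10, 0.01) == 0.0
    assert score_csm(0, 0, 0.01) == 0.0


def test_perfect_match_closed_form():
    # P(X >= 10 | n=10, p=0.01) = 1e-20 -> score 200
    assert score_csm(10, 10, 0.01) == pytest.approx(200.0, abs=1e-6)


def test_score_monotone_in_matched_count():
    scores = [score_csm(k, 20, 0.01) for k in range(21)]
    assert all(b >= a for a, b in zip(scores[:-1], scores[1:], strict=True))


def test_invalid_score_inputs_rejected():
    with pytest.raises(ValueError):
        score_csm(5, 3, 0.01)
    with pytest.raises(ValueError):
        score_csm(1, 3, 1.5)


# ---------------------------------------------------------------------------
# estimate_fdr


def _csm(score, cls, sid="s"):
    peptide = PeptideSpec("KAAAR", "P", 1, 0, decoy=cls in ("TD", "DD"))
    cand = CandidateLink("crosslink", peptide, peptide, 1, 1, "DiSPASO")
    return CSM(
        spectrum_id=sid, candidate=cand, alpha_score=score / 2, beta_score=score / 2,
        combined_score=score, alpha_matched=0, alpha_theoretical=1, beta_matched=0,
        beta_theoretical=1, alpha_stub="alkene", beta_stub="alkene",
        tdc_class=cls, precursor_error_ppm=0.0,
    )


def _brute_force_qvalues(entries):
    """Oracle: FDR at every threshold, then monotonised from the bottom."""
    fdrs = []
    for score, _ in entries:
        above = [cls for s, cls in entries if s >= score]
        tt = sum(cls == "TT" for cls in above)
        td = sum(cls == "TD" for cls in above)
        dd = sum(cls == "DD" for cls in above)
        fdrs.append(max(0, td - dd) / max(tt, 1))
    out = [0.0] * len(entries)
    running = math.inf
    for i in sorted(range(len(entries)), key=lambda j: entries[j][0]):
        running = min(running, fdrs[i]) if running != math.inf else fdrs[i]
        out[i] = running
    # monotonise: ascending score order, running min
    running = math.inf
    order = sorted(range(len(entries)), key=lambda j: entries[j][0])
    for i in order:
        running = min(running, fdrs[i])
        out[i] = running
    return out


def test_all_target_results_get_q_zero_without_decoys():
    csms = [_csm(s, "TT") for s in (50, 40, 30)]
    estimate_fdr(csms)
    assert all(c.q_value == 0.0 for c in csms)


def test_fdr_matches_brute_force_oracle_on_constructed_ranking():
    entries = [(100 - i, "TT") for i in range(99)] + [(0.5, "TD")]
    csms = [_csm(score, cls) for score, cls in entries]
    estimate_fdr(csms)
    expected = _brute_force_qvalues(entries)
    for csm, exp in zip(csms, expected, strict=True):
        assert csm.q_value == pytest.approx(exp, abs=1e-12)
    # the TD entry raises q only after it is included
    assert csms[-1].q_value > csms[0].q_value


def test_balanced_td_dd_gives_zero_fdr_throughout():
    entries = []
    for i in range(10):
        entries += [(90 - i, "TT"), (89.5 - i, "TD"), (89.4 - i, "DD")]
    csms = [_csm(score, cls) for score, cls in entries]
    estimate_fdr(csms)
    # each TD is immediately compensated by a DD at nearly the same score
    assert csms[-1].q_value <= 1 / 10  # loose sanity bound
    expected = _brute_force_qvalues(entries)
    for csm, exp in zip(csms, expected, strict=True):
        assert csm.q_value == pytest.approx(exp, abs=1e-12)


def test_q_values_monotone_non_increasing_in_score():
    import random as _random

    rng = _random.Random(5)
    entries = [
        (rng.uniform(0, 100), rng.choice(["TT", "TT", "TT", "TD", "DD"]))
        for _ in range(200)
    ]
    csms = [_csm(score, cls) for score, cls in entries]
    estimate_fdr(csms)
    ordered = sorted(csms, key=lambda c: c.combined_score)
    qs = [c.q_value for c in ordered]
    assert all(b <= a + 1e-12 for a, b in zip(qs[:-1], qs[1:], strict=True))


# ---------------------------------------------------------------------------
# residue-pair grouping


def test_residue_pair_canonicalisation_collapses_swapped_sites():
    pep_a = PeptideSpec("KAAAR", "PA", 10, 0)
    pep_b = PeptideSpec("KGGGR", "PB", 20, 0)
    cand_ab = CandidateLink("crosslink", pep_a, pep_b, 1, 1, "DiSPASO")
    cand_ba = CandidateLink("crosslink", pep_b, pep_a, 1, 1, "DiSPASO")
    csms = []
    for sid, cand in (("s1", cand_ab), ("s2", cand_ba)):
        csms.append(
            CSM(
                spectrum_id=sid, candidate=cand, alpha_score=30, beta_score=30,
                combined_score=60, alpha_matched=5, alpha_theoretical=10,
                beta_matched=5, beta_theoretical=10, alpha_stub="alkene",
                beta_stub="alkene", tdc_class="TT", precursor_error_ppm=0.0,
            )
        )
    pairs = group_residue_pairs(csms)
    assert len(pairs) == 1
    assert pairs[0].n_csms == 2
    assert pairs[0].site_a == ("PA", 10)
    assert pairs[0].site_b == ("PB", 20)


# ---------------------------------------------------------------------------
# prefilter


def test_prefilter_separates_linear_from_crosslink_spectra(dispaso):
    from xlstub.simulate import (
        SimulationConfig,
        simulate_crosslink_spectrum,
        simulate_linear_spectrum,
    )

    config = SimulationConfig(seed=3, noise_peaks=0, mz_jitter_ppm=0.0)
    peptide = PeptideSpec("LTDKGGAR", "P1", 1, 0)
    linear_spectrum, _ = simulate_linear_spectrum(peptide, config, 1, "lin")
    xl_pep = PeptideSpec("AKGGLTDR", "P2", 1, 0)
    cand = CandidateLink("crosslink", xl_pep, xl_pep, 2, 2, dispaso.name)
    xl_spectrum, _ = simulate_crosslink_spectrum(cand, dispaso, config, 2, "xl")

    index = PeptideIndex([peptide, xl_pep])
    result = prefilter_linear([linear_spectrum, xl_spectrum], index)
    assert [s.spectrum_id for s in result.filtered] == ["lin"]
    assert [s.spectrum_id for s in result.retained] == ["xl"]


def test_prefilter_empty_set():
    result = prefilter_linear([], PeptideIndex([PeptideSpec("KAAAR", "P", 1, 0)]))
    assert result.retained == [] and result.filtered == []


# ---------------------------------------------------------------------------
# end-to-end search


@pytest.fixture(scope="module")
def small_noiseless_run():
    config = SimulationConfig(
        seed=42,
        n_proteins=6,
        protein_length=(120, 200),
        noise_peaks=0,
        mz_jitter_ppm=0.0,
    )
    return simulate_dataset(10, config, n_background=0)


def test_noiseless_run_recovers_all_planted_pairs(small_noiseless_run, dispaso):
    dataset = small_noiseless_run
    result = search_run(dataset.spectra, dataset.proteins, dispaso)
    accepted = {
        tuple(sorted((p.site_a, p.site_b))) for p in result.accepted_pairs(q=0.01)
    }
    planted = dataset.planted_residue_pairs()
    assert planted <= accepted


def test_decoy_only_database_yields_nothing(small_noiseless_run, dispaso):
    dataset = small_noiseless_run
    shuffled = [
        ProteinRecord(p.accession, p.description, p.sequence[::-1])
        for p in dataset.proteins
    ]
    result = search_run(dataset.spectra, shuffled, dispaso)
    planted = dataset.planted_residue_pairs()
    accepted = {
        tuple(sorted((p.site_a, p.site_b))) for p in result.accepted_pairs(q=0.01)
    }
    assert not (planted & accepted)


def test_intensity_scaling_leaves_ranking_unchanged(small_noiseless_run, dispaso):
    dataset = small_noiseless_run
    scaled = [
        MS2Spectrum(
            s.spectrum_id, s.scan, s.precursor_mz, s.precursor_charge,
            peaks=[Peak(p.mz, p.intensity * 1000.0) for p in s.peaks], nce=s.nce,
        )
        for s in dataset.spectra
    ]
    base = search_run(dataset.spectra, dataset.proteins, dispaso)
    boosted = search_run(scaled, dataset.proteins, dispaso)
    assert [
        (c.spectrum_id, c.combined_score, c.q_value) for c in base.csms
    ] == [(c.spectrum_id, c.combined_score, c.q_value) for c in boosted.csms]


def test_single_peptide_selflink_identified_top(
    single_peptide_protein, kssaar_selflink, dispaso
):
    """The acetylated single-peptide standard self-linked at K7 x K7."""
    from xlstub.simulate import SimulationConfig, simulate_crosslink_spectrum

    config = SimulationConfig(seed=5, noise_peaks=0, mz_jitter_ppm=0.0)
    spectrum, _ = simulate_crosslink_spectrum(
        kssaar_selflink, dispaso, config, 11, "kssaar"
    )
    result = search_run([spectrum], [single_peptide_protein], dispaso)
    assert result.csms, "self-link spectrum not identified"
    top = result.csms[0]
    assert top.candidate.site_alpha() == ("XLPEP1", 7)
    assert top.candidate.site_beta() == ("XLPEP1", 7)
    assert top.tdc_class == "TT"


def test_empty_spectra_set_gives_empty_results(dispaso, single_peptide_protein):
    result = search_run([], [single_peptide_protein], dispaso)
    assert result.csms == [] and result.residue_pairs == []
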