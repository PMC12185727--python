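"""Doublet-driven crosslink identification with target-decoy FDR.

The engine mirrors the cleavable-crosslinker workflow: a spectrum is first
checked against linear peptides (confident linear hits are excluded from the
crosslink search); remnant doublet peak pairs are then detected, each doublet
inferring the neutral mass of one constituent peptide; doublet pairs (or a
single-doublet fallback) are reconciled with the precursor mass to yield
candidate peptide pairs; each candidate peptide is matched as a stub-modified
peptide -- every crosslinker fragment species is tried as a modification at
the link site -- and scored with a binomial tail statistic; finally CSMs and
grouped residue pairs receive q-values from a target-decoy estimator
(TT/TD/DD classes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .chem import ACETYL_MASS, RESIDUE_MASS, WATER_MASS
from .digestion import (
    CandidateLink,
    PeptideIndex,
    PeptideSpec,
    acetylated_variants,
    digest,
    generate_decoys,
    link_positions,
    read_fasta,
)
from .linkers import CrosslinkerDefinition, DoubletDistance, enumerate_doublet_distances
from .spectra import MS2Spectrum, mass_to_mz, neutral_mass

__all__ = [
    "DoubletMatch",
    "InferredPair",
    "TheoreticalIon",
    "MatchResult",
    "CSM",
    "ResiduePairResult",
    "SearchConfig",
    "RunResult",
    "detect_doublets",
    "pair_doublets_to_precursor",
    "theoretical_ions",
    "match_ions",
    "score_csm",
    "prefilter_linear",
    "estimate_fdr",
    "group_residue_pairs",
    "search_run",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Doublet detection


@dataclass(frozen=True)
class DoubletMatch:
    """One light/heavy peak pair consistent with a doublet distance."""

    doublet_id: str
    light_index: int
    heavy_index: int
    charge: int
    inferred_peptide_mass: float
    summed_intensity: float
    light_fragment: str
    delta: float


def detect_doublets(
    spectrum: MS2Spectrum,
    doublets: list[DoubletDistance],
    linker: CrosslinkerDefinition,
    fragment_tol_ppm: float = 10.0,
    max_fragment_charge: int = 3,
    min_relative_intensity: float = 0.005,
) -> list[DoubletMatch]:
    """Find peak pairs separated by a doublet distance at any charge.

    A pair (light, heavy) at fragment charge z matches doublet delta d when
    ``|(mz_heavy - mz_light) * z - d|`` is within ``fragment_tol_ppm`` of the
    heavier fragment's neutral mass, and both peaks are above
    ``min_relative_intensity`` of the base peak.  The inferred peptide
    neutral mass is ``neutral_mass(mz_light, z) - mass(light fragment)``.
    """
    if not spectrum.peaks:
        return []
    mz = spectrum.mz_array
    intensity = spectrum.intensity_array
    floor = min_relative_intensity * spectrum.base_peak_intensity()
    strong = intensity >= floor
    light_masses = {f.name: f.mass for f in linker.fragments}

    matches: list[DoubletMatch] = []
    for doublet in doublets:
        light_mass = light_masses[doublet.light]
        for z in range(1, max_fragment_charge + 1):
            targets = mz + doublet.delta / z
            # tolerance relative to the heavier neutral fragment mass
            widths = fragment_tol_ppm * 1e-6 * neutral_mass(targets, z) / z
            lo = np.searchsorted(mz, targets - widths, side="left")
            hi = np.searchsorted(mz, targets + widths, side="right")
            for i in np.nonzero((hi > lo) & strong)[0]:
                for j in range(lo[i], hi[i]):
                    if not strong[j] or j == i:
                        continue
                    inferred = neutral_mass(mz[i], z) - light_mass
                    if inferred <= 0:
                        continue
                    matches.append(
                        DoubletMatch(
                            doublet_id=doublet.id,
                            light_index=int(i),
                            heavy_index=int(j),
                            charge=z,
                            inferred_peptide_mass=inferred,
                            summed_intensity=float(intensity[i] + intensity[j]),
                            light_fragment=doublet.light,
                            delta=doublet.delta,
                        )
                    )
    matches.sort(key=lambda m: (-m.summed_intensity, m.doublet_id, m.charge))
    return matches


@dataclass(frozen=True)
class InferredPair:
    """Two inferred constituent-peptide masses explaining the precursor."""

    mass_alpha: float
    mass_beta: float
    evidence: tuple[DoubletMatch, ...]
    single_doublet_fallback: bool = False


def pair_doublets_to_precursor(
    matches: list[DoubletMatch],
    linker: CrosslinkerDefinition,
    precursor_mass: float,
    precursor_tol_ppm: float = 5.0,
) -> list[InferredPair]:
    """Reconcile doublet-inferred peptide masses with the precursor mass.

    Emits pairs (mA, mB) with ``mA + mB + bridge ~ precursor`` within
    tolerance; every match additionally yields a flagged single-doublet
    fallback pair ``(mA, precursor - bridge - mA)`` so that spectra where one
    peptide's doublet is absent (a known failure mode of heavily fragmenting
    linkers) remain searchable.
    """
    tol = precursor_mass * precursor_tol_ppm * 1e-6
    pairs: list[InferredPair] = []
    remainder = precursor_mass - linker.bridge_mass
    for i, match_a in enumerate(matches):
        for match_b in matches[i:]:
            total = match_a.inferred_peptide_mass + match_b.inferred_peptide_mass
            if abs(total - remainder) <= tol:
                m_a, m_b = sorted(
                    (match_a.inferred_peptide_mass, match_b.inferred_peptide_mass)
                )
                pairs.append(InferredPair(m_a, m_b, (match_a, match_b)))
    for match in matches:
        beta = remainder - match.inferred_peptide_mass
        if beta > 0:
            pairs.append(
                InferredPair(
                    match.inferred_peptide_mass,
                    beta,
                    (match,),
                    single_doublet_fallback=True,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Fragment-ion matching


@dataclass(frozen=True)
class TheoreticalIon:
    label: str
    mz: float
    charge: int


def theoretical_ions(
    peptide: PeptideSpec,
    stub_mass: float,
    link_pos: int | None,
    max_charge: int = 2,
) -> list[TheoreticalIon]:
    """b- and y-series m/z values for a stub-modified peptide.

    The stub mass is added at ``link_pos`` (1-based); ions spanning the link
    position carry it.  With ``stub_mass == 0`` this reduces to the plain
    linear ion series.  Charges 1..``max_charge``.
    """
    seq = peptide.sequence
    n = len(seq)
    if link_pos is not None and not (1 <= link_pos <= n):
        raise ValueError(f"link position {link_pos} outside peptide of length {n}")
    mods = np.zeros(n)
    for pos, mass in peptide.fixed_mods:
        mods[pos - 1] += mass
    if peptide.nterm_acetyl:
        mods[0] += ACETYL_MASS
    if stub_mass and link_pos is not None:
        mods[link_pos - 1] += stub_mass
    residue = np.array([RESIDUE_MASS[r] for r in seq]) + mods
    prefix = np.cumsum(residue)

    ions: list[TheoreticalIon] = []
    for i in range(1, n):  # b1..b(n-1), y1..y(n-1)
        b_neutral = prefix[i - 1]
        y_neutral = prefix[-1] - prefix[n - i - 1] + WATER_MASS
        for z in range(1, max_charge + 1):
            ions.append(TheoreticalIon(f"b{i}+{z}", mass_to_mz(b_neutral, z), z))
            ions.append(TheoreticalIon(f"y{i}+{z}", mass_to_mz(y_neutral, z), z))
    return ions


@dataclass(frozen=True)
class MatchResult:
    n_matched: int
    n_theoretical: int
    matched_intensity_fraction: float
    assignments: tuple[tuple[str, int, float], ...]  # (label, peak index, ppm error)


def match_ions(
    spectrum: MS2Spectrum,
    ions: list[TheoreticalIon],
    fragment_tol_ppm: float = 10.0,
) -> MatchResult:
    """Greedy nearest matching of theoretical ions to peaks within tolerance.

    Each experimental peak is used at most once; the closest pairing wins,
    ties broken in favour of the lower-m/z ion.
    """
    if not spectrum.peaks or not ions:
        return MatchResult(0, len(ions), 0.0, ())
    mz = spectrum.mz_array
    intensity = spectrum.intensity_array
    candidates: list[tuple[float, float, int, int]] = []
    for ion_index, ion in enumerate(ions):
        width = ion.mz * fragment_tol_ppm * 1e-6
        lo = np.searchsorted(mz, ion.mz - width, side="left")
        hi = np.searchsorted(mz, ion.mz + width, side="right")
        for peak_index in range(lo, hi):
            # rank by absolute Da distance so exact ties fall to the
            # lower-m/z ion rather than the ppm-favoured heavier one
            candidates.append(
                (abs(mz[peak_index] - ion.mz), ion.mz, ion_index, peak_index)
            )
    candidates.sort()
    used_peaks: set[int] = set()
    used_ions: set[int] = set()
    assignments = []
    for abs_ppm, _, ion_index, peak_index in candidates:
        if ion_index in used_ions or peak_index in used_peaks:
            continue
        used_ions.add(ion_index)
        used_peaks.add(peak_index)
        ion = ions[ion_index]
        signed = (mz[peak_index] - ion.mz) / ion.mz * 1e6
        assignments.append((ion.label, peak_index, signed))
    total_intensity = float(intensity.sum())
    matched_intensity = float(sum(intensity[p] for _, p, _ in assignments))
    return MatchResult(
        n_matched=len(assignments),
        n_theoretical=len(ions),
        matched_intensity_fraction=(
            matched_intensity / total_intensity if total_intensity else 0.0
        ),
        assignments=tuple(assignments),
    )


def score_csm(n_matched: int, n_theoretical: int, match_probability: float) -> float:
    """Binomial-tail peptide score.

    ``-10 * log10 P(X >= k)`` for ``X ~ Binomial(n, p)`` -- the probability
    of matching at least ``k`` of ``n`` theoretical ions by chance at per-ion
    match probability ``p``.  Zero matches score 0; the score is monotone
    non-decreasing in ``k`` at fixed ``n, p``.
    """
    if not 0 < match_probability < 1:
        raise ValueError("match probability must be in (0, 1)")
    if n_matched > n_theoretical:
        raise ValueError("matched count exceeds theoretical count")
    if n_matched <= 0:
        return 0.0
    log_sf = binom.logsf(n_matched - 1, n_theoretical, match_probability)
    return float(-10.0 * log_sf / LN10)


# ---------------------------------------------------------------------------
# Results


@dataclass
class CSM:
    """One crosslink (or monolink) spectrum match."""

    spectrum_id: str
    candidate: CandidateLink
    alpha_score: float
    beta_score: float | None
    combined_score: float
    alpha_matched: int
    alpha_theoretical: int
    beta_matched: int
    beta_theoretical: int
    alpha_stub: str
    beta_stub: str | None
    tdc_class: str  # {"TT", "TD", "DD"} or {"T", "D"} for monolinks
    precursor_error_ppm: float
    q_value: float = 1.0

    @property
    def is_decoy_free(self) -> bool:
        return self.tdc_class in ("TT", "T")


@dataclass
class ResiduePairResult:
    """Grouped residue-pair identification (best CSM per unique site pair)."""

    site_a: tuple[str, int]
    site_b: tuple[str, int]
    best_score: float
    n_csms: int
    tdc_class: str
    q_value: float = 1.0
    best_csm: CSM | None = None


# ---------------------------------------------------------------------------
# FDR


def estimate_fdr(results: list, level: str = "CSM") -> list:
    """Annotate results with target-decoy q-values (in place; returns input).

    At each score threshold s, ``FDR(s) = max(0, #TD - #DD) / #TT`` over
    results scoring >= s (for single-peptide classes, D counts as TD and T
    as TT); the q-value is the running minimum of FDR towards higher scores,
    which makes q monotone non-increasing in score.  With no decoy classes
    present all q-values are 0 and a warning is logged.
    """
    if level not in ("CSM", "residue_pair"):
        raise ValueError(f"unknown FDR level {level!r}")
    if not results:
        return results
    score_of = lambda r: r.combined_score if isinstance(r, CSM) else r.best_score
    ordered = sorted(results, key=score_of, reverse=True)
    if all(r.tdc_class in ("TT", "T") for r in ordered):
        logger.warning("estimate_fdr(%s): no decoys present; q-values set to 0", level)
        for r in ordered:
            r.q_value = 0.0
        return results

    n_tt = n_td = n_dd = 0
    fdrs = np.empty(len(ordered))
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and score_of(ordered[j]) == score_of(ordered[i]):
            cls = ordered[j].tdc_class
            if cls in ("TT", "T"):
                n_tt += 1
            elif cls in ("TD", "D"):
                n_td += 1
            else:
                n_dd += 1
            j += 1
        fdr = max(0, n_td - n_dd) / max(n_tt, 1)
        fdrs[i:j] = fdr
        i = j
    q = np.minimum.accumulate(fdrs[::-1])[::-1]
    for r, qv in zip(ordered, q, strict=True):
        r.q_value = float(min(qv, 1.0))
    return results


def _canonical_sites(csm: CSM) -> tuple[tuple[str, int], tuple[str, int]]:
    site_a = csm.candidate.site_alpha()
    site_b = csm.candidate.site_beta()
    if site_b is None:
        return site_a, site_a
    return (site_a, site_b) if site_a <= site_b else (site_b, site_a)


def group_residue_pairs(csms: list[CSM]) -> list[ResiduePairResult]:
    """Collapse CSMs to unique residue pairs (canonical site ordering)."""
    groups: dict[tuple, list[CSM]] = {}
    for csm in csms:
        groups.setdefault(_canonical_sites(csm), []).append(csm)
    pairs = []
    for (site_a, site_b), members in sorted(groups.items()):
        best = max(members, key=lambda c: (c.combined_score, -c.q_value))
        pairs.append(
            ResiduePairResult(
                site_a=site_a,
                site_b=site_b,
                best_score=best.combined_score,
                n_csms=len(members),
                tdc_class=best.tdc_class,
                best_csm=best,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Linear prefilter


@dataclass
class LinearMatch:
    spectrum_id: str
    peptide: PeptideSpec
    score: float
    n_matched: int
    n_theoretical: int


@dataclass
class PrefilterResult:
    retained: list[MS2Spectrum]
    filtered: list[MS2Spectrum]
    best_linear: dict[str, LinearMatch]


def prefilter_linear(
    spectra: list[MS2Spectrum],
    index: PeptideIndex,
    score_threshold: float = 50.0,
    precursor_tol_ppm: float = 5.0,
    fragment_tol_ppm: float = 10.0,
    match_probability: float = 0.01,
    ion_max_charge: int = 2,
) -> PrefilterResult:
    """Partition spectra into linear-dominated and crosslink-search sets.

    A spectrum whose best linear (unmodified) peptide match scores above the
    threshold is excluded from the crosslink search and listed separately.
    Because a crosslink precursor equals two peptide masses plus the bridge,
    crosslink spectra rarely have any precursor-matching linear candidate at
    all, so separation is driven primarily by the precursor mass.
    """
    retained, filtered, best_map = [], [], {}
    for spectrum in spectra:
        prec = spectrum.precursor_neutral_mass
        tol = prec * precursor_tol_ppm * 1e-6
        best: LinearMatch | None = None
        for peptide, _ in index.lookup(prec, tol):
            match = match_ions(
                spectrum,
                theoretical_ions(peptide, 0.0, None, ion_max_charge),
                fragment_tol_ppm,
            )
            score = score_csm(match.n_matched, match.n_theoretical, match_probability)
            if best is None or score > best.score:
                best = LinearMatch(
                    spectrum.spectrum_id,
                    peptide,
                    score,
                    match.n_matched,
                    match.n_theoretical,
                )
        if best is not None:
            best_map[spectrum.spectrum_id] = best
        if best is not None and best.score > score_threshold:
            filtered.append(spectrum)
        else:
            retained.append(spectrum)
    return PrefilterResult(retained=retained, filtered=filtered, best_linear=best_map)


# ---------------------------------------------------------------------------
# Full search


@dataclass
class SearchConfig:
    """Tunable parameters of the identification pipeline."""

    fragment_tol_ppm: float = 10.0
    precursor_tol_ppm: float = 5.0
    max_fragment_charge: int = 3  # for doublet detection
    ion_max_charge: int = 2  # for b/y matching
    min_relative_intensity: float = 0.005
    match_probability: float = 0.01
    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    length_range: tuple[int, int] = (5, 45)
    carbamidomethyl: bool = True
    nterm_acetyl: bool = True
    prefilter_threshold: float | None = 50.0
    doublet_ids: tuple[str, ...] | None = None
    pairing_rule: str = "cleavage"
    search_monolinks: bool = True
    csm_fdr: float = 0.01
    max_candidates_per_spectrum: int = 2000


@dataclass
class RunResult:
    csms: list[CSM]
    residue_pairs: list[ResiduePairResult]
    monolinks: list[CSM]
    filtered_spectrum_ids: list[str]
    stats: dict = field(default_factory=dict)

    def accepted_pairs(self, q: float = 0.01) -> list[ResiduePairResult]:
        return [
            p for p in self.residue_pairs if p.tdc_class == "TT" and p.q_value <= q
        ]


def _tdc_class(alpha: PeptideSpec, beta: PeptideSpec | None) -> str:
    if beta is None:
        return "D" if alpha.decoy else "T"
    n_decoy = int(alpha.decoy) + int(beta.decoy)
    return ("TT", "TD", "DD")[n_decoy]


def _score_peptide(
    spectrum: MS2Spectrum,
    peptide: PeptideSpec,
    link_pos: int,
    linker: CrosslinkerDefinition,
    config: SearchConfig,
) -> tuple[float, str, int, int]:
    """Best stub-modified match for one peptide: (score, stub, k, n)."""
    best = (-1.0, "", 0, 0)
    for fragment in linker.fragments:
        ions = theoretical_ions(peptide, fragment.mass, link_pos, config.ion_max_charge)
        match = match_ions(spectrum, ions, config.fragment_tol_ppm)
        score = score_csm(
            match.n_matched, match.n_theoretical, config.match_probability
        )
        if score > best[0]:
            best = (score, fragment.name, match.n_matched, match.n_theoretical)
    return best


def search_run(
    spectra: list[MS2Spectrum],
    fasta,
    linker: CrosslinkerDefinition,
    config: SearchConfig | None = None,
) -> RunResult:
    """Run the full doublet-based crosslink search on a set of spectra.

    ``fasta`` may be a path to a FASTA file or a list of
    :class:`ProteinRecord`.  Decoys are generated internally by sequence
    reversal.  Deterministic given identical inputs and configuration.
    """
    config = config or SearchConfig()
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "__fspath__"):
        proteins = read_fasta(fasta)
    else:
        proteins = list(fasta)
    all_proteins = proteins + generate_decoys(proteins)

    peptides: list[PeptideSpec] = []
    for protein in all_proteins:
        peptides.extend(
            digest(
                protein,
                enzyme=config.enzyme,
                max_missed_cleavages=config.missed_cleavages,
                length_range=config.length_range,
                carbamidomethyl=config.carbamidomethyl,
            )
        )
    if config.nterm_acetyl:
        peptides = acetylated_variants(peptides)
    index = PeptideIndex(peptides)

    doublets = enumerate_doublet_distances(linker, rule=config.pairing_rule, warn=False)
    if config.doublet_ids is not None:
        wanted = set(config.doublet_ids)
        doublets = [d for d in doublets if d.id in wanted]
        if not doublets:
            raise ValueError(f"no doublets left after filtering to {sorted(wanted)}")

    if config.prefilter_threshold is not None:
        prefilter = prefilter_linear(
            spectra,
            index,
            score_threshold=config.prefilter_threshold,
            precursor_tol_ppm=config.precursor_tol_ppm,
            fragment_tol_ppm=config.fragment_tol_ppm,
            match_probability=config.match_probability,
            ion_max_charge=config.ion_max_charge,
        )
        searchable = prefilter.retained
        filtered_ids = [s.spectrum_id for s in prefilter.filtered]
    else:
        searchable = list(spectra)
        filtered_ids = []

    csms: list[CSM] = []
    monolinks: list[CSM] = []
    n_scored = 0
    for spectrum in searchable:
        prec = spectrum.precursor_neutral_mass
        prec_tol = prec * config.precursor_tol_ppm * 1e-6
        matches = detect_doublets(
            spectrum,
            doublets,
            linker,
            fragment_tol_ppm=config.fragment_tol_ppm,
            max_fragment_charge=config.max_fragment_charge,
            min_relative_intensity=config.min_relative_intensity,
        )
        pairs = pair_doublets_to_precursor(
            matches, linker, prec, config.precursor_tol_ppm
        )

        seen: set[tuple] = set()
        candidates: list[CandidateLink] = []
        frag_tol = lambda m: m * config.fragment_tol_ppm * 1e-6
        for pair in pairs:
            for pep_a, mass_a in index.lookup(pair.mass_alpha, frag_tol(pair.mass_alpha)):
                sites_a = link_positions(pep_a, linker)
                if not sites_a:
                    continue
                target_b = prec - linker.bridge_mass - mass_a
                for pep_b, _ in index.lookup(target_b, prec_tol):
                    for pa in sites_a:
                        for pb in link_positions(pep_b, linker):
                            key = _candidate_key(pep_a, pa, pep_b, pb)
                            if key in seen:
                                continue
                            seen.add(key)
                            alpha, pos_a, beta, pos_b = _canonical_order(
                                pep_a, pa, pep_b, pb
                            )
                            candidates.append(
                                CandidateLink(
                                    "crosslink", alpha, beta, pos_a, pos_b, linker.name
                                )
                            )
            if len(candidates) > config.max_candidates_per_spectrum:
                break

        best_csm: CSM | None = None
        best_key: tuple | None = None
        for candidate in candidates:
            assert candidate.beta is not None and candidate.pos_beta is not None
            score_a = _score_peptide(
                spectrum, candidate.alpha, candidate.pos_alpha, linker, config
            )
            score_b = _score_peptide(
                spectrum, candidate.beta, candidate.pos_beta, linker, config
            )
            n_scored += 1
            combined = score_a[0] + score_b[0]
            total_mass = (
                _pep_mass(candidate.alpha)
                + _pep_mass(candidate.beta)
                + linker.bridge_mass
            )
            ppm_error = (prec - total_mass) / total_mass * 1e6
            # tie-breaking: score, matched ions, |precursor error|, lexicographic
            key = (
                combined,
                score_a[2] + score_b[2],
                -abs(ppm_error),
                tuple(sorted((candidate.alpha.sequence, candidate.beta.sequence))),
            )
            if best_key is None or key > best_key:
                best_key = key
                best_csm = CSM(
                    spectrum_id=spectrum.spectrum_id,
                    candidate=candidate,
                    alpha_score=score_a[0],
                    beta_score=score_b[0],
                    combined_score=combined,
                    alpha_matched=score_a[2],
                    alpha_theoretical=score_a[3],
                    beta_matched=score_b[2],
                    beta_theoretical=score_b[3],
                    alpha_stub=score_a[1],
                    beta_stub=score_b[1],
                    tdc_class=_tdc_class(candidate.alpha, candidate.beta),
                    precursor_error_ppm=ppm_error,
                )
        if best_csm is not None:
            csms.append(best_csm)
        elif config.search_monolinks:
            best_mono = _search_monolink(spectrum, index, linker, config, prec, prec_tol)
            if best_mono is not None:
                monolinks.append(best_mono)
                n_scored += 1

    estimate_fdr(csms, "CSM")
    residue_pairs = group_residue_pairs(csms)
    estimate_fdr(residue_pairs, "residue_pair")
    if monolinks:
        estimate_fdr(monolinks, "CSM")

    return RunResult(
        csms=csms,
        residue_pairs=residue_pairs,
        monolinks=monolinks,
        filtered_spectrum_ids=filtered_ids,
        stats={
            "n_spectra": len(spectra),
            "n_searched": len(searchable),
            "n_prefiltered": len(filtered_ids),
            "n_candidates_scored": n_scored,
            "n_peptides": len(peptides),
            "n_doublets": len(doublets),
        },
    )


def _pep_mass(peptide: PeptideSpec) -> float:
    from .digestion import peptide_mass

    return peptide_mass(peptide)


def _candidate_key(pep_a: PeptideSpec, pa: int, pep_b: PeptideSpec, pb: int) -> tuple:
    ka = (pep_a.accession, pep_a.start, pep_a.sequence, pep_a.nterm_acetyl, pa)
    kb = (pep_b.accession, pep_b.start, pep_b.sequence, pep_b.nterm_acetyl, pb)
    return (ka, kb) if ka <= kb else (kb, ka)


def _canonical_order(pep_a: PeptideSpec, pa: int, pep_b: PeptideSpec, pb: int):
    ka = (pep_a.accession, pep_a.start, pep_a.sequence, pa)
    kb = (pep_b.accession, pep_b.start, pep_b.sequence, pb)
    if ka <= kb:
        return pep_a, pa, pep_b, pb
    return pep_b, pb, pep_a, pa


def _search_monolink(
    spectrum: MS2Spectrum,
    index: PeptideIndex,
    linker: CrosslinkerDefinition,
    config: SearchConfig,
    prec: float,
    prec_tol: float,
) -> CSM | None:
    best: CSM | None = None
    for peptide, mass in index.lookup(prec - linker.monolink_mass, prec_tol):
        for pos in link_positions(peptide, linker):
            ions = theoretical_ions(
                peptide, linker.monolink_mass, pos, config.ion_max_charge
            )
            match = match_ions(spectrum, ions, config.fragment_tol_ppm)
            score = score_csm(
                match.n_matched, match.n_theoretical, config.match_probability
            )
            if best is None or score > best.combined_score:
                total = mass + linker.monolink_mass
                best = CSM(
                    spectrum_id=spectrum.spectrum_id,
                    candidate=CandidateLink(
                        "monolink", peptide, None, pos, None, linker.name
                    ),
                    alpha_score=score,
                    beta_score=None,
                    combined_score=score,
                    alpha_matched=match.n_matched,
                    alpha_theoretical=match.n_theoretical,
                    beta_matched=0,
                    beta_theoretical=0,
                    alpha_stub="monolink",
                    beta_stub=None,
                    tdc_class="D" if peptide.decoy else "T",
                    precursor_error_ppm=(prec - total) / total * 1e6,
                )
    return best
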