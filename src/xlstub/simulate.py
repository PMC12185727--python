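"""Synthetic crosslinked-peptide MS2 spectra with ground truth.

The generator emulates the features of cleavable-crosslinker spectra that
the identification engine relies on: stub-modified b/y ions of both
constituent peptides, the characteristic light/heavy doublet peak pair of
the sampled cleavage channel, lognormal fragment intensities, Gaussian ppm
m/z jitter, uniform random noise peaks, and collision-energy-dependent
attenuation of the doublet intensity, ``I ∝ exp(-beta * max(0, NCE - 25))``.
Linker-specific cleavage-channel distributions reproduce the qualitative
fragmentation behaviour of the built-ins: DiSPASO scatters over many
doublets with the ETHMP-alkene channel (D12) dominant, DSBSO concentrates
on its single main doublet (D11).

Every spectrum carries exactly one ground-truth record, and a fixed seed
reproduces the emitted MGF byte-for-byte.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .digestion import (
    PeptideSpec,
    ProteinRecord,
    digest,
    link_positions,
    peptide_mass,
)
from .digestion import CandidateLink
from .linkers import CrosslinkerDefinition, builtin, enumerate_doublet_distances
from .search import theoretical_ions
from .spectra import MS2Spectrum, Peak, mass_to_mz, write_mgf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "default_channel_weights",
    "simulate_crosslink_spectrum",
    "simulate_linear_spectrum",
    "simulate_dataset",
    "random_proteome",
    "estimate_channel_weights",
]

#: SwissProt-like amino-acid frequencies with lysine boosted to 7% so random
#: proteins are guaranteed to carry link sites (renormalised).
_AA_FREQ = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 7.00,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.64, "T": 5.36, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}


@dataclass
class SimulationConfig:
    """Study conditions for the spectrum generator.

    ``channel_weights`` maps doublet ids to sampling probabilities (must sum
    to 1); ``nce_list`` is the stepped collision-energy schedule (one value
    sampled per spectrum); ``doublet_attenuation_beta`` is the decay rate of
    doublet intensity per NCE unit above 25; precursor charges are sampled
    uniformly from ``precursor_charges`` (the instrument schedules 3+..6+).
    """

    seed: int = 0
    linker: str = "DiSPASO"
    n_proteins: int = 20
    protein_length: tuple[int, int] = (100, 500)
    channel_weights: dict[str, float] | None = None
    noise_peaks: int = 60
    mz_jitter_ppm: float = 3.0
    intensity_log_mean: float = 0.0
    intensity_log_sd: float = 0.6
    nce_list: tuple[float, ...] = (25.0, 27.0, 32.0)
    doublet_attenuation_beta: float = 0.08
    precursor_charges: tuple[int, ...] = (3, 4, 5, 6)
    doublet_charge_max: int = 2
    ion_max_charge: int = 2
    background_ratio: float = 10.0  # linear background spectra per crosslink
    mz_range: tuple[float, float] = (150.0, 1500.0)
    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    length_range: tuple[int, int] = (5, 45)

    def resolved_weights(self, linker: CrosslinkerDefinition) -> dict[str, float]:
        weights = self.channel_weights or default_channel_weights(linker.name)
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"channel weights must sum to 1, got {total}")
        known = {d.id for d in enumerate_doublet_distances(linker, warn=False)}
        unknown = set(weights) - known
        if unknown:
            raise ValueError(
                f"channel weights reference unknown doublets {sorted(unknown)}"
            )
        return dict(weights)


def default_channel_weights(linker_name: str) -> dict[str, float]:
    """Qualitative cleavage-channel distributions for the built-in linkers.

    DiSPASO scatters across many doublets (D12 ETHMP-alkene dominant, D11
    ETFP-alkene second, then the alkene-thiol/sulfenic-acid and EMP
    channels); DSBSO concentrates >= 0.7 on its main doublet D11.  These
    shapes are qualitative, not transcriptions of measured channel usage.
    """
    name = linker_name.lower()
    if name == "dispaso":
        return {"D12": 0.30, "D11": 0.22, "D2": 0.14, "D1": 0.13, "D13": 0.11,
                "D14": 0.10}
    if name == "dsbso":
        return {"D11": 0.74, "D1": 0.14, "D5": 0.12}
    if name == "dsso":
        return {"D2": 0.55, "D1": 0.30, "D3": 0.15}
    raise KeyError(f"no default channel weights for linker {linker_name!r}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted in one simulated spectrum."""

    spectrum_id: str
    kind: str  # {"crosslink", "linear"}
    candidate: CandidateLink | None
    peptide: PeptideSpec | None  # for linear background spectra
    channels: tuple[str, ...]
    doublet_peak_indices: tuple[tuple[int, int], ...]
    precursor_charge: int
    nce: float


@dataclass
class SimulatedDataset:
    spectra: list[MS2Spectrum]
    truths: list[GroundTruth]
    proteins: list[ProteinRecord]
    config: SimulationConfig

    @property
    def crosslink_truths(self) -> list[GroundTruth]:
        return [t for t in self.truths if t.kind == "crosslink"]

    def planted_residue_pairs(self) -> set[tuple]:
        pairs = set()
        for truth in self.crosslink_truths:
            assert truth.candidate is not None
            site_a = truth.candidate.site_alpha()
            site_b = truth.candidate.site_beta()
            pairs.add(tuple(sorted((site_a, site_b))))
        return pairs

    def write(self, mgf_path, truth_csv_path) -> None:
        write_mgf(self.spectra, mgf_path)
        with open(truth_csv_path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["spectrum_id", "kind", "acc_a", "pos_a", "pep_a", "acc_b",
                 "pos_b", "pep_b", "channels", "charge", "nce"]
            )
            for truth in self.truths:
                if truth.kind == "crosslink":
                    assert truth.candidate is not None
                    site_a = truth.candidate.site_alpha()
                    site_b = truth.candidate.site_beta() or ("", "")
                    row = [
                        truth.spectrum_id, truth.kind,
                        site_a[0], site_a[1], truth.candidate.alpha.sequence,
                        site_b[0], site_b[1],
                        truth.candidate.beta.sequence if truth.candidate.beta else "",
                    ]
                else:
                    assert truth.peptide is not None
                    row = [truth.spectrum_id, truth.kind,
                           truth.peptide.accession, truth.peptide.start,
                           truth.peptide.sequence, "", "", ""]
                row += [";".join(truth.channels), truth.precursor_charge,
                        f"{truth.nce:g}"]
                writer.writerow(row)


# ---------------------------------------------------------------------------
# Single-spectrum generators


def _lognormal(rng: np.random.Generator, config: SimulationConfig, scale: float) -> float:
    return scale * float(
        rng.lognormal(config.intensity_log_mean, config.intensity_log_sd)
    )


def _jitter(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    if ppm_sd <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm_sd) * 1e-6)


def simulate_crosslink_spectrum(
    candidate: CandidateLink,
    linker: CrosslinkerDefinition,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    spectrum_id: str = "sim_xl_0",
    n_channels: int = 1,
) -> tuple[MS2Spectrum, GroundTruth]:
    """Emit one crosslinked-peptide MS2 spectrum plus its ground truth.

    For each of ``n_channels`` sampled cleavage channels the doublet peak
    pair (peptide + light stub / peptide + heavy stub) is planted for both
    constituent peptides, attenuated by ``exp(-beta * max(0, NCE - 25))``;
    stub-modified b/y ions of both peptides (light stub of the first sampled
    channel), lognormal intensities, Gaussian ppm jitter and uniform noise
    peaks complete the spectrum.
    """
    if candidate.beta is None or candidate.pos_beta is None:
        raise ValueError("simulate_crosslink_spectrum needs a crosslink candidate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = config.resolved_weights(linker)
    doublets = {d.id: d for d in enumerate_doublet_distances(linker, warn=False)}
    fragment_mass = {f.name: f.mass for f in linker.fragments}

    channel_ids = list(weights)
    probs = np.array([weights[c] for c in channel_ids])
    channels = tuple(
        str(rng.choice(channel_ids, p=probs)) for _ in range(n_channels)
    )
    nce = float(rng.choice(config.nce_list))
    charge = int(rng.choice(config.precursor_charges))
    attenuation = float(
        np.exp(-config.doublet_attenuation_beta * max(0.0, nce - 25.0))
    )

    mass_a = peptide_mass(candidate.alpha)
    mass_b = peptide_mass(candidate.beta)
    precursor_mass = mass_a + mass_b + linker.bridge_mass
    precursor_mz = mass_to_mz(precursor_mass, charge)

    peak_list: list[tuple[float, float, str]] = []  # (mz, intensity, tag)

    # doublet pairs for each sampled channel, for both peptides
    for channel in channels:
        doublet = doublets[channel]
        light = fragment_mass[doublet.light]
        heavy = fragment_mass[doublet.heavy]
        doublet_charge = int(rng.integers(1, config.doublet_charge_max + 1))
        for pep_mass, side in ((mass_a, "alpha"), (mass_b, "beta")):
            base = _lognormal(rng, config, 1.0) * attenuation
            for stub, kind in ((light, "light"), (heavy, "heavy")):
                mz = mass_to_mz(pep_mass + stub, doublet_charge)
                peak_list.append(
                    (
                        _jitter(rng, mz, config.mz_jitter_ppm),
                        base * float(rng.uniform(0.8, 1.2)),
                        f"doublet:{channel}:{side}:{kind}",
                    )
                )

    # stub-modified b/y ions of both peptides (light stub of first channel)
    first = doublets[channels[0]]
    for peptide, pos in (
        (candidate.alpha, candidate.pos_alpha),
        (candidate.beta, candidate.pos_beta),
    ):
        stub_mass = fragment_mass[first.light]
        for ion in theoretical_ions(peptide, stub_mass, pos, config.ion_max_charge):
            peak_list.append(
                (
                    _jitter(rng, ion.mz, config.mz_jitter_ppm),
                    _lognormal(rng, config, 0.3),
                    f"ion:{ion.label}",
                )
            )

    # noise
    lo, hi = config.mz_range
    for _ in range(config.noise_peaks):
        peak_list.append(
            (float(rng.uniform(lo, hi)), _lognormal(rng, config, 0.02), "noise")
        )

    spectrum = MS2Spectrum(
        spectrum_id=spectrum_id,
        scan=0,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=[Peak(mz, inten) for mz, inten, _ in peak_list if inten > 0],
        nce=nce,
    )
    # locate the planted doublet peaks in the final sorted peak list
    doublet_indices = []
    sorted_mz = spectrum.mz_array
    tagged = sorted(peak_list, key=lambda t: t[0])
    light_idx = {}
    for idx, (mz, _, tag) in enumerate(tagged):
        if tag.startswith("doublet:"):
            _, channel, side, kind = tag.split(":")
            light_idx[(channel, side, kind)] = int(
                np.searchsorted(sorted_mz, mz) if len(sorted_mz) else 0
            )
    for channel in set(channels):
        for side in ("alpha", "beta"):
            li = light_idx.get((channel, side, "light"))
            hi_ = light_idx.get((channel, side, "heavy"))
            if li is not None and hi_ is not None:
                doublet_indices.append((li, hi_))

    truth = GroundTruth(
        spectrum_id=spectrum_id,
        kind="crosslink",
        candidate=candidate,
        peptide=None,
        channels=channels,
        doublet_peak_indices=tuple(sorted(doublet_indices)),
        precursor_charge=charge,
        nce=nce,
    )
    return spectrum, truth


def simulate_linear_spectrum(
    peptide: PeptideSpec,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    spectrum_id: str = "sim_lin_0",
) -> tuple[MS2Spectrum, GroundTruth]:
    """Plain linear-peptide background spectrum (b/y ions + noise)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nce = float(rng.choice(config.nce_list))
    charge = int(rng.choice((2, 3)))
    mass = peptide_mass(peptide)
    peaks = []
    for ion in theoretical_ions(peptide, 0.0, None, config.ion_max_charge):
        peaks.append(
            Peak(
                _jitter(rng, ion.mz, config.mz_jitter_ppm),
                _lognormal(rng, config, 0.3),
            )
        )
    lo, hi = config.mz_range
    for _ in range(config.noise_peaks):
        peaks.append(Peak(float(rng.uniform(lo, hi)), _lognormal(rng, config, 0.02)))
    spectrum = MS2Spectrum(
        spectrum_id=spectrum_id,
        scan=0,
        precursor_mz=mass_to_mz(mass, charge),
        precursor_charge=charge,
        peaks=peaks,
        nce=nce,
    )
    truth = GroundTruth(
        spectrum_id=spectrum_id,
        kind="linear",
        candidate=None,
        peptide=peptide,
        channels=(),
        doublet_peak_indices=(),
        precursor_charge=charge,
        nce=nce,
    )
    return spectrum, truth


# ---------------------------------------------------------------------------
# Whole datasets


def random_proteome(
    rng: np.random.Generator,
    n_proteins: int,
    length_range: tuple[int, int],
    prefix: str = "SIM",
) -> list[ProteinRecord]:
    """I.i.d.-residue proteins at SwissProt-like frequencies (K at 7%)."""
    letters = list(_AA_FREQ)
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        proteins.append(
            ProteinRecord(
                accession=f"{prefix}{i + 1:03d}",
                description=f"{prefix}{i + 1:03d} synthetic protein",
                sequence=seq,
            )
        )
    return proteins


def _linkable_peptides(
    proteins: list[ProteinRecord],
    linker: CrosslinkerDefinition,
    config: SimulationConfig,
) -> list[tuple[PeptideSpec, list[int]]]:
    out = []
    for protein in proteins:
        for peptide in digest(
            protein,
            enzyme=config.enzyme,
            max_missed_cleavages=config.missed_cleavages,
            length_range=config.length_range,
        ):
            sites = link_positions(peptide, linker)
            if sites:
                out.append((peptide, sites))
    return out


def simulate_dataset(
    n_links: int,
    config: SimulationConfig,
    proteins: list[ProteinRecord] | None = None,
    n_background: int | None = None,
) -> SimulatedDataset:
    """Simulate a full run: crosslink spectra plus linear background.

    Peptide pairs with valid lysine link sites are sampled from the digested
    (random or supplied) proteome; each planted link is a unique residue
    pair.  ``n_background`` linear-peptide spectra (default
    ``background_ratio`` x ``n_links``) emulate the persistent linear
    background of enrichment experiments.  Fully seeded: identical config
    and seed give byte-identical MGF output.
    """
    if n_links < 1:
        raise ValueError("n_links must be >= 1")
    rng = np.random.default_rng(config.seed)
    linker = builtin(config.linker)
    if proteins is None:
        proteins = random_proteome(rng, config.n_proteins, config.protein_length)
    pool = _linkable_peptides(proteins, linker, config)
    if not pool:
        raise ValueError("proteome contains no linkable peptides")

    if n_background is None:
        n_background = int(round(config.background_ratio * n_links))

    used_pairs: set[tuple] = set()
    spectra: list[MS2Spectrum] = []
    truths: list[GroundTruth] = []
    attempts = 0
    while len(truths) < n_links:
        attempts += 1
        if attempts > 200 * n_links:
            raise ValueError(
                f"could not sample {n_links} unique residue pairs from this proteome"
            )
        pep_a, sites_a = pool[int(rng.integers(len(pool)))]
        pep_b, sites_b = pool[int(rng.integers(len(pool)))]
        pos_a = int(rng.choice(sites_a))
        pos_b = int(rng.choice(sites_b))
        site_a = (pep_a.accession, pep_a.start + pos_a - 1)
        site_b = (pep_b.accession, pep_b.start + pos_b - 1)
        if site_a == site_b and pep_a.sequence == pep_b.sequence:
            pass  # homodimeric self-link is legitimate
        pair_key = tuple(sorted((site_a, site_b)))
        if pair_key in used_pairs:
            continue
        used_pairs.add(pair_key)
        candidate = CandidateLink("crosslink", pep_a, pep_b, pos_a, pos_b, linker.name)
        sid = f"sim_xl_{len(truths):05d}"
        spectrum, truth = simulate_crosslink_spectrum(
            candidate, linker, config, rng, spectrum_id=sid
        )
        spectra.append(spectrum)
        truths.append(truth)

    all_peptides = [pep for pep, _ in pool]
    for i in range(n_background):
        peptide = all_peptides[int(rng.integers(len(all_peptides)))]
        sid = f"sim_lin_{i:05d}"
        spectrum, truth = simulate_linear_spectrum(peptide, config, rng, sid)
        spectra.append(spectrum)
        truths.append(truth)

    return SimulatedDataset(
        spectra=spectra, truths=truths, proteins=list(proteins), config=config
    )


# ---------------------------------------------------------------------------
# Channel-weight recovery


def estimate_channel_weights(
    spectra: list[MS2Spectrum],
    linker: CrosslinkerDefinition,
    channel_ids: list[str],
    fragment_tol_ppm: float = 10.0,
    max_fragment_charge: int = 3,
    min_relative_intensity: float = 0.005,
) -> dict[str, float]:
    """Estimate cleavage-channel frequencies from detected doublets.

    Each spectrum votes for the channel (restricted to ``channel_ids``)
    whose detected doublet has the highest summed intensity; the returned
    frequencies estimate the generator's channel weights.
    """
    from .search import detect_doublets

    doublets = [
        d
        for d in enumerate_doublet_distances(linker, warn=False)
        if d.id in set(channel_ids)
    ]
    counts = dict.fromkeys(channel_ids, 0)
    total = 0
    for spectrum in spectra:
        matches = detect_doublets(
            spectrum,
            doublets,
            linker,
            fragment_tol_ppm=fragment_tol_ppm,
            max_fragment_charge=max_fragment_charge,
            min_relative_intensity=min_relative_intensity,
        )
        if not matches:
            continue
        best = max(matches, key=lambda m: (m.summed_intensity, m.doublet_id))
        counts[best.doublet_id] += 1
        total += 1
    if total == 0:
        return dict.fromkeys(channel_ids, 0.0)
    return {cid: counts[cid] / total for cid in channel_ids}
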