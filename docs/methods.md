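# Methods

## The doublet model

An MS-cleavable crosslinker joins two lysine side chains (or a protein
N-terminal α-amine) through a bridge containing labile bonds — for the
sulfoxide family modelled here, C–S bonds flanking S=O.  During HCD
fragmentation the bridge cleaves preferentially, so each constituent peptide
appears in the MS2 spectrum carrying one of a small set of linker remnants
("stubs").  For one peptide observed with two different stubs, the peak
spacing

    doublet distance = mass(fragment_heavy) − mass(fragment_light)

depends only on the linker.  Detecting a doublet therefore (i) flags the
spectrum as containing a crosslink and (ii) yields the neutral mass of one
constituent peptide, `neutral(mz_light, z) − mass(light stub)`.

### Mass conventions

Stub masses are stored as **residue-modification masses**: the mass added to
the intact crosslinked residue (alkene C3H2O = 54.01056 Da, thiol C3H2OS =
85.98264 Da, sulfenic acid C3H4O2S = 103.99320 Da).  Tables that quote
fragments inclusive of the lysine side-chain nitrogen differ by a constant
NH (15.01090 Da); the offset cancels in every doublet distance, and the test
suite asserts the equality for all built-in doublets.  One published worked
example prints the NH-inclusive alkene mass as 59.02146 together with an
alkene/sulfenic-acid distance of 49.98264 — arithmetically inconsistent; the
composition C3H3NO (69.02146 Da NH-inclusive) reproduces the printed
distance exactly and is the reading adopted by the registry (recorded in the
DiSPASO provenance notes).

### The built-in registry

**DiSPASO** (bis(2,5-dioxopyrrolidin-1-yl)
3,3'-((5-ethynyl-1,3-phenylene)bis(methylenesulfinyl))dipropanoate): the
intact bridge is C16H14O4S2 = 334.03335 Da.  Cleavage of either sulfoxide
C–S bond gives, on the short side, the DSSO-type stub trio; the long-side
complements are ETHMP = bridge − alkene (280.02278 Da), its water-loss
product ETFP = ETHMP − H2O (262.01222 Da, thioaldehyde at the benzylic
position) and EMP = bridge − sulfenic acid (230.04015 Da, the desulfurised
benzylic fragment).  The intact linker is carried as a seventh species
("full") to model amide-bond cleavage that transfers the whole bridge to
one peptide.  These compositions reproduce the published doublet distances:
D11 (alkene→ETFP) ≈ 208 Da, D12 (alkene→ETHMP) = 226.01 Da, and
ETHMP − ETFP = 18.011 Da (one water) as a plausibility check.

**DSBSO**: bridge C11H16O6S2 = 308.03883 Da (the crosslink modification mass
used by cleavable-XL search engines), with long fragments defined as bridge
complements of the stub trio.  The alkene/long-thiol distance is then
182.00714 Da, matching the published integer 182 Da; this entry is
constructed (the full azide-tagged structure is not transcribed) and says so
in its provenance notes.

**DSSO**: the classic symmetric linker, bridge C6H6O3S = 158.00377 Da, three
stub species, three doublets.

### Doublet enumeration and its pairing rule

The default rule pairs **all combinations of the cleavage (non-intact)
fragments**: C(6,2) = 15 doublets for DiSPASO, which reproduces both the
published count and the published channel identities — including the
short/short doublets D1 (alkene–thiol) and D2 (alkene–sulfenic acid) that a
short×long-only rule cannot produce.  Two alternatives are available:
`short_long_full` (3 short × 3 long plus each cleavage fragment × intact,
also 15 for DiSPASO) and `all` (C(7,2) = 21).  Doublet ids named in the
source material are pinned (DiSPASO D1, D2, D11–D14; DSBSO D11); the
remaining table positions are assigned deterministically by ascending delta.

Distinct pairings can share a delta *exactly*: for DiSPASO,
alkene→EMP, sulfenic acid→ETHMP and thiol→ETFP all equal
bridge − alkene − sulfenic acid = 176.02959 Da (the two water relationships
make this unavoidable).  Doublets are therefore kept as **pair
definitions** — 15 entries — with collisions reported via a warning;
`merge_collisions=True` collapses collision groups (within 1e-5 Da, far
below instrument resolution) for callers who want unique distances only.

## The identification engine

Per spectrum: (1) a **linear prefilter** removes spectra whose precursor
matches a single unmodified peptide with a confident b/y match — separation
is driven mainly by the precursor mass, since a crosslink precursor equals
two peptide masses plus the bridge; (2) **doublet detection** scans sorted
peaks for pairs satisfying `|(mz_h − mz_l)·z − δ| ≤ tol` at fragment charges
1–3, with the ppm tolerance taken relative to the heavier fragment's neutral
mass and an intensity floor of 0.5% of the base peak; (3) **precursor
reconciliation** keeps inferred mass pairs with `mA + mB + bridge ≈
precursor`, plus a flagged single-doublet fallback `mB = precursor − bridge
− mA` (one of the two doublets is frequently absent for heavily fragmenting
linkers); (4) **candidate lookup** finds peptides at the inferred masses in
a mass-sorted index, restricted to valid link sites (lysines that are not
the enzymatic C-terminus — a modified lysine blocks cleavage — plus
non-acetylated protein N-termini); (5) **scoring**: every linker fragment
species is tried as a modification at the link site, b/y ions are matched
greedily (nearest within tolerance, each peak used once, ties to the
lower-m/z ion), and each peptide receives a binomial tail score
`−10·log10 P(X ≥ k | n, p)` with per-ion match probability p = 0.01; the CSM
score is the sum over both peptides.  One CSM is reported per spectrum (ties
broken by matched-ion count, precursor error, then lexicographic peptide
order).

**FDR**: decoys are full-sequence reversals (`REV_` accessions), giving
TT/TD/DD CSM classes.  At score threshold s,
`FDR(s) = max(0, #TD − #DD) / #TT`; q-values are the running minimum of FDR
towards higher scores.  Residue pairs are grouped first (best CSM per
canonically ordered site pair) and the same estimator is applied to pair
classes.  Monolinks are searched only for spectra with no crosslink
candidate and are reported with their own T/D q-values, never mixed into
crosslink classes.  The engine's score is not comparable to any external
search engine's score.

Defaults: fragment tolerance 10 ppm, precursor 5 ppm (Orbitrap-class MS2),
trypsin with ≤2 missed cleavages, peptide length 5–45,
carbamidomethyl-C fixed (the standard iodoacetamide alkylation),
N-terminal acetylation as a variable modification, prefilter threshold 50
(binomial score).  All are `SearchConfig` fields.

## The simulator

`simulate_crosslink_spectrum` emits, per spectrum: the doublet peak pair of
each sampled cleavage channel for **both** constituent peptides (fragment
charge 1–2), stub-modified b/y ions of both peptides, lognormal peak
intensities (σ = 0.6), Gaussian m/z jitter (3 ppm s.d.), and uniform random
noise peaks (60 per spectrum over 150–1500 Th).  Precursor charges are
sampled from 3+–6+ and the collision energy from the stepped schedule
(25, 27, 32); doublet intensities are attenuated as
`I ∝ exp(−β·max(0, NCE−25))` with β = 0.08 per NCE unit.  The exponential
form encodes the qualitative observation that doublet intensity falls at
higher collision energy; β has no measured value and is an artifact choice.
Channel weights default to qualitative shapes: DiSPASO scattered with
D12 > D11 > D1/D2 > D13/D14; DSBSO ≥ 0.7 on its main doublet; they are not
transcriptions of measured channel usage.  `simulate_dataset` samples unique
planted residue pairs from a digested proteome (supplied or random:
i.i.d. residues at SwissProt-like frequencies with lysine at 7%, lengths
100–500) and adds a 10:1 linear-peptide background emulating the persistent
linear background of enrichment experiments.  Everything is driven by one
`numpy` generator seeded from the config, so a seed fixes the MGF output
byte-for-byte.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: isotope clusters (monoisotopic peaks only),
co-isolated chimeric precursors, internal/immonium/neutral-loss ions,
intensity structure of real fragmentation (mobile-proton effects), retention
time and FAIMS behaviour, and real decoy-vs-entrapment sequence composition
biases.  Recovery and calibration results are statements about the engine's
correctness under the model, not about instrument performance.

## Verification set-up

The test suite checks, among others: mass additivity and agreement of
peptide masses with an independent residue-table implementation (< 1e-6 Da
on 1,000 random peptides); digestion equality with a brute-force cleavage
scan (200 random sequences × both enzymes × 0–2 missed cleavages); MGF
round-trip at the stated precision (m/z 1e-6, intensity 1e-2); exact
recovery of all planted doublets and 50/50 planted residue pairs at
q ≤ 0.01 on noiseless simulations, including the K7×K7 self-link of the
synthetic standard peptide WGGGGRKSSAAR; FDR calibration over 20 seeded
runs of ~130 crosslink + 60 background spectra against a 1:1 entrapment
proteome (mean realised FDP at q ≤ 0.01 required ≤ 0.03), with ≥ 500 scored
candidate decisions per run; channel-weight recovery within ±0.05 from
2,000 simulated spectra; and byte-exact seed determinism.  Run sizes were
chosen to make these checks statistically meaningful at desk scale.

## Permeability descriptors

`props` computes Crippen cLogP and Ertl tPSA via RDKit's reference
implementation of the published contribution tables — the computation is
standard plumbing; the module's content is the curated reagent panel, the
enrichable/permeable/other classification (dominant-property rule) and the
reproducible table/plot.  tPSA defaults to the classic Ertl
parameterisation without S/P contributions; `include_sp=True` selects the
S/P-inclusive variant (which source material rarely states, so both are
exposed).  Panel SMILES are transcribed from published structures or
systematic names; the DSBSO entry is an approximate structural model and is
named accordingly.  Absolute values for approximate structures should not
be compared against published figures.

## Known limitations

- Fragment charge states are not deconvolved; doublets are searched at
  explicit charges 1–3 instead.
- The candidate search scores one CSM per spectrum; chimeric spectra are
  out of scope.
- Looplinks are enumerable as candidates but not searched in the main
  pipeline; monolink search is a single-peptide fallback.
- The binomial score ignores peak intensity (by design — it makes CSM
  ranking invariant to intensity scaling), so it discards information a
  production engine would use.
- DSBSO/DSSO entries carry literature stub chemistry but were not validated
  against instrument data here.
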