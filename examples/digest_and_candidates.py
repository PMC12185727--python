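"""Digest the single-peptide crosslink standard and enumerate candidates.

The peptide WGGGGRKSSAAR carries one internal lysine (K7).  Tryptic
digestion with one missed cleavage yields KSSAAR; self-crosslinking two
copies at K7 gives a precursor equal to twice the peptide mass plus the
intact DiSPASO bridge.
"""

from xlstub import ProteinRecord, builtin, digest, enumerate_candidates, peptide_mass

protein = ProteinRecord("XLPEP1", "single-peptide standard", "WGGGGRKSSAAR")
dispaso = builtin("DiSPASO")

peptides = digest(protein, "trypsin", max_missed_cleavages=1, length_range=(5, 45))
print("tryptic peptides (1 missed cleavage, length 5-45):")
for pep in peptides:
    print(f"  {pep.sequence:<10} start={pep.start:<3} mc={pep.missed_cleavages} "
          f"mass={peptide_mass(pep):.5f} Da")

kssaar = next(p for p in peptides if p.sequence == "KSSAAR")
precursor = 2 * peptide_mass(kssaar) + dispaso.bridge_mass
print(f"\nself-link precursor (2x KSSAAR + bridge): {precursor:.5f} Da")

candidates = enumerate_candidates(peptides, dispaso, precursor, tol_ppm=5)
for cand in candidates:
    print(f"candidate: {cand.alpha.sequence} x {cand.beta.sequence} at "
          f"{cand.site_alpha()} x {cand.site_beta()}")
print("\nThe single candidate is the K7 x K7 self-link: the modified lysine "
      "blocks cleavage, so KSSAAR (one missed cleavage) is the linkable form.")
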