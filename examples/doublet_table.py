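"""Enumerate the doublet distances of the built-in cleavable crosslinkers.

Each doublet is a pair of MS2 peaks from the same peptide carrying the
light vs heavy crosslinker remnant; the delta (Da) is a constant of the
linker chemistry.  DiSPASO scatters over 15 doublets; DSBSO has one
dominant channel at 182 Da; DSSO has the classic three-stub pattern.
"""

from xlstub import builtin, enumerate_doublet_distances, validate_linker

for name in ("DiSPASO", "DSBSO", "DSSO"):
    linker = builtin(name)
    report = validate_linker(linker)
    doublets = enumerate_doublet_distances(linker, warn=False)
    print(f"\n{name}: bridge {linker.bridge_mass:.5f} Da, "
          f"{len(linker.fragments)} fragment species, "
          f"{len(doublets)} doublets, validation ok={report.ok}")
    for d in doublets:
        print(f"  {d.id:>4}  {d.light:>14} -> {d.heavy:<14} {d.delta:10.5f} Da")

print("\nThe DiSPASO D11 (alkene->ETFP, ~208 Da) and D12 (alkene->ETHMP, "
      "226.01 Da) rows are the main channels used for identification; "
      "D2 is the classic 49.98264 Da alkene/sulfenic-acid distance.")
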