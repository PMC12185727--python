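"""Crosslinker permeability landscape: Crippen cLogP vs Ertl tPSA.

Membrane permeability of a crosslinking reagent is governed by the balance
between lipophilicity (computed octanol-water partition coefficient, cLogP,
Crippen atomic contributions) and polarity (topological polar surface area,
tPSA, Ertl fragment contributions).  Enrichable crosslinkers cluster at
high tPSA / low cLogP, membrane-permeable ones at the opposite corner; this
module computes both descriptors for a curated reagent panel and renders
the landscape.  The numerical work is delegated to RDKit's reference
implementation of the Crippen and Ertl contribution tables; the module's
value is the panel, the classification and the reproducible table/plot.

By default tPSA uses the classic Ertl parameterisation (no S/P polar
contributions); ``include_sp=True`` switches to the S/P-inclusive variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

__all__ = [
    "CompoundRecord",
    "compute_properties",
    "landscape_table",
    "builtin_panel",
    "CROSSLINKER_PANEL",
]

CLASSES = ("enrichable", "permeable", "other")


@dataclass(frozen=True)
class CompoundRecord:
    """One crosslinker with its permeability descriptors.

    The class label follows the dominant-property rule: a reagent showing
    both an enrichment handle and good permeability is assigned its dominant
    property.
    """

    name: str
    smiles: str
    compound_class: str
    clogp: float
    tpsa: float

    def __post_init__(self) -> None:
        if self.compound_class not in CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.tpsa < 0:
            raise ValueError("tPSA cannot be negative")


def compute_properties(smiles: str, include_sp: bool = False) -> tuple[float, float]:
    """(cLogP, tPSA in Å²) of a molecule given as SMILES.

    cLogP via Crippen atomic contributions, tPSA via Ertl fragment
    contributions; deterministic.  Invalid SMILES is rejected with the
    offending string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    clogp = float(Crippen.MolLogP(mol))
    tpsa = float(rdMolDescriptors.CalcTPSA(mol, includeSandP=include_sp))
    return clogp, tpsa


#: Curated panel of crosslinking reagents: (name, SMILES, class).  SMILES
#: are transcribed from the published structures / IUPAC names of the
#: reagents (the DiSPASO structure from its systematic name; the DSBSO
#: entry is an approximate structural model and is marked synthetic).
#: Classification follows common usage: reagents carrying an enrichment
#: handle (click/biotin/IMAC group) are "enrichable", plain hydrophobic
#: NHS-ester/imidate linkers "permeable", everything else "other".
_NHS = "ON1C(=O)CCC1=O"
_SULFO_NHS = "ON1C(=O)CC(S(=O)(=O)O)C1=O"

CROSSLINKER_PANEL: tuple[tuple[str, str, str], ...] = (
    ("DiSPASO",
     f"C#Cc1cc(CS(=O)CCC(=O){_NHS})cc(CS(=O)CCC(=O){_NHS})c1",
     "enrichable"),
    ("DiPPASO",
     "C#Cc1cc(CS(=O)CCC(=O)ON2C(=O)c3ccccc3C2=O)cc(CS(=O)CCC(=O)"
     "ON2C(=O)c3ccccc3C2=O)c1",
     "other"),
    ("Azide-DSBSO-model",
     f"[N-]=[N+]=NCCC1(C)OCC(CS(=O)CCC(=O){_NHS})C(CS(=O)CCC(=O){_NHS})O1",
     "enrichable"),
    ("DSSO", f"O=C(CCS(=O)CCC(=O){_NHS}){_NHS}", "permeable"),
    ("DSS", f"O=C(CCCCCCC(=O){_NHS}){_NHS}", "permeable"),
    ("BS3", f"O=C(CCCCCCC(=O){_SULFO_NHS}){_SULFO_NHS}", "other"),
    ("DSG", f"O=C(CCCC(=O){_NHS}){_NHS}", "permeable"),
    ("DSA", f"O=C(CCCCC(=O){_NHS}){_NHS}", "permeable"),
    ("DSBU", f"O=C(CCNC(=O)NCCC(=O){_NHS}){_NHS}", "permeable"),
    ("DSP", f"O=C(CCSSCCC(=O){_NHS}){_NHS}", "permeable"),
    ("DTSSP", f"O=C(CCSSCCC(=O){_SULFO_NHS}){_SULFO_NHS}", "other"),
    ("EGS", f"O=C(CCC(=O)OCCOC(=O)CCC(=O){_NHS}){_NHS}", "permeable"),
    ("DST", f"O=C(C(O)C(O)C(=O){_NHS}){_NHS}", "other"),
    ("sulfo-SDA", f"CC1(CCC(=O){_SULFO_NHS})N=N1", "other"),
    ("SDA", f"CC1(CCC(=O){_NHS})N=N1", "permeable"),
    ("SMCC", f"O=C(C1CCC(CN2C(=O)C=CC2=O)CC1){_NHS}", "permeable"),
    ("PhoX", f"O=C(c1cc(C(=O){_NHS})cc(P(=O)(O)O)c1){_NHS}", "enrichable"),
    ("t-BuPhoX",
     f"O=C(c1cc(C(=O){_NHS})cc(P(=O)(OC(C)(C)C)OC(C)(C)C)c1){_NHS}",
     "enrichable"),
    ("CDI", "O=C(n1ccnc1)n1ccnc1", "permeable"),
    ("DMA", "COC(=N)CCCCC(=N)OC", "permeable"),
    ("DMS", "COC(=N)CCCCCCC(=N)OC", "permeable"),
    ("ADH", "NNC(=O)CCCCC(=O)NN", "other"),
    ("DFDNB",
     "Fc1cc(F)c(cc1[N+](=O)[O-])[N+](=O)[O-]", "permeable"),
    ("glutaraldehyde", "O=CCCCC=O", "permeable"),
)


def builtin_panel() -> list[tuple[str, str, str]]:
    return list(CROSSLINKER_PANEL)


def landscape_table(
    compounds: list[tuple[str, str, str]] | None = None,
    include_sp: bool = False,
    csv_path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Compute the cLogP/tPSA table (and optionally the scatter plot).

    Rows keep input order; duplicate names are disambiguated with ``_2``,
    ``_3``...  Unparseable SMILES are listed in the ``error`` column while
    valid compounds are still emitted.
    """
    compounds = builtin_panel() if compounds is None else list(compounds)
    if not compounds:
        raise ValueError("landscape_table needs at least one compound")
    seen: dict[str, int] = {}
    rows = []
    for name, smiles, compound_class in compounds:
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}_{seen[name]}"
        try:
            clogp, tpsa = compute_properties(smiles, include_sp=include_sp)
            rows.append(
                {"name": name, "class": compound_class, "smiles": smiles,
                 "clogp": clogp, "tpsa": tpsa, "error": ""}
            )
        except ValueError as exc:
            rows.append(
                {"name": name, "class": compound_class, "smiles": smiles,
                 "clogp": float("nan"), "tpsa": float("nan"), "error": str(exc)}
            )
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False, float_format="%.4f")
    if plot_path is not None:
        _plot_landscape(table, plot_path)
    return table


def _plot_landscape(table: pd.DataFrame, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"enrichable": "tab:orange", "permeable": "tab:blue",
              "other": "tab:gray"}
    fig, ax = plt.subplots(figsize=(7, 5))
    valid = table[table["error"] == ""]
    for compound_class, group in valid.groupby("class"):
        ax.scatter(
            group["tpsa"], group["clogp"],
            label=compound_class, color=colors.get(compound_class, "k"), s=40,
        )
        for _, row in group.iterrows():
            ax.annotate(row["name"], (row["tpsa"], row["clogp"]),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("tPSA (Å$^2$)")
    ax.set_ylabel("cLogP")
    ax.set_title("Crosslinker permeability landscape")
    ax.legend()
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
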