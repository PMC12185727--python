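"""Shared fixtures: linkers, the single-peptide worked example, tiny datasets."""

import pytest

from xlstub.digestion import CandidateLink, PeptideSpec, ProteinRecord
from xlstub.linkers import builtin

#: The synthetic test peptide with a defined crosslink site at K7
#: (N-terminally acetylated; the lysine is the only internal link site).
SINGLE_PEPTIDE_SEQ = "WGGGGRKSSAAR"


@pytest.fixture(scope="session")
def dispaso():
    return builtin("DiSPASO")


@pytest.fixture(scope="session")
def dsbso():
    return builtin("DSBSO")


@pytest.fixture(scope="session")
def dsso():
    return builtin("DSSO")


@pytest.fixture(scope="session")
def single_peptide_protein():
    return ProteinRecord(
        accession="XLPEP1",
        description="XLPEP1 synthetic single-peptide standard",
        sequence=SINGLE_PEPTIDE_SEQ,
    )


@pytest.fixture(scope="session")
def kssaar_selflink(single_peptide_protein, dispaso):
    """The K7 x K7 self-crosslink of two KSSAAR tryptic peptides."""
    pep = PeptideSpec(
        sequence="KSSAAR",
        accession=single_peptide_protein.accession,
        start=7,
        missed_cleavages=1,
        protein_cterm=True,
    )
    return CandidateLink("crosslink", pep, pep, 1, 1, dispaso.name)
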