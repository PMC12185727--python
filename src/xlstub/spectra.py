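"""Centroided MS2 spectra: MGF read/write, optional mzML read, mass conversion.

MGF is the required interchange format and is written deterministically
(m/z to 6 decimals, intensity to 2) so that a seeded simulation produces
byte-identical files.  Parsing delegates to :mod:`pyteomics`; the contract
checks (missing PEPMASS, unparseable peak lines) are enforced on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf

from .chem import PROTON_MASS

__all__ = [
    "Peak",
    "MS2Spectrum",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "neutral_mass",
    "mass_to_mz",
]

#: Peaks closer than this (Th) are considered duplicates and summed.
MZ_DEDUP_TOL = 1e-6


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class MS2Spectrum:
    """One centroided MS2 spectrum with peaks sorted strictly ascending in m/z."""

    spectrum_id: str
    scan: int
    precursor_mz: float
    precursor_charge: int
    peaks: list[Peak] = field(default_factory=list)
    nce: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        self.peaks = _dedup_sort(self.peaks)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_mass(self.precursor_mz, self.precursor_charge)

    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


def _dedup_sort(peaks: list[Peak]) -> list[Peak]:
    """Sort by m/z and sum duplicates within ``MZ_DEDUP_TOL``."""
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p.mz)
    out = [ordered[0]]
    for peak in ordered[1:]:
        if peak.mz - out[-1].mz < MZ_DEDUP_TOL:
            out[-1] = Peak(out[-1].mz, out[-1].intensity + peak.intensity)
        else:
            out.append(peak)
    return out


# ---------------------------------------------------------------------------
# m/z <-> neutral mass


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass (Da) of an ion at ``mz`` with ``charge`` protons."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * PROTON_MASS


def mass_to_mz(mass: float, charge: int) -> float:
    """m/z (Th) of a neutral mass carrying ``charge`` protons."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# MGF

_NCE_TOKEN = "NCE="


def read_mgf(path) -> list[MS2Spectrum]:
    """Read an MGF file into spectra, in file order.

    PEPMASS is required per block (rejected with the 1-based block index
    otherwise); peak intensity defaults to 1.0; ``CHARGE=3+`` and
    ``CHARGE=3-`` signs are handled; an NCE token embedded in TITLE is
    recovered.  An empty peak list yields a spectrum with zero peaks.
    """
    spectra: list[MS2Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for block_index, entry in enumerate(reader, start=1):
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: MGF block {block_index} lacks PEPMASS")
            pepmass = float(params["pepmass"][0])
            charge_list = params.get("charge")
            charge = abs(int(charge_list[0])) if charge_list else 2
            title = str(params.get("title", f"spectrum_{block_index}"))
            scan = int(params.get("scans", block_index))
            nce = None
            for token in title.replace(",", " ").split():
                if token.upper().startswith(_NCE_TOKEN):
                    nce = float(token[len(_NCE_TOKEN):])
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            if inten.size == 0 and mz.size > 0:
                inten = np.ones_like(mz)
            peaks = [Peak(float(m), float(i)) for m, i in zip(mz, inten, strict=True)]
            spectra.append(
                MS2Spectrum(
                    spectrum_id=title,
                    scan=scan,
                    precursor_mz=pepmass,
                    precursor_charge=charge,
                    peaks=peaks,
                    nce=nce,
                )
            )
    return spectra


def write_mgf(spectra: list[MS2Spectrum], path) -> None:
    """Write spectra as MGF with deterministic field order and precision.

    Round-trips through :func:`read_mgf` at m/z 1e-6 / intensity 1e-2
    precision; the NCE is embedded as a ``NCE=`` token in TITLE.
    """
    with open(path, "w") as handle:
        for spec in spectra:
            title = spec.spectrum_id
            if spec.nce is not None and _NCE_TOKEN not in title:
                title = f"{title} {_NCE_TOKEN}{spec.nce:g}"
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={title}\n")
            handle.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            handle.write(f"CHARGE={spec.precursor_charge}+\n")
            handle.write(f"SCANS={spec.scan}\n")
            for peak in spec.peaks:
                handle.write(f"{peak.mz:.6f} {peak.intensity:.2f}\n")
            handle.write("END IONS\n")


# ---------------------------------------------------------------------------
# mzML (optional, read-only)


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values)."""
    import base64
    import struct
    import zlib

    kind = None
    is_64bit = True
    compressed = False
    for cv in array_element.iter(f"{_MZML_NS}cvParam"):
        accession = cv.get("accession")
        if accession == _ACC_MZ_ARRAY:
            kind = "mz"
        elif accession == _ACC_INTENSITY_ARRAY:
            kind = "intensity"
        elif accession == _ACC_32BIT:
            is_64bit = False
        elif accession == _ACC_ZLIB:
            compressed = True
    binary = array_element.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    fmt = "d" if is_64bit else "f"
    count = len(raw) // struct.calcsize(fmt)
    values = np.array(struct.unpack(f"<{count}{fmt}", raw))
    return kind, values


def read_mzml(path) -> list[MS2Spectrum]:
    """Read MS2 spectra from an mzML file behind the same contract as MGF.

    A focused lxml-based reader (64/32-bit float arrays, optional zlib
    compression); only level-2 spectra with a selected precursor ion are
    returned.
    """
    from lxml import etree

    spectra: list[MS2Spectrum] = []
    tree = etree.parse(str(path))
    for index, element in enumerate(
        tree.iter(f"{_MZML_NS}spectrum"), start=1
    ):
        params = {
            cv.get("accession"): cv.get("value")
            for cv in element.findall(f"{_MZML_NS}cvParam")
        }
        if params.get(_ACC_MS_LEVEL) != "2":
            continue
        mz0 = None
        charge = 2
        for cv in element.iter(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == _ACC_SELECTED_MZ:
                mz0 = float(cv.get("value"))
            elif cv.get("accession") == _ACC_CHARGE:
                charge = int(cv.get("value"))
        if mz0 is None:
            continue
        mz_array = np.array([])
        intensity_array = np.array([])
        for array_element in element.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(array_element)
            if kind == "mz":
                mz_array = values
            elif kind == "intensity":
                intensity_array = values
        peaks = [
            Peak(float(m), float(i))
            for m, i in zip(mz_array, intensity_array, strict=True)
            if i > 0
        ]
        spectra.append(
            MS2Spectrum(
                spectrum_id=element.get("id", f"scan={index}"),
                scan=index,
                precursor_mz=mz0,
                precursor_charge=charge,
                peaks=peaks,
            )
        )
    return spectra
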