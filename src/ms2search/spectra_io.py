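"""Reading, harmonizing, cleaning and filtering of MS2 fragmentation spectra.

Supported input formats are MGF (``BEGIN IONS``/``END IONS`` blocks), MSP
(``Name:`` / ``Num Peaks:`` records) and mzML (MS level-2 scans).  Metadata
keys are lower-cased and harmonized on read, so downstream code only ever
sees ``precursor_mz``, ``ionmode``, ``smiles``, ``inchi``, ``inchikey`` and
``compound_name``.
"""

from __future__ import annotations

import base64
import csv
import logging
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence
import xml.etree.ElementTree as ElementTree

import numpy as np

logger = logging.getLogger(__name__)

#: Peaks above this m/z are discarded during cleaning.
MAX_FRAGMENT_MZ = 1000.0
#: Normalized intensities strictly below this fraction of the base peak are discarded.
MIN_RELATIVE_INTENSITY = 0.001
#: At most this many peaks are kept (highest intensities win, lower m/z breaks ties).
MAX_PEAKS = 500
#: Spectra with fewer peaks than this after cleaning are rejected.
MIN_PEAKS = 3

#: Sentinel returned by :func:`clean_peaks` for spectra that fail cleaning.
REJECTED = None

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

# metadata key aliases -> canonical key
_KEY_ALIASES = {
    "pepmass": "precursor_mz",
    "precursormz": "precursor_mz",
    "precursor_mz": "precursor_mz",
    "precursor m/z": "precursor_mz",
    "precursormass": "precursor_mz",
    "parentmass": "precursor_mz",
    "ionmode": "ionmode",
    "ion_mode": "ionmode",
    "ion mode": "ionmode",
    "name": "compound_name",
    "compound_name": "compound_name",
    "compoundname": "compound_name",
    "title": "compound_name",
    "smiles": "smiles",
    "inchi": "inchi",
    "inchikey": "inchikey",
    "inchi_key": "inchikey",
    "inchiaux": "inchikey",
}


@dataclass(frozen=True)
class Spectrum:
    """A single MS2 fragmentation spectrum.

    Peaks are kept as two aligned float arrays sorted by ascending m/z.
    ``metadata`` holds every harmonized key/value pair that is not lifted
    into a dedicated field.
    """

    spectrum_id: str
    mz: np.ndarray
    intensities: np.ndarray
    precursor_mz: Optional[float] = None
    ionmode: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=np.float64)
        intensities = np.asarray(self.intensities, dtype=np.float64)
        if mz.shape != intensities.shape or mz.ndim != 1:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: mz and intensities must be "
                f"aligned 1-D arrays, got {mz.shape} vs {intensities.shape}"
            )
        if np.any(intensities < 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: negative intensity")
        if self.precursor_mz is not None and not self.precursor_mz > 0:
            raise ValueError(f"spectrum {self.spectrum_id!r}: precursor_mz must be > 0")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        intensities = intensities[order]
        # merge duplicate m/z values so the strictly-increasing invariant holds
        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, intensities)
            mz, intensities = uniq, summed
        mz.flags.writeable = False
        intensities.flags.writeable = False
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", intensities)
        if self.ionmode not in ("positive", "negative", "unknown"):
            object.__setattr__(self, "ionmode", "unknown")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def smiles(self) -> Optional[str]:
        return self.metadata.get("smiles")

    @property
    def inchi(self) -> Optional[str]:
        return self.metadata.get("inchi")

    @property
    def inchikey(self) -> Optional[str]:
        return self.metadata.get("inchikey")

    def with_peaks(self, mz: np.ndarray, intensities: np.ndarray) -> "Spectrum":
        return replace(self, mz=np.array(mz), intensities=np.array(intensities))


#: Alias for spectra that passed :func:`clean_peaks`; same runtime type.
CleanedSpectrum = Spectrum


def _canonical_ionmode(value: Optional[str]) -> str:
    if not value:
        return "unknown"
    value = value.strip().lower()
    if value.startswith("p") or value == "+":
        return "positive"
    if value.startswith("n") or value == "-":
        return "negative"
    return "unknown"


def _harmonize_metadata(raw: dict) -> dict:
    out = {}
    for key, value in raw.items():
        key = key.strip().lower()
        out[_KEY_ALIASES.get(key, key)] = value
    return out


def _build_spectrum(raw_meta: dict, mz: list, intensities: list,
                    default_id: str) -> Optional[Spectrum]:
    if not mz:
        return None
    meta = _harmonize_metadata(raw_meta)
    precursor = meta.pop("precursor_mz", None)
    if precursor is not None:
        # MGF PEPMASS may carry "mz intensity"
        precursor = float(str(precursor).split()[0])
    ionmode = _canonical_ionmode(meta.pop("ionmode", None))
    if ionmode == "unknown" and "charge" in meta:
        charge = str(meta["charge"]).strip()
        if charge.endswith("+"):
            ionmode = "positive"
        elif charge.endswith("-"):
            ionmode = "negative"
    spectrum_id = str(meta.pop("spectrum_id", meta.get("spectrumid", default_id)))
    return Spectrum(
        spectrum_id=spectrum_id,
        mz=np.array(mz, dtype=np.float64),
        intensities=np.array(intensities, dtype=np.float64),
        precursor_mz=precursor,
        ionmode=ionmode,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def _parse_mgf(path: Path) -> list[Spectrum]:
    spectra = []
    meta: dict = {}
    mz: list = []
    intens: list = []
    in_block = False
    index = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                in_block, meta, mz, intens = True, {}, [], []
            elif line.upper() == "END IONS":
                spectrum = _build_spectrum(meta, mz, intens, f"spectrum_{index}")
                if spectrum is None:
                    logger.warning("skipping MGF record %d in %s: no peaks", index, path)
                else:
                    spectra.append(spectrum)
                index += 1
                in_block = False
            elif in_block:
                parts = line.split()
                try:
                    value = float(parts[0])
                    is_peak = True
                except ValueError:
                    is_peak = False
                if is_peak:
                    mz.append(value)
                    intens.append(float(parts[1]) if len(parts) > 1 else 1.0)
                elif "=" in line:
                    key, _, value = line.partition("=")
                    meta[key] = value.strip()
    return spectra


def _parse_msp(path: Path) -> list[Spectrum]:
    spectra = []
    meta: dict = {}
    mz: list = []
    intens: list = []
    index = 0

    def flush():
        nonlocal meta, mz, intens, index
        if meta or mz:
            spectrum = _build_spectrum(meta, mz, intens, f"spectrum_{index}")
            if spectrum is None:
                logger.warning("skipping MSP record %d in %s: no peaks", index, path)
            else:
                spectra.append(spectrum)
            index += 1
        meta, mz, intens = {}, [], []

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.lower().startswith("name:") and (meta or mz):
                flush()
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                if key.strip().lower() in ("num peaks", "numpeaks", "num_peaks"):
                    continue
                meta[key] = value.strip()
            else:
                # peak lines; tolerate "mz int; mz int;" style
                parts = line.replace(";", " ").split()
                for i in range(0, len(parts) - 1, 2):
                    mz.append(float(parts[i]))
                    intens.append(float(parts[i + 1]))
    flush()
    return spectra


def _decode_mzml_array(element, ns: str) -> Optional[np.ndarray]:
    dtype = np.float64
    compressed = False
    kind = None
    text = None
    for cv in element.iter(f"{ns}cvParam"):
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = np.float32
        elif name == "64-bit float":
            dtype = np.float64
        elif name == "zlib compression":
            compressed = True
        elif name == "m/z array":
            kind = "mz"
        elif name == "intensity array":
            kind = "intensity"
    binary = element.find(f"{ns}binary")
    if binary is not None and binary.text:
        text = binary.text
    if kind is None:
        return None
    if not text:
        return kind, np.array([], dtype=np.float64)
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_mzml(path: Path) -> list[Spectrum]:
    tree = ElementTree.parse(path)
    root = tree.getroot()
    ns = root.tag[: root.tag.index("}") + 1] if root.tag.startswith("{") else ""
    spectra = []
    index = 0
    for spec_el in root.iter(f"{ns}spectrum"):
        ms_level = None
        ionmode = "unknown"
        for cv in spec_el.findall(f"{ns}cvParam"):
            name = cv.get("name", "")
            if name == "ms level":
                ms_level = int(cv.get("value", "0"))
            elif name == "positive scan":
                ionmode = "positive"
            elif name == "negative scan":
                ionmode = "negative"
        if ms_level != 2:
            continue
        precursor = None
        for cv in spec_el.iter(f"{ns}cvParam"):
            if cv.get("name") == "selected ion m/z":
                precursor = float(cv.get("value"))
        arrays = {}
        for arr_el in spec_el.iter(f"{ns}binaryDataArray"):
            decoded = _decode_mzml_array(arr_el, ns)
            if decoded is not None:
                arrays[decoded[0]] = decoded[1]
        mz = arrays.get("mz")
        intensities = arrays.get("intensity")
        if mz is None or mz.size == 0:
            logger.warning("skipping mzML spectrum %d in %s: no peaks", index, path)
            index += 1
            continue
        spectra.append(
            Spectrum(
                spectrum_id=spec_el.get("id", f"spectrum_{index}"),
                mz=mz,
                intensities=intensities,
                precursor_mz=precursor,
                ionmode=ionmode,
                metadata={},
            )
        )
        index += 1
    return spectra


def read_spectra(path, format: str = "auto") -> list[Spectrum]:
    """Read MS2 spectra from an MGF, MSP or mzML file.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"mgf", "msp", "mzml", "auto"}
        File format; ``auto`` dispatches on the file extension.

    Returns
    -------
    list of Spectrum
        One spectrum per record, peaks sorted by ascending m/z.  Records
        without peaks are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = {"mgf": "mgf", "msp": "msp", "mzml": "mzml"}.get(
            path.suffix.lower().lstrip("."), ""
        )
        if not format:
            raise ValueError(f"cannot infer format from extension of {path}")
    if format == "mgf":
        return _parse_mgf(path)
    if format == "msp":
        return _parse_msp(path)
    if format == "mzml":
        return _parse_mzml(path)
    raise ValueError(f"unknown format {format!r}")


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra to an MGF file (one BEGIN IONS/END IONS block each)."""
    with open(path, "w") as handle:
        for s in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"SPECTRUM_ID={s.spectrum_id}\n")
            if s.precursor_mz is not None:
                handle.write(f"PEPMASS={float(s.precursor_mz)!r}\n")
            if s.ionmode != "unknown":
                handle.write(f"IONMODE={s.ionmode}\n")
            for key, value in s.metadata.items():
                handle.write(f"{key.upper()}={value}\n")
            for mz, inten in zip(s.mz, s.intensities):
                handle.write(f"{float(mz)!r} {float(inten)!r}\n")
            handle.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def clean_peaks(s: Spectrum):
    """Apply the peak-cleaning rules; return a cleaned spectrum or ``REJECTED``.

    Steps, in this fixed order:

    1. remove peaks with m/z above 1000 Da;
    2. normalize intensities to the (remaining) base peak;
    3. remove peaks with normalized intensity strictly below 0.001
       (exactly 0.001 is kept);
    4. if more than 500 peaks remain, keep the 500 highest-intensity peaks
       (ties broken in favour of lower m/z);
    5. reject if fewer than 3 peaks remain.
    """
    if s.n_peaks == 0:
        raise ValueError(f"spectrum {s.spectrum_id!r} has no peaks")
    mask = s.mz <= MAX_FRAGMENT_MZ
    mz, intensities = s.mz[mask], s.intensities[mask]
    if mz.size == 0 or intensities.max() <= 0:
        return REJECTED
    intensities = intensities / intensities.max()
    keep = intensities >= MIN_RELATIVE_INTENSITY
    mz, intensities = mz[keep], intensities[keep]
    if mz.size > MAX_PEAKS:
        order = np.lexsort((mz, -intensities))[:MAX_PEAKS]
        mz, intensities = mz[order], intensities[order]
        order = np.argsort(mz, kind="stable")
        mz, intensities = mz[order], intensities[order]
    if mz.size < MIN_PEAKS:
        return REJECTED
    return s.with_peaks(mz, intensities)


def clean_spectra(spectra: Iterable[Spectrum]):
    """Clean a batch; return ``(cleaned, rejected)`` where *rejected* is a
    list of ``(spectrum_id, reason)`` pairs."""
    cleaned, rejected = [], []
    for s in spectra:
        if s.n_peaks == 0:
            rejected.append((s.spectrum_id, "no peaks"))
            continue
        result = clean_peaks(s)
        if result is REJECTED:
            rejected.append((s.spectrum_id, f"fewer than {MIN_PEAKS} peaks after cleaning"))
        else:
            cleaned.append(result)
    return cleaned, rejected


def write_rejected_csv(rejected: Sequence[tuple], path) -> None:
    """Write the rejected-spectrum report (spectrum_id, reason)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["spectrum_id", "reason"])
        writer.writerows(rejected)


def is_fully_annotated(s: Spectrum) -> bool:
    """True iff the spectrum carries a parseable SMILES, InChI and InChIKey.

    The SMILES must yield a fingerprint, the InChIKey must match the
    14-10-1 block pattern, and the InChI must start with ``InChI=``.
    """
    if not (s.smiles and s.inchi and s.inchikey):
        return False
    if not _INCHIKEY_RE.match(s.inchikey.strip().upper()):
        return False
    if not s.inchi.strip().startswith("InChI="):
        return False
    from ms2search.chem import compute_fingerprint, FingerprintError

    try:
        compute_fingerprint(s.smiles)
    except FingerprintError:
        return False
    return True


def partition_by_ionmode(spectra: Sequence[Spectrum]):
    """Split spectra into (positive, negative, dropped-with-unknown-mode)."""
    positive, negative, dropped = [], [], []
    for s in spectra:
        if s.ionmode == "positive":
            positive.append(s)
        elif s.ionmode == "negative":
            negative.append(s)
        else:
            dropped.append(s)
    return positive, negative, dropped
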