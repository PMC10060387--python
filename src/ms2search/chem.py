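"""Chemical-structure handling.

Library spectra are collapsed to unique 2D structures keyed on the first 14
characters of the InChIKey.  Each structure carries a 2048-bit path-based
(Daylight-type) fingerprint from which pairwise Tanimoto similarities and
the per-structure table of top-k chemically related structures are derived.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

FINGERPRINT_BITS = 2048
TOP_RELATED = 10


class FingerprintError(ValueError):
    """Raised when a SMILES cannot be parsed into a fingerprint."""


@dataclass(frozen=True)
class StructureRecord:
    """A unique 2D structure and the library spectra that share it."""

    inchikey14: str
    representative_smiles: str
    representative_inchi: str
    fingerprint: np.ndarray  # bool, length FINGERPRINT_BITS
    spectrum_ids: tuple

    def __post_init__(self):
        if len(self.inchikey14) != 14:
            raise ValueError(f"inchikey14 must have 14 characters: {self.inchikey14!r}")
        fp = np.asarray(self.fingerprint, dtype=bool)
        if fp.shape != (FINGERPRINT_BITS,):
            raise ValueError(f"fingerprint must have {FINGERPRINT_BITS} bits")
        if not self.spectrum_ids:
            raise ValueError("spectrum_ids must be non-empty")
        fp.flags.writeable = False
        object.__setattr__(self, "fingerprint", fp)
        object.__setattr__(self, "spectrum_ids", tuple(self.spectrum_ids))


@dataclass(frozen=True)
class RelatedStructures:
    """Up to k most chemically similar library structures, best first."""

    inchikey14: str
    neighbours: tuple  # of (inchikey14, tanimoto), descending tanimoto

    def __post_init__(self):
        object.__setattr__(self, "neighbours", tuple(self.neighbours))
        scores = [t for _, t in self.neighbours]
        if any(not 0.0 <= t <= 1.0 for t in scores):
            raise ValueError("tanimoto values must lie in [0, 1]")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(scores, scores[1:])):
            raise ValueError("neighbours must be sorted by descending tanimoto")
        keys = [k for k, _ in self.neighbours]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate neighbour inchikey14")


def inchikey14(inchikey: str) -> str:
    """First 14 characters of an InChIKey, upper-cased (the 2D-structure block)."""
    if len(inchikey) < 14:
        raise ValueError(f"InChIKey too short: {inchikey!r}")
    return inchikey[:14].upper()


@lru_cache(maxsize=100_000)
def _fingerprint_cached(smiles: str) -> bytes:
    mol = Chem.MolFromSmiles(smiles)  # sanitizes by default
    if mol is None:
        raise FingerprintError(f"cannot parse SMILES {smiles!r}")
    bitvect = Chem.RDKFingerprint(mol, fpSize=FINGERPRINT_BITS)
    return np.array(bitvect, dtype=bool).tobytes()


def compute_fingerprint(smiles: str) -> np.ndarray:
    """2048-bit path-based fingerprint of a (sanitized) SMILES.

    Raises :class:`FingerprintError` naming the input when the SMILES does
    not parse.
    """
    return np.frombuffer(_fingerprint_cached(smiles), dtype=bool).copy()


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def fingerprint_matrix(structures: Sequence[StructureRecord]) -> np.ndarray:
    return np.stack([s.fingerprint for s in structures]).astype(np.float64)


def tanimoto_matrix(structures: Sequence[StructureRecord]) -> np.ndarray:
    """Symmetric matrix of pairwise Tanimoto scores between structures."""
    if len(structures) == 0:
        raise ValueError("need at least one structure")
    fp = fingerprint_matrix(structures)
    inter = fp @ fp.T
    pop = fp.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return matrix


def select_representative_structure(spectra) -> tuple:
    """Pick the (smiles, inchi) of the modal InChI among spectra sharing a
    2D structure; ties go to the first-encountered InChI in library order."""
    if not spectra:
        raise ValueError("empty spectrum group")
    counts: dict = {}
    first_spectrum: dict = {}
    for s in spectra:
        key = s.inchi
        counts[key] = counts.get(key, 0) + 1
        first_spectrum.setdefault(key, s)
    # max() returns the first key attaining the maximum in insertion order,
    # which implements the documented first-encountered tie-break
    best = max(counts, key=counts.get)
    chosen = first_spectrum[best]
    return chosen.smiles, chosen.inchi


def collapse_structures(
    spectra,
    fingerprint_overrides: Optional[dict] = None,
) -> list[StructureRecord]:
    """Group annotated spectra by inchikey14 into StructureRecords.

    ``fingerprint_overrides`` maps inchikey14 -> precomputed bit vector and
    bypasses SMILES-based fingerprinting (used by the synthetic generator,
    whose ground-truth fingerprints are not derivable from its surrogate
    SMILES).
    """
    groups: dict = {}
    for s in spectra:
        if not s.inchikey:
            raise ValueError(f"spectrum {s.spectrum_id!r} lacks an InChIKey")
        groups.setdefault(inchikey14(s.inchikey), []).append(s)
    records = []
    for key in sorted(groups):
        members = groups[key]
        smiles, inchi = select_representative_structure(members)
        if fingerprint_overrides is not None and key in fingerprint_overrides:
            fp = np.asarray(fingerprint_overrides[key], dtype=bool)
        else:
            fp = compute_fingerprint(smiles)
        records.append(
            StructureRecord(
                inchikey14=key,
                representative_smiles=smiles,
                representative_inchi=inchi,
                fingerprint=fp,
                spectrum_ids=tuple(m.spectrum_id for m in members),
            )
        )
    return records


def top_related_structures(
    target: str,
    structures: Sequence[StructureRecord],
    k: int = TOP_RELATED,
    include_self: bool = True,
) -> RelatedStructures:
    """The k structures most similar to *target* by Tanimoto, best first.

    The target itself is eligible by default (it ranks first with score 1.0);
    set ``include_self=False`` to exclude it.  Ties are broken
    lexicographically on inchikey14.
    """
    index = {s.inchikey14: i for i, s in enumerate(structures)}
    if target not in index:
        raise KeyError(f"structure {target!r} not in library")
    target_fp = structures[index[target]].fingerprint
    scored = []
    for s in structures:
        if not include_self and s.inchikey14 == target:
            continue
        scored.append((s.inchikey14, tanimoto(target_fp, s.fingerprint)))
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return RelatedStructures(inchikey14=target, neighbours=tuple(scored[:k]))


def build_related_table(
    structures: Sequence[StructureRecord],
    k: int = TOP_RELATED,
    include_self: bool = True,
) -> list[RelatedStructures]:
    """Precompute :func:`top_related_structures` for every structure.

    Uses the vectorized Tanimoto matrix; equivalent to calling
    :func:`top_related_structures` per structure.
    """
    matrix = tanimoto_matrix(structures)
    keys = np.array([s.inchikey14 for s in structures])
    out = []
    for i, s in enumerate(structures):
        scores = matrix[i]
        order = np.lexsort((keys, -scores))
        neighbours = []
        for j in order:
            if not include_self and j == i:
                continue
            neighbours.append((str(keys[j]), float(scores[j])))
            if len(neighbours) == k:
                break
        out.append(RelatedStructures(inchikey14=s.inchikey14, neighbours=tuple(neighbours)))
    return out


def write_related_csv(related: Sequence[RelatedStructures], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["inchikey14", "neighbour_rank", "neighbour_inchikey14", "tanimoto"])
        for entry in related:
            for rank, (key, score) in enumerate(entry.neighbours, start=1):
                writer.writerow([entry.inchikey14, rank, key, f"{score:.9f}"])
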