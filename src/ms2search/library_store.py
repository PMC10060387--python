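"""On-disk spectral library: metadata in SQLite, embeddings in array files.

A library directory contains::

    library.sqlite            spectra / structures / related_structures tables
    embeddings_primary.bin    one row per spectrum (npy payload)
    embeddings_secondary.bin  one row per spectrum (npy payload)
    manifest.json             model parameters, parameter hash, timestamp

Spectrum rows are sorted by spectrum_id at build time; that row order is the
canonical index shared by the metadata tables and both embedding matrices.
The precursor m/z column is indexed for fast range lookups.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ms2search import chem
from ms2search.chem import RelatedStructures, StructureRecord
from ms2search.embed import EmbeddingModel, embed_spectrum, model_from_params
from ms2search.spectra_io import Spectrum

_SCHEMA = """
CREATE TABLE spectra (
    row INTEGER PRIMARY KEY,
    spectrum_id TEXT UNIQUE NOT NULL,
    precursor_mz REAL NOT NULL,
    inchikey14 TEXT NOT NULL,
    metadata TEXT NOT NULL,
    mz TEXT NOT NULL,
    intensities TEXT NOT NULL
);
CREATE INDEX idx_precursor ON spectra (precursor_mz);
CREATE TABLE structures (
    inchikey14 TEXT PRIMARY KEY,
    representative_smiles TEXT NOT NULL,
    representative_inchi TEXT NOT NULL,
    fingerprint TEXT NOT NULL,
    spectrum_ids TEXT NOT NULL
);
CREATE TABLE related_structures (
    inchikey14 TEXT NOT NULL,
    rank INTEGER NOT NULL,
    neighbour_inchikey14 TEXT NOT NULL,
    tanimoto REAL NOT NULL,
    PRIMARY KEY (inchikey14, rank)
);
"""


def _fingerprint_to_hex(fp: np.ndarray) -> str:
    return np.packbits(np.asarray(fp, dtype=bool)).tobytes().hex()


def _fingerprint_from_hex(hexstr: str, n_bits: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))[:n_bits].astype(bool)


def _params_hash(primary_params: dict, secondary_params: dict) -> str:
    payload = json.dumps([primary_params, secondary_params], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class LibraryStore:
    """A fully built spectral library, in memory, with optional disk form."""

    def __init__(
        self,
        ionmode: str,
        spectra: Sequence[Spectrum],
        embeddings_primary: np.ndarray,
        embeddings_secondary: np.ndarray,
        structures: Sequence[StructureRecord],
        related: Sequence[RelatedStructures],
        manifest: dict,
    ):
        self.ionmode = ionmode
        self.spectra = list(spectra)
        self.embeddings_primary = np.asarray(embeddings_primary, dtype=np.float64)
        self.embeddings_secondary = np.asarray(embeddings_secondary, dtype=np.float64)
        self.structures = list(structures)
        self.related = list(related)
        self.manifest = manifest
        n = len(self.spectra)
        if self.embeddings_primary.shape[0] != n or self.embeddings_secondary.shape[0] != n:
            raise ValueError("one embedding row per spectrum per role is required")
        self._id_to_row = {s.spectrum_id: i for i, s in enumerate(self.spectra)}
        self._structure_by_key = {s.inchikey14: s for s in self.structures}
        self._related_by_key = {r.inchikey14: r for r in self.related}
        self.row_inchikey14 = np.array(
            [chem.inchikey14(s.inchikey) for s in self.spectra]
        )
        self.precursor_mz = np.array([s.precursor_mz for s in self.spectra])
        self.structure_rows = {
            key: np.flatnonzero(self.row_inchikey14 == key)
            for key in self._structure_by_key
        }
        for key in self._structure_by_key:
            if key not in self._related_by_key:
                raise ValueError(f"structure {key} lacks a related-structures entry")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def spectrum_ids(self) -> list:
        return [s.spectrum_id for s in self.spectra]

    @property
    def parameter_hash(self) -> str:
        return self.manifest["parameter_hash"]

    def row_of(self, spectrum_id: str) -> int:
        try:
            return self._id_to_row[spectrum_id]
        except KeyError:
            raise KeyError(f"unknown spectrum_id {spectrum_id!r}") from None

    def get_spectrum(self, spectrum_id: str) -> Spectrum:
        return self.spectra[self.row_of(spectrum_id)]

    def get_precursor_mz(self, spectrum_ids: Sequence[str]) -> list:
        return [float(self.precursor_mz[self.row_of(sid)]) for sid in spectrum_ids]

    def get_metadata(self, spectrum_ids: Sequence[str]) -> list:
        rows = []
        for sid in spectrum_ids:
            s = self.spectra[self.row_of(sid)]
            row = dict(s.metadata)
            row["spectrum_id"] = s.spectrum_id
            row["precursor_mz"] = float(s.precursor_mz)
            row["inchikey14"] = chem.inchikey14(s.inchikey)
            rows.append(row)
        return rows

    def get_structure(self, inchikey14: str) -> StructureRecord:
        try:
            return self._structure_by_key[inchikey14]
        except KeyError:
            raise KeyError(f"unknown inchikey14 {inchikey14!r}") from None

    def get_related(self, inchikey14: str) -> RelatedStructures:
        try:
            return self._related_by_key[inchikey14]
        except KeyError:
            raise KeyError(f"unknown inchikey14 {inchikey14!r}") from None

    # -- models -------------------------------------------------------------

    def primary_model(self) -> EmbeddingModel:
        return model_from_params(self.manifest["primary_model"])

    def secondary_model(self) -> EmbeddingModel:
        return model_from_params(self.manifest["secondary_model"])

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        db_path = directory / "library.sqlite"
        if db_path.exists():
            db_path.unlink()
        conn = sqlite3.connect(db_path)
        try:
            conn.executescript(_SCHEMA)
            for i, s in enumerate(self.spectra):
                conn.execute(
                    "INSERT INTO spectra VALUES (?, ?, ?, ?, ?, ?, ?)",
                    (
                        i,
                        s.spectrum_id,
                        float(s.precursor_mz),
                        chem.inchikey14(s.inchikey),
                        json.dumps(s.metadata, sort_keys=True),
                        json.dumps(list(s.mz)),
                        json.dumps(list(s.intensities)),
                    ),
                )
            for st in self.structures:
                conn.execute(
                    "INSERT INTO structures VALUES (?, ?, ?, ?, ?)",
                    (
                        st.inchikey14,
                        st.representative_smiles,
                        st.representative_inchi,
                        _fingerprint_to_hex(st.fingerprint),
                        json.dumps(list(st.spectrum_ids)),
                    ),
                )
            for rel in self.related:
                for rank, (key, score) in enumerate(rel.neighbours, start=1):
                    conn.execute(
                        "INSERT INTO related_structures VALUES (?, ?, ?, ?)",
                        (rel.inchikey14, rank, key, score),
                    )
            conn.commit()
        finally:
            conn.close()
        for name, matrix in (
            ("embeddings_primary.bin", self.embeddings_primary),
            ("embeddings_secondary.bin", self.embeddings_secondary),
        ):
            with open(directory / name, "wb") as handle:
                np.save(handle, matrix)
        with open(directory / "manifest.json", "w") as handle:
            json.dump(self.manifest, handle, indent=2, sort_keys=True)

    @classmethod
    def open(cls, directory) -> "LibraryStore":
        directory = Path(directory)
        with open(directory / "manifest.json") as handle:
            manifest = json.load(handle)
        conn = sqlite3.connect(directory / "library.sqlite")
        try:
            spectra = []
            for row in conn.execute(
                "SELECT spectrum_id, precursor_mz, metadata, mz, intensities "
                "FROM spectra ORDER BY row"
            ):
                sid, precursor, meta_json, mz_json, int_json = row
                spectra.append(
                    Spectrum(
                        spectrum_id=sid,
                        mz=np.array(json.loads(mz_json)),
                        intensities=np.array(json.loads(int_json)),
                        precursor_mz=precursor,
                        ionmode=manifest["ionmode"],
                        metadata=json.loads(meta_json),
                    )
                )
            structures = []
            for row in conn.execute(
                "SELECT inchikey14, representative_smiles, representative_inchi, "
                "fingerprint, spectrum_ids FROM structures ORDER BY inchikey14"
            ):
                key, smiles, inchi, fp_hex, ids_json = row
                structures.append(
                    StructureRecord(
                        inchikey14=key,
                        representative_smiles=smiles,
                        representative_inchi=inchi,
                        fingerprint=_fingerprint_from_hex(fp_hex, chem.FINGERPRINT_BITS),
                        spectrum_ids=tuple(json.loads(ids_json)),
                    )
                )
            related_raw: dict = {}
            for key, rank, nkey, score in conn.execute(
                "SELECT inchikey14, rank, neighbour_inchikey14, tanimoto "
                "FROM related_structures ORDER BY inchikey14, rank"
            ):
                related_raw.setdefault(key, []).append((nkey, score))
            related = [
                RelatedStructures(inchikey14=key, neighbours=tuple(neigh))
                for key, neigh in related_raw.items()
            ]
        finally:
            conn.close()
        embeddings = {}
        for name in ("embeddings_primary.bin", "embeddings_secondary.bin"):
            with open(directory / name, "rb") as handle:
                embeddings[name] = np.load(handle)
        return cls(
            ionmode=manifest["ionmode"],
            spectra=spectra,
            embeddings_primary=embeddings["embeddings_primary.bin"],
            embeddings_secondary=embeddings["embeddings_secondary.bin"],
            structures=structures,
            related=related,
            manifest=manifest,
        )


def build_library(
    spectra: Sequence[Spectrum],
    primary: EmbeddingModel,
    secondary: EmbeddingModel,
    out_path=None,
    include_self: bool = True,
    fingerprint_overrides: Optional[dict] = None,
    top_related: int = chem.TOP_RELATED,
) -> LibraryStore:
    """Build a library store from cleaned, annotated spectra of one ionmode.

    Spectra are sorted by spectrum_id (the canonical row order), embedded
    once per role, collapsed into unique 2D structures with the modal-InChI
    representative, and the top-``top_related`` related-structure table is
    precomputed.  If *out_path* is given the store is also written to disk.
    """
    if not spectra:
        raise ValueError("cannot build a library from zero spectra")
    ionmodes = {s.ionmode for s in spectra}
    if len(ionmodes) != 1:
        raise ValueError(f"mixed ionmodes in library input: {sorted(ionmodes)}")
    ionmode = ionmodes.pop()
    if ionmode not in ("positive", "negative"):
        raise ValueError(f"library spectra must have a known ionmode, got {ionmode!r}")
    for s in spectra:
        if not (s.smiles and s.inchi and s.inchikey):
            raise ValueError(f"spectrum {s.spectrum_id!r} is not fully annotated")
        if s.precursor_mz is None:
            raise ValueError(f"spectrum {s.spectrum_id!r} lacks a precursor m/z")
    ordered = sorted(spectra, key=lambda s: s.spectrum_id)
    if len({s.spectrum_id for s in ordered}) != len(ordered):
        raise ValueError("duplicate spectrum_ids in library input")

    embeddings_primary = np.stack([embed_spectrum(primary, s) for s in ordered])
    embeddings_secondary = np.stack([embed_spectrum(secondary, s) for s in ordered])
    structures = chem.collapse_structures(ordered, fingerprint_overrides)
    related = chem.build_related_table(structures, k=top_related, include_self=include_self)

    primary_params = primary.to_params()
    secondary_params = secondary.to_params()
    manifest = {
        "ionmode": ionmode,
        "n_spectra": len(ordered),
        "primary_model": primary_params,
        "secondary_model": secondary_params,
        "parameter_hash": _params_hash(primary_params, secondary_params),
        "include_self_in_related": include_self,
        "top_related": top_related,
        "built_at": datetime.now(timezone.utc).isoformat(),
    }
    store = LibraryStore(
        ionmode=ionmode,
        spectra=ordered,
        embeddings_primary=embeddings_primary,
        embeddings_secondary=embeddings_secondary,
        structures=structures,
        related=related,
        manifest=manifest,
    )
    if out_path is not None:
        store.save(out_path)
    return store


# module-level forms of the store accessors (operation-style API)

def get_precursor_mz(store: LibraryStore, spectrum_ids: Sequence[str]) -> list:
    return store.get_precursor_mz(spectrum_ids)


def get_related(store: LibraryStore, inchikey14: str) -> RelatedStructures:
    return store.get_related(inchikey14)


def get_metadata(store: LibraryStore, spectrum_ids: Sequence[str]) -> list:
    return store.get_metadata(spectrum_ids)
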