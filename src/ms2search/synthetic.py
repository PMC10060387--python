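"""Seeded generator of annotated synthetic spectral libraries.

Structures are organized in clusters: each cluster has a random fingerprint
center; members flip a fixed number of random bits, so within-cluster
Tanimoto is high while between-cluster similarity sits near the density
baseline.  Every set fingerprint bit maps deterministically to a fragment
peak, so spectral similarity tracks chemical similarity by construction,
and the precursor mass is a deterministic function of the set bits, so
similar structures get nearby precursor masses.

Records carry surrogate SMILES/InChI/InChIKey annotations so the regular
annotation plumbing works end to end; the generator's ground-truth
fingerprints are meant to be passed to ``build_library`` as
``fingerprint_overrides`` (the surrogate SMILES cannot reproduce them).
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from ms2search.spectra_io import Spectrum, clean_peaks, write_mgf, REJECTED

PROTON_MASS = 1.007


@dataclass(frozen=True)
class SyntheticConfig:
    n_clusters: int = 30
    structures_per_cluster: int = 10
    spectra_per_structure: int = 3
    fp_bits: int = 2048
    fp_density: float = 0.05
    mutation_bits: int = 20
    peak_dropout_prob: float = 0.1
    intensity_jitter_sd: float = 0.2
    noise_peaks_per_spectrum: int = 3
    analogue_holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_clusters", "structures_per_cluster", "spectra_per_structure",
                     "fp_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fp_density", "peak_dropout_prob", "analogue_holdout_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_bits >= self.fp_bits:
            raise ValueError("mutation_bits must be smaller than fp_bits")


@dataclass(frozen=True)
class SyntheticStructure:
    """Ground-truth record for one generated 2D structure."""

    index: int
    cluster: int
    key: str  # 14-char inchikey14-like identifier
    fingerprint: np.ndarray
    mass: float
    smiles: str
    inchi: str
    flipped_bits: tuple  # bits flipped relative to the cluster center

    @property
    def inchikey(self) -> str:
        return f"{self.key}-UHFFFAOYSA-N"

    @property
    def precursor_mz(self) -> float:
        return self.mass + PROTON_MASS


# deterministic per-bit constants (independent of the seed)

def _bit_masses(n_bits: int) -> np.ndarray:
    i = np.arange(n_bits, dtype=np.uint64)
    return 0.5 + ((i * np.uint64(2654435761)) % np.uint64(1000)).astype(float) / 500.0


def _bit_mz(n_bits: int) -> np.ndarray:
    i = np.arange(n_bits, dtype=np.uint64)
    offset = ((i * np.uint64(40503)) % np.uint64(89)).astype(float) / 100.0
    return 50.0 + 0.95 * (np.arange(n_bits) % 950) + offset


def _bit_base_intensity(n_bits: int) -> np.ndarray:
    i = np.arange(n_bits, dtype=np.uint64)
    return 0.1 + 0.9 * ((i * np.uint64(97)) % np.uint64(1000)).astype(float) / 1000.0


@lru_cache(maxsize=None)
def _surrogate_annotation(n_carbons: int) -> tuple:
    """Valid (SMILES, InChI) for a linear alkane; annotation plumbing only."""
    from rdkit import Chem
    from rdkit.Chem import inchi as rd_inchi

    smiles = "C" * n_carbons
    mol = Chem.MolFromSmiles(smiles)
    return smiles, rd_inchi.MolToInchi(mol)


def _random_key(rng: np.random.Generator, taken: set) -> str:
    letters = np.array(list(string.ascii_uppercase))
    while True:
        key = "".join(rng.choice(letters, size=14))
        if key not in taken:
            taken.add(key)
            return key


def generate_structures(cfg: SyntheticConfig) -> list:
    """Clustered synthetic structures with known fingerprints and masses."""
    rng = np.random.default_rng(cfg.seed)
    masses = _bit_masses(cfg.fp_bits)
    taken: set = set()
    structures = []
    index = 0
    for cluster in range(cfg.n_clusters):
        center = rng.random(cfg.fp_bits) < cfg.fp_density
        for _ in range(cfg.structures_per_cluster):
            flips = rng.choice(cfg.fp_bits, size=cfg.mutation_bits, replace=False)
            fp = center.copy()
            fp[flips] = ~fp[flips]
            if not fp.any():
                fp = center.copy()  # degenerate all-zero member: fall back to center
            mass = 100.0 + float(masses[np.flatnonzero(fp)].sum())
            n_carbons = 1 + index % 30
            smiles, inchi = _surrogate_annotation(n_carbons)
            structures.append(
                SyntheticStructure(
                    index=index,
                    cluster=cluster,
                    key=_random_key(rng, taken),
                    fingerprint=fp,
                    mass=mass,
                    smiles=smiles,
                    inchi=inchi,
                    flipped_bits=tuple(int(b) for b in np.sort(flips)),
                )
            )
            index += 1
    return structures


def generate_spectrum(structure: SyntheticStructure, cfg: SyntheticConfig,
                      replicate_index: int) -> Spectrum:
    """One noisy replicate spectrum of a structure; passes clean_peaks.

    Each set fingerprint bit yields a peak at a deterministic m/z with a
    deterministic base intensity; per replicate peaks are dropped with
    ``peak_dropout_prob``, intensities get lognormal jitter, and uniform
    noise peaks are added.
    """
    set_bits = np.flatnonzero(structure.fingerprint)
    if set_bits.size == 0:
        raise ValueError(f"structure {structure.key} has no set fingerprint bits")
    rng = np.random.default_rng([cfg.seed, structure.index, replicate_index])
    mz = _bit_mz(cfg.fp_bits)[set_bits]
    intensities = _bit_base_intensity(cfg.fp_bits)[set_bits]

    keep = rng.random(set_bits.size) >= cfg.peak_dropout_prob
    if keep.sum() < 3:  # keep the 3 strongest so cleaning cannot reject
        keep[np.argsort(intensities)[-3:]] = True
    mz, intensities = mz[keep], intensities[keep]
    if cfg.intensity_jitter_sd > 0:
        intensities = intensities * rng.lognormal(0.0, cfg.intensity_jitter_sd,
                                                  size=intensities.size)
    if cfg.noise_peaks_per_spectrum > 0:
        noise_mz = rng.uniform(50.0, 1000.0, size=cfg.noise_peaks_per_spectrum)
        noise_int = rng.uniform(0.02, 0.3, size=cfg.noise_peaks_per_spectrum) * intensities.max()
        mz = np.concatenate([mz, noise_mz])
        intensities = np.concatenate([intensities, noise_int])

    spectrum = Spectrum(
        spectrum_id=f"{structure.key}_r{replicate_index}",
        mz=mz,
        intensities=intensities,
        precursor_mz=structure.precursor_mz,
        ionmode="positive",
        metadata={
            "smiles": structure.smiles,
            "inchi": structure.inchi,
            "inchikey": structure.inchikey,
            "compound_name": f"synthetic-{structure.index}",
        },
    )
    cleaned = clean_peaks(spectrum)
    assert cleaned is not REJECTED, "synthetic spectra are cleanable by construction"
    return cleaned


def generate_library(cfg: SyntheticConfig):
    """All structures plus ``spectra_per_structure`` replicates of each."""
    structures = generate_structures(cfg)
    spectra = [
        generate_spectrum(s, cfg, r)
        for s in structures
        for r in range(cfg.spectra_per_structure)
    ]
    return spectra, structures


def fingerprint_overrides(structures) -> dict:
    """inchikey14 -> ground-truth fingerprint map for ``build_library``."""
    return {s.key: s.fingerprint for s in structures}


def structure_of_spectrum(structures) -> dict:
    """spectrum-id prefix lookup: inchikey14 -> SyntheticStructure."""
    return {s.key: s for s in structures}


# ---------------------------------------------------------------------------
# benchmark suite on disk
# ---------------------------------------------------------------------------

def generate_benchmark_suite(cfg: SyntheticConfig, out_dir) -> dict:
    """Write a complete synthetic benchmark to *out_dir*.

    Produces an annotated library MGF, a structure-disjoint analogue query
    MGF (held-out structures), a noisy-replicate exact-match query MGF, and
    ground-truth CSVs; returns the file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structures = generate_structures(cfg)
    rng = np.random.default_rng([cfg.seed, 2**31 - 1])

    n_holdout_per_cluster = int(round(cfg.structures_per_cluster * cfg.analogue_holdout_fraction))
    holdout: set = set()
    for cluster in range(cfg.n_clusters):
        members = [s.index for s in structures if s.cluster == cluster]
        if n_holdout_per_cluster and len(members) > n_holdout_per_cluster:
            holdout.update(
                rng.choice(members, size=n_holdout_per_cluster, replace=False).tolist()
            )
    library_structures = [s for s in structures if s.index not in holdout]
    holdout_structures = [s for s in structures if s.index in holdout]

    library_spectra = [
        generate_spectrum(s, cfg, r)
        for s in library_structures
        for r in range(cfg.spectra_per_structure)
    ]
    analogue_queries = [generate_spectrum(s, cfg, 0) for s in holdout_structures]
    # replicate indices beyond spectra_per_structure are fresh noise draws
    exact_queries = [
        generate_spectrum(s, cfg, cfg.spectra_per_structure)
        for s in library_structures
    ]

    paths = {
        "library": out_dir / "library.mgf",
        "analogue_queries": out_dir / "analogue_queries.mgf",
        "exact_queries": out_dir / "exact_queries.mgf",
        "ground_truth_spectra": out_dir / "ground_truth_spectra.csv",
        "ground_truth_structures": out_dir / "ground_truth_structures.csv",
    }
    write_mgf(library_spectra, paths["library"])
    write_mgf(analogue_queries, paths["analogue_queries"])
    write_mgf(exact_queries, paths["exact_queries"])

    with open(paths["ground_truth_spectra"], "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["spectrum_id", "inchikey14", "cluster", "role"])
        for spectra, role in (
            (library_spectra, "library"),
            (analogue_queries, "analogue_query"),
            (exact_queries, "exact_query"),
        ):
            for s in spectra:
                key = s.inchikey[:14]
                struct = next(st for st in structures if st.key == key)
                writer.writerow([s.spectrum_id, key, struct.cluster, role])
    with open(paths["ground_truth_structures"], "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["inchikey14", "cluster", "mass", "fingerprint_hex"])
        for s in structures:
            fp_hex = np.packbits(s.fingerprint).tobytes().hex()
            writer.writerow([s.key, s.cluster, f"{s.mass:.6f}", fp_hex])
    return {name: str(path) for name, path in paths.items()}


def load_ground_truth_structures(path, fp_bits: int = 2048) -> dict:
    """Read the structure ground-truth CSV back into inchikey14 -> fingerprint."""
    out = {}
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            fp = np.unpackbits(
                np.frombuffer(bytes.fromhex(row["fingerprint_hex"]), dtype=np.uint8)
            )[:fp_bits].astype(bool)
            out[row["inchikey14"]] = fp
    return out
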