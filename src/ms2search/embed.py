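"""Spectral-similarity engines.

Two pluggable embedding roles exist: *primary_similarity* (used for whole
library preselection and the related-structure averaging feature) and
*secondary_similarity* (one of the re-ranking features).  Trained neural or
word-embedding models can be dropped in behind the same contract; the
package ships deterministic binned reference embedders so the full pipeline
runs without any model files.

Classic peak-matching baselines (cosine and modified cosine) are also here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ms2search.spectra_io import Spectrum

PRIMARY_ROLE = "primary_similarity"
SECONDARY_ROLE = "secondary_similarity"

DEFAULT_FRAGMENT_TOLERANCE = 0.05  # Da


class EmbeddingModel:
    """Contract for spectrum -> fixed-length-vector models.

    Subclasses must provide ``name``, ``dim``, ``role`` and implement
    :meth:`embed`; ``embed`` must be deterministic and self-similarity of any
    spectrum must be 1.0 within 1e-9.
    """

    name: str
    dim: int
    role: str
    ionmode: Optional[str] = None

    def embed(self, spectrum: Spectrum) -> np.ndarray:
        raise NotImplementedError

    def similarity(self, a: Spectrum, b: Spectrum) -> float:
        return embedding_similarity(self.embed(a), self.embed(b))

    def to_params(self) -> dict:
        raise NotImplementedError

    def _check_ionmode(self, spectrum: Spectrum) -> None:
        if self.ionmode is not None and spectrum.ionmode != self.ionmode:
            raise ValueError(
                f"model {self.name!r} is for {self.ionmode} mode but spectrum "
                f"{spectrum.spectrum_id!r} is {spectrum.ionmode}"
            )


class BinnedEmbedder(EmbeddingModel):
    """Deterministic reference embedder: per-bin summed intensity^power,
    L2-normalized.  Stands in for a trained embedding model."""

    kind = "binned"

    def __init__(
        self,
        bin_width: float = 1.0,
        max_mz: float = 1000.0,
        intensity_power: float = 0.5,
        role: str = PRIMARY_ROLE,
        ionmode: Optional[str] = None,
        name: Optional[str] = None,
    ):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = float(bin_width)
        self.max_mz = float(max_mz)
        self.intensity_power = float(intensity_power)
        self.role = role
        self.ionmode = ionmode
        self.dim = int(math.ceil(self.max_mz / self.bin_width))
        self.name = name or f"binned-{bin_width:g}Da"

    def embed(self, spectrum: Spectrum) -> np.ndarray:
        self._check_ionmode(spectrum)
        bins = np.minimum(
            (spectrum.mz / self.bin_width).astype(np.int64), self.dim - 1
        )
        vector = np.zeros(self.dim, dtype=np.float64)
        np.add.at(vector, bins, spectrum.intensities ** self.intensity_power)
        norm = np.linalg.norm(vector)
        if norm == 0:
            raise ValueError(f"spectrum {spectrum.spectrum_id!r} embeds to zero vector")
        return vector / norm

    def to_params(self) -> dict:
        return {
            "kind": self.kind,
            "name": self.name,
            "role": self.role,
            "bin_width": self.bin_width,
            "max_mz": self.max_mz,
            "intensity_power": self.intensity_power,
            "ionmode": self.ionmode,
        }

    @classmethod
    def from_params(cls, params: dict) -> "BinnedEmbedder":
        params = dict(params)
        params.pop("kind", None)
        return cls(**params)


_MODEL_KINDS = {"binned": BinnedEmbedder}


def model_from_params(params: dict) -> EmbeddingModel:
    kind = params.get("kind")
    if kind not in _MODEL_KINDS:
        raise ValueError(f"unknown embedding model kind {kind!r}")
    return _MODEL_KINDS[kind].from_params(params)


def save_embedding_model(model: EmbeddingModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.json", "w") as handle:
        json.dump(model.to_params(), handle, indent=2)


def load_embedding_model(directory) -> EmbeddingModel:
    with open(Path(directory) / "manifest.json") as handle:
        return model_from_params(json.load(handle))


def reference_binned_embedder(
    bin_width: float = 1.0,
    max_mz: float = 1000.0,
    intensity_power: float = 0.5,
    role: str = PRIMARY_ROLE,
    ionmode: Optional[str] = None,
) -> BinnedEmbedder:
    """Factory for the deterministic reference embedders.

    Defaults: primary role 1.0 Da bins, secondary role 0.1 Da bins.
    """
    return BinnedEmbedder(
        bin_width=bin_width,
        max_mz=max_mz,
        intensity_power=intensity_power,
        role=role,
        ionmode=ionmode,
    )


def default_models(ionmode: Optional[str] = None):
    """The (primary, secondary) reference embedder pair at default settings."""
    primary = reference_binned_embedder(1.0, role=PRIMARY_ROLE, ionmode=ionmode)
    secondary = reference_binned_embedder(0.1, role=SECONDARY_ROLE, ionmode=ionmode)
    return primary, secondary


def embed_spectrum(model: EmbeddingModel, spectrum: Spectrum) -> np.ndarray:
    """Embed one spectrum; deterministic, all entries finite."""
    vector = model.embed(spectrum)
    if not np.all(np.isfinite(vector)):
        raise ValueError(f"non-finite embedding for spectrum {spectrum.spectrum_id!r}")
    return vector


def embedding_similarity(va: np.ndarray, vb: np.ndarray) -> float:
    """Cosine similarity of two embedding vectors, clipped to [-1, 1]."""
    va = np.asarray(va, dtype=np.float64)
    vb = np.asarray(vb, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cannot take cosine similarity with a zero vector")
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# peak-matching similarities
# ---------------------------------------------------------------------------

DIRECT = "direct"
SHIFTED = "precursor-shifted"


@dataclass
class PeakMatchList:
    """Accepted one-to-one peak pairs of a cosine-type score."""

    pairs: list = field(default_factory=list)  # (index_a, index_b, contribution)
    used_shift: list = field(default_factory=list)  # DIRECT or SHIFTED per pair


def _candidate_pairs(sa: Spectrum, sb: Spectrum, tolerance: float,
                     shift: Optional[float]) -> list:
    """All admissible (i, j, contribution, kind) peak pairs.

    A pair admissible both directly and via the precursor shift is counted
    once, as direct.
    """
    candidates = {}
    mza, mzb = sa.mz, sb.mz
    ia, ib = sa.intensities, sb.intensities
    deltas = [(0.0, DIRECT)]
    if shift is not None and shift != 0.0:
        deltas.append((shift, SHIFTED))
    for delta, kind in deltas:
        targets = mza - delta
        lo = np.searchsorted(mzb, targets - tolerance, side="left")
        hi = np.searchsorted(mzb, targets + tolerance, side="right")
        for i in np.flatnonzero(hi > lo):
            for j in range(lo[i], hi[i]):
                if (i, j) not in candidates:  # direct wins over shifted
                    candidates[(i, j)] = (float(ia[i] * ib[j]), kind)
    return [(i, j, contrib, kind) for (i, j), (contrib, kind) in candidates.items()]


def _greedy_score(sa: Spectrum, sb: Spectrum, tolerance: float,
                  shift: Optional[float]):
    pairs = _candidate_pairs(sa, sb, tolerance, shift)
    # descending contribution; index pair breaks ties deterministically
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    used_a: set = set()
    used_b: set = set()
    matches = PeakMatchList()
    total = 0.0
    for i, j, contrib, kind in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.pairs.append((i, j, contrib))
        matches.used_shift.append(kind)
        total += contrib
    norm = float(np.linalg.norm(sa.intensities) * np.linalg.norm(sb.intensities))
    score = total / norm if norm > 0 else 0.0
    return min(score, 1.0), matches


def cosine_greedy(sa: Spectrum, sb: Spectrum,
                  tolerance: float = DEFAULT_FRAGMENT_TOLERANCE):
    """Greedy cosine similarity between two spectra.

    Peak pairs within *tolerance* Da are accepted greedily in order of
    descending intensity product, each peak used at most once; the summed
    products are normalized by the intensity-vector norms.
    """
    return _greedy_score(sa, sb, tolerance, shift=None)


def modified_cosine(sa: Spectrum, sb: Spectrum,
                    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE):
    """Greedy modified cosine: like :func:`cosine_greedy` but peak pairs
    offset by the precursor-mass difference (neutral losses) also match."""
    if sa.precursor_mz is None or sb.precursor_mz is None:
        raise ValueError("modified cosine requires precursor m/z on both spectra")
    shift = sa.precursor_mz - sb.precursor_mz
    return _greedy_score(sa, sb, tolerance, shift=shift)
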