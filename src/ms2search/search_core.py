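"""Core search algorithm: preselection, features, ranker training, scoring.

For a query spectrum the primary-embedding similarity is computed against
every library spectrum (no precursor prefilter), the top-n candidates are
kept, and each candidate is scored by a random forest over five features:

1. secondary-embedding similarity between query and candidate,
2. query precursor m/z,
3. absolute precursor m/z difference,
4. mean, over the candidate structure's (up to) 10 chemically most related
   library structures, of the per-structure mean primary-embedding
   similarity to the query,
5. mean Tanimoto between the candidate structure and those related
   structures.

The forest is trained to predict the Tanimoto similarity between the query
and candidate 2D structures, so its score in [0, 1] reads as predicted
chemical similarity; thresholding it filters unreliable matches.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ms2search import chem
from ms2search.embed import embed_spectrum
from ms2search.library_store import LibraryStore
from ms2search.spectra_io import Spectrum

logger = logging.getLogger(__name__)

DEFAULT_PRESELECT = 2000
DEFAULT_TRAIN_TOP_N = 100
DEFAULT_POOL_FRACTION = 1.0 / 40.0
DEFAULT_N_ESTIMATORS = 250
DEFAULT_MAX_DEPTH = 5
DEFAULT_THRESHOLD = 0.633
EXACT_MATCH_MZ_WINDOW = 1.0  # Da; below this a match counts as exact-match candidate

FEATURE_NAMES = (
    "secondary_similarity",
    "query_precursor_mz",
    "precursor_mz_difference",
    "avg_primary_similarity_related",
    "avg_tanimoto_related",
)

#: how feature 4 aggregates scores over the related structures
F4_VARIANTS = ("mean", "tanimoto_weighted", "per_spectrum_mean")


@dataclass(frozen=True)
class FeatureVector:
    """The five ranker inputs for one query-candidate pair, in fixed order."""

    f1_secondary_similarity: float
    f2_query_precursor_mz: float
    f3_precursor_mz_difference: float
    f4_avg_primary_similarity_related: float
    f5_avg_tanimoto_related: float

    def __post_init__(self):
        if self.f3_precursor_mz_difference < 0:
            raise ValueError("precursor m/z difference must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.f1_secondary_similarity,
                self.f2_query_precursor_mz,
                self.f3_precursor_mz_difference,
                self.f4_avg_primary_similarity_related,
                self.f5_avg_tanimoto_related,
            ]
        )


@dataclass
class RankedMatch:
    query_id: str
    library_spectrum_id: str
    rf_score: float
    features: FeatureVector
    candidate_metadata: dict
    decision: str  # analogue | exact_match_candidate | below_threshold


@dataclass(frozen=True)
class TrainingPair:
    query_spectrum_id: str
    library_spectrum_id: str
    features: FeatureVector
    label: float

    def __post_init__(self):
        if not 0.0 <= self.label <= 1.0:
            raise ValueError("label must be a Tanimoto score in [0, 1]")


class RankerModel:
    """Random-forest re-ranker plus its training manifest."""

    def __init__(self, forest: RandomForestRegressor, manifest: dict):
        self.forest = forest
        self.manifest = manifest

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        return np.clip(self.forest.predict(features), 0.0, 1.0)

    def save(self, path) -> None:
        joblib.dump({"forest": self.forest, "manifest": self.manifest}, path)

    @classmethod
    def load(cls, path) -> "RankerModel":
        payload = joblib.load(path)
        return cls(payload["forest"], payload["manifest"])

    def check_compatible(self, store: LibraryStore) -> None:
        expected = self.manifest.get("library_parameter_hash")
        if expected is not None and expected != store.parameter_hash:
            raise ValueError(
                "ranker was trained against a library with different embedding "
                f"models (hash {expected} != {store.parameter_hash})"
            )


# ---------------------------------------------------------------------------
# per-query similarity context
# ---------------------------------------------------------------------------

@dataclass
class _QueryContext:
    """All per-query quantities shared across candidate feature rows."""

    precursor_mz: float
    sims_primary: np.ndarray  # vs every library row
    sims_secondary: np.ndarray
    f4_by_key: dict
    f5_by_key: dict


def _related_feature_tables(store: LibraryStore, structure_mean: dict,
                            sims_primary: np.ndarray, f4_variant: str):
    """Per-structure f4/f5 values given per-structure mean primary scores."""
    f4_by_key = {}
    f5_by_key = {}
    for structure in store.structures:
        related = store.get_related(structure.inchikey14)
        tans = np.array([t for _, t in related.neighbours])
        if f4_variant == "mean":
            f4 = float(np.mean([structure_mean[k] for k, _ in related.neighbours]))
        elif f4_variant == "tanimoto_weighted":
            means = np.array([structure_mean[k] for k, _ in related.neighbours])
            f4 = float((means * tans).sum() / tans.sum()) if tans.sum() > 0 else float(means.mean())
        elif f4_variant == "per_spectrum_mean":
            rows = np.concatenate(
                [store.structure_rows[k] for k, _ in related.neighbours]
            )
            f4 = float(sims_primary[rows].mean())
        else:
            raise ValueError(f"unknown f4 variant {f4_variant!r}")
        f4_by_key[structure.inchikey14] = f4
        f5_by_key[structure.inchikey14] = float(tans.mean())
    return f4_by_key, f5_by_key


def _make_query_context(
    store: LibraryStore,
    precursor_mz: float,
    sims_primary: np.ndarray,
    sims_secondary: np.ndarray,
    f4_variant: str = "mean",
) -> _QueryContext:
    structure_mean = {
        key: float(sims_primary[rows].mean())
        for key, rows in store.structure_rows.items()
    }
    f4_by_key, f5_by_key = _related_feature_tables(
        store, structure_mean, sims_primary, f4_variant
    )
    return _QueryContext(
        precursor_mz=precursor_mz,
        sims_primary=sims_primary,
        sims_secondary=sims_secondary,
        f4_by_key=f4_by_key,
        f5_by_key=f5_by_key,
    )


def _context_for_spectrum(store: LibraryStore, query: Spectrum,
                          f4_variant: str = "mean") -> _QueryContext:
    if query.precursor_mz is None:
        raise ValueError(f"query {query.spectrum_id!r} lacks a precursor m/z")
    q_primary = embed_spectrum(store.primary_model(), query)
    q_secondary = embed_spectrum(store.secondary_model(), query)
    sims_primary = np.clip(store.embeddings_primary @ q_primary, -1.0, 1.0)
    sims_secondary = np.clip(store.embeddings_secondary @ q_secondary, -1.0, 1.0)
    return _make_query_context(
        store, query.precursor_mz, sims_primary, sims_secondary, f4_variant
    )


def _feature_matrix(store: LibraryStore, ctx: _QueryContext,
                    rows: np.ndarray) -> np.ndarray:
    keys = store.row_inchikey14[rows]
    features = np.empty((rows.size, 5), dtype=np.float64)
    features[:, 0] = ctx.sims_secondary[rows]
    features[:, 1] = ctx.precursor_mz
    features[:, 2] = np.abs(ctx.precursor_mz - store.precursor_mz[rows])
    features[:, 3] = [ctx.f4_by_key[k] for k in keys]
    features[:, 4] = [ctx.f5_by_key[k] for k in keys]
    return features


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def preselect_candidates(query: Spectrum, store: LibraryStore,
                         n: int = DEFAULT_PRESELECT):
    """Top-n library spectra by primary-embedding similarity to the query.

    The similarity is computed against *all* library spectra (no precursor
    prefilter).  Returns ``(spectrum_ids, scores)`` in descending score
    order; ties break on ascending spectrum_id (= row order).
    """
    if store.n_spectra == 0:
        raise ValueError("empty library")
    q_primary = embed_spectrum(store.primary_model(), query)
    sims = np.clip(store.embeddings_primary @ q_primary, -1.0, 1.0)
    order = np.lexsort((np.arange(sims.size), -sims))[:n]
    ids = [store.spectra[i].spectrum_id for i in order]
    return ids, sims[order]


def compute_feature_vector(
    query: Spectrum,
    candidate_id: str,
    store: LibraryStore,
    preselection_scores: Optional[dict] = None,
    f4_variant: str = "mean",
) -> FeatureVector:
    """The five-feature vector for one query-candidate pair.

    ``preselection_scores`` maps spectrum_id -> primary score from
    preselection; scores present there are reused, anything missing is
    filled in from the stored embeddings (embeddings are never recomputed).
    """
    q_primary = embed_spectrum(store.primary_model(), query)
    sims_primary = np.clip(store.embeddings_primary @ q_primary, -1.0, 1.0)
    if preselection_scores:
        for sid, score in preselection_scores.items():
            sims_primary[store.row_of(sid)] = score
    q_secondary = embed_spectrum(store.secondary_model(), query)
    sims_secondary = np.clip(store.embeddings_secondary @ q_secondary, -1.0, 1.0)
    ctx = _make_query_context(
        store, query.precursor_mz, sims_primary, sims_secondary, f4_variant
    )
    row = store.row_of(candidate_id)
    values = _feature_matrix(store, ctx, np.array([row]))[0]
    return FeatureVector(*values)


def generate_training_pairs(
    store: LibraryStore,
    inchikey_fraction: float = DEFAULT_POOL_FRACTION,
    spectrum_fraction: float = DEFAULT_POOL_FRACTION,
    top_n: int = DEFAULT_TRAIN_TOP_N,
    seed: int = 0,
    f4_variant: str = "mean",
) -> list:
    """Seeded training pairs for the ranker.

    The query pool is every spectrum of a random ``ceil(inchikey_fraction *
    n_structures)`` sample of unique structures, plus a random
    ``ceil(spectrum_fraction * n_remaining)`` sample of the remaining
    spectra.  Each pooled spectrum is paired with its ``top_n``
    highest-primary-score library spectra (itself included); the label is
    the Tanimoto score between the two structures.
    """
    rng = np.random.default_rng(seed)
    n_structures = len(store.structures)
    n_pick = math.ceil(n_structures * inchikey_fraction)
    picked = rng.choice(n_structures, size=min(n_pick, n_structures), replace=False)
    pool_rows = set()
    for idx in picked:
        pool_rows.update(store.structure_rows[store.structures[idx].inchikey14].tolist())
    remaining = np.array(sorted(set(range(store.n_spectra)) - pool_rows))
    if remaining.size:
        n_extra = math.ceil(remaining.size * spectrum_fraction)
        extra = rng.choice(remaining.size, size=min(n_extra, remaining.size), replace=False)
        pool_rows.update(remaining[extra].tolist())
    pool_rows = sorted(pool_rows)
    if not pool_rows:
        raise ValueError(
            "training pool is empty; use larger inchikey/spectrum fractions "
            "for this library size"
        )

    tan_matrix = chem.tanimoto_matrix(store.structures)
    struct_index = {s.inchikey14: i for i, s in enumerate(store.structures)}

    pairs = []
    for row in pool_rows:
        query = store.spectra[row]
        sims_primary = np.clip(
            store.embeddings_primary @ store.embeddings_primary[row], -1.0, 1.0
        )
        sims_secondary = np.clip(
            store.embeddings_secondary @ store.embeddings_secondary[row], -1.0, 1.0
        )
        ctx = _make_query_context(
            store, query.precursor_mz, sims_primary, sims_secondary, f4_variant
        )
        top = np.lexsort((np.arange(sims_primary.size), -sims_primary))[:top_n]
        features = _feature_matrix(store, ctx, top)
        qi = struct_index[store.row_inchikey14[row]]
        for k, cand_row in enumerate(top):
            ci = struct_index[store.row_inchikey14[cand_row]]
            pairs.append(
                TrainingPair(
                    query_spectrum_id=query.spectrum_id,
                    library_spectrum_id=store.spectra[cand_row].spectrum_id,
                    features=FeatureVector(*features[k]),
                    label=float(tan_matrix[qi, ci]),
                )
            )
    return pairs


def train_ranker(
    pairs: Sequence[TrainingPair],
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    max_depth: int = DEFAULT_MAX_DEPTH,
    seed: int = 0,
    library_parameter_hash: Optional[str] = None,
    f4_variant: str = "mean",
) -> RankerModel:
    """Fit the random-forest re-ranker (squared-error loss) on feature ->
    Tanimoto-label pairs.  Deterministic given the seed."""
    if len(pairs) < 100:
        raise ValueError(f"need at least 100 training pairs, got {len(pairs)}")
    features = np.stack([p.features.to_array() for p in pairs])
    labels = np.array([p.label for p in pairs])
    bad = np.flatnonzero(~np.isfinite(features).all(axis=1))
    if bad.size:
        p = pairs[bad[0]]
        raise ValueError(
            f"non-finite feature in pair ({p.query_spectrum_id!r}, "
            f"{p.library_spectrum_id!r})"
        )
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        criterion="squared_error",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(features, labels)
    manifest = {
        "feature_names": list(FEATURE_NAMES),
        "n_estimators": n_estimators,
        "max_depth": max_depth,
        "seed": seed,
        "n_pairs": len(pairs),
        "f4_variant": f4_variant,
        "library_parameter_hash": library_parameter_hash,
    }
    return RankerModel(forest, manifest)


def _decision(rf_score: float, f3: float, threshold: float) -> str:
    if rf_score < threshold:
        return "below_threshold"
    return "exact_match_candidate" if f3 < EXACT_MATCH_MZ_WINDOW else "analogue"


def rank_candidates(
    query: Spectrum,
    store: LibraryStore,
    ranker: RankerModel,
    n_preselect: int = DEFAULT_PRESELECT,
    threshold: float = DEFAULT_THRESHOLD,
) -> list:
    """Preselect, score and sort candidates for one query.

    Returns RankedMatch entries sorted by descending rf_score, with ties
    broken by descending preselection score then ascending spectrum_id.
    """
    ranker.check_compatible(store)
    f4_variant = ranker.manifest.get("f4_variant", "mean")
    ctx = _context_for_spectrum(store, query, f4_variant)
    order = np.lexsort((np.arange(store.n_spectra), -ctx.sims_primary))[:n_preselect]
    features = _feature_matrix(store, ctx, order)
    scores = ranker.predict(features)
    rank_order = np.lexsort((order, -ctx.sims_primary[order], -scores))
    matches = []
    for idx in rank_order:
        row = order[idx]
        s = store.spectra[row]
        fv = FeatureVector(*features[idx])
        matches.append(
            RankedMatch(
                query_id=query.spectrum_id,
                library_spectrum_id=s.spectrum_id,
                rf_score=float(scores[idx]),
                features=fv,
                candidate_metadata=store.get_metadata([s.spectrum_id])[0],
                decision=_decision(float(scores[idx]), fv.f3_precursor_mz_difference, threshold),
            )
        )
    return matches


def search(
    queries: Sequence[Spectrum],
    store: LibraryStore,
    ranker: RankerModel,
    threshold: float = DEFAULT_THRESHOLD,
    n_preselect: int = DEFAULT_PRESELECT,
    top_k: int = 1,
) -> list:
    """Search the library; per query return up to top_k matches with
    rf_score >= threshold (usually one best match, or none).

    Per-query failures are logged and the query skipped.
    """
    results = []
    for query in queries:
        try:
            ranked = rank_candidates(query, store, ranker, n_preselect, threshold)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping query %r: %s", query.spectrum_id, exc)
            continue
        for match in ranked[:top_k]:
            if match.rf_score >= threshold:
                results.append(match)
    return results


def write_results_csv(results: Sequence[RankedMatch], path) -> None:
    """Write the result table; rf_scores are formatted to 6 decimal places."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "query_id",
                "query_precursor_mz",
                "rf_score",
                "match_spectrum_id",
                "match_precursor_mz",
                "precursor_mz_difference",
                "smiles",
                "inchikey",
                "compound_name",
                "decision",
            ]
        )
        for match in results:
            meta = match.candidate_metadata
            writer.writerow(
                [
                    match.query_id,
                    f"{match.features.f2_query_precursor_mz:.4f}",
                    f"{match.rf_score:.6f}",
                    match.library_spectrum_id,
                    f"{meta['precursor_mz']:.4f}",
                    f"{match.features.f3_precursor_mz_difference:.4f}",
                    meta.get("smiles", ""),
                    meta.get("inchikey", ""),
                    meta.get("compound_name", ""),
                    match.decision,
                ]
            )
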