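"""Evaluation protocol: disjoint folds, threshold-sweep curves, baselines.

Analogue benchmarks are *structure-disjoint*: unique 2D structures are split
into k groups and no structure occurs in both the library and the queries of
a fold.  Exact-match benchmarks are *spectrum-disjoint*: per test set one
randomly chosen spectrum of every multi-spectrum structure becomes a query
while the rest stay in the library.

Curve semantics per threshold: recall is the fraction of queries with a
returned match; quality is the mean Tanimoto between true and predicted
structures (analogue mode) or the fraction of matches with the correct
inchikey14 (exact-match mode).  Baseline methods get the conventional
precursor prefilters (100 Da for analogue, 0.25 Da for exact-match
searches); the re-ranking search uses none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ms2search import chem
from ms2search.embed import (
    DEFAULT_FRAGMENT_TOLERANCE,
    cosine_greedy,
    default_models,
    embed_spectrum,
    modified_cosine,
)
from ms2search.library_store import LibraryStore, build_library
from ms2search.search_core import (
    RankerModel,
    generate_training_pairs,
    rank_candidates,
    train_ranker,
)
from ms2search.spectra_io import Spectrum

ANALOGUE_PREFILTER_DA = 100.0
EXACT_PREFILTER_DA = 0.25
ANALOGUE_METHODS = ("ms2query", "primary_embedding", "modified_cosine")
EXACT_METHODS = ("ms2query", "primary_embedding", "cosine")


def default_thresholds(n: int = 101) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


@dataclass(frozen=True)
class QueryTruth:
    """Ground truth for one benchmark query spectrum."""

    inchikey14: str
    fingerprint: np.ndarray


@dataclass
class BenchmarkCurve:
    method: str
    points: list  # (threshold, recall, quality); quality is NaN when no matches
    metadata: dict

    def __post_init__(self):
        recalls = [r for _, r, _ in self.points]
        if any(r2 > r1 + 1e-12 for r1, r2 in zip(recalls, recalls[1:])):
            raise ValueError("recall must be non-increasing in threshold")

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=["threshold", "recall", "quality"])
        frame.insert(0, "method", self.method)
        return frame


def quality_at_recall(curve: BenchmarkCurve, target_recall: float) -> float:
    """Quality read off the curve at a target recall via linear interpolation."""
    points = [(r, q) for _, r, q in curve.points if not math.isnan(q)]
    if not points:
        return float("nan")
    points.sort()
    recalls = np.array([r for r, _ in points])
    qualities = np.array([q for _, q in points])
    return float(np.interp(target_recall, recalls, qualities))


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def _spectrum_key(s: Spectrum) -> str:
    return chem.inchikey14(s.inchikey)


def make_analogue_folds(spectra: Sequence[Spectrum], k: int = 20, seed: int = 0):
    """Structure-disjoint k-fold splits: unique 2D structures are divided
    into k equal groups; each group's spectra test exactly once."""
    keys = sorted({_spectrum_key(s) for s in spectra})
    if len(keys) < k:
        raise ValueError(f"need at least {k} unique structures, got {len(keys)}")
    rng = np.random.default_rng(seed)
    shuffled = np.array(keys)[rng.permutation(len(keys))]
    folds = []
    for group in np.array_split(shuffled, k):
        test_keys = set(group.tolist())
        train = [s for s in spectra if _spectrum_key(s) not in test_keys]
        test = [s for s in spectra if _spectrum_key(s) in test_keys]
        assert not ({_spectrum_key(s) for s in train} & {_spectrum_key(s) for s in test})
        folds.append((train, test))
    return folds


def make_exact_match_testsets(spectra: Sequence[Spectrum], k: int = 20, seed: int = 0):
    """k spectrum-disjoint (library, test) splits: per split, one random
    spectrum of every structure with >= 2 spectra goes to the test side."""
    by_key: dict = {}
    for s in spectra:
        by_key.setdefault(_spectrum_key(s), []).append(s)
    multi = {key: group for key, group in by_key.items() if len(group) >= 2}
    if not multi:
        raise ValueError("no structure has two or more spectra")
    splits = []
    for i in range(k):
        rng = np.random.default_rng([seed, i])
        test_ids = set()
        for key in sorted(multi):
            group = multi[key]
            test_ids.add(group[rng.integers(len(group))].spectrum_id)
        library = [s for s in spectra if s.spectrum_id not in test_ids]
        test = [s for s in spectra if s.spectrum_id in test_ids]
        assert not ({s.spectrum_id for s in library} & {s.spectrum_id for s in test})
        splits.append((library, test))
    return splits


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def baseline_search(
    method: str,
    query: Spectrum,
    store: LibraryStore,
    prefilter_da: Optional[float] = None,
    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
):
    """Single-score baseline search; returns ``(spectrum_id, score)`` or
    ``None`` when no candidate survives the precursor prefilter.

    Candidates are restricted to ``|precursor difference| <= prefilter_da``
    (no restriction when None); ties break on the lowest spectrum_id.
    """
    if method not in ("cosine", "modified_cosine", "primary_embedding"):
        raise ValueError(f"unknown baseline method {method!r}")
    rows = np.arange(store.n_spectra)
    if prefilter_da is not None:
        rows = rows[np.abs(store.precursor_mz - query.precursor_mz) <= prefilter_da]
    if rows.size == 0:
        return None
    if method == "primary_embedding":
        q = embed_spectrum(store.primary_model(), query)
        scores = np.clip(store.embeddings_primary[rows] @ q, -1.0, 1.0)
    else:
        score_fn = cosine_greedy if method == "cosine" else modified_cosine
        scores = np.array(
            [score_fn(query, store.spectra[row], tolerance)[0] for row in rows]
        )
    best = np.lexsort((rows, -scores))[0]
    return store.spectra[rows[best]].spectrum_id, float(scores[best])


def _best_matches(method, queries, store, ranker, prefilter_da, tolerance,
                  n_preselect):
    """Per query: (score, predicted inchikey14) or (None, None)."""
    out = []
    for query in queries:
        if method == "ms2query":
            ranked = rank_candidates(query, store, ranker, n_preselect=n_preselect,
                                     threshold=0.0)
            top = ranked[0]
            out.append((top.rf_score, top.candidate_metadata["inchikey14"]))
        else:
            hit = baseline_search(method, query, store, prefilter_da, tolerance)
            if hit is None:
                out.append((None, None))
            else:
                sid, score = hit
                out.append((score, store.row_inchikey14[store.row_of(sid)]))
    return out


def _sweep(method, matches, truths, thresholds, quality_fn, metadata):
    points = []
    for t in thresholds:
        selected = [
            (match, truth)
            for match, truth in zip(matches, truths)
            if match[0] is not None and match[0] >= t
        ]
        recall = len(selected) / len(matches) if matches else 0.0
        if selected:
            quality = float(np.mean([quality_fn(m, tr) for m, tr in selected]))
        else:
            quality = float("nan")
        points.append((float(t), recall, quality))
    return BenchmarkCurve(method=method, points=points, metadata=metadata)


def evaluate_analogue_curve(
    method: str,
    queries: Sequence[Spectrum],
    query_truth: dict,
    store: LibraryStore,
    thresholds: Optional[np.ndarray] = None,
    ranker: Optional[RankerModel] = None,
    prefilter_da: float = ANALOGUE_PREFILTER_DA,
    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
    n_preselect: int = 2000,
) -> BenchmarkCurve:
    """Threshold sweep in the analogue regime (query structures absent from
    the library); quality is the mean Tanimoto between the true query
    structure and the predicted library structure."""
    thresholds = default_thresholds() if thresholds is None else thresholds
    truths = [query_truth[q.spectrum_id] for q in queries]
    for truth in truths:
        if truth.inchikey14 in store.structure_rows:
            raise ValueError(
                f"query structure {truth.inchikey14} is present in the library; "
                "not an analogue regime"
            )
    matches = _best_matches(
        method, queries, store, ranker,
        None if method == "ms2query" else prefilter_da,
        tolerance, n_preselect,
    )

    def quality_fn(match, truth):
        predicted_fp = store.get_structure(match[1]).fingerprint
        return chem.tanimoto(truth.fingerprint, predicted_fp)

    return _sweep(method, matches, truths, thresholds, quality_fn,
                  {"mode": "analogue", "n_queries": len(queries),
                   "prefilter_da": None if method == "ms2query" else prefilter_da})


def evaluate_exact_match_curve(
    method: str,
    queries: Sequence[Spectrum],
    query_truth: dict,
    store: LibraryStore,
    thresholds: Optional[np.ndarray] = None,
    ranker: Optional[RankerModel] = None,
    prefilter_da: float = EXACT_PREFILTER_DA,
    tolerance: float = DEFAULT_FRAGMENT_TOLERANCE,
    n_preselect: int = 2000,
) -> BenchmarkCurve:
    """Threshold sweep in the exact-match regime (every query structure has
    a library spectrum); quality is the fraction of returned matches whose
    inchikey14 equals the query's."""
    thresholds = default_thresholds() if thresholds is None else thresholds
    truths = [query_truth[q.spectrum_id] for q in queries]
    for truth in truths:
        if truth.inchikey14 not in store.structure_rows:
            raise ValueError(
                f"query structure {truth.inchikey14} has no library spectrum"
            )
    matches = _best_matches(
        method, queries, store, ranker,
        None if method == "ms2query" else prefilter_da,
        tolerance, n_preselect,
    )

    def quality_fn(match, truth):
        return 1.0 if match[1] == truth.inchikey14 else 0.0

    return _sweep(method, matches, truths, thresholds, quality_fn,
                  {"mode": "exact_match", "n_queries": len(queries),
                   "prefilter_da": None if method == "ms2query" else prefilter_da})


# ---------------------------------------------------------------------------
# end-to-end protocol
# ---------------------------------------------------------------------------

def _truth_table(queries, fingerprints: dict) -> dict:
    truth = {}
    for q in queries:
        key = _spectrum_key(q)
        truth[q.spectrum_id] = QueryTruth(inchikey14=key, fingerprint=fingerprints[key])
    return truth


def _fold_store_and_ranker(train_spectra, fingerprints, seed, train_top_n):
    primary, secondary = default_models()
    store = build_library(train_spectra, primary, secondary,
                          fingerprint_overrides=fingerprints)
    # the canonical pool fraction is 1/40; small desk-scale libraries need a
    # larger structure sample to reach the 100-pair training minimum
    per_query = min(train_top_n, store.n_spectra)
    needed_queries = math.ceil(100 / per_query)
    fraction = max(1.0 / 40.0, needed_queries / len(store.structures))
    pairs = generate_training_pairs(store, inchikey_fraction=fraction,
                                    top_n=train_top_n, seed=seed)
    ranker = train_ranker(pairs, seed=seed,
                          library_parameter_hash=store.parameter_hash)
    return store, ranker


def run_analogue_benchmark(
    spectra: Sequence[Spectrum],
    fingerprints: dict,
    k: int = 5,
    seed: int = 0,
    thresholds: Optional[np.ndarray] = None,
    methods: Sequence[str] = ANALOGUE_METHODS,
    train_top_n: int = 100,
) -> pd.DataFrame:
    """Full structure-disjoint analogue protocol; per fold a fresh library
    store and ranker are built from the training side only.  Returns a tidy
    frame (method, fold, threshold, recall, quality), mean-of-fold-means
    aggregation is done by :func:`summarize_curves`."""
    thresholds = default_thresholds() if thresholds is None else thresholds
    frames = []
    for fold, (train, test) in enumerate(make_analogue_folds(spectra, k, seed)):
        store, ranker = _fold_store_and_ranker(train, fingerprints, seed, train_top_n)
        truth = _truth_table(test, fingerprints)
        for method in methods:
            curve = evaluate_analogue_curve(
                method, test, truth, store, thresholds, ranker
            )
            frame = curve.as_frame()
            frame.insert(1, "fold", fold)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_exact_match_benchmark(
    spectra: Sequence[Spectrum],
    fingerprints: dict,
    k: int = 5,
    seed: int = 0,
    thresholds: Optional[np.ndarray] = None,
    methods: Sequence[str] = EXACT_METHODS,
    train_top_n: int = 100,
) -> pd.DataFrame:
    """Full spectrum-disjoint exact-match protocol; same output shape as
    :func:`run_analogue_benchmark`."""
    thresholds = default_thresholds() if thresholds is None else thresholds
    frames = []
    splits = make_exact_match_testsets(spectra, k, seed)
    for fold, (library, test) in enumerate(splits):
        store, ranker = _fold_store_and_ranker(library, fingerprints, seed, train_top_n)
        truth = _truth_table(test, fingerprints)
        for method in methods:
            curve = evaluate_exact_match_curve(
                method, test, truth, store, thresholds, ranker
            )
            frame = curve.as_frame()
            frame.insert(1, "fold", fold)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def summarize_curves(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean of per-fold curves with standard deviation, per method and
    threshold (fold quality NaNs, i.e. empty selections, are ignored)."""
    grouped = frame.groupby(["method", "threshold"])
    out = grouped.agg(
        recall_mean=("recall", "mean"),
        recall_std=("recall", "std"),
        quality_mean=("quality", "mean"),
        quality_std=("quality", "std"),
        n_folds=("fold", "nunique"),
    ).reset_index()
    return out
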