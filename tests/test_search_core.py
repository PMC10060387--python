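import numpy as np
import pytest

from ms2search import synthetic
from ms2search.chem import tanimoto
from ms2search.embed import default_models, embed_spectrum, embedding_similarity
from ms2search.library_store import build_library
from ms2search.search_core import (
    FeatureVector,
    TrainingPair,
    compute_feature_vector,
    generate_training_pairs,
    preselect_candidates,
    rank_candidates,
    search,
    train_ranker,
    write_results_csv,
)

from conftest import make_spectrum


@pytest.fixture(scope="module")
def hundred_structure_store():
    cfg = synthetic.SyntheticConfig(
        n_clusters=25, structures_per_cluster=4, spectra_per_structure=2, seed=21
    )
    spectra, structures = synthetic.generate_library(cfg)
    store = build_library(
        spectra, *default_models(),
        fingerprint_overrides=synthetic.fingerprint_overrides(structures),
    )
    return cfg, spectra, structures, store


# ---------------------------------------------------------------------------
# preselection
# ---------------------------------------------------------------------------

class TestPreselect:
    def test_small_library_truncation(self, small_store, small_cfg, small_library):
        _, structures = small_library
        query = synthetic.generate_spectrum(structures[0], small_cfg, 30)
        ids, scores = preselect_candidates(query, small_store, n=2000)
        assert len(ids) == small_store.n_spectra
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))

    def test_identical_query_ranks_first(self, small_store, small_library):
        spectra, _ = small_library
        query = spectra[7]
        ids, scores = preselect_candidates(query, small_store, n=5)
        assert ids[0] == query.spectrum_id
        assert scores[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_full_sort_oracle(self, hundred_structure_store):
        cfg, spectra, structures, store = hundred_structure_store
        model = store.primary_model()
        for seed in range(3):
            query = synthetic.generate_spectrum(structures[seed * 7], cfg, 40 + seed)
            ids, scores = preselect_candidates(query, store, n=25)
            # independent route: per-spectrum similarity loop then sort
            qv = embed_spectrum(model, query)
            oracle = sorted(
                (
                    (-embedding_similarity(qv, embed_spectrum(model, s)),
                     s.spectrum_id)
                    for s in spectra
                ),
            )[:25]
            assert ids == [sid for _, sid in oracle]
            np.testing.assert_allclose(scores, [-sc for sc, _ in oracle], atol=1e-9)


# ---------------------------------------------------------------------------
# feature vector
# ---------------------------------------------------------------------------

def naive_f4_f5(query, candidate_key, spectra, structures, model, k=10,
                include_self=True):
    """Independent double-loop recomputation of features 4 and 5."""
    by_key = {}
    for s in structures:
        by_key[s.key] = s
    cand_fp = by_key[candidate_key].fingerprint
    scored = sorted(
        ((s.key, tanimoto(cand_fp, s.fingerprint)) for s in structures
         if include_self or s.key != candidate_key),
        key=lambda pair: (-pair[1], pair[0]),
    )[:k]
    qv = embed_spectrum(model, query)
    per_structure_means = []
    for key, _ in scored:
        sims = [
            embedding_similarity(qv, embed_spectrum(model, s))
            for s in spectra
            if s.inchikey[:14] == key
        ]
        per_structure_means.append(np.mean(sims))
    return float(np.mean(per_structure_means)), float(np.mean([t for _, t in scored]))


class TestFeatureVector:
    def test_precursor_difference_example(self, small_store, small_library):
        spectra, _ = small_library
        candidate = small_store.spectra[0]
        query = make_spectrum(
            list(candidate.mz), list(candidate.intensities),
            precursor_mz=candidate.precursor_mz + 10.5,
        )
        fv = compute_feature_vector(query, candidate.spectrum_id, small_store)
        assert fv.f3_precursor_mz_difference == pytest.approx(10.5)
        assert fv.f2_query_precursor_mz == pytest.approx(query.precursor_mz)

    def test_degenerate_single_structure_library(self):
        spectra = [
            make_spectrum([100.0, 200.0, 300.0 + i], [0.5, 1.0, 0.2],
                          spectrum_id=f"s{i}", precursor_mz=300.0,
                          smiles="CCO",
                          inchi="InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3",
                          inchikey="LFQSCWFLJHTTHZ-UHFFFAOYSA-N")
            for i in range(3)
        ]
        store = build_library(spectra, *default_models())
        query = spectra[0]
        fv = compute_feature_vector(query, "s1", store)
        assert fv.f5_avg_tanimoto_related == pytest.approx(1.0)
        model = store.primary_model()
        qv = embed_spectrum(model, query)
        expected_f4 = np.mean(
            [embedding_similarity(qv, embed_spectrum(model, s)) for s in spectra]
        )
        assert fv.f4_avg_primary_similarity_related == pytest.approx(expected_f4,
                                                                     abs=1e-9)

    def test_f4_f5_match_naive_double_loop(self, hundred_structure_store):
        cfg, spectra, structures, store = hundred_structure_store
        model = store.primary_model()
        rng = np.random.default_rng(17)
        query = synthetic.generate_spectrum(structures[3], cfg, 60)
        for cand_idx in rng.choice(len(spectra), 5, replace=False):
            candidate = spectra[cand_idx]
            fv = compute_feature_vector(query, candidate.spectrum_id, store)
            f4, f5 = naive_f4_f5(query, candidate.inchikey[:14], spectra,
                                 structures, model)
            assert fv.f4_avg_primary_similarity_related == pytest.approx(f4, abs=1e-9)
            assert fv.f5_avg_tanimoto_related == pytest.approx(f5, abs=1e-9)

    def test_f4_f5_with_self_excluded(self, small_cfg, small_library):
        spectra, structures = small_library
        store = build_library(
            spectra, *default_models(), include_self=False,
            fingerprint_overrides=synthetic.fingerprint_overrides(structures),
        )
        model = store.primary_model()
        query = synthetic.generate_spectrum(structures[1], small_cfg, 61)
        candidate = spectra[0]
        fv = compute_feature_vector(query, candidate.spectrum_id, store)
        f4, f5 = naive_f4_f5(query, candidate.inchikey[:14], spectra, structures,
                             model, include_self=False)
        assert fv.f4_avg_primary_similarity_related == pytest.approx(f4, abs=1e-9)
        assert fv.f5_avg_tanimoto_related == pytest.approx(f5, abs=1e-9)

    def test_preselection_scores_are_reused(self, small_store, small_library):
        spectra, _ = small_library
        query = spectra[2]
        ids, scores = preselect_candidates(query, small_store)
        provided = dict(zip(ids, scores))
        fv = compute_feature_vector(query, ids[0], small_store,
                                    preselection_scores=provided)
        fv_fresh = compute_feature_vector(query, ids[0], small_store)
        assert fv == fv_fresh

    def test_negative_f3_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(0.5, 300.0, -1.0, 0.5, 0.5)


# ---------------------------------------------------------------------------
# training pairs
# ---------------------------------------------------------------------------

class TestTrainingPairs:
    def test_pool_nonempty_via_ceiling(self, small_store):
        pairs = generate_training_pairs(small_store, top_n=10, seed=0)
        assert pairs  # ceil(16/40) = 1 structure at least

    def test_labels_bounded_and_self_pairs_one(self, small_store):
        pairs = generate_training_pairs(small_store, top_n=20, seed=1)
        for p in pairs:
            assert 0.0 <= p.label <= 1.0
            if p.query_spectrum_id == p.library_spectrum_id:
                assert p.label == pytest.approx(1.0)
        assert any(p.query_spectrum_id == p.library_spectrum_id for p in pairs)

    def test_pair_count_matches_counting_oracle(self, small_store):
        top_n = 20
        pairs = generate_training_pairs(small_store, top_n=top_n, seed=2)
        n_queries = len({p.query_spectrum_id for p in pairs})
        expected = n_queries * min(top_n, small_store.n_spectra)
        assert len(pairs) == expected

    def test_deterministic_given_seed(self, small_store):
        a = generate_training_pairs(small_store, top_n=15, seed=5)
        b = generate_training_pairs(small_store, top_n=15, seed=5)
        assert a == b
        c = generate_training_pairs(small_store, top_n=15, seed=6)
        assert a != c


class TestTrainRanker:
    def _constant_pairs(self, n=150, label=0.7):
        rng = np.random.default_rng(3)
        return [
            TrainingPair(
                query_spectrum_id=f"q{i}",
                library_spectrum_id=f"l{i}",
                features=FeatureVector(*rng.uniform(0.1, 0.9, 5)),
                label=label,
            )
            for i in range(n)
        ]

    def test_constant_target_predicts_constant(self):
        ranker = train_ranker(self._constant_pairs(), n_estimators=50, seed=0)
        rng = np.random.default_rng(4)
        predictions = ranker.predict(rng.uniform(0.1, 0.9, (20, 5)))
        np.testing.assert_allclose(predictions, 0.7, atol=1e-6)

    def test_deterministic_given_seed(self, small_store):
        pairs = generate_training_pairs(small_store, top_n=30, seed=11)
        ra = train_ranker(pairs, n_estimators=100, seed=11)
        rb = train_ranker(pairs, n_estimators=100, seed=11)
        features = np.stack([p.features.to_array() for p in pairs[:50]])
        np.testing.assert_array_equal(ra.predict(features), rb.predict(features))

    def test_training_predictions_correlate_with_labels(self, small_store,
                                                        small_ranker):
        pairs = generate_training_pairs(small_store, top_n=30, seed=11)
        features = np.stack([p.features.to_array() for p in pairs])
        labels = np.array([p.label for p in pairs])
        predictions = small_ranker.predict(features)
        assert np.corrcoef(predictions, labels)[0, 1] > 0.5

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="100"):
            train_ranker(self._constant_pairs(n=50))

    def test_nan_feature_error_names_pair(self):
        pairs = self._constant_pairs()
        bad = TrainingPair("qx", "lx", FeatureVector(0.5, 300.0, 1.0, 0.5, 0.5), 0.5)
        object.__setattr__(bad.features, "f1_secondary_similarity", float("nan"))
        with pytest.raises(ValueError, match="qx"):
            train_ranker(pairs + [bad])

    def test_ranker_rejects_mismatched_store(self, small_store, small_library,
                                             small_cfg):
        pairs = generate_training_pairs(small_store, top_n=30, seed=11)
        ranker = train_ranker(pairs, n_estimators=10, seed=0,
                              library_parameter_hash="deadbeef")
        _, structures = small_library
        query = synthetic.generate_spectrum(structures[0], small_cfg, 70)
        with pytest.raises(ValueError, match="hash"):
            rank_candidates(query, small_store, ranker)


# ---------------------------------------------------------------------------
# ranking and search
# ---------------------------------------------------------------------------

class TestRankCandidates:
    def test_output_length_and_bounds(self, small_store, small_ranker,
                                      small_cfg, small_library):
        _, structures = small_library
        query = synthetic.generate_spectrum(structures[2], small_cfg, 80)
        ranked = rank_candidates(query, small_store, small_ranker)
        assert len(ranked) == small_store.n_spectra
        assert all(0.0 <= m.rf_score <= 1.0 for m in ranked)
        scores = [m.rf_score for m in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_replicate_query_recovers_structure(self, small_store, small_ranker,
                                                small_cfg, small_library):
        _, structures = small_library
        hits = 0
        for i, structure in enumerate(structures[:8]):
            query = synthetic.generate_spectrum(structure, small_cfg, 90 + i)
            top = rank_candidates(query, small_store, small_ranker)[0]
            hits += top.candidate_metadata["inchikey14"] == structure.key
        assert hits >= 7


@pytest.fixture(scope="module")
def queries(small_cfg, small_library):
    _, structures = small_library
    return [synthetic.generate_spectrum(s, small_cfg, 100) for s in structures[:6]]


class TestSearch:
    def test_impossible_threshold_returns_nothing(self, queries, small_store,
                                                  small_ranker):
        assert search(queries, small_store, small_ranker, threshold=1.01) == []

    def test_zero_threshold_returns_everything(self, queries, small_store,
                                               small_ranker):
        results = search(queries, small_store, small_ranker, threshold=0.0)
        assert len(results) == len(queries)
        assert all(r.decision in ("analogue", "exact_match_candidate")
                   for r in results)

    def test_match_count_monotone_in_threshold(self, queries, small_store,
                                               small_ranker):
        counts = [
            len(search(queries, small_store, small_ranker, threshold=t))
            for t in np.linspace(0, 1, 11)
        ]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_exact_match_window_convention(self, queries, small_store,
                                           small_ranker):
        for r in search(queries, small_store, small_ranker, threshold=0.0):
            if r.features.f3_precursor_mz_difference < 1.0:
                assert r.decision == "exact_match_candidate"
            else:
                assert r.decision == "analogue"

    def test_end_to_end_determinism(self, tmp_path, queries, small_store,
                                    small_ranker):
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_results_csv(search(queries, small_store, small_ranker, 0.2), pa)
        write_results_csv(search(queries, small_store, small_ranker, 0.2), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_top_k_option(self, queries, small_store, small_ranker):
        top3 = search(queries[:2], small_store, small_ranker, threshold=0.0,
                      top_k=3)
        assert len(top3) == 6


class TestResultsCsv:
    HEADER = ("query_id,query_precursor_mz,rf_score,match_spectrum_id,"
              "match_precursor_mz,precursor_mz_difference,smiles,inchikey,"
              "compound_name,decision")

    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results_csv([], path)
        assert path.read_text().strip() == self.HEADER

    def test_row_count(self, tmp_path, small_store, small_ranker, small_cfg,
                       small_library):
        _, structures = small_library
        queries = [synthetic.generate_spectrum(s, small_cfg, 110)
                   for s in structures[:4]]
        results = search(queries, small_store, small_ranker, threshold=0.0)
        path = tmp_path / "out.csv"
        write_results_csv(results, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(results) + 1

    def test_rf_score_round_trip_at_6_decimals(self, tmp_path, small_store,
                                               small_ranker, small_cfg,
                                               small_library):
        import csv as csv_mod

        _, structures = small_library
        queries = [synthetic.generate_spectrum(s, small_cfg, 111)
                   for s in structures[:4]]
        results = search(queries, small_store, small_ranker, threshold=0.0)
        path = tmp_path / "out.csv"
        write_results_csv(results, path)
        with open(path) as handle:
            rows = list(csv_mod.DictReader(handle))
        for row, result in zip(rows, results):
            assert row["rf_score"] == f"{result.rf_score:.6f}"
            assert float(row["rf_score"]) == pytest.approx(result.rf_score,
                                                           abs=5e-7)
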