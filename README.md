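# ms2search

Analogue and exact-match search engine for MS2 fragmentation spectra.

Instead of prefiltering a spectral library on precursor m/z, `ms2search`
scores a query spectrum against *every* library spectrum using precomputed
spectral embeddings, keeps the top 2000 candidates, and re-ranks them with a
random forest trained to predict the Tanimoto chemical similarity between the
query and candidate 2D structures. Thresholding the forest score (default
0.633) filters unreliable matches; surviving matches are labelled exact-match
candidates (precursor difference < 1 Da) or analogues.

The five ranking features per query–candidate pair:

1. secondary-embedding cosine similarity,
2. query precursor m/z,
3. absolute precursor m/z difference,
4. mean primary-embedding similarity between the query and all spectra of the
   candidate structure's ten chemically most related library structures,
5. mean Tanimoto between the candidate structure and those related structures.

Trained neural / word-embedding models can be plugged in behind the
`EmbeddingModel` contract; deterministic binned reference embedders are
bundled so the whole pipeline runs with no model files. A seeded synthetic
library generator with known ground-truth chemistry makes everything testable
offline.

## Layout

| module          | contents |
|-----------------|----------|
| `spectra_io`    | MGF / MSP / mzML readers, metadata harmonization, peak-cleaning rules, ionmode partitioning |
| `chem`          | InChIKey-based structure collapsing, 2048-bit path fingerprints, Tanimoto scores, top-10 related-structure table |
| `embed`         | embedding-model contract, binned reference embedders, cosine and modified-cosine baselines |
| `library_store` | on-disk library: SQLite metadata (indexed precursor m/z), embedding matrices, manifest |
| `search_core`   | preselection, feature computation, random-forest training, ranking, search, CSV results |
| `benchmark`     | structure-/spectrum-disjoint folds, threshold-sweep curves, baseline searches |
| `synthetic`     | seeded synthetic spectral-library generator with ground-truth fingerprints |

## CLI

```bash
# generate a synthetic benchmark suite (library + queries + ground truth)
ms2search simulate --out-dir data --seed 0

# build the on-disk library store
ms2search build-library --spectra data/library.mgf --ionmode positive \
    --fingerprints data/ground_truth_structures.csv --out library

# train the random-forest re-ranker
ms2search train --library library --out model.bin --seed 0

# search (one best match per query above the score threshold)
ms2search search --library library --queries data/analogue_queries.mgf \
    --model model.bin --threshold 0.633 --out results.csv

# k-fold disjoint benchmarking protocol with threshold-sweep curves
ms2search benchmark --library data/library.mgf \
    --fingerprints data/ground_truth_structures.csv \
    --mode analogue --k 5 --seed 0 --out-dir bench
```

For real (non-synthetic) annotated libraries, omit `--fingerprints`;
fingerprints are then computed from the spectra's SMILES annotations.

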