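# biodata-inventory

Tools for building an inventory of **biodata resources** — online sources of
structured biological data such as PDB or FlyBase — by mining the titles and
abstracts of life-sciences articles.

Thousands of biodata resources are announced in the literature but never
registered anywhere, so nobody (least of all the funders who sustain them)
knows how many exist, where they run, or who pays for them. This package
implements a machine-learning-enabled pipeline that turns a literature query
into a curated resource inventory:

1. **Corpus retrieval** — fetch candidate articles from a cursor-paged
   literature API (Europe PMC style) using a user-provided query file, drop
   records without PMIDs, and normalize title+abstract text.
2. **Classification** — label each article as describing a biodata resource
   or not (binary classifier over the concatenated title and abstract).
3. **Name extraction (NER)** — tag tokens with a five-label BIO scheme
   (`B-COM`/`I-COM` for short *common* names like "PDB", `B-FUL`/`I-FUL` for
   expanded *full* names like "Protein Data Bank", `O` otherwise), decode the
   label runs into name mentions, and score each mention with the mean of its
   token probabilities. URLs are extracted from the abstract by regular
   expression.
4. **Inventory construction** — keep positively classified articles with at
   least one name of ≥ 2 characters and 1–2 complete URLs; merge records that
   agree on (exact best name, normalized URL); flag records whose best-name
   probability is below 0.978 (`low_prob`) or that share a name
   (`duplicate_names`) or URL (`duplicate_urls`) with another record.
5. **Manual review** — a strict CSV interface through which a curator keeps,
   removes, or merges flagged records. Predicted names and URLs are never
   edited, so the inventory stays fully machine-generated.
6. **Enrichment** — article metadata (affiliations, funders, citations), URL
   viability (three attempts, 5 s each, 1 s pause before the third; alive iff
   2xx/3xx), web-archive snapshots, IP geolocation, and ISO-3166 country
   mentions in author affiliations.
7. **Registry comparison** — overlap counts against registry exports
   (re3data, FAIRsharing) on common-name, full-name, and cleaned-URL channels.

Model backends are pluggable: any object with `classify(text)` and
`tag(text)` works. The package ships a deterministic rule-based backend
(cue phrases + name dictionary) used for offline testing, and trainable
scikit-learn backends with a fine-tuning harness (≤ 10 epochs, per-epoch
validation metrics, checkpoint selection by validation precision for
classification and entity-level F1 for NER).

Classification is scored with precision = TP/(TP+FP), recall = TP/(TP+FN)
and F1 = 2PR/(P+R); NER with partial-match entity-level metrics, where a
prediction is credited when it overlaps ≥ 1 token of a same-kind gold
entity. Labeled data splits 70/15/15 into train/validation/test (1587
labeled articles split 1110/238/239).

## Worked example

A synthetic corpus with known ground truth runs the whole pipeline offline:

```python
from biodata_inventory import CorpusSpec, generate_corpus, fixture_services, run_pipeline

spec = CorpusSpec(n_articles=50, positive_fraction=0.4, dup_pairs=3, seed=11)
articles, truth = generate_corpus(spec)
services = fixture_services(truth, articles)
resources, report = run_pipeline(articles, services.backend)
print(report)
```

```
retrieved: 50
with_pmid: 50
classified_positive: 20
with_name: 20
with_url: 20
after_dedup: 17
```

Fifty articles yield 20 positives (40% were planted as resource
announcements); all 20 carry a decoded name and a complete URL, and the
three planted duplicate pairs collapse during deduplication, leaving
exactly the 17 planted distinct resources. One recovered record:

```
Chemical Expression Atlas <http://chemoatlas.example.org> pmids=['6000045'] best_prob=0.9842 flags=[]
```

`best_prob` 0.9842 is the mention confidence of the winning name; it clears
the 0.978 review threshold, so the record carries no flags and would enter
the final inventory without manual review.

The same workflow is available from the shell:

```bash
biodata-inventory simulate --spec spec.json --out sim/
biodata-inventory fetch --query query.txt --out corpus.jsonl --fixture sim/
biodata-inventory predict --in corpus.jsonl --backend rule:names.json --out pred.jsonl
biodata-inventory build --predictions pred.jsonl --out inventory.csv
biodata-inventory apply-review --inventory inventory.csv --review review.csv --out final.csv
biodata-inventory enrich --inventory final.csv --out enriched.csv --offline-fixtures sim/
biodata-inventory compare --inventory final.csv --registry re3data.csv --out overlap.csv
```

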