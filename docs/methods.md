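# Methods

This note records the models, parameters, and design choices behind the
pipeline, and what the synthetic test bed does and does not establish.

## Pipeline model

The pipeline treats inventory construction as staged attrition over an
article corpus: retrieval → PMID filter → binary classification → name
extraction → URL/name filters → deduplication → review flagging → manual
review → enrichment. Stage counts are reported after every run and must be
monotonically non-increasing from classification onward; a violation
indicates a stage that invented records and aborts the run's integrity
assumptions.

Articles are represented by their title and abstract only. Classification
input is `title + " " + abstract` with XML/HTML tags removed; a space is
inserted only where removing a tag would glue sentence punctuation onto
the next word. We deliberately do not apply a global
space-after-punctuation rule because it would corrupt URLs and
abbreviations inside abstracts; the tag-join rule reproduces the intended
behaviour (repairing text glued together by markup) without that damage.
Text preparation iterates tag removal to a fixpoint so it is idempotent
even on pathological nested markup.

## Name extraction

Token taggers emit one of five labels: `B-COM`, `I-COM`, `B-FUL`,
`I-FUL`, `O`. Decoding groups sub-word tokens by word index, then reads
maximal `B-X (I-X)*` runs as mentions. Two lenient repairs are applied,
both standard BIO practice: an orphan `I-X` opens a new mention (dropping
it would sacrifice recall to a boundary error), and `B-X` after `B-X`
closes the first mention. Mention confidence is the arithmetic mean of
all member-token probabilities, so it always lies within the min/max of
its tokens. Trailing punctuation is stripped; mentions emptied by
stripping are discarded. The decoder is verified against a brute-force
run-enumeration oracle over the full label alphabet.

Best-name selection takes the per-kind confidence argmax and then the
higher-confidence of the two winners. An exact tie prefers the common
name, because common names are empirically the more reliably extracted
kind. When the same surface string is mentioned several times we keep its
maximum confidence before selection.

URL extraction uses the pattern
`(?:https?://|www\.)[^\s<>()\[\]{}"']+` (case-insensitive) followed by
stripping of trailing sentence punctuation and closing brackets. The
character class excludes whitespace and closing delimiters so URLs inside
parentheses terminate correctly.

## Model backends

Every consumer of model output depends only on a two-method contract
(`classify`, `tag`), so backends are interchangeable:

* **RuleBackend** — classification by cue-phrase lookup, tagging by
  longest-match dictionary lookup with configured per-name probabilities.
  Deterministic and dependency-free; it is the reference backend for all
  pipeline tests and synthetic runs.
* **LinearArticleClassifier** — TF-IDF (uni+bigram) features into an SGD
  logistic regression. **LinearTokenTagger** — per-token shape/affix/
  neighbour features into a multinomial SGD logistic regression.

Both trainable backends are scikit-learn-style estimators trained one
epoch at a time (10 epochs maximum). When validation data is supplied,
per-epoch validation metrics are recorded and the snapshot maximizing
validation **precision** (classification) or entity-level **F1** (NER) is
kept, regardless of epoch; an undefined metric (e.g. an epoch predicting
no positives) never wins selection, and ties resolve to the earliest
epoch. Training is deterministic for a fixed seed and dataset. The linear
models are the package's own trainable baseline — small enough to fit in
seconds on a CPU — while heavier transformer backends can be plugged in
through the same contract without touching the pipeline.

## Inventory construction

Filters keep records that are positively classified, have ≥ 1 decoded
name, a best name of ≥ 2 characters (`min_name_length`, default 2), and
1–2 complete URLs (`max_urls`, default 2; abstracts with more URLs nearly
always describe several distinct resources and are removed rather than
disambiguated). A URL is *complete* when it parses with a host component.

Deduplication merges records agreeing on (exact best name, normalized
URL). Name matching is case-sensitive — distinctly cased names such as
Seed/SEED denote distinct resources — while URL keys ignore scheme
(http/https), trailing slashes, and case. Merged records union their
member PMIDs and keep the title-abstract and date of the most recently
published member; a date tie keeps the first record encountered (dates
are compared as ISO strings, so granularity differences fall back to
lexicographic order). Resource identifiers are a stable SHA-1 prefix of
(best name, URL key), reproducible across runs so review files stay valid.

Review flags are always computed, never hand-set: `low_prob` iff best-name
probability < 0.978 (strict; 0.978 itself is unflagged), and
`duplicate_names`/`duplicate_urls` iff ≥ 2 records share the respective
key. The 0.978 default is the mean probability of names judged correct in
a manual evaluation of a 10% prediction sample; it is configurable
(`InventoryConfig.review_threshold`). The review file is the only human
input: actions are restricted to `keep`, `remove`, `merge:<id>`, and
`partial_merge:<id>`, validated strictly (unknown actions, unknown ids,
missing targets, and undecided flagged records are all errors).
`partial_merge` applies the same PMID-union merge as `merge`; its partial
character lies in being issued for only part of a suspected-duplicate
set, leaving the rest unmerged.

## Enrichment

URL viability: up to three GET attempts per URL, each with a 5-second
response window; the second attempt follows immediately, the third after
a 1-second delay (worst case ≈ 16 s per URL). The first definitive HTTP
status ends the probe; a site is alive iff that status is 2xx or 3xx.
Requests do not follow redirects, so 3xx is observed rather than
collapsed into its target — a deliberate choice, since the redirect
series itself is the datum of interest. For archived snapshots, the most
recent web-archive snapshot is recorded; a live but unarchived URL is
submitted for archiving once. IP geolocation runs only for URLs whose
status is < 400 (enforced as a hard gate) and queries providers in
configured order, first success winning.

Affiliation countries are matched against a bundled ISO-3166-1 table
(name, alpha-2, alpha-3; 249 entries) by case-insensitive substring on
names. This deliberately reproduces the known artifacts of substring
matching — "New Mexico" counts as Mexico, while "South Korea" misses the
formal name "Republic of Korea" — because the default mode is meant to
mirror how affiliation mining behaves in practice; a word-boundary mode
is available but off by default. Alpha-3 codes match only as standalone
uppercase tokens, since substring matching of three-letter codes inside
ordinary words is pathologically noisy. Funder frequencies count distinct
resources (not articles) per verbatim agency string, with no name
normalization, and drop agencies below 3 resources by default.

## Evaluation

Labeled data splits 70/15/15 (train/validation/test) by unstratified
seeded permutation; sizes are `floor(0.70·n)` and `floor(0.15·n)` with
the rounding remainder in the test set, so 1587 articles split
1110/238/239. Splits are unstratified because the class balance of the
reference splits varies between partitions, which stratification would
have prevented.

Undefined metrics (zero denominators) raise rather than returning 0,
because a silent 0 can masquerade as a legitimate score during model
selection. NER uses partial-match entity-level metrics: predictions and
gold entities are sorted by span, paired greedily left-to-right, a pair
requires same kind and ≥ 1 token of overlap, and each gold entity credits
at most one prediction. The greedy pairing rule is an explicit assumption
of this package; it is deterministic and order-invariant, which is what
the test suite requires of it. Model selection takes the validation
precision argmax for classification and the F1 argmax for NER, ties going
to the first-listed model with a warning.

## Synthetic test bed

`generate_corpus` emulates a retrieval corpus: positives embed one
(common, full) name pair and 1–2 URLs in announcement-style template
sentences; negatives contain URLs but none of the cue phrases the rule
classifier keys on; `dup_pairs` resources receive a second article with a
distinct PMID and later date. Correctly planted names carry per-token
probabilities in [0.98, 1.0] (above the review threshold); corrupted ones
(`noise_level`) have the full name truncated and probabilities in
[0.5, 0.95], strictly below the threshold, so every corrupted record is
either filtered out or flagged — never silently wrong. Confidences are
drawn once per (resource, kind) and shared across a resource's articles
so planted duplicates deterministically merge. Everything is a pure
function of the seed.

The generator does **not** model realistic scientific language, name
ambiguity across resources, partial or malformed URLs, non-English text,
or classifier boundary cases; a passing end-to-end run therefore
establishes the correctness of the pipeline's bookkeeping (filtering,
decoding, dedup, flagging, counting), not the accuracy of any particular
trained model on real abstracts. Default acceptance-scale conditions are
200 articles at 30% positives with 5 duplicate pairs and zero noise;
tests use 40–200 articles so the full suite runs in seconds.

## Known limitations

* The trainable backends are linear models; their scores are calibrated
  by the logistic loss but are not comparable to transformer posteriors.
* URL normalization keys on host+path+query; resources served under
  distinct hosts (mirrors) remain distinct records by design and are only
  reconciled through the duplicate-name flag and manual review.
* Substring country matching over- and under-counts as described above.
* Registry overlap uses exact cleaned keys; renamed or migrated resources
  are missed, and no fuzzy matching is attempted.
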