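# Methods

This note documents the models and procedures implemented in `herbkg`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish
about behaviour on real literature.

## Document model and offsets

A document is a title, an abstract, typed entity mentions and gold
relations. Mention offsets are 0-based, end-exclusive character positions
into the concatenation `title + " " + abstract`. The single-space separator
is the convention under which the published sample abstract's printed
offsets verify exactly (the title keeps its trailing period); because
exports in the wild differ on the separator, it is kept as a module
constant and `AnnotatedDocument.concat_text(sep=...)` accepts alternatives.
Both the tab-delimited and the pipe-delimited (`pmid|t|…`) dialects are
parsed; output is always tab-delimited. Relations whose endpoint ids match
no mention are **retained and flagged** rather than dropped: truncated
exports legitimately contain them, and lossless I/O keeps validation a
separate, inspectable step (`validate_document` returns violations as data,
never exceptions).

## Ontology, NER adaptation, screening

The ontology is closed: four entity types, five positive relation labels
with fixed (head, tail) type signatures, and a `Neg` class with no
signature. Only signature-valid triplets may enter the graph. Upstream NER
emits six raw tags; adaptation removes mutations and cell lines, re-types a
species mention as Herb when its surface text matches the curated domain
vocabulary, and passes Gene/Chemical/Disease through. Matching is by
surface text rather than concept id — the vocabulary is a curated term
list, so text is the natural key; id-based matching would require the
vocabulary to carry taxonomy identifiers it does not have. Vocabulary
matching is case-insensitive, whitespace-collapsed, and whole-word ("rice"
does not match inside "price"); corpus screening asks whether any
vocabulary phrase occurs in the title-plus-abstract text.

## Dataset construction

One positive example per gold relation: sentence A is the concatenated
abstract text; the head/tail surface form is the **first** mention carrying
the endpoint's concept id (printed dataset instances show surface forms,
not ids). Negative sampling draws ordered mention pairs *within one
abstract* whose types fit some positive signature but which carry no
annotation; cross-document pairs are never eligible, since unrelatedness is
only meaningful where co-mention creates the possibility of relation. The
default per-document quota balances the negative class against the largest
positive class, mirroring the benchmark dataset's near-parity between its
largest positive class and its negatives.

The 3:1 train/test split is stratified by label. Per-label test quotas are
apportioned by the largest-remainder method so that the overall test
fraction is exact while every label's proportion is preserved within one
example; remainder ties go to larger classes first. On the benchmark's
class totals (3,536 examples) this yields exactly 884 test and 2,652
training examples. Labels with fewer examples than `ratio_train +
ratio_test` go entirely to training, with a warning. Percentages in dataset
statistics are rounded half-up to one decimal.

## The relation classifier

The classifier is the standard encoder architecture: summed token, segment
and position embeddings; `N` encoder layers, each multi-head
scaled-dot-product self-attention and a ReLU feed-forward block with
residual connections and layer normalisation; masked-mean pooling; a tanh
dense layer; a softmax over the six labels. Two presets are provided —
`base` (12 layers, 12 heads, width 768, 512-token budget, matching the
published configuration) and `tiny` (2/2/32/64), which all tests use. The
implementation is numpy float64 with hand-derived backpropagation,
verified against central finite differences in the suite; training,
inference and fine-tuning are bit-deterministic given the seed. External
pretrained weights can be supplied through the checkpoint field of
`EncoderConfig`; nothing in the training loop depends on how the initial
weights were obtained.

Choices worth recording:

* **Tokenizer** — whitespace splitting with a fixed, case-preserving
  vocabulary and five reserved specials (pad, unknown, separator, MLM mask,
  occlusion). Case is preserved so detokenisation is the exact inverse on
  in-vocabulary text, which entity surfaces require.
* **Truncation** — when a pair exceeds the token budget, sentence A loses
  its tail (titles and openings carry the finding); sentence B is never
  truncated, and a sentence B that cannot fit at all is rejected as
  degenerate.
* **Weighted cross-entropy** — class weights are inverse class frequency
  normalised to mean one over the classes present, so equal frequencies
  reproduce the unweighted loss exactly.
* **Optimizers** — SGD, SGD with momentum 0.9, and Adam (0.9/0.999/1e-8).

### Masked-language-model fine-tuning

Domain text is injected by masking a fraction (default 0.15) of real
tokens in title+abstract sequences and training the encoder plus a
vocabulary-projection head to recover them (Adam, default 3e-4). A held-out
corpus slice (default 10%) is masked once, deterministically, and its
masked-token cross-entropy is measured before and after training; the
decrease is the reported effect. At least one token is always masked, so
short documents still contribute signal.

### Hyperparameter search

The grid is exhaustive over epochs {1, 3, 5, 7, 9}, learning rate {1e-4,
3e-4, 1e-3, 3e-3, 1e-2}, loss {plain, weighted cross-entropy} and optimizer
{SGD, Adam, momentum} — 150 configurations — selected by macro-F1, ties
broken toward fewer epochs then lower learning rate. The evaluation set is
the caller's: a held-out validation split is the hygienic default, and
passing the test set reproduces the tuning-on-test convention some
benchmark reports use.

## Substitution-based augmentation

Per positive relation type: (1) collect every sentence containing both
endpoints of a gold relation of that type; (2) replace all entity mentions
with type placeholders (`[Herb]` …); (3) generate new templates; (4) fill
the placeholders with an entity pair whose relation of that type is already
known, yielding a labelled synthetic example. Step 3 is a pluggable
contract — n templates, exactly one head-type and one tail-type placeholder
each — and the default generator recombines prefix/middle/suffix fragments
of corpus templates around the placeholders under a seed. A fine-tuned
generative language model slots into the same contract; fragment
recombination was chosen as the default because it is deterministic,
dependency-free and desk-testable while preserving exactly the property
that matters downstream: **label soundness** (every augmented example's
label matches a known relation of its entity pair). If a template type has
more than one placeholder occurrence of a signature type, all occurrences
of the head type take the head entity — soundness over variety. Augmented
examples carry an `augmented` provenance flag and are only ever appended to
training data. Sentence segmentation throughout is rule-based (sentence
punctuation followed by whitespace and an uppercase letter/digit):
deterministic, dependency-light, and adequate for abstracts, at the cost of
over-splitting around abbreviations.

## Evaluation conventions

The metric suite reproduces the benchmark tables bit-for-bit: label order
CAG, HHC, HTD, CAD, GID, Neg; `TN_k = trace(cm) − TP_k` (the tables count
correctly classified instances of the other classes as true negatives —
the standard everything-else complement is available behind
`tn_convention="standard"`); the "Total" column is the unweighted macro
mean of per-class percentages computed on raw values, then rounded half-up
to one decimal (half-up, not banker's: 13/16 recall prints as 81.3). A
class never predicted has undefined precision, reported as 0.0 with an
explicit flag. Average precision is the recall-step weighted sum over the
descending-score ranking (stable sort for ties); multi-class AP defaults to
the unweighted mean of one-vs-rest APs, with micro pooling available, as
the macro/micro choice is not fixed by the reporting convention.

Token importance is occlusion-based: the first sentence of sentence A
containing both entity surfaces is extracted, scored (c\* = gold-label
probability), then each token in turn is replaced by the reserved `[OCC]`
token — never seen in training, hence carrying no learned evidence — and
the drop `d_i = c* − c_i` is that token's importance.

## Knowledge graph

Assembly deduplicates triplets by (relation type, head id, tail id),
rejects signature-violating triplets, and attaches one evidence record per
occurrence: the first sentence where both endpoint surfaces co-occur, or
the whole abstract with an explicit flag when they never share a sentence.
Support is the number of distinct articles in a relation's evidence.
Herb–gene analytics traverse herb → chemical → gene paths (a herb reaches a
gene through a contained chemical); herb–disease analytics use direct
treats-disease edges. The traversal definition for herb–gene counts was an
open choice — direct herb–gene edges do not exist in the ontology, so the
two-hop path is the only signature-consistent reading. Similarity is the
half-sum of the gene-profile and disease-profile Jaccard indices; a term
with an empty union contributes 0 (logged), keeping scores defined for
sparsely connected herbs. Repurposing candidates for a disease are
chemicals associated with the disease's genes that lack a direct
chemical–disease edge, ranked by shared-gene count. Rankings break ties
alphabetically for determinism. Graph storage is plain dictionaries;
networkx is used only for GraphML export, and node/edge CSV tables support
bulk import into graph databases.

## Synthetic corpora and what the tests show

The generator plants relations as cue-word template sentences (`<head>
<cue> <tail> …`) with a deterministic, injective cue-word map, plus filler
sentences pairing type-compatible but unrelated entities
(`negative_density`, default 0.3, controls their share). Defaults — 30
documents, 3 sentences each, per-type vocabularies of 8–12 names, a uniform
mix over the five relation types — keep every planted structure recoverable
while exercising all code paths; entity names are fixed-width coinages so
no name is a substring of another. Offsets are exact by construction and
every generated document validates cleanly.

Because the cue-word map makes the synthetic task linearly separable,
passing tests establish *mechanism*, not literature-scale accuracy: that
the classifier has the capacity to represent and recover the mapping (100%
training accuracy on the separable set; perfect held-out accuracy from the
same distribution), that occlusion attribution finds the planted cue, that
MLM fine-tuning reduces held-out masked loss on corpus-like text, and that
augmentation is label-sound and non-harmful on this benchmark. Real
abstracts have paraphrase, inter-sentence relations, ambiguous entities and
class imbalance that the generator deliberately does not emulate; headline
scores on the real benchmark additionally require large pretrained
checkpoints, which enter through the pluggable weight interface.

Problem sizes used by the test suite and the acceptance script — 30–200
documents, 60-example training sets, 500 MLM steps, the tiny encoder preset
— are the package's chosen desk scale: large enough that every property is
exercised end to end, small enough to run anywhere in seconds.

## Numerical notes

Float64 throughout; attention masking by additive −1e9 bias; layer-norm
epsilon 1e-5; Gaussian(0, 0.02) initialisation; per-epoch shuffling from a
seeded generator, so identical seeds give identical weights. Rounding for
display uses decimal half-up; raw floats are retained internally and used
for all comparisons except printed-table reproduction.

## Known limitations

* Document-level relations whose endpoints never co-occur in a sentence
  fall back to whole-abstract evidence (flagged) and are invisible to
  template extraction.
* The whitespace tokenizer has no subword fallback; out-of-vocabulary
  words map to `[UNK]`.
* The default template generator recombines observed fragments only; it
  cannot produce genuinely novel phrasings the way a generative LM can.
* `read_tsv` recovers sentence B's head/tail by splitting at the first
  space, which is only exact for single-token heads; the JSONL dialect
  preserves full provenance.
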