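# Methods

## Problem setting and data model

The unit of analysis is a sentence with a dependency tree T = ⟨N, E, R⟩:
nodes N carry string attributes (word, lemma, POS), each edge ⟨n_g, r,
n_d⟩ links a governor to a dependent through a typed relation r, and R is
the root. Each *opinion class* c_i (an aspect of a reviewed service, e.g.
wait time) takes exactly one of three values per sentence: c_i^x ("yes"),
c_i^y ("no"), c_i^0 (neutral — the sentence does not address the aspect).
A sentence may be non-neutral for several classes at once; one classifier
is trained per class. Relation labels are treated as uninterpreted
strings, so any label inventory works; only the negation label (default
`neg`, configurable because newer schemes rename it) has special status.

Corpus records whose annotator union assigns both x and y to one class
are contradictory; the loader excludes such records with a logged warning
rather than inventing a resolution. Missing class entries default to
neutral, which encodes "not relevant".

## Pattern language

The matcher implements the semgrex subset the extractor can emit:
attribute descriptors (`{word:wait}`, regex values `/wait.*/`, wildcard
`{}`), the governor-direction operators `>` (one edge), `>label` (one
edge with that relation), and `>>` (a downward path of length ≥ 1), with
parenthesized grouping. Dependent-direction (`<`, `<<`) and typed
indirect operators are rejected at parse time: extraction never produces
them, and supporting unexercised operators would only add untested code.

Matching semantics: a pattern matches a tree iff *some* mapping of
pattern nodes to tree nodes satisfies every descriptor and relation
constraint; the leading pattern node may map anywhere in the tree. The
mapping is deliberately not required to be injective — with
non-injective semantics a pattern that matches keeps matching when a
constraint is deleted (monotonicity), which the test suite checks, and
the permissive reading of "matches any part of the tree" holds. All
attribute comparisons are case-insensitive; regex values must match the
whole attribute, so learned prefix constraints are written `/w.*/`.
Canonical serialization orders each node's children by their rendered
text, making pattern equality, deduplication, and model files
order-independent.

## Extraction

Given seed words W and a budget m (per-pattern word cap):

* **prune(t, C)** removes leaves, innermost first, whose word does not
  start (case-insensitively) with any word of C and whose incoming
  relation is not the negation label; surviving non-matching nodes become
  wildcards. Prefix matching makes one seed cover its inflections
  ("wait" → "waited", "waiting"), mirroring the `/w.*/` form of the
  learned constraints.
* **collapse(t)** descends the root past single-child wildcards, then
  splices out interior single-child wildcards, joining parent to
  grandchild with an indirect edge. Wildcards with ≥ 2 children stay: they
  pin sibling structure (`{} > A > B` is stronger than A and B merely
  coexisting).
* **extract** seeds a stack with the min(|W|, m)-sized combinations of W,
  and for each working tree emits the pruned-and-collapsed pattern if its
  canonical text is new, then recurses on every ≥ 2-sized combination of
  the surviving non-wildcard words. Patterns with no word-constrained
  node match every tree and are suppressed. Because recursion only
  happens for newly emitted patterns and working trees never grow, the
  procedure terminates.

One implementation note: pruning with combination C depends only on
C ∩ W_t, where W_t are the seed words that prefix-match some word of the
tree. The seed loop therefore enumerates the distinct realizable
intersections instead of all C(|W|, m) combinations — with |W| = 30 and
m = 4 that replaces 27 405 prunes per tree by a handful, with a provably
identical output set.

## Training

Per non-neutral label: the corpus labels are binarized (target vs rest)
and word types are ranked by information gain of their presence
indicator, IG(w) = H(y) − H(y | w present), computed on lowercased
surface words (presence, not counts; surface, not lemma, to line up with
the extractor's prefix semantics). Ties break lexicographically. The top
n_x (resp. n_y) words seed extraction over every tree with that label;
defaults n_x = n_y = 30 and m = 4 — beyond roughly 30 seed words per label
additional words stop being discriminative, and the pattern space grows
combinatorially in m.

Each distinct (pattern, label) pair is scored on the **full** class
corpus, neutral sentences included, by weighted accuracy: the unweighted
mean over the three label values of the per-label accuracy, where the
pair is correct on an instance iff it matches ∧ the instance has the
pattern's label, or it does not match ∧ the instance does not. A label
with zero instances contributes accuracy 1 — the pattern cannot err on
absent instances, and this keeps scores in [0, 1] without special cases.
The list is sorted by descending score; ties prefer the longer (more
specific) canonical text, then lexicographic order, then the label, so
training is fully deterministic — there is no randomness anywhere in
training or extraction. The majority label is recorded for fallback
(ties prefer neutral). Scoring uses a per-tree match memo: repeated
scoring of the same pattern on the same tree object (ubiquitous under
cross-validation) costs a dictionary lookup.

## Classification and evaluation

Classification scans the ranked list and returns the first matching
pattern's label; otherwise the majority label, or a user-supplied backup
classifier (any callable text → label) when configured — the backup is
an interface only, no secondary model ships. Evaluation reports per-label
accuracy, their mean (weighted accuracy), the predicted-correct ratio
(among sentences predicted x or y, the fraction predicted correctly), and
the 3×3 confusion table. A label absent from an evaluation corpus is
reported as not applicable and excluded from the mean, with a warning.

Cross-validation is stratified on the class label and shuffled with a
recorded seed (stratification and its seeding are a package choice and
are flagged in the report). When a label has fewer instances than k,
splitting degrades to plain shuffled folds with a warning. Fold
assignment is delegated to scikit-learn.

## Synthetic generator

`GeneratorConfig` defaults define the package's reference test bed,
chosen once:

* **2 classes** (wait_time, staff), so each classifier sees the other
  class's non-neutral sentences as realistic neutral distractors.
  wait_time/x plants a negated construction — a wildcard governor with a
  `neg` dependent and, below it, wait → long — whose recovery pattern is
  `{} >neg {} >> ({word:/wait.*/} > {word:/long.*/})`; wait_time/y plants
  waited → hour; the staff motifs are direct two-word subtrees.
* **n_per_label = 100**: per class, 100 x-motif, 100 y-motif and 100
  neutral sentences — small enough that a 10-fold cross-validation of the
  full pipeline runs in tens of seconds, large enough for stable fold
  statistics.
* **Filler vocabulary**: 1500 deterministic 4-letter pseudo-words (any
  prefix of the shuffled combination table is diverse in leading
  letters), filtered so no filler shares a prefix with a motif word; 5–9
  filler tokens per sentence attached at random with UD-like labels, the
  negation label reserved for motifs. The sparseness is deliberate: as in
  open-vocabulary review text, two specific filler words rarely co-occur,
  so spurious filler patterns generalize weakly.
* **label_noise** flips a sentence's own-class label to one of the other
  two values with the given probability; **motif_dropout** omits the
  motif while keeping the label. Both default to 0.
* Sentence text is the token join of the tree (traceability only; no
  surface realization).

Everything is driven by one `random.Random(seed)`, so corpora are
byte-reproducible.

What passing on this data shows — and what it does not: with clean labels
the pipeline recovers each planted motif at training score 1.0 and
classifies held-out x/y sentences perfectly; measured 10-fold weighted
accuracy is ≈ 0.96 clean and ≈ 0.87 at 10% label noise (the test suite
asserts ≥ 0.95 and ≥ 0.80 at fixed seeds). The residual errors are
neutral sentences caught by low-ranked patterns built from filler words
that happened to enter the information-gain list — the method's real
overprediction weakness, visible here in miniature. None of this bounds
accuracy on real reviews, where paraphrase, parser errors, and correlated
topics replace exact motifs.

## Numerical and degenerate-input choices

* Information gain uses base-2 entropy; 0·log 0 = 0.
* Fewer distinct words than the cap: all are returned. Empty corpora are
  errors everywhere; a class with no x (or y) sentences trains on what
  exists, with a warning; a corpus with only neutral sentences yields an
  empty ranked list and a majority-neutral fallback model.
* Token indices are 1-based (CoNLL-U convention); child order is
  preserved in serialization but carries no matching semantics.
* Model files store full-precision `repr` floats, so save → load → save
  is byte-stable.
* Reference problem sizes: matcher-vs-enumeration equivalence is checked
  on 500 random pairs (trees ≤ 8 nodes, patterns ≤ 4 nodes — small enough
  that exhaustive assignment enumeration is exact and fast); extraction
  soundness on 200 random trees; recovery experiments at n_per_label=100.

## Known limitations

* No tokenizer, sentence splitter, or dependency parser is included;
  inputs are parsed sentences. The external-parser adapter is a callable
  protocol with no bundled implementation.
* Only governor-direction semgrex operators exist; named nodes, optional
  or negated relations, and regex over relation types are out of scope.
* The ranked list is kept whole (optional `top_k` truncation exists but
  defaults to off); with large corpora the list can contain many
  low-value patterns, and classification cost is linear in its length.
* Multi-word expressions are not modeled; seeds are single words.
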