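# Methods

This note documents the models and procedures implemented in `ontoembed`,
the defaults and why they are set where they are, what the synthetic data
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Ontology model

Axioms are normalized logical statements `subject kind object` with
`kind ∈ {SubClassOf, EquivalentTo, DisjointWith}`, a named-class subject
(CURIE `PREFIX:LOCALID`), and objects drawn from named classes, existential
restrictions `R some Y`, and conjunctions. This is the fragment whose
structure the downstream corpora and graphs exploit; richer OWL features
(cardinalities, unions, property chains) are skipped with a warning and
counted in the parse report, because nothing downstream could consume them.

Identity of an axiom is `(kind, subject, canonical object serialization)`;
provenance (`asserted`/`inferred`, source tag) never distinguishes axioms,
and an asserted duplicate wins over an inferred one when sets merge.
Canonicalization sorts conjuncts lexicographically and flattens nested
conjunctions, so parse → serialize → parse is a fixpoint in both supported
dialects (OBO 1.4 subset; a whitespace-tokenized axiom-lines format with
Manchester-like precedence: `some` binds tighter than `and`).

"Membership in an ontology" is decided purely by CURIE prefix: an axiom is
internal to GO when every named class it mentions has prefix `GO`, and it
is a cross-reference to ChEBI when it also mentions a `CHEBI:` class.
Relations are deliberately excluded from that test — `has_participant` is
vocabulary, not ontology membership.

## Saturation

The "inferred axioms" that enrich the corpus come from three rules run to
fixpoint:

* **R1** equivalence expansion: `A ≡ E` yields `A ⊑ c` for each conjunct
  `c` of `E`, plus `B ⊑ A` when `E` is a named class `B`;
* **R2** transitivity of `⊑` over named classes;
* **R3** existential filler lifting: `A ⊑ ∃R.B` and `B ⊑ C` (named) yield
  `A ⊑ ∃R.C`.

The rule set is an EL-style fragment chosen so that expressions never get
deeper: the closure is finite, monotone and idempotent, and cycles in the
hierarchy simply make their members mutual (and self-) subclasses. No
disjointness propagation is performed — the corpus only needs co-occurrence
structure, and consistency checking is a non-goal. Internally R2 uses a
transitive-closure computation on the named-subclass digraph (networkx);
the test suite checks the result against an independent naive
rule-application-to-fixpoint oracle on random ontologies. Equivalence with
any particular production reasoner is not claimed.

## Corpora

The logical corpus contains one sentence per axiom (its canonical token
serialization) and one per annotation `(entity, hasAssociation, class)`.
`hasAssociation` is an arbitrary but fixed vocabulary item; any consistent
token works, it only has to be shared by all annotation sentences.
Sentences are ordered canonically (axioms lexicographically, then
annotations), making corpus construction bit-identical across runs.

The meta-data corpus contains one sentence per selected annotation property
(`label`, `synonym`, `definition` by default, `comment` optional):
the subject CURIE, the property keyword, then the text lowercased and split
on whitespace and `.,;()[]{}"` only. The conservative splitter keeps
hyphenated chemistry tokens such as `-15-hete` or `5'-phosphate` intact,
and CURIE-shaped tokens keep their case so that text mentions of classes
land on the same vocabulary item as the logical corpus.

Annotation files are read as simple TSV (`entity  class  [evidence]`) or
GAF 2.x (column 2 entity, column 5 class, column 7 evidence); rows whose
evidence code is in the exclusion set (typically `{IEA}`) are dropped
before deduplication. Entity identifiers and class CURIEs are disjoint
token spaces — an entity ID may not contain `:` unless it uses the reserved
`ENT:` prefix.

A user-supplied plain-text background corpus can either be appended as
extra sentences or used in a two-phase mode (train on the background first,
then continue on the ontology corpus). Corpus-scale pre-training on real
literature is out of scope; the hook exists so users can bring their own.

## Relational-pattern graph and walks

Axioms involving exactly two named classes map to labeled edges:
`X ⊑ Y` ⟹ `X→Y` (`subClassOf`), `X ⊑ ∃R.Y` ⟹ `X→Y` labeled `R`,
equivalences produce the same edge in both directions, `X disjointWith Y`
⟹ `X→Y` (`disjointWith`), and each annotation adds `entity→class`. Axioms
mentioning any other number of named classes contribute nothing — but
saturation has already decomposed genus–differentia equivalences into
two-class axioms, so little is lost. Named-class equivalences emit the
`subClassOf` edge both ways, consistent with their R1 decomposition.

Walks are standard second-order biased walks: from previous node `t` at
current node `v`, the next candidate `x` is weighted `1/p` if `x = t`, `1`
if `x` is adjacent to `t`, `1/q` otherwise; the first step is uniform.
Three choices deserve a note:

* direction is stored but traversal is undirected — forward-only traversal
  dead-ends at hierarchy roots and starves leaves of context;
* edge labels do not enter the sentences (node sequences only);
* multi-edges collapse to one adjacency entry per node pair, so duplicated
  axioms do not silently re-weight a class.

Defaults `p = q = 1`, walk length 20, 10 walks per node; all configurable,
and all walks are reproducible from the seed.

## Skip-gram embeddings

The trainer is a compact single-threaded skip-gram with negative sampling:
symmetric fixed window (5), unigram^0.75 noise distribution, 5 negatives
per pair, linearly decaying learning rate from 0.025, minibatched SGD over
the (center, context) pair stream, vectors initialized uniform in
±0.5/dimension with zero output vectors. With a fixed seed the resulting
table is bit-identical across runs, which the determinism tests assert.

Three small-corpus adaptations matter and are defaults for a reason:

* **Frequent-token subsampling, t = 5 × 10⁻³.** Axiom sentences repeat a
  handful of keyword tokens (`SubClassOf`, `some`, the annotation relation)
  in nearly every sentence; without downsampling them, every vector aligns
  with the keywords' directions and cosine similarities collapse toward 1.
  The natural-language default (10⁻³) is wrong here: these corpora have
  vocabularies of a few hundred tokens, so *every* token exceeds it and the
  pair stream almost vanishes. The threshold is set so that only the
  keyword hubs are heavily downsampled while classes and entities survive.
* **Dimension 50, 100 epochs.** The corpora this package produces are
  orders of magnitude smaller than literature-scale text; a few hundred
  vocabulary items and a few thousand sentences support neither very high
  dimensions (initialization noise dominates rarely-updated vectors) nor
  few epochs (rare tokens receive too few updates to leave their random
  starting points). These defaults were chosen by measuring downstream
  separation on synthetic studies and are the package's own; nothing in
  them is tied to any external reference setup.
* **All-but-the-top post-processing.** After training, the table is
  centered and its top 6 principal components are removed before cosine
  scoring. Skip-gram tables carry a large shared component that compresses
  cosine similarities; removing the common directions is the standard
  remedy and is exposed as `remove_top_components` (set 0 to disable).

Because run-to-run variance of skip-gram on small corpora is visible in
downstream AUCs, the pipeline trains 3 independently seeded restarts per
corpus and averages the per-pair scores ("embedding_restarts", default 3).
This stabilizes the similarity estimate without touching what is measured.

Vectors persist in the word2vec text format (`<vocab> <dim>` header, one
token per line, 17 significant digits), and `load(save(T)) = T` up to float
formatting. `min_count` defaults to 1 so that every entity and class is
embedded; a token below the threshold is absent from the table and lookups
fail loudly rather than silently back-filling.

## Pair prediction

Positive pairs come from a two-column list; negatives are sampled uniformly
without replacement from the non-positive, non-self unordered pairs at a
1:1 ratio by default (configurable); the 70/30 split is stratified by label
and performed at the pair level, so an entity may appear on both sides —
that matches the stated experimental procedure, and an entity-disjoint
split was deliberately not made the default (fidelity first; the stricter
protocol can be built from the same pieces). Sampling and splitting are
deterministic given the seed.

The supervised scorer is a feed-forward network with hidden layers (800,
200), ReLU activations, sigmoid output, binary cross-entropy, adam at
10⁻³, batch 64, 20 epochs (scikit-learn `MLPClassifier` underneath; the
fixed epoch budget means its convergence warning is expected and
suppressed). Pairs are unordered, so each training pair is presented in
both concatenation orders and inference averages the two order scores,
making the scorer exactly symmetric. Scoring never reads test labels; the
test suite includes a permuted-label canary asserting that shuffled train
labels drive test AUC to chance.

## Evaluation

AUC is computed from midranks — exactly the pairwise-counting definition
with ties half-weighted — and the ROC curve from the sorted unique
thresholds; the brute-force double loop lives in the tests as an
independent oracle. The Mann–Whitney U test uses the exact null
distribution when `n_a·n_b ≤ 400` and the pooled sample is tie-free, and
the tie- and continuity-corrected normal approximation otherwise. The
U–AUC identity `U/(n_a·n_b) = AUC` holds exactly because both sides share
the same tie convention.

Model-vs-model comparison implements both defensible readings of a
"Mann–Whitney comparison of two scorers": an MWU between the two models'
scores on positive pairs, and a label-stratified paired bootstrap over
pairs for ΔAUC (1000 resamples by default); results name the method used.
Across seeds, the harness uses a paired one-sided t-test on the per-seed
deltas — deltas across generator seeds are approximately normal, and with
~10 replicates the t-test is the natural paired choice. No multiple-testing
correction is applied across ablation rows by default (raw p-values are
reported); a Benjamini–Hochberg pass can be applied by the caller.

## Ablation harness

One run holds the annotation set, positive pairs, sampled negatives and
split assignments byte-identical across variants (asserted by hashing the
serialized dataset) and varies only the ontology handed to the encoder:
`base`, `plus`, `plus-ns:<PREFIX>` (base-internal axioms plus
cross-references into one namespace), `plus-external` (full external axiom
sets merged in), `plus-metadata` (meta-data corpus included),
`substitute:<PREFIX>` (sub-ontology of a host replaced by the enriched
set). Embeddings are retrained from scratch per variant — the corpus
changes, so vector reuse would leak one variant into another. A generic
two-column ID map can translate pair endpoints (many-to-many, cartesian
expansion, unmapped endpoints drop the pair and are counted).

## Synthetic studies

The generator builds the one causal structure the ablation is meant to
detect: entity interactions whose signal flows through inter-ontology
links.

* The primary ontology is a random rooted tree (node *i*'s parent uniform
  over earlier nodes). Leaves are dealt round-robin, in branch order, into
  `n_modules` modules — consecutive leaves of a branch land in different
  modules, so each module's members scatter across branches and are distant
  in the hierarchy. Module membership is therefore *invisible* in the
  primary ontology.
* Each leaf is bridged to its module's class in a small external tree with
  probability ρ: `leaf SubClassOf related_to some EXT:k`. (`related_to` is
  a placeholder relation; the motif being modeled does not depend on the
  relation's name.)
* Entities annotate `annotations_per_entity` distinct leaves; an unordered
  pair is positive with probability π₁ if the two entities touch leaves
  bridged to a common external class and π₀ otherwise. π₀ > 0 keeps the
  task noisy and AUC meaningfully below 1.
* Labels are always planted: with the signal on, every module member's
  label contains a module-specific marker word among noise words; with
  `signal='none'` labels are pure noise. The null comparison is therefore
  "labels present but uninformative" rather than "no labels".

Defaults: 300 entities, 120 primary classes, 8 external classes, 8
modules, 3 annotations per entity, ρ = 0.9, π₁ = 0.35, π₀ = 0.03. With
these settings an indicator oracle that knows each entity's bridged
modules reaches AUC ≈ 0.72 — the ceiling any encoder can approach — while
the base pipeline sits near 0.52 (a small residue from entities sharing
identical leaves), leaving a wide window in which the bridge-axiom effect
is measurable.

What the generator does *not* emulate: realistic GO topology or depth
distributions, annotation-count skew, evidence-code semantics, STRING
score calibration, or literature-scale meta-data. Passing tests show the
pipeline detects background-knowledge effects with the intended causal
structure at desk scale; they do not certify effect sizes on real corpora.

## Problem sizes and runtime

The standard study (defaults above) yields ≈ 45 000 candidate pairs,
≈ 10 000 positives, corpora of ≈ 1 500 sentences and vocabularies of ≈ 500
tokens. The headline experiments run 10 study replicates per arm; one
replicate (two variants, 3 embedding restarts each, cosine scoring) takes
≈ 15 s on one CPU, so each ablation completes in a few minutes. These sizes
were chosen as the smallest at which the module structure is statistically
comfortable, not as approximations of any real dataset's scale.

## Known limitations

* Saturation is deliberately incomplete relative to OWL-DL semantics
  (no role hierarchies, no disjointness reasoning, no nominals); it
  captures hierarchy completion, which is what co-occurrence encoders use.
* The OBO writer covers the parsed subset only; saturated sets containing
  nested existentials or non-conjunctive equivalences must round-trip
  through the axiom-lines format instead.
* Cosine scoring reads geometry only; entities with identical annotation
  sets are indistinguishable by construction.
* The NN scorer's determinism holds for single-threaded execution with a
  fixed seed; across BLAS builds bit-identity is not guaranteed.
* Walk generation is pure-Python and fine for desk-scale graphs; very
  large ontologies would want a compiled walker.
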