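# Methods

## The extraction task

A reaction paragraph in a chemical patent describes one synthesis example: a
heading ("EXAMPLE 48"), the compounds involved, the actions performed on them,
and the conditions and outcome.  The package extracts this as a typed graph:

* **Entity mentions**, one of 12 labels.  Ten are semantic roles —
  EXAMPLE_LABEL, STARTING_MATERIAL, REAGENT_CATALYST, REACTION_PRODUCT,
  SOLVENT, TIME, TEMPERATURE, YIELD_PERCENT, YIELD_OTHER, OTHER_COMPOUND —
  and two are event triggers: REACTION_STEP (the synthesis action) and
  WORKUP (washing, drying, purification, isolation).  The alternative
  spellings REACTION_SETUP and WORK_UP are accepted on input and normalized.
* **Relation mentions** from a trigger to a role: ARG1 when the argument is a
  compound-type role (starting material, reagent/catalyst, product, solvent,
  other compound), ARGM when it is auxiliary (time, temperature, either yield
  type).  Because the relation label is fully determined by the argument's
  role type, relation extraction reduces to a *binary* accept/reject decision
  per candidate pair plus a deterministic label assignment.

Annotations use BRAT-style standoff files (`T` lines for entities, `R` lines
for relations) with 0-based, half-open offsets counted in Unicode code
points.  In an `R` line the `Arg1:` slot always holds the trigger and `Arg2:`
the role argument.  Discontinuous spans are rejected: the scheme uses
contiguous mentions only.

## Two-stage tokenization

Chemical names and numeric expressions are the reason general-purpose
tokenizers fail on this genre.  Stage one treats **every** punctuation
character (any non-alphanumeric, non-whitespace code point — hyphens,
brackets, commas, decimal points, `%`, `°`, underscore) as a token separator,
so `6.5 mg` → `6 / . / 5 / mg` and a bracketed IUPAC name decomposes into a
fully predictable alternation of alphanumeric runs and single punctuation
marks.  Splitting decimal points is a deliberate uniformity choice: one rule,
no exception list, consistent output for the boundary detector to learn from.
Stage two decomposes each token into word pieces from a vocabulary by greedy
longest-prefix-first matching, continuation pieces carrying a leading `##`;
a token with no decomposition maps to the single unknown marker `[UNK]`.
Greedy (rather than likelihood-optimal) segmentation is intentional — it is
the behavior of the WordPiece family this stage stands in for.

Because no pretrained word-piece inventory ships with the package, the
vocabulary is induced from the training corpus: all observed single
characters (in both initial and continuation form — this guarantees zero
unknowns on in-corpus text) plus the most frequent character n-grams
(length 2–6) up to `max_size` (default 2000), ties broken lexicographically
so the result is deterministic.

Sentence segmentation is rule-based: terminators are `.`, `!`, `?` followed
by whitespace, plus the newline (headings sit on their own lines).  A guard
list of abbreviations ({sat., aq., approx., conc., vs., e.g., i.e., no.,
fig.}) suppresses the period terminator; "sat." and "aq." are the
load-bearing entries, because splitting "washed with sat. aq. NH4Cl" detaches
the chemical from its clause.  The sentence-merge rule (below) remains as a
safety net for pre-segmented input that arrives already split.

## Named entity recognition

Roles and triggers are recognized **jointly** by one BIO tagger over 25
states (O plus B/I for each of the 12 labels).  Entities must align to token
boundaries — with the punctuation separator this holds by construction, and a
misaligned gold span fails loudly by default (an opt-in `snap_spans` widens
spans outward instead).  Decoding is lenient: a dangling `I-` tag is repaired
as `B-`.

The tagger backend is a pluggable contract (`register_tagger_backend`); a
transformer can be dropped in without touching the pipeline.  The default
backend is a **linear-chain averaged structured perceptron**: emission scores
are sums of per-feature weight vectors (token surface, lowercase, compressed
character-shape, 2–4 character prefixes and suffixes, punctuation flag,
lowercased neighbors and shapes in a ±2 window, and left/right bigram
conjunctions), transition scores are a dense matrix including a
sentence-start state, and decoding is exact Viterbi.  Label identity inside a
long chemical name is carried by the transition weights (the B- decision is
made at the boundary, where context is visible, and propagated by I-to-I
transitions), which is why a chain model rather than an independent per-token
classifier is needed here.  Training shuffles sentences with a seeded
generator each epoch (default 8 epochs) and is exactly reproducible; models
serialize to a single versioned JSON file, byte-identical across runs with
the same seed and data.

For the transformer configuration the pipeline config records the reference
hyperparameters (dropout 0.2, max sequence length 310, hidden dim 128,
learning rate 5e-5, batch size 24) as documentation defaults; no weights
ship.

Ensemble voting over k prediction sets keeps an entity (identified by
label + span) iff it appears in **strictly more than k/2** sets — the
conservative reading of unqualified "majority voting" — then resolves
overlapping survivors by vote count, earlier start, longer span.

## Relation extraction

Candidates are the Cartesian product of triggers × roles within each
sentence; EXAMPLE_LABEL mentions are excluded (never a relation argument in
the scheme).  Each candidate is represented by the sentence's token sequence
with **every** entity mention collapsed to a single token equal to its label
name — masking all mentions, not only the focus pair, is the consistent
reading of type-generalization and maximizes transfer across lexical
variants.  Since the masked sequence is therefore identical for all
candidates of one sentence, the classifier additionally receives the focus
positions: features are the bag of masked tokens, the bag of tokens between
the pair, the trigger surface, trigger and argument label, token distance
(raw and bucketed), and pair order.  The default backend is an L2-regularized
logistic regression (C=10, liblinear, seeded); weights are exported to plain
JSON so serialization is byte-stable.  Training uses all non-annotated
candidates as negatives — no subsampling, since candidate sets are small at
sentence scale.  Accepted candidates become relations labeled by the
deterministic ARG1/ARGM assignment.  Cross-sentence relations are out of the
classifier's reach by design and are handled only by rules.

## Postprocessing rules

All rules are deterministic, idempotent, individually switchable, and emit
one machine-replayable `RuleTrace` per modification.

1. **Heading relabeling.**  When a top-level example heading is followed by a
   sub-step heading (`<n>.<m> ...`), the snippet's topic is the sub-step:
   product-labeled compounds in the top-level heading region are relabeled
   OTHER_COMPOUND, and compounds on the sub-step heading line receive the
   product label.  Heading detection is a line starting with
   EXAMPLE/Example/Step plus an identifier, or a bare identifier line —
   patent layout gives no formal grammar, so this is a pragmatic definition.
2. **Example-label trimming.**  Lead words ("reference example", "example",
   "step", "intermediate", "core") and the three bracket kinds `()[]{}` are
   stripped from EXAMPLE_LABEL spans by shrinking offsets ("Example 95" →
   "95").  A trim that would empty the span is refused with a warning trace.
3. **Compound-prefix trimming.**  "compound", "example", "immediate" are
   stripped from compound mentions whose remainder matches the identifier
   pattern `[0-9][0-9A-Za-z-]*` ("compound 1-0003" → "1-0003",
   "Example 56A" → "56A"); purely verbal names are untouched.
4. **sat.-aq. merge and link.**  A sentence ending in "sat. aq." followed by
   a sentence starting with a chemical mention is re-merged; then the
   chemical behind "sat. aq." is linked to an event trigger earlier in the
   clause, unless the chemical already participates in a relation.  The
   trigger choice is a strategy switch: `nearest` (default — nearest
   preceding trigger by distance, the stated rule) or `clause-head` (first
   trigger of the clause).  The two can disagree on clauses like "dissolved
   in X and washed with sat. aq. Y", which is precisely why the switch
   exists.
5. **Yield-sentence linking.**  A sentence matching `Yield:` containing yield
   mentions gets ARGM relations from the last trigger of the previous
   sentence to each yield mention; a missing previous trigger produces a
   warning trace, not a relation.

Span-trimming rules only ever shrink spans.  Replaying a trace list against
the pre-rule document reproduces the post-rule document exactly (tested).

## Evaluation

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), all defined as
0 when the denominator is 0.  **Exact** entity matching requires identical
label and span; **relaxed** requires identical label and ≥1 character of
overlap (label equality in relaxed mode follows the convention of the shared
task the scheme comes from).  Matching is one-to-one, greedy by largest
overlap then earliest span — deterministic and, on realistic prediction
patterns, equal to the maximum-bipartite-matching optimum (asserted against a
`scipy` matching oracle on generated cases; contrived many-to-many overlap
patterns are the only place greedy can fall short).  Relation matching
requires equal relation labels and both endpoints matching under the chosen
entity mode; counts are grouped by `LABEL|TRIGGER_TYPE|ARGUMENT_TYPE`.
For any fixed prediction set, relaxed TP ≥ exact TP, hence relaxed F1 ≥
exact F1.

End-to-end scoring evaluates relations predicted over *pipeline* entities,
so entity errors propagate: end-to-end relation F1 cannot exceed relation F1
computed on gold entities when the same relation rules are applied in both
runs (tested as the cascade property).

## Synthetic corpus generator

The generator emulates the phenomena the system is built around, not the
statistics of real patent prose.  Each document has an example heading with
an EXAMPLE_LABEL identifier; a setup sentence (starting material, solvent,
REACTION_STEP trigger, temperature, time); optionally a reagent sentence
whose second trigger takes no arguments (hard negatives for the classifier);
a workup sentence with two WORKUP triggers each governing their own compound
(cross-pair negatives); and a product sentence with yields.  Compound names
are built compositionally from locants, hyphens, brackets and ring/suffix
morphemes ("7-bromo-4-(pyridin-2-yl)-..."), exercising the punctuation
tokenizer; they are drawn from per-role lexicons of 30 names generated once
per corpus, and make no claim of chemical validity.

Three document-level phenomena appear at configured rates, chosen so any
moderate corpus exercises every rule: sub-step headings (fraction 0.3),
"sat. aq." workup clauses (0.2), and separate "Yield: ..." sentences (0.3).
Only yield-sentence documents carry cross-sentence gold relations — exactly
the gap the yield-linking rule closes, which makes the rules load-bearing for
end-to-end recall rather than decorative.  Corpora are split 0.6/0.15/0.25
into train/dev/test directories.  Generation is deterministic under the
config seed.

**What passing on this data shows — and what it does not.**  The templated
language is separable by surface features, so high synthetic scores
demonstrate that the pipeline's plumbing (tokenization, alignment, encoding,
candidate generation, rules, scoring) is correct end to end, and that the
default backends can learn the mapping when the signal is present.  They say
nothing about performance on real patent text, whose lexical diversity,
annotation noise and long-range structure the generator deliberately does
not model; real-corpus performance is the province of the pluggable
transformer backends.

## Problem sizes and defaults

The shipped experiments train the default backends on 500 generated
documents (≈3000 sentences) and evaluate on 167 held-out documents from the
same generator run — large enough that every label and rule fires many
times, small enough that the full suite trains in well under a minute on one
CPU.  Key defaults: tagger epochs 8, vocabulary size 2000, classifier
threshold 0.5, majority threshold strictly > k/2, relaxed overlap ≥ 1
character.

## Known limitations

* The default backends are surface-feature models; they are stand-ins wired
  to the same contracts a transformer backend would implement, not
  competitive models for real patents.
* Greedy matching is not provably optimal on adversarial overlap patterns.
* Heading detection is heuristic; unusual patent layouts may not trigger the
  relabeling rule.
* Word-piece induction is frequency-based, not likelihood-based; no
  subword-pooling question arises because the default tagger predicts per
  punctuation-level token.
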