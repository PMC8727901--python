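# chemrext

Information extraction for chemical reactions described in patent text.
Given a reaction paragraph, the package recovers a typed event graph:
entity mentions in 12 classes — 10 semantic roles (EXAMPLE_LABEL,
STARTING_MATERIAL, REAGENT_CATALYST, REACTION_PRODUCT, SOLVENT, TIME,
TEMPERATURE, YIELD_PERCENT, YIELD_OTHER, OTHER_COMPOUND) plus 2 event
triggers (REACTION_STEP, WORKUP) — and directed trigger→role relations,
ARG1 for compound arguments and ARGM for auxiliary ones (time, temperature,
yield).  It is aimed at cheminformatics and text-mining practitioners who
need a complete, testable reference pipeline for the patent-reaction
extraction task, with every stage replaceable by stronger learned backends.

The pipeline is a classic cascade:

1. **Preprocessing** — rule-based sentence segmentation with an
   abbreviation guard, then two-stage tokenization: every punctuation
   character is a token separator, followed by greedy longest-prefix word
   piece alignment against a vocabulary (`##` continuation pieces).
2. **NER** — one joint BIO tagger over all 25 states (O + B/I × 12 labels).
   Default backend: a linear-chain averaged structured perceptron over
   surface features with Viterbi decoding; the backend is a pluggable
   contract.  Majority-vote ensembling over several seeds is built in.
3. **Relation extraction** — same-sentence trigger×role candidate pairs,
   each represented by the sentence with every entity mention replaced by
   its type name; a binary classifier (default: seeded logistic regression)
   accepts pairs, and ARG1/ARGM follows deterministically from the
   argument's role:  P(accept) ≥ τ ⇒ link, label = ARGM iff role ∈
   {TIME, TEMPERATURE, YIELD_OTHER, YIELD_PERCENT}.
4. **Rules** — deterministic postprocessing with full audit traces:
   heading-based compound relabeling, span trims ("Example 95" → "95",
   "compound 1-0003" → "1-0003"), re-merging sentences wrongly split at
   "sat. aq." plus trigger-chemical linking, and linking separate
   "Yield: …" sentences to the previous sentence's trigger.
5. **Evaluation** — exact (label + identical span) and relaxed (label +
   overlap) one-to-one matching with per-type and overall precision,
   recall and F1:  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

Documents and annotations use BRAT-style standoff (`<id>.txt` / `<id>.ann`,
tab-separated `T`/`R` lines, 0-based half-open code-point offsets).  A
deterministic synthetic-corpus generator produces annotated reaction
paragraphs exhibiting all of the above phenomena, so the whole system
trains and evaluates without any external data.

## Worked example

The tokenizer on a bracketed chemical name heading:

```python
>>> import chemrext as cx
>>> text = "7-Bromo-4-(pyridin-2-yl)-3,4-dihydro-2H-benzo(b) (1,4)oxazine (1)"
>>> "/".join(t.surface for t in cx.tokenize_punct(text))
'7/-/Bromo/-/4/-/(/pyridin/-/2/-/yl/)/-/3/,/4/-/dihydro/-/2H/-/benzo/(/b/)/(/1/,/4/)/oxazine/(/1/)'
```

Every hyphen, bracket and comma is its own token (35 tokens here), so
entity boundaries always coincide with token boundaries and the sequence
model only has to learn where runs begin and end.

The full cascade from the command line:

```
$ chemrext run-all --work-dir demo_run
ner_exact: P=0.9840 R=0.9933 F1=0.9886
ner_relaxed: P=0.9906 R=1.0000 F1=0.9953
end_to_end_exact: P=1.0000 R=1.0000 F1=1.0000
end_to_end_relaxed: P=1.0000 R=1.0000 F1=1.0000
```

This generates a 200-document synthetic corpus, splits it 0.6/0.15/0.25,
trains the vocabulary, tagger and relation classifier on train+dev, runs
the cascade over the test texts, and scores predictions against gold in
both matching modes.  The four lines report overall precision/recall/F1
for entity recognition and for end-to-end relation extraction (relations
scored over *predicted* entities, so entity errors propagate).  Artifacts
land in `demo_run/`: the standoff predictions, e.g.

```
T1	EXAMPLE_LABEL 8 11	336
T2	STARTING_MATERIAL 26 65	5-(benzylmethyl)-thiazol-6(3H)-benzoate
T4	REACTION_STEP 81 87	heated
...
R1	ARG1 Arg1:T4 Arg2:T2
```

plus serialized models, a manifest with the config hash and seeds, and
per-type JSON reports.  `chemrext generate / train / predict / evaluate`
expose the individual stages; `--config file.yaml` overrides any default.
All randomness is seeded: the same config reproduces the same corpus,
models and scores bit for bit.

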