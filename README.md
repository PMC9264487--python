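# dsqa — question answering for dietary-supplement consumers

Consumers take vitamins, botanicals and other dietary supplements (DS)
without prescriptions, and the information about their efficacy, safety and
drug interactions is scattered and uneven.  `dsqa` is a task-oriented
question-answering toolkit for this domain: it classifies a consumer
question into one of eight intents, extracts the supplement / disease /
medication mentions, links them into a triple-store supplement knowledge
base, and renders a slot-filled natural-language answer.

It is aimed at biomedical-NLP practitioners who want a hermetic, fully
testable reference implementation of this pipeline — every component is
plain Python on numpy/scipy/scikit-learn, and a synthetic-data module
generates knowledge bases and annotated corpora with the statistical
structure the pipeline assumes.

## The pipeline

1. **Question-type classification.**  Eight intents (Availability,
   AdverseEffects, Background, Effectiveness, Indication, Interaction,
   Safety, Usage).  Two models:
   * a mean-embedding + multinomial logistic-regression baseline, and
   * a convolutional network over frozen word embeddings: parallel 1-D
     convolutions of widths (1, 2, 3, 5), per-filter max-pooling over time,
     concatenation, dropout, dense softmax.
2. **Named-entity recognition.**  BIO tagging over four entity types (DS,
   DIS, MED, MISC).  Two sequence models: an add-k smoothed HMM with
   Viterbi decoding, and a linear-chain CRF with window ±2 indicator
   features trained by L-BFGS; both use constrained decoding, so emitted
   tag sequences are always BIO-valid.
3. **Knowledge base.**  An in-process triple store read from pipe-delimited
   (RRF-convention) concept/relation/attribute files: 7 concept types
   (SDSI, DSP, DIS, SPD, SOC, SS, TC) and 6 relations with fixed type
   signatures (e.g. `SDSI is_effective_for DIS`), compiled into one JSON
   index per relation.  Entity linking is exact case-insensitive match,
   then fuzzy normalized-edit-similarity match against a threshold.
4. **Answer generation.**  The question type selects the relation(s) or
   attribute to query; a per-type sentence template is filled with the
   retrieved strings (see `src/dsqa/templates.cfg`), e.g.
   `{DS} is effective for {disease}` or
   `Here is what I found about {DS}: {safety}`.
5. **Evaluation metrics.**  For judged responses graded 1–4:
   average score = mean(grade − 1) ∈ [0, 3], succ@i+ = |{grade ≥ i}|/N,
   and response error rate RER = |{grade = 1}|/N = 1 − succ@2+.
   Inter-annotator agreement uses Fleiss' κ = (P̄ − P̄e)/(1 − P̄e).

## Worked example

```python
from dsqa import fixtures, kb
from dsqa.answers import route_question, render_answer

store = fixtures.toy_store("scratch/toy")          # frozen worked-example KB
indices = kb.build_relation_indices(store)

plan = route_question("Effectiveness", [("shark cartilage", "DS")], store)
print(render_answer(plan, store, indices).text)

plan = route_question("Safety", [("melatonin", "DS")], store)
print(render_answer(plan, store, indices).text)
```

prints

```
Shark Cartilage is effective for Degenerative Polyarthritis
Here is what I found about pure crystalline Melatonin: Melatonin may cause drowsiness. Patients should not drive or operate heavy machinery until familiar with the effects of melatonin
```

The first line shows the `is_effective_for` relation filled into the
Effectiveness template with the *stored* preferred names (the user wrote
"shark cartilage"; linking resolved it).  The second shows a Safety answer
drawn from the concept's free-text safety attribute — the display name is
the knowledge base's preferred term, "pure crystalline Melatonin", not the
user's surface form.

The full chain (classify → tag → link → query → render) is one call:

```python
from dsqa.pipeline import answer_question
trace = answer_question("Is it safe to take melatonin?", clf, tagger, store, indices)
print(trace.qtype, trace.entities, trace.answer.text)
```

A command-line interface mirrors the lifecycle:

```bash
dsqa gen-fixtures --seed 42 --out fx/           # synthetic KB + corpus
dsqa build-kb --concepts fx/concepts.psv --relations fx/relations.psv \
              --attributes fx/attributes.psv --out fx/indices
dsqa train-classifier --corpus fx/corpus.jsonl --kind cnn --seed 42 --out fx/clf.npz
dsqa train-ner --corpus fx/corpus.jsonl --model crf --seed 42 --out fx/ner.npz
dsqa ask "Does Niacin really work?" --config config.json
```

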