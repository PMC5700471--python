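# phenorec

Phenotype concept recognition for biomedical abstracts: a linear-chain CRF
sequence labeler over a rich token feature set, followed by a validation
stage that combines an ontology-derived dictionary with hand-crafted
identification and removal rules.  The package also provides corpus I/O for
offset-annotated gold corpora, exact-span evaluation, a false-positive
filter experiment, gold-corpus extension tooling, an annotation
inconsistency report, and a synthetic fixture generator so everything is
testable fully offline.

## Layout

| module | role |
| --- | --- |
| `phenorec.corpus` | read/write offset-annotated corpora, OBO ontology loading, corpus diffing |
| `phenorec.preprocess` | sentence splitting, tokenization, Penn POS tagging, lemmatization (offset-preserving, pluggable backend) |
| `phenorec.features` | six feature families (linguistic, orthographic, morphological, context, lexical, other) + BIO encode/decode |
| `phenorec.brown` | greedy agglomerative Brown clustering trained on corpus text |
| `phenorec.crf` | from-scratch linear-chain CRF (l2sgd / L-BFGS), model persistence, k-fold plans |
| `phenorec.lexicon` | validation dictionary, term-variation generation, word lists, exact dictionary matching |
| `phenorec.rules` | identification rules (dictionary, head-noun structures, boundary expansion, coordination splitting, second pass) and removal rules (general errors, structure, negative connotation, stop lists) |
| `phenorec.evaluate` | micro exact-span P/R/F, false-positive filter, corpus extension, inconsistency report |
| `phenorec.fixtures` | deterministic synthetic ontology/corpus/word-list generator with a phenomenon ledger |
| `phenorec.pipeline` | cross-validated end-to-end runs with leakage-free per-fold dictionaries |

## CLI

```sh
# generate a synthetic corpus + ontology + word lists
phenorec fixtures --out fix/ --seed 4 --n-docs 8 --n-terms 10

# cross-validated train/predict/validate/score, with ablation switches
phenorec run --docs fix/docs --anns fix/anns --obo fix/ontology.obo \
    --word-lists fix/word_lists --k 2 --out results.json
phenorec run ... --features linguistic,morphological --rules identification
phenorec run ... --rules none --no-validation          # raw CRF output

# scoring, diffing, corpus extension, consistency audit
phenorec score --docs fix/docs --gold fix/anns --pred pred/
phenorec diff --docs fix/docs --old fix/anns --new new_anns/ --out diff.tsv
phenorec extend --docs fix/docs --anns fix/anns --pred pred/ \
    --obo fix/ontology.obo --out-anns extended/
phenorec inconsistencies --docs fix/docs --anns fix/anns --obo fix/ontology.obo
```

Corpus layout: one single-line `*.txt` per abstract in the documents
directory, and one annotation file per abstract (same stem) with lines like

```
[27::42] HP_0000110 | renal dysplasia
```

(0-based half-open character offsets; accession; surface text).

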