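# reportal

Active-learning information extraction for clinical free-text reports.

Clinical NLP teams that need named-entity recognition (NER) and relation
extraction (RE) on radiology reports — or similar clinical documents in a
low-resource language — face an annotation bottleneck: labeling requires
medical experts, and most sentences in a report archive are short, routine
and uninformative. `reportal` implements the full annotate–train–query
workflow around an *intrinsic* acquisition function, so that each round of
expert annotation is spent on the most informative sentences without ever
needing a task model's uncertainty estimates:

- **Corpus handling** — brat-standoff (.txt/.ann) reading and writing with
  strict offset checking, report sectioning (findings / impression /
  history / comparison), pluggable sentence splitting, and validation
  against a general radiology annotation schema (20 entity classes, 15
  undirected relation classes with argument rules).
- **Sample encoding** — IOB tag sequences for NER; for RE, every sentence
  with $k$ entities yields all $\binom{k}{2}$ unordered entity pairs,
  annotated pairs keeping their label and the rest auto-labeled
  `no_relation`, with configurable positive oversampling on the train
  split only.
- **Acquisition** — pseudo-perplexity scoring under a masked language
  model,

  $$\mathrm{PPL}(X) = \exp\Big(-\tfrac{1}{n}\sum_{i=1}^{n} \log p_\theta(x_i \mid X_{-i})\Big),$$

  and *strategic sampling*: drawing annotation batches from the
  intersection of the upper 75–90% percentile bands of PPL and sentence
  length — surprising and content-rich, but not outliers.
- **The active-learning cycle** — random seed annotation, batch proposal
  with model pre-annotations (*soft labels*, shown to the annotator for
  correction and never trained on directly), retraining on the full
  corrected set, stopping on a held-out metric.
- **Evaluation** — strict-span entity-level macro-F1, RE macro-F1 over the
  pair universe, per-batch diagnostics (entities per sentence, class
  histograms), Cohen's kappa for annotator agreement.
- **Synthetic corpora** — a schema-consistent pseudo-clinical generator
  (Zipf vocabularies, minority classes concentrated in long sentences,
  controllable cross-domain overlap) plus an oracle annotator, so every
  stage runs and is tested without any clinical data.

Model backends are pluggable contracts (masked LM, sequence tagger,
relation classifier). The shipped reference backends — a smoothed unigram
masked LM and linear classifiers over hashed features — run the whole loop
in seconds on one CPU; transformer adapters can be registered behind the
same contracts.

## Worked example

A sentence with six annotated entities and four annotated relations yields
$\binom{6}{2} = 15$ relation samples — 4 positive, 11 `no_relation`; with
four-fold positive oversampling the train split becomes $16 + 11 = 27$
samples (a test split is never oversampled). `examples/02_sample_encoding.py`
prints this arithmetic on a generated sentence.

Strategic versus random batch selection on the default 2,000-sentence
synthetic corpus (`examples/03_pseudo_perplexity.py`):

```
strategic batch:  17.2 tokens, 7.58 entities per sentence
random batch:     11.8 tokens, 3.47 entities per sentence
```

The strategic batch concentrates annotation effort on long, surprising
sentences carrying roughly twice the entities per sentence. Running the
simulated cycle (`examples/04_active_learning.py`) shows the effect on the
learning curve — entities per batch jump when the schedule switches to
strategic sampling at iteration 3, and held-out macro-F1 climbs with it:

```
iter   strategy ents/sent soft-acc  NER F1   RE F1
   1     random      2.77     0.95   0.665   0.918
   2     random      3.20     0.92   0.862   0.812
   3  strategic      6.88     0.94   0.839   0.895
   4  strategic      4.42     0.97   0.875   0.903
   5  strategic      3.98     0.99   0.909   0.904
```

`examples/05_domain_transfer.py` demonstrates warm-started domain
adaptation: a tagger pre-trained on a source domain and fine-tuned on 200
target sentences beats a cold-started one, the more so the closer the
domains.

## Command line

A thin CLI wraps the library for shell use:

```bash
reportal synth --n-sentences 500 --seed 1 --out corpus/   # synthetic standoff corpus
reportal validate corpus/                                  # schema validation
reportal encode corpus/ --task ner --out ner.tsv           # CoNLL IOB export
reportal sample corpus/ --strategy strategic --batch 100 --seed 1
reportal simulate --n-sentences 800 --iterations 8 --out curve.csv
```

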