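"""Encode an annotated sentence for NER (IOB tags) and RE (entity pairs).

A sentence with k entities yields C(k, 2) relation samples: annotated
pairs keep their label, every other pair is auto-labeled no_relation.
With six entities and four annotated relations that is 15 samples, 4
positive and 11 negative; four-fold positive oversampling turns the train
split into 16 + 11 = 27 samples while a test split is left untouched.
"""

from reportal import (
    SynthConfig,
    build_pool,
    default_schema,
    generate_corpus,
    generate_relation_samples,
    oversample_positives,
    spans_to_iob,
)
from reportal.schema import NO_RELATION

schema = default_schema()
pool = build_pool(generate_corpus(SynthConfig(n_sentences=50, seed=4)))
item = max(pool.values(), key=lambda it: len(it.entities))

iob = spans_to_iob(item.sentence, list(item.entities))
print("tokens:", " ".join(iob.tokens))
print("tags:  ", " ".join(iob.tags))

samples = generate_relation_samples(item.sentence, list(item.entities), list(item.relations), schema)
k = len(item.entities)
n_pos = sum(s.label != NO_RELATION for s in samples)
print(f"{k} entities -> {len(samples)} pair samples = C({k},2); {n_pos} positive")

train = oversample_positives(samples, factor=4, split="train")
print(f"after 4x positive oversampling: {len(train)} train samples "
      f"({sum(s.label != NO_RELATION for s in train)} positive, "
      f"{sum(s.label == NO_RELATION for s in train)} negative)")
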