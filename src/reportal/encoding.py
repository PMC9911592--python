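"""Sample encoding: IOB sequences for NER and entity-pair samples for RE.

NER training uses the IOB (Inside-Outside-Beginning) tagging scheme: the
first token of an entity of class ``c`` is tagged ``B-c``, subsequent tokens
``I-c``, everything else ``O``. RE training enumerates every unordered pair
of distinct entities within a sentence — C(k, 2) pairs for k entities —
labeling annotated pairs with their relation class and all remaining pairs
``no_relation``. Positive pairs may be oversampled on the train split to
counter the dominance of the negative class; the test split is never
oversampled so that evaluation reflects the true label distribution.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

from .corpus import EntitySpan, SentenceRecord
from .schema import NO_RELATION, SchemaDef


class AlignmentError(ValueError):
    """Entity span does not align with token boundaries."""


@dataclass(frozen=True)
class IOBSequence:
    """Tokens of one sentence with aligned IOB tags."""

    sent_id: str
    tokens: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{self.sent_id}: {len(self.tokens)} tokens but {len(self.tags)} tags"
            )


@dataclass(frozen=True)
class RelationSample:
    """One candidate entity pair, offset-ordered (e1 before e2), with its label."""

    sent_id: str
    e1: EntitySpan
    e2: EntitySpan
    label: str
    split: str = "train"
    copy_index: int = 0  # >0 marks an oversampled duplicate

    def __post_init__(self) -> None:
        if (self.e1.start, self.e1.end) > (self.e2.start, self.e2.end):
            raise ValueError(f"{self.sent_id}: e1 must precede e2 in offset order")
        if self.e1.id == self.e2.id:
            raise ValueError(f"{self.sent_id}: pair must use distinct entities")


def spans_to_iob(sentence: SentenceRecord, entities: list[EntitySpan]) -> IOBSequence:
    """Encode entity spans over a sentence as an IOB tag sequence.

    Every entity must start and end exactly on token boundaries; a
    misaligned span raises :class:`AlignmentError` rather than being
    silently clipped (clipping would corrupt the round trip).
    """
    starts = {t.start: i for i, t in enumerate(sentence.tokens)}
    ends = {t.end: i for i, t in enumerate(sentence.tokens)}
    tags = ["O"] * len(sentence.tokens)
    for ent in sorted(entities, key=lambda e: (e.start, e.end)):
        if ent.start not in starts or ent.end not in ends:
            raise AlignmentError(
                f"{sentence.sent_id}: entity {ent.id} [{ent.start},{ent.end}) does not align "
                "with token boundaries"
            )
        first, last = starts[ent.start], ends[ent.end]
        for i in range(first, last + 1):
            if tags[i] != "O":
                raise AlignmentError(
                    f"{sentence.sent_id}: entity {ent.id} overlaps an already tagged token"
                )
        tags[first] = f"B-{ent.label}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{ent.label}"
    return IOBSequence(
        sent_id=sentence.sent_id,
        tokens=tuple(t.surface for t in sentence.tokens),
        tags=tuple(tags),
    )


def iob_to_spans(
    iob: IOBSequence, sentence: SentenceRecord, id_prefix: str = "T"
) -> tuple[list[EntitySpan], list[str]]:
    """Decode an IOB tag sequence back into entity spans.

    Inverse of :func:`spans_to_iob` on well-formed input. An orphan ``I-c``
    (no preceding ``B-c``/``I-c`` of the same class) is repaired to ``B-c``
    and logged. Returns (spans, repair_log).
    """
    if len(iob.tags) != len(sentence.tokens):
        raise ValueError(f"{iob.sent_id}: tag/token length mismatch with sentence record")
    spans: list[EntitySpan] = []
    repairs: list[str] = []
    open_cls: str | None = None
    first = last = -1

    def _close() -> None:
        nonlocal open_cls
        if open_cls is not None:
            s, e = sentence.tokens[first].start, sentence.tokens[last].end
            spans.append(
                EntitySpan(
                    id=f"{id_prefix}{len(spans) + 1}",
                    label=open_cls,
                    start=s,
                    end=e,
                    surface=" ".join(t.surface for t in sentence.tokens[first : last + 1]),
                )
            )
        open_cls = None

    for i, tag in enumerate(iob.tags):
        if tag == "O":
            _close()
            continue
        kind, cls = tag.split("-", 1)
        if kind == "I" and open_cls == cls:
            last = i
            continue
        if kind == "I":
            repairs.append(f"{iob.sent_id}: orphan I-{cls} at token {i} treated as B-{cls}")
        _close()
        open_cls, first, last = cls, i, i
    _close()
    return spans, repairs


def generate_relation_samples(
    sentence: SentenceRecord,
    entities: list[EntitySpan],
    gold_relations: list,
    schema: SchemaDef,
    split: str = "train",
    enforce_rules: bool = False,
) -> list[RelationSample]:
    """Enumerate all C(k, 2) entity pairs of a sentence as relation samples.

    Pairs present in ``gold_relations`` carry their annotated label; every
    other pair is ``no_relation``. With ``enforce_rules`` (strict mode),
    candidate pairs allowed by no schema rule are dropped; by default they
    are retained as ``no_relation`` so the pair count stays exactly
    C(k, 2).
    """
    by_id = {e.id: e for e in entities}
    gold: dict[frozenset[str], str] = {}
    for rel in gold_relations:
        if rel.arg1 not in by_id or rel.arg2 not in by_id:
            raise ValueError(
                f"{sentence.sent_id}: gold relation {rel.label} references entities outside the sentence"
            )
        gold[frozenset({rel.arg1, rel.arg2})] = rel.label
    ordered = sorted(entities, key=lambda e: (e.start, e.end, e.id))
    samples: list[RelationSample] = []
    for e1, e2 in itertools.combinations(ordered, 2):
        label = gold.get(frozenset({e1.id, e2.id}), NO_RELATION)
        if (
            enforce_rules
            and label == NO_RELATION
            and not any(
                schema.pair_allowed(rel, e1.label, e2.label) for rel in schema.relation_classes
            )
        ):
            continue
        samples.append(RelationSample(sent_id=sentence.sent_id, e1=e1, e2=e2, label=label, split=split))
    return samples


def oversample_positives(
    samples: list[RelationSample], factor: int = 4, split: str = "train"
) -> list[RelationSample]:
    """Duplicate positive train samples ``factor`` times; leave the rest alone.

    Negatives are never duplicated and the test split is returned unchanged,
    preserving the true class distribution at evaluation time. Duplicates
    carry a ``copy_index`` so they can be deduplicated downstream.
    """
    if factor < 1:
        raise ValueError(f"oversampling factor must be >= 1, got {factor}")
    if split == "test":
        return list(samples)
    out: list[RelationSample] = []
    for s in samples:
        out.append(s)
        if s.label != NO_RELATION and s.split == "train":
            out.extend(replace(s, copy_index=c) for c in range(1, factor))
    return out


# ---------------------------------------------------------------------------
# Export / import

def iob_to_conll(sequences: list[IOBSequence]) -> str:
    """CoNLL-style TSV: one `token<TAB>tag` per line, blank line between sentences."""
    blocks = [
        "\n".join(f"{tok}\t{tag}" for tok, tag in zip(seq.tokens, seq.tags)) for seq in sequences
    ]
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def conll_to_iob(content: str, sent_prefix: str = "s") -> list[IOBSequence]:
    sequences: list[IOBSequence] = []
    for i, block in enumerate(b for b in content.strip().split("\n\n") if b.strip()):
        toks, tags = [], []
        for line in block.splitlines():
            tok, tag = line.split("\t")
            toks.append(tok)
            tags.append(tag)
        sequences.append(IOBSequence(sent_id=f"{sent_prefix}{i}", tokens=tuple(toks), tags=tuple(tags)))
    return sequences


def relation_samples_to_jsonl(samples: list[RelationSample]) -> str:
    """One JSON object per sample with entity spans inlined."""
    lines = []
    for s in samples:
        lines.append(
            json.dumps(
                {
                    "sent_id": s.sent_id,
                    "label": s.label,
                    "split": s.split,
                    "copy_index": s.copy_index,
                    "e1": {"id": s.e1.id, "label": s.e1.label, "start": s.e1.start, "end": s.e1.end, "surface": s.e1.surface},
                    "e2": {"id": s.e2.id, "label": s.e2.label, "start": s.e2.start, "end": s.e2.end, "surface": s.e2.surface},
                },
                ensure_ascii=False,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
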