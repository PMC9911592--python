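"""Evaluation: macro-F1 for NER and RE, batch diagnostics, agreement.

Macro-F1 — the unweighted mean of per-class F1 — is the headline metric
throughout, on the view that every entity and relation class matters
equally regardless of how rare it is. NER matching is strict by default: a
predicted span counts as a true positive only on an exact (start, end,
class) match; a token-level mode is available by flag. For RE the
overwhelming ``no_relation`` class is excluded from the macro mean by
default (including it would mask exactly the minority classes the metric
is meant to protect); a flag includes it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .acquisition import AcquisitionScore
from .corpus import DocumentRecord, EntitySpan, PoolItem
from .encoding import RelationSample
from .schema import NO_RELATION


@dataclass
class ClassScore:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass
class EvalReport:
    """Per-class precision/recall/F1 plus the macro mean, with raw counts.

    The report carries its own confusion counts so every number in it can
    be recomputed from the report alone.
    """

    task: str
    per_class: dict[str, ClassScore] = field(default_factory=dict)

    @property
    def macro_f1(self) -> float:
        if not self.per_class:
            return 0.0
        return sum(c.f1 for c in self.per_class.values()) / len(self.per_class)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "macro_f1": self.macro_f1,
            "per_class": {
                cls: {
                    "precision": c.precision,
                    "recall": c.recall,
                    "f1": c.f1,
                    "support": c.support,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                }
                for cls, c in sorted(self.per_class.items())
            },
        }


def _spans_of(docs) -> dict[str, list[EntitySpan]]:
    if isinstance(docs, dict):
        return {k: list(v) for k, v in docs.items()}
    out: dict[str, list[EntitySpan]] = {}
    for doc in docs:
        if isinstance(doc, DocumentRecord):
            out[doc.doc_id] = list(doc.entities)
        else:
            raise TypeError("expected DocumentRecords or a mapping doc_id -> spans")
    return out


def macro_f1_ner(gold_docs, pred_docs, matching: str = "strict") -> EvalReport:
    """Entity-level macro-F1 over documents.

    ``gold_docs``/``pred_docs`` are DocumentRecords or mappings
    doc_id -> list of EntitySpan, with identical id sets. ``strict``
    matching counts a TP only on an exact (start, end, class) match;
    ``token`` matching scores per-token class labels. Classes with neither
    gold nor predicted support are excluded from the macro mean.
    """
    if matching not in {"strict", "token"}:
        raise ValueError(f"matching must be 'strict' or 'token', got {matching!r}")
    gold, pred = _spans_of(gold_docs), _spans_of(pred_docs)
    if set(gold) != set(pred):
        raise ValueError("gold and predicted document ids differ")
    report = EvalReport(task="ner")

    def score(cls: str) -> ClassScore:
        return report.per_class.setdefault(cls, ClassScore())

    for doc_id in sorted(gold):
        if matching == "strict":
            g = Counter((e.start, e.end, e.label) for e in gold[doc_id])
            p = Counter((e.start, e.end, e.label) for e in pred[doc_id])
            for key in g | p:
                cls = key[2]
                tp = min(g[key], p[key])
                score(cls).tp += tp
                score(cls).fn += g[key] - tp
                score(cls).fp += p[key] - tp
        else:
            g_tok = Counter(
                (pos, e.label) for e in gold[doc_id] for pos in range(e.start, e.end)
            )
            p_tok = Counter(
                (pos, e.label) for e in pred[doc_id] for pos in range(e.start, e.end)
            )
            for key in g_tok | p_tok:
                cls = key[1]
                tp = min(g_tok[key], p_tok[key])
                score(cls).tp += tp
                score(cls).fn += g_tok[key] - tp
                score(cls).fp += p_tok[key] - tp
    return report


def _pair_key(s: RelationSample) -> tuple[str, str, str]:
    return (s.sent_id, s.e1.id, s.e2.id)


def macro_f1_re(
    gold_samples: list[RelationSample],
    pred_samples: list[RelationSample],
    include_no_relation: bool = False,
) -> EvalReport:
    """Macro-F1 over relation classes on aligned entity-pair samples.

    Samples align on (sent_id, e1, e2); a predicted pair absent from the
    gold universe is an error. Pairs the predictor left unlabeled count as
    predicted ``no_relation``. ``no_relation`` joins the class set only on
    request.
    """
    gold = {_pair_key(s): s.label for s in gold_samples}
    pred = {}
    for s in pred_samples:
        key = _pair_key(s)
        if key not in gold:
            raise ValueError(f"predicted pair {key} is not in the gold sample universe")
        pred[key] = s.label
    report = EvalReport(task="re")

    def score(cls: str) -> ClassScore:
        return report.per_class.setdefault(cls, ClassScore())

    for key, g in sorted(gold.items()):
        p = pred.get(key, NO_RELATION)
        if g == p:
            score(g).tp += 1
        else:
            score(g).fn += 1
            score(p).fp += 1
    if not include_no_relation:
        report.per_class.pop(NO_RELATION, None)
    # drop classes with neither gold nor predicted support
    for cls in [c for c, s in report.per_class.items() if s.tp + s.fp + s.fn == 0]:
        report.per_class.pop(cls)
    return report


@dataclass(frozen=True)
class BatchStats:
    """Summary of one annotation batch (always computed pre-oversampling)."""

    n_sentences: int
    avg_sentence_length: float
    avg_ppl: float
    avg_entities_per_sentence: float
    n_entities: int
    n_relations_positive: int
    n_relations_negative: int
    entity_histogram: dict[str, int]
    relation_histogram: dict[str, int]


def batch_stats(items: list[PoolItem], scores: dict[str, AcquisitionScore]) -> BatchStats:
    """Diagnostics for a batch of pool sentences.

    ``scores`` must cover every sentence in the batch. Negative relation
    counts are the C(k, 2) candidate pairs not annotated positive.
    """
    if not items:
        raise ValueError("batch_stats of an empty batch is undefined")
    for it in items:
        if it.sent_id not in scores:
            raise ValueError(f"missing acquisition score for sentence {it.sent_id}")
    n = len(items)
    n_entities = sum(len(it.entities) for it in items)
    n_pos = sum(len(it.relations) for it in items)
    n_pairs = sum(len(it.entities) * (len(it.entities) - 1) // 2 for it in items)
    ent_hist = Counter(e.label for it in items for e in it.entities)
    rel_hist = Counter(r.label for it in items for r in it.relations)
    return BatchStats(
        n_sentences=n,
        avg_sentence_length=sum(scores[it.sent_id].length for it in items) / n,
        avg_ppl=sum(scores[it.sent_id].ppl for it in items) / n,
        avg_entities_per_sentence=n_entities / n,
        n_entities=n_entities,
        n_relations_positive=n_pos,
        n_relations_negative=n_pairs - n_pos,
        entity_histogram=dict(sorted(ent_hist.items())),
        relation_histogram=dict(sorted(rel_hist.items())),
    )


def class_distribution(items: list[PoolItem]) -> dict:
    """Entity and relation class histograms with normalized shares.

    Also reports, per task, the combined share of the k rarest observed
    classes (k = half the observed classes, at least 1) — a skew summary
    used to compare how strongly different sampling strategies enrich
    minority classes.
    """
    ent_hist = Counter(e.label for it in items for e in it.entities)
    rel_hist = Counter(r.label for it in items for r in it.relations)

    def summarize(hist: Counter) -> dict:
        total = sum(hist.values())
        shares = {c: hist[c] / total for c in hist} if total else {}
        out = {"counts": dict(sorted(hist.items())), "shares": dict(sorted(shares.items()))}
        if hist:
            k = max(1, len(hist) // 2)
            rarest = sorted(hist.items(), key=lambda kv: (kv[1], kv[0]))[:k]
            out["rare_share"] = sum(c for _, c in rarest) / total if total else 0.0
            out["rare_classes"] = [c for c, _ in rarest]
        else:
            out["rare_share"] = 0.0
            out["rare_classes"] = []
        return out

    return {"entities": summarize(ent_hist), "relations": summarize(rel_hist)}


def rare_class_share(items: list[PoolItem], rare_classes: list[str]) -> float:
    """Share of entity mentions belonging to a fixed set of rare classes."""
    hist = Counter(e.label for it in items for e in it.entities)
    total = sum(hist.values())
    return sum(hist[c] for c in rare_classes) / total if total else 0.0


def cohen_kappa(ann1_labels: list, ann2_labels: list) -> float:
    """Cohen's kappa for two annotators' label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the annotators' marginal label distributions. When p_e = 1
    (both annotators constant): kappa = 1 if they agree, otherwise
    undefined (raises).
    """
    if len(ann1_labels) != len(ann2_labels):
        raise ValueError("label sequences must have equal length")
    if not ann1_labels:
        raise ValueError("cannot compute agreement on empty sequences")
    n = len(ann1_labels)
    p_o = sum(a == b for a, b in zip(ann1_labels, ann2_labels)) / n
    m1, m2 = Counter(ann1_labels), Counter(ann2_labels)
    p_e = sum(m1[c] * m2.get(c, 0) for c in m1) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("chance agreement is 1 but observed agreement is not; kappa undefined")
    return (p_o - p_e) / (1 - p_e)
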