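"""The active-learning cycle: seed annotation, query with soft labels, retrain.

Phase 1 draws a random seed set from the unlabeled pool, has it annotated,
and fits the task models once. Each subsequent iteration (phases 2-3)
selects a batch by the configured strategy (random, or strategic
percentile-band sampling on pseudo-perplexity and length), pre-annotates it
with the current models — these predictions are the *soft labels* shown to
the annotator for correction, never trained on directly — then retrains
both task models on the full corrected labeled set. Iteration stops when a
held-out metric reaches its threshold, the pool is exhausted, or a
max-iteration guard trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import BandSpec, ScoreCache, random_sample, score_pool, strategic_sample
from .backends import PairClassifier, WindowTagger
from .corpus import PoolItem
from .encoding import (
    IOBSequence,
    RelationSample,
    generate_relation_samples,
    oversample_positives,
    spans_to_iob,
)
from .evaluation import BatchStats, batch_stats, macro_f1_ner, macro_f1_re
from .schema import SchemaDef


@dataclass(frozen=True)
class SoftLabels:
    """Model pre-annotations for one sentence, presented for correction."""

    sent_id: str
    tags: tuple[str, ...]
    relation_labels: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass(frozen=True)
class GoldAnnotation:
    """Annotator-corrected gold for one sentence."""

    sent_id: str
    entities: tuple
    relations: tuple


@dataclass
class IterationRecord:
    """History row for one AL iteration."""

    iteration: int
    strategy: str
    batch_ids: list[str]
    stats: BatchStats
    metrics: dict[str, float]
    soft_label_acceptance: float  # fraction of soft labels the annotator kept


@dataclass
class ALState:
    """Mutable state of one active-learning run."""

    pool: dict[str, PoolItem]
    labeled_ids: list[str]
    unlabeled_ids: list[str]
    iteration: int
    history: list[IterationRecord]
    gold: dict[str, GoldAnnotation]
    tagger: WindowTagger | None = None
    relation_clf: PairClassifier | None = None
    mlm: object | None = None

    def check_invariants(self) -> None:
        lab, unlab = set(self.labeled_ids), set(self.unlabeled_ids)
        assert not lab & unlab, "labeled and unlabeled pools overlap"
        assert lab | unlab == set(self.pool), "pool partition lost sentences"
        assert len(self.history) == self.iteration


@dataclass(frozen=True)
class StoppingCriterion:
    metric: str = "ner_macro_f1"
    threshold: float = 1.1  # above any bounded metric: run to max_iterations by default
    max_iterations: int = 50


@dataclass(frozen=True)
class ALConfig:
    """Configuration of a full cycle.

    ``schedule`` maps iteration index (1-based) to a strategy name; unlisted
    iterations reuse the last listed strategy. The default mirrors the
    reference protocol of random sampling for seven iterations and a
    strategic intervention from iteration 8.
    """

    n_init: int = 268
    batch_size: int = 100
    schedule: dict[int, str] = field(default_factory=lambda: {1: "random", 8: "strategic"})
    band: BandSpec = field(default_factory=BandSpec)
    oversample_factor: int = 4
    stopping: StoppingCriterion = field(default_factory=StoppingCriterion)
    seed: int = 0
    warm_start: bool = False

    def strategy_at(self, iteration: int) -> str:
        chosen = "random"
        for it in sorted(self.schedule):
            if iteration >= it:
                chosen = self.schedule[it]
        return chosen


def _training_data(
    state: ALState, schema: SchemaDef, oversample_factor: int
) -> tuple[list[IOBSequence], list[RelationSample], dict[str, object]]:
    iobs: list[IOBSequence] = []
    rels: list[RelationSample] = []
    sentences: dict[str, object] = {}
    for sid in sorted(state.labeled_ids):
        item = state.pool[sid]
        gold = state.gold[sid]
        iobs.append(spans_to_iob(item.sentence, list(gold.entities)))
        samples = generate_relation_samples(
            item.sentence, list(gold.entities), list(gold.relations), schema, split="train"
        )
        rels.extend(oversample_positives(samples, factor=oversample_factor, split="train"))
        sentences[sid] = item.sentence
    return iobs, rels, sentences


def _refit(state: ALState, schema: SchemaDef, config: ALConfig) -> None:
    iobs, rels, sentences = _training_data(state, schema, config.oversample_factor)
    tagger = WindowTagger(tag_set=schema.iob_tags(), seed=config.seed)
    tagger.fit(iobs, init=state.tagger if config.warm_start else None)
    state.tagger = tagger
    clf = PairClassifier(labels=schema.relation_labels(), seed=config.seed)
    if rels:
        clf.fit(rels, sentences=sentences, init=state.relation_clf if config.warm_start else None)
        state.relation_clf = clf


def predict_soft_labels(state: ALState, schema: SchemaDef, sent_ids: list[str]) -> list[SoftLabels]:
    """Pre-annotate sentences with the current tagger and relation classifier."""
    items = [state.pool[sid] for sid in sent_ids]
    all_tokens = [tuple(t.surface for t in it.sentence.tokens) for it in items]
    all_tags = (
        state.tagger.predict_many(all_tokens)
        if state.tagger
        else [["O"] * len(t) for t in all_tokens]
    )
    candidates: list = []
    if state.relation_clf is not None:
        for it in items:
            if len(it.entities) >= 2:
                candidates.extend(
                    generate_relation_samples(it.sentence, list(it.entities), [], schema, split="train")
                )
    labels = (
        state.relation_clf.predict_many(candidates, {it.sent_id: it.sentence for it in items})
        if state.relation_clf is not None
        else []
    )
    rel_by_sent: dict[str, dict[tuple[str, str], str]] = {}
    for cand, label in zip(candidates, labels):
        rel_by_sent.setdefault(cand.sent_id, {})[(cand.e1.id, cand.e2.id)] = label
    return [
        SoftLabels(sent_id=it.sent_id, tags=tuple(tags), relation_labels=rel_by_sent.get(it.sent_id, {}))
        for it, tags in zip(items, all_tags)
    ]


def initialize_state(
    pool: dict[str, PoolItem],
    n_init: int,
    seed: int,
    annotator,
    schema: SchemaDef,
    config: ALConfig | None = None,
) -> ALState:
    """Phase 1: draw and annotate the random seed set, fit the first models."""
    if not 1 <= n_init <= len(pool):
        raise ValueError(f"n_init must lie in [1, {len(pool)}], got {n_init}")
    config = config or ALConfig(n_init=n_init, seed=seed)
    all_ids = sorted(pool)
    seed_ids = sorted(random_sample(all_ids, n_init, seed))
    state = ALState(
        pool=pool,
        labeled_ids=[],
        unlabeled_ids=[sid for sid in all_ids if sid not in set(seed_ids)],
        iteration=0,
        history=[],
        gold={},
    )
    blanks = [
        SoftLabels(
            sent_id=sid, tags=tuple("O" for _ in pool[sid].sentence.tokens), relation_labels={}
        )
        for sid in seed_ids
    ]
    for sid, soft in zip(seed_ids, blanks):
        ann = annotator.annotate(pool[sid].sentence, soft)
        state.gold[sid] = ann
        state.labeled_ids.append(sid)
    _refit(state, schema, config)
    state.check_invariants()
    return state


def propose_batch(
    state: ALState,
    strategy: str,
    batch_size: int,
    band: BandSpec,
    seed: int,
    schema: SchemaDef,
    cache: ScoreCache | None = None,
) -> list[SoftLabels]:
    """Phase 2: select a batch from the unlabeled pool and pre-annotate it.

    Returns an empty list when the pool is exhausted (completion signal,
    not an error). Percentile thresholds are recomputed over the current
    (shrinking) unlabeled pool.
    """
    if not state.unlabeled_ids:
        return []
    candidates = sorted(state.unlabeled_ids)
    k = min(batch_size, len(candidates))
    if strategy == "random":
        chosen = sorted(random_sample(candidates, k, seed))
    elif strategy == "strategic":
        if state.mlm is None:
            raise ValueError("strategic sampling requires a masked LM on the state")
        scores = score_pool(state.mlm, [state.pool[sid].sentence for sid in candidates], cache=cache)
        chosen = strategic_sample(scores, band, k, seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return predict_soft_labels(state, schema, chosen)


def incorporate_annotations(
    state: ALState,
    corrected_batch: list[tuple[SoftLabels, GoldAnnotation]],
    strategy: str,
    schema: SchemaDef,
    config: ALConfig,
    metrics: dict[str, float] | None = None,
    scores: dict[str, object] | None = None,
) -> ALState:
    """Phase 3: move the corrected batch into the labeled set and retrain.

    Appends a history row with batch diagnostics (count, average length,
    average pseudo-perplexity, entities per sentence) and the fraction of
    soft labels the annotator accepted unchanged.
    """
    proposed = {soft.sent_id for soft, _ in corrected_batch}
    for soft, gold in corrected_batch:
        if gold.sent_id != soft.sent_id:
            raise ValueError(f"annotation for {gold.sent_id} does not match proposed {soft.sent_id}")
        if gold.sent_id not in state.unlabeled_ids:
            raise ValueError(f"sentence {gold.sent_id} is not in the unlabeled pool")
    kept = total = 0
    for soft, gold in corrected_batch:
        gold_tags = spans_to_iob(state.pool[soft.sent_id].sentence, list(gold.entities)).tags
        kept += sum(a == b for a, b in zip(soft.tags, gold_tags))
        total += len(gold_tags)
        state.gold[soft.sent_id] = gold
    state.unlabeled_ids = [sid for sid in state.unlabeled_ids if sid not in proposed]
    state.labeled_ids.extend(sorted(proposed))
    state.iteration += 1
    if corrected_batch:
        _refit(state, schema, config)
    batch_items = [state.pool[sid] for sid in sorted(proposed)]
    if batch_items:
        if scores is None:
            if state.mlm is not None:
                scores = {
                    s.sent_id: s
                    for s in score_pool(state.mlm, [it.sentence for it in batch_items])
                }
            else:
                from .acquisition import AcquisitionScore

                scores = {
                    it.sent_id: AcquisitionScore(
                        it.sent_id, max(len(it.sentence.tokens), 1), 1.0
                    )
                    for it in batch_items
                }
        stats = batch_stats(batch_items, scores)
    else:
        stats = BatchStats(0, 0.0, 0.0, 0.0, 0, 0, 0, {}, {})
    state.history.append(
        IterationRecord(
            iteration=state.iteration,
            strategy=strategy,
            batch_ids=sorted(proposed),
            stats=stats,
            metrics=metrics or {},
            soft_label_acceptance=kept / total if total else 1.0,
        )
    )
    state.check_invariants()
    return state


def should_stop(
    history: list[IterationRecord],
    criterion: StoppingCriterion,
    pool_exhausted: bool = False,
) -> bool:
    """Stop when the held-out metric clears its threshold, the pool is empty,
    or the iteration guard is reached."""
    if pool_exhausted:
        return True
    if len(history) >= criterion.max_iterations:
        return True
    if not history:
        return False
    latest = history[-1].metrics
    if criterion.metric not in latest:
        if latest:
            raise KeyError(f"unknown stopping metric {criterion.metric!r}; have {sorted(latest)}")
        return False
    return latest[criterion.metric] >= criterion.threshold


def evaluate_state(
    state: ALState, test_items: list[PoolItem], schema: SchemaDef
) -> dict[str, float]:
    """Held-out macro-F1 of the current tagger and relation classifier."""
    from .encoding import iob_to_spans

    gold_docs: dict[str, list] = {}
    pred_docs: dict[str, list] = {}
    gold_rel: list[RelationSample] = []
    all_tokens = [tuple(t.surface for t in item.sentence.tokens) for item in test_items]
    all_tags = (
        state.tagger.predict_many(all_tokens)
        if state.tagger
        else [["O"] * len(t) for t in all_tokens]
    )
    sentences = {item.sent_id: item.sentence for item in test_items}
    for item, tokens, tags in zip(test_items, all_tokens, all_tags):
        gold_docs[item.sent_id] = list(item.entities)
        iob = IOBSequence(sent_id=item.sent_id, tokens=tokens, tags=tuple(tags))
        spans, _ = iob_to_spans(iob, item.sentence)
        pred_docs[item.sent_id] = spans
        if len(item.entities) >= 2:
            gold_rel.extend(
                generate_relation_samples(
                    item.sentence, list(item.entities), list(item.relations), schema, split="test"
                )
            )
    if state.relation_clf is not None:
        labels = state.relation_clf.predict_many(gold_rel, sentences)
    else:
        labels = ["no_relation"] * len(gold_rel)
    pred_rel = [replace(s, label=label) for s, label in zip(gold_rel, labels)]
    out = {"ner_macro_f1": macro_f1_ner(gold_docs, pred_docs).macro_f1}
    if gold_rel:
        out["re_macro_f1"] = macro_f1_re(gold_rel, pred_rel).macro_f1
    return out


def run_cycle(
    pool: dict[str, PoolItem],
    annotator,
    config: ALConfig,
    schema: SchemaDef,
    mlm=None,
    test_items: list[PoolItem] | None = None,
) -> ALState:
    """Run the full annotate-train-query cycle to the stopping criterion.

    ``mlm`` is the (fixed) masked LM used for strategic scoring; it is not
    refreshed during the loop. Per-iteration seeds are derived
    deterministically from ``config.seed`` so the whole run is reproducible
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize_state(
        pool, config.n_init, int(rng.integers(2**31)), annotator, schema, config
    )
    state.mlm = mlm
    cache = ScoreCache()
    while True:
        if should_stop(state.history, config.stopping, pool_exhausted=not state.unlabeled_ids):
            break
        iteration = state.iteration + 1
        strategy = config.strategy_at(iteration)
        iter_seed = int(rng.integers(2**31))
        try:
            batch = propose_batch(
                state, strategy, config.batch_size, config.band, iter_seed, schema, cache
            )
            if not batch:
                break
            corrected = [
                (soft, annotator.annotate(state.pool[soft.sent_id].sentence, soft))
                for soft in batch
            ]
            metrics = None
            state = incorporate_annotations(state, corrected, strategy, schema, config)
            if test_items is not None:
                metrics = evaluate_state(state, test_items, schema)
                state.history[-1].metrics = metrics
        except Exception as exc:
            raise RuntimeError(f"active-learning iteration {iteration} failed: {exc}") from exc
    return state


def history_to_rows(state: ALState) -> list[dict]:
    """Flatten the run history into CSV-ready dictionaries (learning curve)."""
    rows = []
    for rec in state.history:
        row = {
            "iteration": rec.iteration,
            "strategy": rec.strategy,
            "n_sentences": rec.stats.n_sentences,
            "avg_sentence_length": rec.stats.avg_sentence_length,
            "avg_ppl": rec.stats.avg_ppl,
            "avg_entities_per_sentence": rec.stats.avg_entities_per_sentence,
            "n_relations_positive": rec.stats.n_relations_positive,
            "n_relations_negative": rec.stats.n_relations_negative,
            "soft_label_acceptance": rec.soft_label_acceptance,
        }
        row.update(rec.metrics)
        rows.append(row)
    return rows
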