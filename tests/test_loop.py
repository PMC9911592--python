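import pytest

from reportal import (
    ALConfig,
    BandSpec,
    SynthConfig,
    build_pool,
    fit_unigram_mlm,
    generate_corpus,
    incorporate_annotations,
    initialize_state,
    oracle_annotator,
    propose_batch,
    run_cycle,
    should_stop,
)
from reportal.evaluation import batch_stats
from reportal.loop import IterationRecord, StoppingCriterion
from reportal.evaluation import BatchStats


@pytest.fixture(scope="module")
def tiny_setup(schema):
    docs = generate_corpus(SynthConfig(n_sentences=80, seed=21))
    pool = build_pool(docs)
    mlm = fit_unigram_mlm([[t.surface for t in p.sentence.tokens] for p in pool.values()])
    return pool, mlm


def fresh_annotator(pool):
    return oracle_annotator(pool)


class TestInitializeState:
    def test_partition_sizes(self, tiny_setup, schema):
        pool, _ = tiny_setup
        state = initialize_state(pool, 3, seed=0, annotator=fresh_annotator(pool), schema=schema)
        assert len(state.labeled_ids) == 3
        assert len(state.unlabeled_ids) == len(pool) - 3

    def test_default_seed_size_is_268(self):
        assert ALConfig().n_init == 268

    def test_same_seed_same_selection(self, tiny_setup, schema):
        pool, _ = tiny_setup
        a = initialize_state(pool, 5, seed=4, annotator=fresh_annotator(pool), schema=schema)
        b = initialize_state(pool, 5, seed=4, annotator=fresh_annotator(pool), schema=schema)
        assert a.labeled_ids == b.labeled_ids

    def test_oversized_seed_rejected(self, tiny_setup, schema):
        pool, _ = tiny_setup
        with pytest.raises(ValueError):
            initialize_state(pool, len(pool) + 1, 0, fresh_annotator(pool), schema)


class TestProposeBatch:
    def test_default_batch_size_is_100(self):
        assert ALConfig().batch_size == 100

    def test_batch_capped_at_pool(self, tiny_setup, schema):
        pool, _ = tiny_setup
        state = initialize_state(pool, len(pool) - 2, 0, fresh_annotator(pool), schema)
        batch = propose_batch(state, "random", 100, BandSpec(), 0, schema)
        assert len(batch) == 2

    def test_empty_pool_signals_completion(self, tiny_setup, schema):
        pool, _ = tiny_setup
        state = initialize_state(pool, len(pool), 0, fresh_annotator(pool), schema)
        assert propose_batch(state, "random", 10, BandSpec(), 0, schema) == []

    def test_strategic_consistent_with_acquisition_module(self, tiny_setup, schema):
        from reportal import score_pool, strategic_sample

        pool, mlm = tiny_setup
        state = initialize_state(pool, 10, 0, fresh_annotator(pool), schema)
        state.mlm = mlm
        band = BandSpec(0.5, 1.0)
        batch = propose_batch(state, "strategic", 5, band, 3, schema)
        candidates = sorted(state.unlabeled_ids)
        scores = score_pool(mlm, [pool[sid].sentence for sid in candidates])
        expected = strategic_sample(scores, band, 5, 3)
        assert sorted(s.sent_id for s in batch) == sorted(expected)

    def test_soft_labels_cover_tokens_and_pairs(self, tiny_setup, schema):
        pool, _ = tiny_setup
        state = initialize_state(pool, 30, 0, fresh_annotator(pool), schema)
        batch = propose_batch(state, "random", 5, BandSpec(), 1, schema)
        for soft in batch:
            item = pool[soft.sent_id]
            assert len(soft.tags) == len(item.sentence.tokens)
            k = len(item.entities)
            assert len(soft.relation_labels) == k * (k - 1) // 2


class TestIncorporateAnnotations:
    def test_seed_plus_batch_arithmetic(self, schema):
        docs = generate_corpus(SynthConfig(n_sentences=400, seed=31))
        pool = build_pool(docs)
        ann = oracle_annotator(pool)
        config = ALConfig(n_init=268, batch_size=100, seed=0)
        state = initialize_state(pool, 268, 0, ann, schema, config)
        batch = propose_batch(state, "random", 100, BandSpec(), 1, schema)
        corrected = [(s, ann.annotate(pool[s.sent_id].sentence, s)) for s in batch]
        state = incorporate_annotations(state, corrected, "random", schema, config)
        assert len(state.labeled_ids) == 368

    def test_empty_batch_only_advances_iteration(self, tiny_setup, schema):
        pool, _ = tiny_setup
        config = ALConfig(n_init=5, seed=0)
        state = initialize_state(pool, 5, 0, fresh_annotator(pool), schema, config)
        before = list(state.labeled_ids)
        state = incorporate_annotations(state, [], "random", schema, config)
        assert state.iteration == 1
        assert state.labeled_ids == before

    def test_already_labeled_sentence_rejected(self, tiny_setup, schema):
        from reportal.loop import GoldAnnotation, SoftLabels

        pool, _ = tiny_setup
        config = ALConfig(n_init=5, seed=0)
        state = initialize_state(pool, 5, 0, fresh_annotator(pool), schema, config)
        sid = state.labeled_ids[0]  # already labeled, not in the unlabeled pool
        item = pool[sid]
        soft = SoftLabels(sent_id=sid, tags=tuple("O" for _ in item.sentence.tokens))
        gold = GoldAnnotation(sent_id=sid, entities=item.entities, relations=item.relations)
        with pytest.raises(ValueError):
            incorporate_annotations(state, [(soft, gold)], "random", schema, config)

    def test_history_row_matches_recomputation(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        config = ALConfig(n_init=10, seed=0)
        ann = fresh_annotator(pool)
        state = initialize_state(pool, 10, 0, ann, schema, config)
        state.mlm = mlm
        batch = propose_batch(state, "random", 8, BandSpec(), 2, schema)
        corrected = [(s, ann.annotate(pool[s.sent_id].sentence, s)) for s in batch]
        state = incorporate_annotations(state, corrected, "random", schema, config)
        rec = state.history[-1]
        items = [pool[sid] for sid in rec.batch_ids]
        from reportal import score_pool

        scores = {s.sent_id: s for s in score_pool(mlm, [it.sentence for it in items])}
        recomputed = batch_stats(items, scores)
        assert rec.stats.n_sentences == recomputed.n_sentences == 8
        assert rec.stats.avg_entities_per_sentence == pytest.approx(
            recomputed.avg_entities_per_sentence
        )
        assert rec.stats.avg_ppl == pytest.approx(recomputed.avg_ppl)


class TestShouldStop:
    def _hist(self, value):
        return [
            IterationRecord(
                iteration=1,
                strategy="random",
                batch_ids=[],
                stats=BatchStats(0, 0, 0, 0, 0, 0, 0, {}, {}),
                metrics={"ner_macro_f1": value},
                soft_label_acceptance=1.0,
            )
        ]

    def test_metric_above_threshold_stops(self):
        crit = StoppingCriterion(metric="ner_macro_f1", threshold=0.9)
        assert should_stop(self._hist(0.91), crit)

    def test_unreachable_threshold_continues(self):
        crit = StoppingCriterion(metric="ner_macro_f1", threshold=1.1)
        assert not should_stop(self._hist(0.99), crit)

    def test_pool_exhaustion_stops_regardless(self):
        crit = StoppingCriterion(metric="ner_macro_f1", threshold=1.1)
        assert should_stop(self._hist(0.1), crit, pool_exhausted=True)

    def test_max_iterations_guard(self):
        crit = StoppingCriterion(threshold=1.1, max_iterations=1)
        assert should_stop(self._hist(0.0), crit)

    def test_unknown_metric_rejected(self):
        crit = StoppingCriterion(metric="nope", threshold=0.5)
        with pytest.raises(KeyError):
            should_stop(self._hist(0.5), crit)


class TestRunCycle:
    def _run(self, pool, schema, mlm, schedule, seed=5, iters=3, batch=10, n_init=12):
        config = ALConfig(
            n_init=n_init,
            batch_size=batch,
            schedule=schedule,
            stopping=StoppingCriterion(max_iterations=iters),
            seed=seed,
        )
        return run_cycle(pool, oracle_annotator(pool), config, schema, mlm=mlm)

    def test_history_and_labeled_arithmetic(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        state = self._run(pool, schema, mlm, {1: "random"})
        assert len(state.history) == 3
        assert len(state.labeled_ids) == 12 + 3 * 10

    def test_schedule_switch_recorded(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        state = self._run(pool, schema, mlm, {1: "random", 2: "strategic"})
        assert [h.strategy for h in state.history] == ["random", "strategic", "strategic"]

    def test_bit_reproducible_under_seed(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        a = self._run(pool, schema, mlm, {1: "strategic"}, seed=9)
        b = self._run(pool, schema, mlm, {1: "strategic"}, seed=9)
        assert [h.batch_ids for h in a.history] == [h.batch_ids for h in b.history]
        assert [h.stats for h in a.history] == [h.stats for h in b.history]
        assert a.labeled_ids == b.labeled_ids

    def test_no_sentence_in_two_batches(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        state = self._run(pool, schema, mlm, {1: "strategic"})
        seen = set(state.history[0].batch_ids)
        for rec in state.history[1:]:
            assert not seen & set(rec.batch_ids)
            seen |= set(rec.batch_ids)

    def test_pool_conservation(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        state = self._run(pool, schema, mlm, {1: "random"})
        assert len(state.labeled_ids) + len(state.unlabeled_ids) == len(pool)
        state.check_invariants()

    def test_soft_label_acceptance_logged(self, tiny_setup, schema):
        pool, mlm = tiny_setup
        state = self._run(pool, schema, mlm, {1: "random"})
        for rec in state.history:
            assert 0.0 <= rec.soft_label_acceptance <= 1.0
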