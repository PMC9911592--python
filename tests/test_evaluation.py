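import random

import numpy as np
import pytest

from reportal import (
    batch_stats,
    class_distribution,
    cohen_kappa,
    generate_relation_samples,
    macro_f1_ner,
    macro_f1_re,
)
from reportal.acquisition import AcquisitionScore
from reportal.corpus import EntitySpan, PoolItem, RelationAnnotation, SentenceRecord, Token
from reportal.schema import NO_RELATION


def span(eid, label, start, end):
    return EntitySpan(eid, label, start, end, "x" * (end - start))


class TestMacroF1Ner:
    def test_perfect_predictions(self):
        gold = {"d": [span("T1", "A", 0, 3), span("T2", "B", 4, 7)]}
        assert macro_f1_ner(gold, gold).macro_f1 == pytest.approx(1.0)

    def test_one_missed_class_halves_macro(self):
        gold = {"d": [span("T1", "A", 0, 3), span("T2", "B", 4, 7)]}
        pred = {"d": [span("P1", "A", 0, 3)]}
        report = macro_f1_ner(gold, pred)
        assert report.per_class["A"].f1 == pytest.approx(1.0)
        assert report.per_class["B"].f1 == pytest.approx(0.0)
        assert report.macro_f1 == pytest.approx(0.5)

    def test_strict_mode_rejects_shifted_boundary(self):
        gold = {"d": [span("T1", "A", 0, 3)]}
        pred = {"d": [span("P1", "A", 0, 4)]}
        assert macro_f1_ner(gold, pred).per_class["A"].f1 == pytest.approx(0.0)

    def test_token_mode_gives_partial_credit(self):
        gold = {"d": [span("T1", "A", 0, 4)]}
        pred = {"d": [span("P1", "A", 0, 3)]}
        report = macro_f1_ner(gold, pred, matching="token")
        assert 0.0 < report.per_class["A"].f1 < 1.0

    def test_mismatched_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            macro_f1_ner({"a": []}, {"b": []})

    def test_agrees_with_independent_oracle_on_random_fixtures(self):
        # Oracle: literal per-class TP/FP/FN counting over (start, end, cls)
        # triples, written without reference to the scorer implementation.
        rng = random.Random(42)
        for _ in range(100):
            gold, pred = {}, {}
            for d in range(3):
                gold[f"d{d}"] = [
                    span(f"T{i}", rng.choice("ABC"), 10 * i, 10 * i + rng.randint(1, 9))
                    for i in range(rng.randint(0, 5))
                ]
                pred[f"d{d}"] = [
                    span(f"P{i}", rng.choice("ABC"), 10 * i, 10 * i + rng.randint(1, 9))
                    for i in range(rng.randint(0, 5))
                ]
            report = macro_f1_ner(gold, pred)
            f1s = {}
            classes = {e.label for es in gold.values() for e in es} | {
                e.label for es in pred.values() for e in es
            }
            for cls in classes:
                tp = fp = fn = 0
                for d in gold:
                    g = {(e.start, e.end) for e in gold[d] if e.label == cls}
                    p = {(e.start, e.end) for e in pred[d] if e.label == cls}
                    tp += len(g & p)
                    fn += len(g - p)
                    fp += len(p - g)
                prec = tp / (tp + fp) if tp + fp else 0
                rec = tp / (tp + fn) if tp + fn else 0
                f1s[cls] = 2 * prec * rec / (prec + rec) if prec + rec else 0
            expected = sum(f1s.values()) / len(f1s) if f1s else 0.0
            assert report.macro_f1 == pytest.approx(expected)

    def test_macro_invariant_under_class_relabeling(self):
        gold = {"d": [span("T1", "A", 0, 3), span("T2", "B", 4, 7), span("T3", "B", 8, 9)]}
        pred = {"d": [span("P1", "A", 0, 3), span("P2", "B", 4, 7)]}
        swap = {"A": "B", "B": "A"}

        def relabel(docs):
            return {
                d: [EntitySpan(e.id, swap[e.label], e.start, e.end, e.surface) for e in es]
                for d, es in docs.items()
            }

        assert macro_f1_ner(gold, pred).macro_f1 == pytest.approx(
            macro_f1_ner(relabel(gold), relabel(pred)).macro_f1
        )

    def test_report_scores_recomputable_from_counts(self):
        gold = {"d": [span("T1", "A", 0, 3), span("T2", "A", 4, 7)]}
        pred = {"d": [span("P1", "A", 0, 3), span("P2", "A", 8, 9)]}
        cs = macro_f1_ner(gold, pred).per_class["A"]
        p = cs.tp / (cs.tp + cs.fp)
        r = cs.tp / (cs.tp + cs.fn)
        assert cs.f1 == pytest.approx(2 * p * r / (p + r))


def re_fixture(schema):
    words = [f"w{i}" for i in range(6)]
    tokens, pos = [], 0
    for w in words:
        tokens.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    sent = SentenceRecord("s0", 0, pos - 1, tuple(tokens))
    ents = [
        EntitySpan(f"T{i+1}", "Medical_condition", t.start, t.end, t.surface)
        for i, t in enumerate(tokens)
    ]
    gold_rel = [
        RelationAnnotation("Compares", f"T{a}", f"T{b}") for a, b in [(1, 2), (2, 3), (4, 5), (5, 6)]
    ]
    return generate_relation_samples(sent, ents, gold_rel, schema, split="test")


class TestMacroF1Re:
    def test_perfect_predictions(self, schema):
        gold = re_fixture(schema)
        assert macro_f1_re(gold, gold).macro_f1 == pytest.approx(1.0)

    def test_all_positives_missed(self, schema):
        from dataclasses import replace

        gold = re_fixture(schema)
        pred = [replace(s, label=NO_RELATION) for s in gold]
        report = macro_f1_re(gold, pred)
        assert report.per_class["Compares"].f1 == pytest.approx(0.0)

    def test_unknown_pair_rejected(self, schema):
        from dataclasses import replace

        gold = re_fixture(schema)
        alien = replace(gold[0], sent_id="s999")
        with pytest.raises(ValueError):
            macro_f1_re(gold, [alien])

    def test_no_relation_excluded_by_default(self, schema):
        gold = re_fixture(schema)
        report = macro_f1_re(gold, gold)
        assert NO_RELATION not in report.per_class
        with_neg = macro_f1_re(gold, gold, include_no_relation=True)
        assert NO_RELATION in with_neg.per_class

    def test_unlabeled_pairs_count_as_predicted_negative(self, schema):
        gold = re_fixture(schema)
        report = macro_f1_re(gold, [])
        assert report.per_class["Compares"].f1 == pytest.approx(0.0)


def make_item(sent_id, n_entities, labels=None):
    tokens = tuple(Token(f"w{i}", 6 * i, 6 * i + 2) for i in range(max(n_entities, 1)))
    sent = SentenceRecord(sent_id, 0, 6 * len(tokens), tokens)
    labels = labels or ["Medical_condition"] * n_entities
    ents = tuple(
        EntitySpan(f"T{i+1}", labels[i], t.start, t.end, "w" + str(i)[:1]) for i, t in enumerate(tokens[:n_entities])
    )
    return PoolItem(sentence=sent, entities=ents, relations=(), doc_id=sent_id)


class TestBatchStats:
    def test_average_entities(self):
        items = [make_item("s0", 3), make_item("s1", 5)]
        scores = {
            "s0": AcquisitionScore("s0", 3, 2.0),
            "s1": AcquisitionScore("s1", 5, 4.0),
        }
        stats = batch_stats(items, scores)
        assert stats.avg_entities_per_sentence == pytest.approx(4.0)
        assert stats.avg_sentence_length == pytest.approx(4.0)
        assert stats.avg_ppl == pytest.approx(3.0)

    def test_single_sentence(self):
        items = [make_item("s0", 2)]
        stats = batch_stats(items, {"s0": AcquisitionScore("s0", 2, 1.5)})
        assert stats.n_sentences == 1
        assert stats.avg_entities_per_sentence == pytest.approx(2.0)

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            batch_stats([make_item("s0", 1)], {})

    def test_negative_pair_count_is_remaining_combinations(self):
        items = [make_item("s0", 4)]
        stats = batch_stats(items, {"s0": AcquisitionScore("s0", 4, 1.0)})
        assert stats.n_relations_negative == 6  # C(4,2), no positives


class TestClassDistribution:
    def test_empty_set(self):
        out = class_distribution([])
        assert out["entities"]["counts"] == {}
        assert out["entities"]["rare_share"] == 0.0

    def test_histogram_sums_match_totals(self, small_pool):
        items = list(small_pool.values())
        out = class_distribution(items)
        total_entities = sum(len(it.entities) for it in items)
        total_relations = sum(len(it.relations) for it in items)
        assert sum(out["entities"]["counts"].values()) == total_entities
        assert sum(out["relations"]["counts"].values()) == total_relations

    def test_shares_normalized(self, small_pool):
        out = class_distribution(list(small_pool.values()))
        assert sum(out["entities"]["shares"].values()) == pytest.approx(1.0)


class TestCohenKappa:
    def test_identical_sequences(self):
        assert cohen_kappa(["A", "B", "A"], ["A", "B", "A"]) == pytest.approx(1.0)

    def test_hand_computed_zero(self):
        # p_o = 0.5, p_e = 0.5 -> kappa = 0
        assert cohen_kappa(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_constant_agreement_degenerate_case(self):
        assert cohen_kappa(["A", "A"], ["A", "A"]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["A"], ["A", "B"])

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [str(x) for x in rng.integers(0, 3, size=50)]
            b = [str(x) for x in rng.integers(0, 3, size=50)]
            assert cohen_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))
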