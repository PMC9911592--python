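import pytest

from reportal import (
    IOBSequence,
    PairClassifier,
    WindowTagger,
    fit_reference_relation_classifier,
    fit_reference_tagger,
    fit_unigram_mlm,
    generate_relation_samples,
    load_backend,
    mask_tokens,
    save_backend,
)
from reportal.backends import MASK, UnigramMLM
from reportal.corpus import EntitySpan, SentenceRecord, Token
from reportal.schema import NO_RELATION


def make_sentence(words, sent_id="s0"):
    tokens, pos = [], 0
    for w in words:
        tokens.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    return SentenceRecord(sent_id=sent_id, start=0, end=max(pos - 1, 0), tokens=tuple(tokens))


def span_over(sent, first, last, label, eid):
    return EntitySpan(
        id=eid,
        label=label,
        start=sent.tokens[first].start,
        end=sent.tokens[last].end,
        surface=" ".join(t.surface for t in sent.tokens[first : last + 1]),
    )


class TestMaskTokens:
    def test_fifteen_percent_of_twenty_is_three(self):
        (masked, targets), = mask_tokens([[f"w{i}" for i in range(20)]], rate=0.15, seed=0)
        assert sum(t == MASK for t in masked) == 3
        assert len(targets) == 3

    def test_single_token_sentence_still_masked(self):
        (masked, targets), = mask_tokens([["solo"]], rate=0.15, seed=0)
        assert masked == [MASK] and targets == ["solo"]

    def test_same_seed_same_positions(self):
        sents = [[f"w{i}" for i in range(30)]]
        assert mask_tokens(sents, seed=5) == mask_tokens(sents, seed=5)

    def test_targets_recover_originals(self):
        sent = [f"w{i}" for i in range(10)]
        (masked, targets), = mask_tokens([sent], rate=0.3, seed=1)
        it = iter(targets)
        restored = [next(it) if t == MASK else t for t in masked]
        assert restored == sent

    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            mask_tokens([["a"]], rate=rate)


class TestUnigramMLM:
    def test_maximum_likelihood(self):
        mlm = fit_unigram_mlm(["a", "a", "b"], smoothing=0.0)
        assert mlm.conditional_prob("a", [], []) == pytest.approx(2 / 3)
        assert mlm.conditional_prob("b", [], []) == pytest.approx(1 / 3)

    def test_additive_smoothing(self):
        mlm = fit_unigram_mlm(["a", "a", "b"], smoothing=1.0)
        assert mlm.conditional_prob("a", [], []) == pytest.approx(3 / 5)

    def test_unseen_token_mass(self):
        mlm = fit_unigram_mlm(["a", "a", "b"], smoothing=1.0)
        assert mlm.conditional_prob("zzz", [], []) == pytest.approx(1 / 5)

    def test_distribution_normalizes(self):
        mlm = fit_unigram_mlm(list("aabbccddee"), smoothing=0.7)
        total = sum(mlm.conditional_prob(t, [], []) for t in "abcde")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_unigram_mlm([])
        with pytest.raises(ValueError):
            UnigramMLM({}, alpha=0.0)

    def test_fingerprint_tracks_content(self):
        a = fit_unigram_mlm(["a", "b"])
        b = fit_unigram_mlm(["a", "b"])
        c = fit_unigram_mlm(["a", "c"])
        assert a.fingerprint == b.fingerprint != c.fingerprint


def tagger_fixture_data(schema):
    sentences = [
        ["keine", "blutung", "links"],
        ["akute", "fraktur", "rechts"],
        ["unauffällige", "darstellung", "der", "ventrikel"],
        ["keine", "fraktur", "links"],
        ["akute", "blutung", "rechts"],
    ]
    labels = [
        [("Certainty_descriptor", 0, 0), ("Medical_condition", 1, 1), ("Location_descriptor", 2, 2)],
        [("Time_information", 0, 0), ("Medical_condition", 1, 1), ("Location_descriptor", 2, 2)],
        [("State_of_health", 0, 0), ("Anatomical_entity", 3, 3)],
        [("Certainty_descriptor", 0, 0), ("Medical_condition", 1, 1), ("Location_descriptor", 2, 2)],
        [("Time_information", 0, 0), ("Medical_condition", 1, 1), ("Location_descriptor", 2, 2)],
    ]
    from reportal import spans_to_iob

    seqs = []
    for i, (words, spans) in enumerate(zip(sentences, labels)):
        sent = make_sentence(words, f"s{i}")
        ents = [span_over(sent, a, b, cls, f"T{j+1}") for j, (cls, a, b) in enumerate(spans)]
        seqs.append(spans_to_iob(sent, ents))
    return seqs


class TestWindowTagger:
    def test_memorizes_small_fixture(self, schema):
        seqs = tagger_fixture_data(schema)
        tagger = fit_reference_tagger(seqs, seed=0)
        correct = total = 0
        for seq in seqs:
            pred = tagger.predict(seq.tokens)
            correct += sum(p == g for p, g in zip(pred, seq.tags))
            total += len(seq.tags)
        assert correct / total >= 0.95

    def test_unseen_token_falls_back_to_majority_o(self, schema):
        seqs = [
            IOBSequence(f"s{i}", tuple(f"w{i}{j}" for j in range(4)), ("O", "O", "O", "O"))
            for i in range(4)
        ]
        tagger = fit_reference_tagger(seqs, seed=0)
        assert tagger.predict(("neuwort", "nocheins")) == ["O", "O"]

    def test_predictions_within_schema_tag_set(self, schema):
        seqs = tagger_fixture_data(schema)
        tagger = WindowTagger(tag_set=schema.iob_tags(), seed=0).fit(seqs)
        for seq in seqs:
            assert set(tagger.predict(seq.tokens)) <= set(schema.iob_tags())

    def test_deterministic_under_seed(self, schema):
        seqs = tagger_fixture_data(schema)
        t1 = WindowTagger(tag_set=schema.iob_tags(), seed=3).fit(seqs)
        t2 = WindowTagger(tag_set=schema.iob_tags(), seed=3).fit(seqs)
        sample = ("keine", "blutung", "irgendwo", "neu")
        assert t1.predict(sample) == t2.predict(sample)

    def test_warm_start_accepted_and_functional(self, schema):
        seqs = tagger_fixture_data(schema)
        base = WindowTagger(tag_set=schema.iob_tags(), seed=0).fit(seqs)
        warm = WindowTagger(tag_set=schema.iob_tags(), seed=0).fit(seqs, init=base)
        assert warm.predict(("keine", "blutung")) is not None

    def test_empty_training_rejected(self, schema):
        with pytest.raises(ValueError):
            WindowTagger(tag_set=schema.iob_tags()).fit([])


def relation_fixture(schema, n_sent=5):
    samples = []
    sentences = {}
    for i in range(n_sent):
        sent = make_sentence(["wort", f"mittel{i}", "und", f"ziel{i}"], f"s{i}")
        e1 = span_over(sent, 0, 0, "Dosing", "T1")
        e2 = span_over(sent, 3, 3, "Non_anatomical_substance", "T2")
        e3 = span_over(sent, 1, 1, "Medical_condition", "T3")
        from reportal.corpus import RelationAnnotation

        gold = [RelationAnnotation("Has_dosing", "T1", "T2")]
        samples.extend(generate_relation_samples(sent, [e1, e3, e2], gold, schema))
        sentences[sent.sent_id] = sent
    return samples, sentences


class TestPairClassifier:
    def test_memorizes_small_fixture(self, schema):
        samples, sentences = relation_fixture(schema, n_sent=7)
        clf = fit_reference_relation_classifier(samples, seed=0, sentences=sentences)
        preds = clf.predict_many(samples, sentences)
        acc = sum(p == s.label for p, s in zip(preds, samples)) / len(samples)
        assert acc >= 0.9

    def test_symmetric_in_argument_order(self, schema):
        samples, sentences = relation_fixture(schema)
        clf = fit_reference_relation_classifier(samples, seed=0, sentences=sentences)
        s = samples[0]
        # rebuilding the pair from either listing order yields the same
        # offset-ordered sample, hence the same prediction
        sent = sentences[s.sent_id]
        regenerated = generate_relation_samples(sent, [s.e2, s.e1], [], schema)
        match = [c for c in regenerated if {c.e1.id, c.e2.id} == {s.e1.id, s.e2.id}]
        assert match and clf.predict(match[0], sent) == clf.predict(s, sent)

    def test_only_negative_training_predicts_negative(self, schema):
        samples, sentences = relation_fixture(schema)
        negatives = [s for s in samples if s.label == NO_RELATION]
        clf = PairClassifier(labels=[NO_RELATION], seed=0).fit(negatives, sentences=sentences)
        assert set(clf.predict_many(samples, sentences)) == {NO_RELATION}

    def test_labels_within_schema(self, schema):
        samples, sentences = relation_fixture(schema)
        clf = PairClassifier(labels=schema.relation_labels(), seed=0).fit(samples, sentences=sentences)
        assert set(clf.predict_many(samples, sentences)) <= set(schema.relation_labels())

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            PairClassifier(labels=["x"]).fit([])


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, schema):
        seqs = tagger_fixture_data(schema)
        tagger = fit_reference_tagger(seqs, seed=0)
        path = tmp_path / "tagger.bin"
        save_backend(tagger, str(path))
        loaded = load_backend(str(path))
        sample = ("keine", "blutung", "links")
        assert loaded.predict(sample) == tagger.predict(sample)

    def test_corrupt_blob_detected(self, tmp_path, schema):
        mlm = fit_unigram_mlm(["a", "b"])
        path = tmp_path / "m.bin"
        save_backend(mlm, str(path))
        raw = bytearray(path.read_bytes())
        raw[-3] ^= 0xFF
        path.write_bytes(bytes(raw))
        with pytest.raises((ValueError, Exception)):
            load_backend(str(path))
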