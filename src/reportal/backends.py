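"""Model backends: masked-LM, sequence-tagger and relation-classifier contracts.

The framework only ever talks to three small contracts, so heavyweight
transformer models (a clinical BERT for tagging, an R-BERT-style pair
classifier for relations) can be plugged in behind the same interfaces.
The reference implementations shipped here are deliberately lightweight —
a smoothed unigram masked LM and linear classifiers over hashed window /
pair features — so the whole annotate-train-query loop runs in seconds on
one CPU. They exercise the loop; they make no claim of matching
transformer-level accuracy.

Every backend is deterministic under a fixed seed and supports warm
starting: ``fit(data, init=previous)`` continues training from the previous
model's parameters, which is how source-domain knowledge is transferred to
a new reporting domain.
"""

from __future__ import annotations

import copy
import hashlib
import math
import pickle

import numpy as np
from sklearn.feature_extraction import FeatureHasher
from sklearn.linear_model import SGDClassifier

from .encoding import IOBSequence, RelationSample

MASK = "[MASK]"

_BLOB_VERSION = 1


# ---------------------------------------------------------------------------
# Masked language modeling

def mask_tokens(
    sentences: list[list[str]], rate: float = 0.15, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Randomly mask ``ceil(rate * n)`` tokens per sentence for MLM training.

    Returns, per sentence, the input with masked positions replaced by the
    mask symbol and the list of original tokens at those positions. No
    80/10/10 replacement split is applied — masked positions are always
    replaced by the mask symbol.
    """
    if not 0 < rate < 1:
        raise ValueError(f"mask rate must lie in (0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    out: list[tuple[list[str], list[str]]] = []
    for sent in sentences:
        n = len(sent)
        if n == 0:
            out.append(([], []))
            continue
        k = math.ceil(rate * n)
        positions = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
        masked = list(sent)
        targets = []
        for pos in positions:
            targets.append(masked[pos])
            masked[pos] = MASK
        out.append((masked, targets))
    return out


class UnigramMLM:
    """Additively smoothed unigram model behind the masked-LM contract.

    ``conditional_prob`` ignores context: p(t) = (count(t) + a) / (N + a*V)
    with V the number of observed types, so the distribution sums to one
    over the vocabulary. Context independence is exactly what makes this
    backend a transparent oracle for pseudo-perplexity behavior: surprise
    is purely token rarity.
    """

    def __init__(self, counts: dict[str, int], alpha: float = 1.0) -> None:
        if alpha < 0:
            raise ValueError("smoothing alpha must be >= 0")
        if not counts and alpha == 0:
            raise ValueError("an empty corpus with alpha=0 defines no distribution")
        self.counts = dict(counts)
        self.alpha = alpha
        self.total = sum(counts.values())
        self.vocab_size = len(counts)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.alpha).encode())
        for tok, c in sorted(self.counts.items()):
            h.update(f"{tok}\x00{c}\x01".encode())
        return h.hexdigest()[:16]

    def conditional_prob(self, token: str, left_context, right_context) -> float:
        denom = self.total + self.alpha * self.vocab_size
        if denom == 0:
            raise ValueError("degenerate unigram model (empty corpus)")
        return (self.counts.get(token, 0) + self.alpha) / denom


def fit_unigram_mlm(corpus: list[str] | list[list[str]], smoothing: float = 1.0) -> UnigramMLM:
    """Fit the reference unigram masked LM on a token corpus.

    ``corpus`` is either a flat token list or a list of token lists.
    """
    if not corpus:
        raise ValueError("cannot fit a language model on an empty corpus")
    tokens: list[str] = []
    for item in corpus:
        if isinstance(item, str):
            tokens.append(item)
        else:
            tokens.extend(item)
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    return UnigramMLM(counts, alpha=smoothing)


# ---------------------------------------------------------------------------
# Shared linear-model machinery

class _ConstantEstimator:
    """Degenerate classifier for single-class training sets."""

    def __init__(self, label: str) -> None:
        self.label = label

    def predict(self, X):
        return np.full(X.shape[0], self.label, dtype=object)


def _fit_sgd(
    features: list[dict[str, float]],
    labels: list[str],
    classes: list[str],
    seed: int,
    n_features: int,
    epochs: int,
    init,
) -> tuple[FeatureHasher, object]:
    hasher = FeatureHasher(n_features=n_features, alternate_sign=True)
    X = hasher.transform(features)
    y = np.asarray(labels)
    cls_arr = np.asarray(sorted(classes))
    if len(cls_arr) < 2:
        return hasher, _ConstantEstimator(str(cls_arr[0]))
    if init is not None and not isinstance(init, _ConstantEstimator):
        est = copy.deepcopy(init)
    else:
        est = SGDClassifier(
            loss="log_loss",
            alpha=1e-6,
            learning_rate="optimal",
            random_state=seed,
            shuffle=False,
        )
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        order = rng.permutation(len(y))
        est.partial_fit(X[order], y[order], classes=cls_arr)
    return hasher, est


# ---------------------------------------------------------------------------
# Sequence tagger

def _token_features(tokens: tuple[str, ...], i: int) -> dict[str, float]:
    w = tokens[i]
    prev_w = tokens[i - 1] if i > 0 else "<s>"
    next_w = tokens[i + 1] if i + 1 < len(tokens) else "</s>"
    shape = "".join("X" if c.isupper() else "x" if c.isalpha() else "9" if c.isdigit() else "-" for c in w[:6])
    return {
        f"w={w.lower()}": 1.0,
        f"W={w}": 1.0,
        f"w-1={prev_w.lower()}": 1.0,
        f"w+1={next_w.lower()}": 1.0,
        f"shape={shape}": 1.0,
        f"suf3={w[-3:].lower()}": 1.0,
        "title": float(w[:1].isupper()),
        "digit": float(any(c.isdigit() for c in w)),
    }


class WindowTagger:
    """Reference sequence tagger: logistic regression over hashed window features.

    Features per token: the surface form (cased and lowercased), its
    immediate neighbors, a character shape, a 3-character suffix and
    casing/digit flags. Predicted tags are drawn from the schema's IOB
    tag set fixed at construction.
    """

    def __init__(self, tag_set: list[str], seed: int = 0, n_features: int = 2**16, epochs: int = 12) -> None:
        self.tag_set = sorted(tag_set)
        self.seed = seed
        self.n_features = n_features
        self.epochs = epochs
        self._hasher: FeatureHasher | None = None
        self._est: SGDClassifier | None = None

    def fit(self, iob_sequences: list[IOBSequence], init: "WindowTagger | None" = None) -> "WindowTagger":
        if not iob_sequences:
            raise ValueError("cannot fit a tagger on an empty training set")
        feats: list[dict[str, float]] = []
        labels: list[str] = []
        for seq in iob_sequences:
            for i in range(len(seq.tokens)):
                feats.append(_token_features(seq.tokens, i))
                labels.append(seq.tags[i])
        self._hasher, self._est = _fit_sgd(
            feats,
            labels,
            classes=self.tag_set,
            seed=self.seed,
            n_features=self.n_features,
            epochs=self.epochs,
            init=None if init is None else init._est,
        )
        return self

    def predict(self, tokens: tuple[str, ...] | list[str]) -> list[str]:
        return self.predict_many([tuple(tokens)])[0]

    def predict_many(self, sentences: list[tuple[str, ...]]) -> list[list[str]]:
        if self._est is None:
            raise RuntimeError("tagger is not fitted")
        feats: list[dict[str, float]] = []
        lengths: list[int] = []
        for tokens in sentences:
            tokens = tuple(tokens)
            lengths.append(len(tokens))
            feats.extend(_token_features(tokens, i) for i in range(len(tokens)))
        if not feats:
            return [[] for _ in sentences]
        flat = [str(t) for t in self._est.predict(self._hasher.transform(feats))]
        out: list[list[str]] = []
        pos = 0
        for n in lengths:
            out.append(flat[pos : pos + n])
            pos += n
        return out


def fit_reference_tagger(
    iob_sequences: list[IOBSequence], seed: int = 0, tag_set: list[str] | None = None
) -> WindowTagger:
    """Fit the reference window tagger; tag set defaults to the tags seen in training."""
    if tag_set is None:
        tag_set = sorted({t for seq in iob_sequences for t in seq.tags} | {"O"})
    return WindowTagger(tag_set=tag_set, seed=seed).fit(iob_sequences)


# ---------------------------------------------------------------------------
# Relation classifier

def _pair_features(sample: RelationSample, tokens: tuple[str, ...] | None = None) -> dict[str, float]:
    e1, e2 = sample.e1, sample.e2  # offset-ordered by construction => symmetric
    feats: dict[str, float] = {
        f"cls={'|'.join(sorted([e1.label, e2.label]))}": 1.0,
        f"s1={e1.surface.lower()}": 1.0,
        f"s2={e2.surface.lower()}": 1.0,
        "char_dist": math.log1p(max(e2.start - e1.end, 0)),
    }
    if tokens:
        between = [t for t in tokens if t]  # caller passes only between-tokens
        for t in between:
            feats[f"btw={t.lower()}"] = 1.0
    return feats


class PairClassifier:
    """Reference relation classifier over hashed entity-pair features.

    Features: the unordered entity-class pair, both surfaces, the character
    distance and a bag of tokens lying between the two spans. Because the
    pair is offset-ordered before featurization, predictions are symmetric
    in argument order by construction.
    """

    def __init__(self, labels: list[str], seed: int = 0, n_features: int = 2**15, epochs: int = 12) -> None:
        self.labels = sorted(labels)
        self.seed = seed
        self.n_features = n_features
        self.epochs = epochs
        self._hasher: FeatureHasher | None = None
        self._est: SGDClassifier | None = None

    def _featurize(self, sample: RelationSample, sentence=None) -> dict[str, float]:
        between: tuple[str, ...] | None = None
        if sentence is not None:
            between = tuple(
                t.surface for t in sentence.tokens if sample.e1.end <= t.start and t.end <= sample.e2.start
            )
        return _pair_features(sample, between)

    def fit(
        self,
        samples: list[RelationSample],
        sentences: dict[str, object] | None = None,
        init: "PairClassifier | None" = None,
    ) -> "PairClassifier":
        if not samples:
            raise ValueError("cannot fit a relation classifier on an empty training set")
        sentences = sentences or {}
        feats = [self._featurize(s, sentences.get(s.sent_id)) for s in samples]
        labels = [s.label for s in samples]
        self._hasher, self._est = _fit_sgd(
            feats,
            labels,
            classes=self.labels,
            seed=self.seed,
            n_features=self.n_features,
            epochs=self.epochs,
            init=None if init is None else init._est,
        )
        return self

    def predict(self, sample: RelationSample, sentence=None) -> str:
        return self.predict_many([sample], {sample.sent_id: sentence} if sentence is not None else None)[0]

    def predict_many(
        self, samples: list[RelationSample], sentences: dict[str, object] | None = None
    ) -> list[str]:
        if self._est is None:
            raise RuntimeError("relation classifier is not fitted")
        if not samples:
            return []
        sentences = sentences or {}
        X = self._hasher.transform([self._featurize(s, sentences.get(s.sent_id)) for s in samples])
        return [str(label) for label in self._est.predict(X)]


def fit_reference_relation_classifier(
    samples: list[RelationSample],
    seed: int = 0,
    labels: list[str] | None = None,
    sentences: dict[str, object] | None = None,
) -> PairClassifier:
    """Fit the reference pair classifier; label set defaults to labels seen in training."""
    if labels is None:
        labels = sorted({s.label for s in samples})
    return PairClassifier(labels=labels, seed=seed).fit(samples, sentences=sentences)


# ---------------------------------------------------------------------------
# Registry and serialization

_REGISTRY: dict[str, type] = {
    "unigram_mlm": UnigramMLM,
    "window_tagger": WindowTagger,
    "pair_classifier": PairClassifier,
}


def register_backend(name: str, cls: type) -> None:
    """Register a backend class (e.g. a transformer adapter) under a config name."""
    _REGISTRY[name] = cls


def get_backend(name: str) -> type:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}") from None


def save_backend(model, path: str) -> None:
    """Serialize a backend to a versioned binary blob with a content fingerprint."""
    payload = pickle.dumps(model, protocol=pickle.HIGHEST_PROTOCOL)
    blob = {
        "version": _BLOB_VERSION,
        "fingerprint": hashlib.sha256(payload).hexdigest()[:16],
        "payload": payload,
    }
    with open(path, "wb") as fh:
        pickle.dump(blob, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_backend(path: str):
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("version") != _BLOB_VERSION:
        raise ValueError(f"unsupported model blob version {blob.get('version')!r}")
    payload = blob["payload"]
    if hashlib.sha256(payload).hexdigest()[:16] != blob["fingerprint"]:
        raise ValueError("model blob fingerprint mismatch (corrupt file)")
    return pickle.loads(payload)
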