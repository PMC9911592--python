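"""Acquisition: pseudo-perplexity scoring and percentile-band batch selection.

The pseudo-perplexity (PPL) of a tokenized sentence ``X = (x_1 .. x_n)``
under a masked language model is

    PPL(X) = exp( -(1/n) * sum_i log p(x_i | X_{-i}) )

where each token is masked out in turn and predicted from the remaining
context. PPL is an intrinsic surprise score: it needs no task labels, only
a self-supervised model of the raw text, which is what makes it usable as
an acquisition function before any annotation exists.

Strategic sampling selects sentences lying jointly in an upper percentile
band (default the 75th-90th) of both PPL and sentence length: high enough
to be informative, capped to exclude outliers. Random sampling is the
baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corpus import SentenceRecord


@dataclass(frozen=True)
class AcquisitionScore:
    """Per-sentence (length, pseudo-perplexity) pair used for selection."""

    sent_id: str
    length: int
    ppl: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.sent_id}: length must be >= 1")
        if not math.isfinite(self.ppl) or self.ppl <= 0:
            raise ValueError(f"{self.sent_id}: pseudo-perplexity must be finite and positive")


@dataclass(frozen=True)
class BandSpec:
    """Percentile band (lo, hi] with bounds as fractions in [0, 1]."""

    lo: float = 0.75
    hi: float = 0.90

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi <= 1:
            raise ValueError(f"band bounds must satisfy 0 <= lo < hi <= 1, got ({self.lo}, {self.hi})")


def pseudo_perplexity(mlm, tokens: list[str], prob_floor: float = 1e-12) -> float:
    """Pseudo-perplexity of a token sequence under a masked language model.

    ``mlm`` must provide ``conditional_prob(token, left_context,
    right_context)`` returning a probability in (0, 1]. Probabilities are
    floored at ``prob_floor`` before taking logs (the score is undefined at
    p = 0).
    """
    if not tokens:
        raise ValueError("pseudo-perplexity of an empty token list is undefined")
    total = 0.0
    for i, tok in enumerate(tokens):
        p = mlm.conditional_prob(tok, tokens[:i], tokens[i + 1 :])
        if not math.isfinite(p):
            raise ValueError(f"non-finite probability for token {tok!r} at position {i}")
        total += math.log(max(p, prob_floor))
    return math.exp(-total / len(tokens))


class ScoreCache:
    """Memo of pseudo-perplexity scores keyed by (sent_id, model fingerprint)."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], AcquisitionScore] = {}

    def get(self, sent_id: str, fingerprint: str) -> AcquisitionScore | None:
        return self._store.get((sent_id, fingerprint))

    def put(self, score: AcquisitionScore, fingerprint: str) -> None:
        self._store[(score.sent_id, fingerprint)] = score

    def to_tsv(self) -> str:
        lines = ["sent_id\tlength\tppl\tmodel_fingerprint"]
        for (sid, fp), sc in sorted(self._store.items()):
            lines.append(f"{sid}\t{sc.length}\t{sc.ppl!r}\t{fp}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, content: str) -> "ScoreCache":
        cache = cls()
        for line in content.strip().splitlines()[1:]:
            sid, length, ppl, fp = line.split("\t")
            cache.put(AcquisitionScore(sent_id=sid, length=int(length), ppl=float(ppl)), fp)
        return cache


def score_pool(
    mlm,
    sentences: list[SentenceRecord],
    cache: ScoreCache | None = None,
    prob_floor: float = 1e-12,
) -> list[AcquisitionScore]:
    """Score each sentence with (token count, pseudo-perplexity), in input order.

    Length is measured in corpus tokens, not model subwords, so scores stay
    comparable across backends. Scores are cached by sentence id and model
    fingerprint when a cache is supplied.
    """
    fp = getattr(mlm, "fingerprint", None) or "unfingerprinted"
    scores: list[AcquisitionScore] = []
    for sent in sentences:
        if cache is not None:
            hit = cache.get(sent.sent_id, fp)
            if hit is not None:
                scores.append(hit)
                continue
        tokens = [t.surface for t in sent.tokens]
        try:
            ppl = pseudo_perplexity(mlm, tokens, prob_floor=prob_floor)
        except ValueError as exc:
            raise ValueError(f"scoring failed for sentence {sent.sent_id}: {exc}") from exc
        score = AcquisitionScore(sent_id=sent.sent_id, length=len(tokens), ppl=ppl)
        if cache is not None:
            cache.put(score, fp)
        scores.append(score)
    return scores


def percentile_band(values, band: BandSpec) -> set[int]:
    """Indices whose empirical percentile falls in the band (lo, hi].

    Index ``i`` is selected iff ``lo < rank_i / N <= hi`` where ``rank_i``
    is the 1-based ascending rank (ties broken by stable input order). No
    interpolation: selection needs index sets, not interpolated values.
    """
    values = list(values)
    n = len(values)
    if n == 0:
        raise ValueError("percentile band of an empty value list is undefined")
    order = np.argsort(np.asarray(values), kind="stable")
    selected: set[int] = set()
    for rank, idx in enumerate(order, start=1):
        frac = rank / n
        if band.lo < frac <= band.hi:
            selected.add(int(idx))
    return selected


def strategic_sample(
    scores: list[AcquisitionScore],
    band: BandSpec,
    batch_size: int,
    seed: int,
) -> list[str]:
    """Select a batch jointly high (but not extreme) in PPL and length.

    Candidates are the intersection of the PPL percentile band and the
    length percentile band. If too few, the batch is topped up uniformly
    from the union of the two bands, then from the full pool (fallback
    ladder). Deterministic under seed.
    """
    if not scores:
        raise ValueError("cannot sample from an empty pool")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    ppl_band = percentile_band([s.ppl for s in scores], band)
    len_band = percentile_band([s.length for s in scores], band)
    ids = [s.sent_id for s in scores]

    def _pick(pool: list[str], k: int) -> list[str]:
        if k >= len(pool):
            return list(pool)
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    inter = [ids[i] for i in sorted(ppl_band & len_band)]
    if len(inter) >= batch_size:
        return sorted(_pick(inter, batch_size))
    chosen = list(inter)
    union = [ids[i] for i in sorted(ppl_band | len_band) if ids[i] not in set(chosen)]
    chosen.extend(_pick(union, batch_size - len(chosen)))
    if len(chosen) < batch_size:
        rest = [sid for sid in ids if sid not in set(chosen)]
        chosen.extend(_pick(rest, batch_size - len(chosen)))
    return sorted(chosen)


def random_sample(pool: list[str], batch_size: int, seed: int) -> list[str]:
    """Uniform draw without replacement from sentence ids; seeded."""
    if batch_size > len(pool):
        raise ValueError(f"batch_size {batch_size} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=batch_size, replace=False)
    return [pool[i] for i in idx]
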