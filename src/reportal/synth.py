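"""Synthetic pseudo-clinical corpora for exercising the full pipeline.

Real clinical reports cannot be shipped, so this module generates
schema-consistent stand-in corpora from grammar-free slot-filler templates
over German-like nonsense tokens (no real clinical text, no PHI). The
generator is engineered to reproduce the statistical structure the
acquisition method exploits rather than realistic language:

* token types are drawn Zipf-wise within each entity class, so rare terms
  exist and sentences containing them are high-surprise under any
  frequency-based language model;
* a designated set of minority entity classes appears predominantly in the
  long templates (explicit length affinity), so longer sentences carry
  more, and rarer, entities;
* templates instantiate schema-legal relations, so relation samples obey
  the C(k, 2) pair law and the schema rules by construction.

A domain-pair generator shares a controllable fraction of vocabulary and
templates between two corpora, emulating the contrast between closely
related reporting domains (same anatomy, different modality) and distant
ones. An oracle annotator returns gold regardless of the soft labels it is
shown, enabling fully simulated active-learning runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import (
    DocumentRecord,
    EntitySpan,
    PoolItem,
    RelationAnnotation,
    SentenceRecord,
    Token,
    canonicalize_relation,
)
from .loop import GoldAnnotation, SoftLabels
from .schema import default_schema

# ---------------------------------------------------------------------------
# Templates

@dataclass(frozen=True)
class Slot:
    """An entity slot in a template; ``n_tokens`` is the surface length."""

    entity_class: str
    n_tokens: int = 1


@dataclass(frozen=True)
class Template:
    """A slot-filler sentence template.

    ``parts`` mixes literal filler strings and :class:`Slot` entries;
    ``relations`` lists (slot_index, slot_index, relation_class) triples
    over the slot sequence (0-based, in order of appearance).
    """

    name: str
    parts: tuple
    relations: tuple[tuple[int, int, str], ...]
    weight: float

    @property
    def slots(self) -> list[Slot]:
        return [p for p in self.parts if isinstance(p, Slot)]


_S = Slot

#: Majority entity classes (short/medium templates).
MAJORITY_CLASSES = (
    "Medical_condition",
    "Anatomical_entity",
    "Imaging_observation",
    "Certainty_descriptor",
    "Location_descriptor",
    "State_of_health",
    "Diaglab_procedure",
    "Time_information",
)

#: Minority classes, confined to the long templates (length affinity).
MINORITY_CLASSES = (
    "Dosing",
    "Non_anatomical_substance",
    "Procedure",
    "Medical_device",
    "Follow_Up",
    "Prior_investigation",
    "Quality_descriptor",
    "Radlex_descriptor",
    "Measurement",
    "Dynamism",
    "Property",
    "Score_Grade_Type",
)

#: Relation classes instantiated by the default templates.
ACTIVE_RELATIONS = ("Certainty", "Has_state", "Is_located", "Shows", "Examines", "Has_dosing")


def default_templates() -> tuple[Template, ...]:
    """The built-in template inventory.

    Weights put ~60% of sentences on short templates (0-3 entities), ~15%
    on medium, ~15% on long minority-rich templates and ~10% on extra-long
    outliers. The proportions are deliberate: sentence lengths then place
    the long templates in roughly the 75th-90th length percentile and the
    outliers above it, so an upper-but-capped percentile band selects the
    informative long sentences while genuinely excluding something.
    """
    return (
        # --- short (~60%) ----------------------------------------------
        Template(
            "short_negation",
            (_S("Certainty_descriptor"), _S("Medical_condition", 1), "."),
            ((0, 1, "Certainty"),),
            0.18,
        ),
        Template(
            "short_normal",
            (_S("State_of_health"), "darstellung", "der", _S("Anatomical_entity"), "."),
            ((0, 1, "Has_state"),),
            0.14,
        ),
        Template(
            "short_located",
            (_S("Medical_condition", 2), _S("Location_descriptor"), "."),
            ((0, 1, "Is_located"),),
            0.10,
        ),
        Template("short_filler", ("im", "verlauf", "unverändert", "."), (), 0.12),
        Template(
            "short_time",
            (_S("Time_information"), _S("Certainty_descriptor"), _S("Medical_condition"), "."),
            ((1, 2, "Certainty"),),
            0.06,
        ),
        # --- medium (~15%) ---------------------------------------------
        Template(
            "medium_exam",
            (
                _S("Diaglab_procedure"),
                "der",
                _S("Anatomical_entity"),
                "zeigt",
                _S("Certainty_descriptor"),
                _S("Medical_condition", 2),
                ".",
            ),
            ((0, 1, "Examines"), (2, 3, "Certainty")),
            0.09,
        ),
        Template(
            "medium_finding",
            (
                _S("Certainty_descriptor"),
                _S("Medical_condition", 2),
                "im",
                "bereich",
                _S("Location_descriptor"),
                "der",
                _S("Anatomical_entity"),
                ".",
            ),
            ((0, 1, "Certainty"), (1, 2, "Is_located"), (1, 3, "Is_located")),
            0.06,
        ),
        # --- long, minority-rich (~15%; 3 minority classes each) -------
        Template(
            "long_report",
            (
                _S("Diaglab_procedure"),
                "vom",
                "vortag",
                "zeigt",
                _S("Medical_condition", 2),
                _S("Location_descriptor"),
                "der",
                _S("Anatomical_entity"),
                "mit",
                _S("Measurement", 2),
                "sowie",
                _S("Dynamism"),
                _S("Imaging_observation"),
                "bei",
                _S("Radlex_descriptor"),
                "konfiguration",
                ".",
            ),
            ((0, 1, "Shows"), (1, 2, "Is_located"), (1, 3, "Is_located")),
            0.0375,
        ),
        Template(
            "long_dosing",
            (
                "nach",
                "gabe",
                "von",
                _S("Dosing", 2),
                _S("Non_anatomical_substance"),
                "zeigt",
                "sich",
                _S("Certainty_descriptor"),
                _S("Medical_condition", 2),
                _S("Location_descriptor"),
                "der",
                _S("Anatomical_entity"),
                "nach",
                _S("Procedure"),
                ".",
            ),
            ((0, 1, "Has_dosing"), (2, 3, "Certainty"), (3, 4, "Is_located")),
            0.0375,
        ),
        Template(
            "long_followup",
            (
                _S("Prior_investigation"),
                "im",
                "vergleich",
                _S("Imaging_observation", 2),
                _S("Location_descriptor"),
                "der",
                _S("Anatomical_entity"),
                "mit",
                _S("Medical_device"),
                "einliegend",
                "und",
                _S("State_of_health"),
                "befund",
                _S("Follow_Up", 2),
                "empfohlen",
                ".",
            ),
            ((1, 2, "Is_located"), (3, 5, "Has_state")),
            0.0375,
        ),
        Template(
            "long_exam_state",
            (
                _S("Diaglab_procedure"),
                "der",
                _S("Anatomical_entity"),
                "und",
                "der",
                _S("Anatomical_entity"),
                "mit",
                _S("State_of_health"),
                "darstellung",
                "sowie",
                _S("Score_Grade_Type", 2),
                _S("Quality_descriptor"),
                "bei",
                _S("Property"),
                _S("Imaging_observation"),
                ".",
            ),
            ((0, 1, "Examines"), (0, 2, "Examines"), (1, 3, "Has_state")),
            0.0375,
        ),
        # --- extra-long outliers (~10%) --------------------------------
        Template(
            "xlong_outlier",
            (
                "bei",
                "zustand",
                "nach",
                "voroperation",
                "und",
                "bekannter",
                _S("Medical_condition", 2),
                "zeigt",
                "die",
                _S("Diaglab_procedure"),
                "im",
                "wesentlichen",
                "unveränderte",
                "verhältnisse",
                "ohne",
                "anhalt",
                "für",
                "eine",
                "frische",
                "läsion",
                "im",
                "gesamten",
                "untersuchten",
                "bereich",
                "beidseits",
                "sowie",
                "regelrechte",
                "darstellung",
                "aller",
                "übrigen",
                "strukturen",
                _S("Time_information"),
                ".",
            ),
            ((0, 1, "Shows"),),
            0.10,
        ),
    )


# ---------------------------------------------------------------------------
# Configuration

_SYLLABLES = (
    "ba", "be", "bi", "bo", "bu", "da", "de", "di", "do", "du",
    "fa", "fe", "fi", "fo", "ga", "ge", "gi", "go", "ka", "ke",
    "ki", "ko", "la", "le", "li", "lo", "ma", "me", "mi", "mo",
    "na", "ne", "ni", "no", "ra", "re", "ri", "ro", "sa", "se",
    "si", "so", "ta", "te", "ti", "to", "va", "ve", "vi", "vo",
)

# Suffixes are drawn from a pool shared across all classes: a word's ending
# must not reveal its entity class, otherwise tagging degenerates into a
# suffix lookup and rare classes would need no labeled examples at all.
_SUFFIXES = ("e", "ung", "is", "al", "er", "en", "om", "ie")


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    Defaults define the package's standard study conditions: 2,000
    sentences over the 20-class default schema with 6 active relation
    classes, Zipf exponent 1.2 within each class vocabulary, ~8% of entity
    mentions from minority classes that occur only in long templates, and
    a 0.9 probability that a template relation is actually annotated.
    """

    n_sentences: int = 2000
    zipf_exponent: float = 1.2
    vocab_sizes: dict[str, int] = field(default_factory=dict)
    templates: tuple[Template, ...] = field(default_factory=default_templates)
    relation_density: float = 0.9
    minority_classes: tuple[str, ...] = MINORITY_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if not 0 <= self.relation_density <= 1:
            raise ValueError("relation_density must lie in [0, 1]")

    def vocab_size(self, cls: str) -> int:
        if cls in self.vocab_sizes:
            return self.vocab_sizes[cls]
        return 10 if cls in self.minority_classes else 25


@dataclass(frozen=True)
class DomainPairConfig:
    """Two-domain configuration: a base config plus an overlap fraction.

    ``overlap`` is the expected fraction of word types and templates shared
    between domain A and domain B; 1 means identical generative
    distributions, 0 means disjoint content vocabularies.
    """

    base: SynthConfig = field(default_factory=SynthConfig)
    overlap: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Vocabulary

def _make_word(rng: np.random.Generator, domain_tag: str, used: set[str]) -> str:
    for _ in range(1000):
        n = int(rng.integers(2, 4))
        suffix = str(rng.choice(_SUFFIXES))
        word = "".join(rng.choice(_SYLLABLES, size=n)) + suffix + domain_tag
        if word not in used:
            used.add(word)
            return word
    raise RuntimeError("vocabulary space exhausted")


def build_vocabulary(
    config: SynthConfig, rng: np.random.Generator, domain_tag: str = ""
) -> dict[str, list[str]]:
    """Per-class word-type lists; index order is Zipf rank order."""
    schema = default_schema()
    used: set[str] = set()
    vocab: dict[str, list[str]] = {}
    for cls in sorted(schema.entity_classes):
        vocab[cls] = [_make_word(rng, domain_tag, used) for _ in range(config.vocab_size(cls))]
    return vocab


def _zipf_probs(n: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-s
    return w / w.sum()


# ---------------------------------------------------------------------------
# Corpus generation

def _instantiate(
    template: Template,
    vocab: dict[str, list[str]],
    zipf_exponent: float,
    relation_density: float,
    rng: np.random.Generator,
    doc_id: str,
) -> DocumentRecord:
    tokens: list[str] = []
    entities: list[EntitySpan] = []
    slot_eids: list[str] = []
    cursor = 0
    offsets: list[tuple[int, int]] = []
    for part in template.parts:
        if isinstance(part, Slot):
            words = []
            probs = _zipf_probs(len(vocab[part.entity_class]), zipf_exponent)
            for _ in range(part.n_tokens):
                words.append(vocab[part.entity_class][int(rng.choice(len(probs), p=probs))])
            surface = " ".join(words)
            start = cursor
            end = start + len(surface)
            eid = f"T{len(entities) + 1}"
            entities.append(
                EntitySpan(id=eid, label=part.entity_class, start=start, end=end, surface=surface)
            )
            slot_eids.append(eid)
            tokens.append(surface)
            offsets.append((start, end))
            cursor = end + 1
        else:
            tokens.append(part)
            offsets.append((cursor, cursor + len(part)))
            cursor += len(part) + 1
    text = " ".join(tokens)
    by_id = {e.id: e for e in entities}
    relations = []
    for i, j, label in template.relations:
        if rng.random() < relation_density:
            relations.append(canonicalize_relation(label, slot_eids[i], slot_eids[j], by_id))
    doc = DocumentRecord(doc_id=doc_id, text=text, entities=entities, relations=relations)
    tok_objs = []
    for surf, (s, _e) in zip(tokens, offsets):
        for w_off, w in _iter_words(surf):
            tok_objs.append(Token(w, s + w_off, s + w_off + len(w)))
    doc.sentences = [
        SentenceRecord(
            sent_id=f"{doc_id}:s0",
            start=0,
            end=len(text),
            tokens=tuple(tok_objs),
            entity_ids=tuple(e.id for e in entities),
        )
    ]
    return doc


def _iter_words(surface: str):
    off = 0
    for w in surface.split(" "):
        yield off, w
        off += len(w) + 1


def generate_corpus(config: SynthConfig) -> list[DocumentRecord]:
    """Generate a corpus of single-sentence documents with gold annotations.

    Fully deterministic under ``config.seed``: the same config yields a
    byte-identical corpus. Every document is schema-valid by construction.
    """
    rng = np.random.default_rng(config.seed)
    vocab = build_vocabulary(config, rng)
    return _generate_docs(config, vocab, rng, prefix="syn")


def _generate_docs(
    config: SynthConfig,
    vocab: dict[str, list[str]],
    rng: np.random.Generator,
    prefix: str,
) -> list[DocumentRecord]:
    weights = np.array([t.weight for t in config.templates], dtype=float)
    weights = weights / weights.sum()
    docs = []
    for i in range(config.n_sentences):
        template = config.templates[int(rng.choice(len(weights), p=weights))]
        docs.append(
            _instantiate(
                template,
                vocab,
                config.zipf_exponent,
                config.relation_density,
                rng,
                doc_id=f"{prefix}{i:05d}",
            )
        )
    return docs


def _perturb_template(template: Template, rng: np.random.Generator, tag: str) -> Template:
    """Domain-specific template variant: fillers replaced, slots preserved."""
    parts = tuple(
        part if isinstance(part, Slot) or part == "." else f"{part}{tag}" for part in template.parts
    )
    return replace(template, name=f"{template.name}{tag}", parts=parts)


def domain_pair_materials(
    pair_config: DomainPairConfig,
) -> tuple[dict[str, list[str]], dict[str, list[str]], tuple[Template, ...]]:
    """The generative materials of a domain pair: vocab A, vocab B, templates B.

    Domain B keeps each of A's word types (per class) and each template
    independently with probability ``overlap``, replacing the rest with
    B-specific material.
    """
    base = pair_config.base
    rng = np.random.default_rng(base.seed)
    vocab_a = build_vocabulary(base, rng)
    rng_b = np.random.default_rng(base.seed + 1)
    vocab_b_fresh = build_vocabulary(base, rng_b, domain_tag="q")
    vocab_b: dict[str, list[str]] = {}
    for cls in sorted(vocab_a):
        vocab_b[cls] = [
            a if rng_b.random() < pair_config.overlap else b
            for a, b in zip(vocab_a[cls], vocab_b_fresh[cls])
        ]
    templates_b = tuple(
        t if rng_b.random() < pair_config.overlap else _perturb_template(t, rng_b, "q")
        for t in base.templates
    )
    return vocab_a, vocab_b, templates_b


def vocabulary_overlap_fraction(pair_config: DomainPairConfig) -> float:
    """Realized fraction of domain-B word types shared with domain A."""
    vocab_a, vocab_b, _ = domain_pair_materials(pair_config)
    types_a = {w for words in vocab_a.values() for w in words}
    types_b = [w for words in vocab_b.values() for w in words]
    return sum(w in types_a for w in types_b) / len(types_b)


def make_domain_pair(pair_config: DomainPairConfig) -> tuple[list[DocumentRecord], list[DocumentRecord]]:
    """Generate two corpora sharing an ``overlap`` fraction of vocabulary and templates.

    Domain A uses the base configuration unchanged; domain B uses the
    materials of :func:`domain_pair_materials`. Both corpora are
    schema-valid; only content differs.
    """
    base = pair_config.base
    vocab_a, vocab_b, templates_b = domain_pair_materials(pair_config)
    docs_a = _generate_docs(base, vocab_a, np.random.default_rng(base.seed + 10), prefix="da")
    config_b = replace(base, templates=templates_b)
    docs_b = _generate_docs(config_b, vocab_b, np.random.default_rng(base.seed + 11), prefix="db")
    return docs_a, docs_b


def shared_vocabulary_fraction(
    docs_a: list[DocumentRecord], docs_b: list[DocumentRecord]
) -> float:
    """Fraction of domain-B entity word types also occurring in domain A."""
    types_a = {w for d in docs_a for e in d.entities for w in e.surface.split()}
    types_b = {w for d in docs_b for e in d.entities for w in e.surface.split()}
    if not types_b:
        return 0.0
    return len(types_a & types_b) / len(types_b)


# ---------------------------------------------------------------------------
# Oracle annotator

class OracleAnnotator:
    """Simulated annotator that corrects soft labels back to gold.

    Returns the gold annotation of each sentence regardless of the soft
    labels shown, and records how many soft tags / relation labels differed
    from gold (the correction effort a human would have spent).
    """

    def __init__(self, gold: dict[str, PoolItem]) -> None:
        self.gold = gold
        self.corrections: list[tuple[str, int]] = []

    def annotate(self, sentence: SentenceRecord, soft_labels: SoftLabels) -> GoldAnnotation:
        sid = sentence.sent_id
        if sid not in self.gold:
            raise KeyError(f"sentence {sid} is outside the gold pool")
        item = self.gold[sid]
        from .encoding import spans_to_iob

        gold_tags = spans_to_iob(item.sentence, list(item.entities)).tags
        n_bad = sum(a != b for a, b in zip(soft_labels.tags, gold_tags))
        if len(soft_labels.tags) != len(gold_tags):
            n_bad += abs(len(soft_labels.tags) - len(gold_tags))
        gold_rel = {
            frozenset({r.arg1, r.arg2}): r.label for r in item.relations
        }
        for (a, b), label in soft_labels.relation_labels.items():
            if gold_rel.get(frozenset({a, b}), "no_relation") != label:
                n_bad += 1
        self.corrections.append((sid, n_bad))
        return GoldAnnotation(sent_id=sid, entities=item.entities, relations=item.relations)


def oracle_annotator(gold: dict[str, PoolItem]) -> OracleAnnotator:
    """Build an oracle annotator over a gold pool (keyed by sentence id)."""
    return OracleAnnotator(gold)
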