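"""Corpus handling: brat-standoff I/O, section extraction, sentence splitting.

Documents are plain text with character-offset annotations. All offsets are
0-based half-open character positions into the raw document text, everywhere
in the package; token offsets inside sentences are document-absolute.
Relations are undirected and stored canonically with the earlier span first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .schema import NO_RELATION, SchemaDef


class StandoffParseError(ValueError):
    """Malformed or inconsistent brat-standoff content."""


class SchemaViolationError(ValueError):
    """Annotation uses a class unknown to the schema."""


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity anchored by character offsets.

    ``surface`` must equal ``text[start:end]`` of the owning document;
    this is asserted on every standoff read.
    """

    id: str
    label: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"entity {self.id}: invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class RelationAnnotation:
    """An undirected binary relation between two entity spans.

    ``arg1``/``arg2`` are entity ids; canonical form puts the span that
    starts (then ends) earlier in ``arg1``. Use :func:`canonicalize_relation`
    to build canonical instances — direction is never meaningful.
    """

    label: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if self.arg1 == self.arg2:
            raise ValueError(f"relation {self.label}: arguments must be distinct entities")


def canonicalize_relation(
    label: str, arg1: str, arg2: str, entities_by_id: dict[str, EntitySpan]
) -> RelationAnnotation:
    """Order relation arguments by (start, end) offset of their spans. Idempotent."""
    e1, e2 = entities_by_id[arg1], entities_by_id[arg2]
    if (e1.start, e1.end) > (e2.start, e2.end):
        arg1, arg2 = arg2, arg1
    return RelationAnnotation(label=label, arg1=arg1, arg2=arg2)


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence: document slice plus its tokens and wholly contained entities."""

    sent_id: str
    start: int
    end: int
    tokens: tuple[Token, ...]
    entity_ids: tuple[str, ...] = ()


@dataclass
class DocumentRecord:
    """One report: raw text, section map, sentences, entities, relations."""

    doc_id: str
    text: str
    sections: dict[str, tuple[int, int]] = field(default_factory=dict)
    sentences: list[SentenceRecord] = field(default_factory=list)
    entities: list[EntitySpan] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    @property
    def entities_by_id(self) -> dict[str, EntitySpan]:
        return {e.id: e for e in self.entities}

    def sentence_entities(self, sentence: SentenceRecord) -> list[EntitySpan]:
        by_id = self.entities_by_id
        return [by_id[eid] for eid in sentence.entity_ids]


@dataclass(frozen=True)
class PoolItem:
    """One sentence of the unlabeled/labeled pool with its gold annotations.

    ``relations`` holds only within-sentence relations whose arguments are
    both in ``entities``; cross-sentence relations never enter the pool.
    """

    sentence: SentenceRecord
    entities: tuple[EntitySpan, ...]
    relations: tuple[RelationAnnotation, ...]
    doc_id: str

    @property
    def sent_id(self) -> str:
        return self.sentence.sent_id


def build_pool(docs: list[DocumentRecord]) -> dict[str, PoolItem]:
    """Flatten documents into a sentence pool keyed by sentence id.

    Documents must already be sentence-split. Relations are attached to the
    sentence containing both arguments; others are dropped (they are
    surfaced by validate_annotations).
    """
    pool: dict[str, PoolItem] = {}
    for doc in docs:
        by_id = doc.entities_by_id
        for sent in doc.sentences:
            eids = set(sent.entity_ids)
            rels = tuple(r for r in doc.relations if r.arg1 in eids and r.arg2 in eids)
            pool[sent.sent_id] = PoolItem(
                sentence=sent,
                entities=tuple(by_id[eid] for eid in sent.entity_ids),
                relations=rels,
                doc_id=doc.doc_id,
            )
    return pool


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

#: German-flavored abbreviations that must not terminate a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {"z.b", "u.a", "ca", "bzw", "vgl", "dr", "prof", "st", "evtl", "ggf", "v.a", "re", "li"}
)


def tokenize(text: str, offset: int = 0) -> tuple[Token, ...]:
    """Default tokenizer: runs of word characters plus standalone punctuation.

    Subword tokenization is a model concern and lives behind the backend
    tokenizer interface; corpus offsets stay model-independent.
    """
    return tuple(
        Token(m.group(), m.start() + offset, m.end() + offset) for m in _TOKEN_RE.finditer(text)
    )


def rule_based_splitter(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Abbreviation-safe period/linebreak sentence splitter.

    Returns (start, end) character ranges. A period ends a sentence unless
    the preceding word (with trailing dots stripped, lowercased) is a known
    abbreviation or a single letter/digit (enumeration markers, initials).
    """
    boundaries: list[int] = []
    for m in re.finditer(r"[.!?]+|\n+", text):
        if m.group().startswith("\n"):
            boundaries.append(m.end())
            continue
        before = text[: m.start()]
        word_m = re.search(r"(\S+)$", before)
        if word_m:
            word = word_m.group(1).rstrip(".").lower()
            if word in abbreviations or len(word) <= 1:
                continue
        boundaries.append(m.end())
    spans: list[tuple[int, int]] = []
    prev = 0
    for b in boundaries + [len(text)]:
        seg = text[prev:b]
        stripped = seg.strip()
        if stripped:
            lead = len(seg) - len(seg.lstrip())
            spans.append((prev + lead, prev + lead + len(stripped)))
        prev = b
    return spans


def split_sentences(doc: DocumentRecord, splitter=None) -> tuple[list[SentenceRecord], list[str]]:
    """Split a document into sentences and assign wholly contained entities.

    Returns (sentences, issues). An entity straddling a sentence boundary is
    recorded as an issue and assigned to no sentence (it is then excluded
    from sentence-level samples). The sentence list is also stored on the
    document.
    """
    splitter = splitter or rule_based_splitter
    ranges = splitter(doc.text)
    issues: list[str] = []
    sentences: list[SentenceRecord] = []
    assigned: set[str] = set()
    for i, (s, e) in enumerate(ranges):
        toks = tokenize(doc.text[s:e], offset=s)
        eids = tuple(ent.id for ent in doc.entities if s <= ent.start and ent.end <= e)
        assigned.update(eids)
        sentences.append(
            SentenceRecord(sent_id=f"{doc.doc_id}:s{i}", start=s, end=e, tokens=toks, entity_ids=eids)
        )
    for ent in doc.entities:
        if ent.id not in assigned:
            issues.append(
                f"entity {ent.id} [{ent.start},{ent.end}) straddles a sentence boundary; "
                "excluded from sentence-level samples"
            )
    doc.sentences = sentences
    return sentences, issues


# ---------------------------------------------------------------------------
# Section extraction

#: Default header synonyms (case-insensitive), German and English variants.
DEFAULT_SECTION_HEADERS: dict[str, str] = {
    "befund": "findings",
    "findings": "findings",
    "beurteilung": "impression",
    "impression": "impression",
    "anamnese": "history",
    "history": "history",
    "klinik": "history",
    "vergleich": "comparison",
    "voruntersuchung": "comparison",
    "comparison": "comparison",
}


def extract_sections(
    report_text: str, section_headers: dict[str, str] | None = None
) -> dict[str, str]:
    """Segment a report into named sections.

    ``section_headers`` maps header surface form (matched case-insensitively,
    followed by a colon) to canonical section name. Each detected header owns
    the text up to the next header; text before the first header goes to
    ``preamble``; a repeated header appends to its section. Missing sections
    are simply absent.
    """
    headers = section_headers or DEFAULT_SECTION_HEADERS
    pattern = re.compile(
        r"(?i)\b(" + "|".join(re.escape(h) for h in sorted(headers, key=len, reverse=True)) + r")\s*:",
    )
    matches = list(pattern.finditer(report_text))
    sections: dict[str, str] = {}

    def _append(name: str, chunk: str) -> None:
        chunk = chunk.strip()
        if not chunk:
            return
        sections[name] = (sections[name] + "\n" + chunk) if name in sections else chunk

    if not matches:
        _append("preamble", report_text)
        return sections
    _append("preamble", report_text[: matches[0].start()])
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(report_text)
        name = headers[m.group(1).lower()]
        _append(name, report_text[m.end() : end])
    return sections


# ---------------------------------------------------------------------------
# brat standoff

def read_standoff(
    txt_content: str,
    ann_content: str,
    schema: SchemaDef,
    doc_id: str = "doc",
) -> DocumentRecord:
    """Parse a brat-standoff (.txt, .ann) pair into a DocumentRecord.

    Recognizes T (entity) and R (binary relation) lines. Offsets are 0-based
    half-open; every T line's surface field is cross-checked against the text
    slice. Relations are canonicalized (earlier span first). A- and #-lines
    are out of scope and rejected; blank lines are ignored.
    """
    entities: list[EntitySpan] = []
    raw_relations: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise StandoffParseError(f"line {lineno} ({tag}): expected 3 tab-separated fields")
            try:
                label, start_s, end_s = fields[1].split(" ")
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise StandoffParseError(f"line {lineno} ({tag}): malformed span field") from exc
            surface = fields[2]
            if label not in schema.entity_classes:
                raise SchemaViolationError(f"line {lineno} ({tag}): unknown entity class {label!r}")
            if not 0 <= start < end <= len(txt_content):
                raise StandoffParseError(
                    f"line {lineno} ({tag}): span [{start},{end}) outside text of length {len(txt_content)}"
                )
            if txt_content[start:end] != surface:
                raise StandoffParseError(
                    f"line {lineno} ({tag}): surface {surface!r} does not match text slice "
                    f"{txt_content[start:end]!r}"
                )
            entities.append(EntitySpan(id=tag, label=label, start=start, end=end, surface=surface))
        elif tag.startswith("R"):
            if len(fields) < 2:
                raise StandoffParseError(f"line {lineno} ({tag}): expected 2 tab-separated fields")
            try:
                label, a1, a2 = fields[1].split(" ")
                arg1 = a1.split(":", 1)[1]
                arg2 = a2.split(":", 1)[1]
            except (ValueError, IndexError) as exc:
                raise StandoffParseError(f"line {lineno} ({tag}): malformed relation field") from exc
            if label not in schema.relation_classes and label != NO_RELATION:
                raise SchemaViolationError(f"line {lineno} ({tag}): unknown relation class {label!r}")
            raw_relations.append((label, arg1, arg2))
        else:
            raise StandoffParseError(
                f"line {lineno}: unsupported annotation type {tag!r} (only T and R lines)"
            )
    by_id = {e.id: e for e in entities}
    relations = []
    for label, arg1, arg2 in raw_relations:
        for a in (arg1, arg2):
            if a not in by_id:
                raise StandoffParseError(f"relation {label} references unknown entity {a!r}")
        relations.append(canonicalize_relation(label, arg1, arg2, by_id))
    return DocumentRecord(doc_id=doc_id, text=txt_content, entities=entities, relations=relations)


def write_standoff(doc: DocumentRecord) -> tuple[str, str]:
    """Serialize a document to (txt_content, ann_content).

    Inverse of :func:`read_standoff`: the round trip reproduces entities and
    relations exactly.
    """
    lines: list[str] = []
    for ent in doc.entities:
        lines.append(f"{ent.id}\t{ent.label} {ent.start} {ent.end}\t{ent.surface}")
    for i, rel in enumerate(doc.relations, start=1):
        lines.append(f"R{i}\t{rel.label} Arg1:{rel.arg1} Arg2:{rel.arg2}")
    ann = "\n".join(lines)
    if lines:
        ann += "\n"
    return doc.text, ann


# ---------------------------------------------------------------------------
# Validation

def validate_annotations(doc: DocumentRecord, schema: SchemaDef) -> list[str]:
    """Report schema and consistency issues; never raises.

    Flags unknown classes, surface mismatches, overlapping entity spans,
    relations violating the schema's argument rules, and cross-sentence
    relations (excluded from within-sentence samples).
    """
    issues: list[str] = []
    by_id = doc.entities_by_id
    for ent in doc.entities:
        if ent.label not in schema.entity_classes:
            issues.append(f"entity {ent.id}: unknown class {ent.label!r}")
        if ent.end > len(doc.text) or doc.text[ent.start : ent.end] != ent.surface:
            issues.append(f"entity {ent.id}: surface does not match text slice")
    ordered = sorted(doc.entities, key=lambda e: (e.start, e.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            issues.append(f"entities {a.id} and {b.id}: overlapping spans")
    sent_of: dict[str, str] = {}
    for sent in doc.sentences:
        for eid in sent.entity_ids:
            sent_of[eid] = sent.sent_id
    for rel in doc.relations:
        if rel.label not in schema.relation_classes and rel.label != NO_RELATION:
            issues.append(f"relation {rel.label}({rel.arg1},{rel.arg2}): unknown class")
            continue
        e1, e2 = by_id.get(rel.arg1), by_id.get(rel.arg2)
        if e1 is None or e2 is None:
            issues.append(f"relation {rel.label}: missing argument entity")
            continue
        if not schema.pair_allowed(rel.label, e1.label, e2.label):
            issues.append(
                f"relation {rel.label}({rel.arg1},{rel.arg2}): pair "
                f"({e1.label}, {e2.label}) not allowed by schema rules"
            )
        if doc.sentences:
            s1, s2 = sent_of.get(rel.arg1), sent_of.get(rel.arg2)
            if s1 != s2 or s1 is None:
                issues.append(
                    f"relation {rel.label}({rel.arg1},{rel.arg2}): arguments not in the same sentence"
                )
    return issues
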