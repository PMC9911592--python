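"""Annotation schema for clinical information extraction.

The default schema covers general radiology reporting: 20 entity classes
(findings, anatomy, descriptors, specifications such as dosing and
measurements) and 15 undirected binary relation classes, plus the reserved
``no_relation`` label that marks entity pairs with no annotated relation.
Relation rules restrict which unordered entity-class pairs a relation may
connect; an empty rule set means the relation is unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

NO_RELATION = "no_relation"

#: The 20 default entity classes.
DEFAULT_ENTITY_CLASSES = (
    "Medical_condition",
    "Anatomical_entity",
    "Imaging_observation",
    "Diaglab_procedure",
    "Non_anatomical_substance",
    "Procedure",
    "Medical_device",
    "Follow_Up",
    "Prior_investigation",
    "Location_descriptor",
    "Certainty_descriptor",
    "Quality_descriptor",
    "Radlex_descriptor",
    "Dosing",
    "State_of_health",
    "Measurement",
    "Time_information",
    "Dynamism",
    "Property",
    "Score_Grade_Type",
)

#: The 15 default relation classes (undirected).
DEFAULT_RELATION_CLASSES = (
    "Shows",
    "Examines",
    "Compares",
    "DDx",
    "Recommendation",
    "Has_state",
    "Has_property",
    "Has_dosing",
    "Has_time_info",
    "Has_measure",
    "Has_dynamic",
    "Has_score",
    "Has_treated",
    "Is_located",
    "Certainty",
)

# Argument restrictions for relations whose definitions name concrete
# entity classes.  Relations defined over "various terms" carry an empty
# set and accept any pair.
DEFAULT_RELATION_RULES: dict[str, frozenset[frozenset[str]]] = {
    "Shows": frozenset(
        {
            frozenset({"Diaglab_procedure", "Medical_condition"}),
            frozenset({"Diaglab_procedure", "Imaging_observation"}),
            frozenset({"Diaglab_procedure", "State_of_health"}),
        }
    ),
    "Examines": frozenset({frozenset({"Diaglab_procedure", "Anatomical_entity"})}),
    "Compares": frozenset(),
    "DDx": frozenset(),
    "Recommendation": frozenset(),
    "Has_state": frozenset(
        {
            frozenset({"Medical_condition", "Imaging_observation"}),
            frozenset({"Anatomical_entity", "Imaging_observation"}),
            frozenset({"Anatomical_entity", "State_of_health"}),
            frozenset({"Medical_condition", "State_of_health"}),
        }
    ),
    "Has_property": frozenset(),
    "Has_dosing": frozenset({frozenset({"Dosing", "Non_anatomical_substance"})}),
    "Has_time_info": frozenset(),
    "Has_measure": frozenset(),
    "Has_dynamic": frozenset(),
    "Has_score": frozenset(
        {
            frozenset({"Score_Grade_Type", "Medical_condition"}),
            frozenset({"Score_Grade_Type", "Imaging_observation"}),
            frozenset({"Score_Grade_Type", "Anatomical_entity"}),
            frozenset({"Score_Grade_Type", "Property"}),
        }
    ),
    "Has_treated": frozenset({frozenset({"Procedure", "Medical_condition"})}),
    "Is_located": frozenset(
        {
            frozenset({"Location_descriptor", "Medical_condition"}),
            frozenset({"Location_descriptor", "Imaging_observation"}),
            frozenset({"Location_descriptor", "Anatomical_entity"}),
            frozenset({"Anatomical_entity", "Medical_condition"}),
            frozenset({"Anatomical_entity", "Imaging_observation"}),
        }
    ),
    "Certainty": frozenset(),
}


class SchemaError(ValueError):
    """Invalid schema definition (duplicate/unknown class, bad name)."""


@dataclass(frozen=True)
class SchemaDef:
    """A validated annotation schema.

    Parameters
    ----------
    entity_classes
        Allowed entity class names.
    relation_classes
        Allowed relation class names. ``no_relation`` is reserved for
        unannotated pairs and must not appear here.
    relation_rules
        Map relation name -> set of unordered entity-class pairs the
        relation may connect. A relation absent from the map, or mapped
        to an empty set, is unrestricted.
    """

    entity_classes: frozenset[str]
    relation_classes: frozenset[str]
    relation_rules: dict[str, frozenset[frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in list(self.entity_classes) + list(self.relation_classes):
            if not name or any(ch.isspace() for ch in name):
                raise SchemaError(f"invalid class name: {name!r}")
        if NO_RELATION in self.relation_classes:
            raise SchemaError(f"{NO_RELATION!r} is reserved and cannot be a relation class")
        overlap = self.entity_classes & self.relation_classes
        if overlap:
            raise SchemaError(f"names used as both entity and relation class: {sorted(overlap)}")
        for rel, pairs in self.relation_rules.items():
            if rel not in self.relation_classes:
                raise SchemaError(f"rule for unknown relation class {rel!r}")
            for pair in pairs:
                unknown = set(pair) - set(self.entity_classes)
                if unknown:
                    raise SchemaError(f"rule for {rel!r} references unknown entity class(es) {sorted(unknown)}")
                if not 1 <= len(pair) <= 2:
                    raise SchemaError(f"rule pair for {rel!r} must contain one or two classes")

    def iob_tags(self) -> list[str]:
        """All IOB tags implied by the schema: O plus B-/I- per entity class."""
        tags = ["O"]
        for cls in sorted(self.entity_classes):
            tags.extend([f"B-{cls}", f"I-{cls}"])
        return tags

    def relation_labels(self) -> list[str]:
        """All relation sample labels: the relation classes plus no_relation."""
        return sorted(self.relation_classes) + [NO_RELATION]

    def pair_allowed(self, relation: str, class_a: str, class_b: str) -> bool:
        """Whether ``relation`` may connect entities of the two classes."""
        if relation == NO_RELATION:
            return True
        if relation not in self.relation_classes:
            raise SchemaError(f"unknown relation class {relation!r}")
        pairs = self.relation_rules.get(relation, frozenset())
        if not pairs:  # unrestricted
            return True
        return frozenset({class_a, class_b}) in pairs


def default_schema() -> SchemaDef:
    """The built-in general radiology schema (20 entity / 15 relation classes)."""
    return SchemaDef(
        entity_classes=frozenset(DEFAULT_ENTITY_CLASSES),
        relation_classes=frozenset(DEFAULT_RELATION_CLASSES),
        relation_rules=dict(DEFAULT_RELATION_RULES),
    )


def _check_duplicates(names: list[str], kind: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise SchemaError(f"duplicate {kind} class name {n!r}")
        seen.add(n)


def load_schema(path: str | None = None) -> SchemaDef:
    """Load a schema from a YAML config, or the built-in default.

    The config is a mapping with keys ``entities`` (list of names),
    ``relations`` (list of names) and optional ``rules`` (mapping
    relation name -> list of two-element entity-class lists).
    """
    if path is None:
        return default_schema()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    entities = [str(e) for e in raw.get("entities", [])]
    relations = [str(r) for r in raw.get("relations", [])]
    _check_duplicates(entities, "entity")
    _check_duplicates(relations, "relation")
    rules: dict[str, frozenset[frozenset[str]]] = {}
    for rel, pair_list in (raw.get("rules") or {}).items():
        rules[str(rel)] = frozenset(frozenset(str(c) for c in pair) for pair in pair_list)
    return SchemaDef(
        entity_classes=frozenset(entities),
        relation_classes=frozenset(relations),
        relation_rules=rules,
    )


def dump_schema(schema: SchemaDef, path: str) -> None:
    """Write a schema back to the YAML config format read by load_schema."""
    doc = {
        "entities": sorted(schema.entity_classes),
        "relations": sorted(schema.relation_classes),
        "rules": {
            rel: [sorted(pair) for pair in sorted(pairs, key=sorted)]
            for rel, pairs in sorted(schema.relation_rules.items())
            if pairs
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
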