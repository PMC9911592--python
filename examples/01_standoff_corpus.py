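"""Read a brat-standoff annotated sentence, validate it, and round-trip it.

Brat standoff pairs a raw .txt with a .ann file whose T lines anchor typed
entity spans by character offsets and whose R lines connect two entities
with an undirected relation.
"""

from reportal import default_schema, read_standoff, split_sentences, validate_annotations, write_standoff

text = "Keine rezente Blutung"
ann = (
    "T1\tCertainty_descriptor 0 5\tKeine\n"
    "T2\tTime_information 6 13\trezente\n"
    "T3\tMedical_condition 14 21\tBlutung\n"
    "R1\tCertainty Arg1:T1 Arg2:T3\n"
)

schema = default_schema()
doc = read_standoff(text, ann, schema, doc_id="report1")
split_sentences(doc)

print(f"entities: {[(e.label, e.surface) for e in doc.entities]}")
print(f"relations: {[(r.label, r.arg1, r.arg2) for r in doc.relations]}")
print(f"validation issues: {validate_annotations(doc, schema)}")

txt2, ann2 = write_standoff(doc)
doc2 = read_standoff(txt2, ann2, schema)
print(f"round trip preserves annotations: {doc2.entities == doc.entities and doc2.relations == doc.relations}")
# The three spans cover a negated finding: the certainty descriptor "Keine"
# (no) qualifies the medical condition "Blutung" (bleeding) via a Certainty
# relation; an empty issue list means the annotation is schema-consistent.
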