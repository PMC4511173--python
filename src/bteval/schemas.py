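"""Task schemas and document validation.

A schema names the entity types allowed in a task and, for each event
type, its role signature: which roles exist and what may fill them.
Role fillers are entity type names, or ``event:<Type>`` for nested
events (``event:*`` admits any event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .standoff import AnnotatedDocument, EventAnnotation, SchemaError

EFFECT_LABELS = ("Activation", "Inhibition", "Requirement", "Regulation")
MECHANISM_LABELS = ("Binding", "Transcription")
ARC_LABELS = EFFECT_LABELS + MECHANISM_LABELS

INTERACTION_TYPES = tuple(f"Interaction:{label}" for label in ARC_LABELS)


@dataclass(frozen=True)
class RoleSpec:
    fillers: frozenset[str]
    required: bool = True

    def admits(self, doc: AnnotatedDocument, arg_id: str) -> bool:
        if arg_id in doc.entities:
            return doc.entities[arg_id].etype in self.fillers
        if arg_id in doc.events:
            etype = doc.events[arg_id].etype
            return "event:*" in self.fillers or f"event:{etype}" in self.fillers
        return False


@dataclass(frozen=True)
class TaskSchema:
    name: str
    entity_types: frozenset[str]
    events: dict[str, dict[str, RoleSpec]] = field(default_factory=dict)


def _roles(**kwargs: object) -> dict[str, RoleSpec]:
    out = {}
    for role, spec in kwargs.items():
        required = True
        if isinstance(spec, tuple) and spec and spec[-1] is None:
            required, spec = False, spec[:-1]
        fillers = frozenset([spec] if isinstance(spec, str) else spec)  # type: ignore[list-item]
        out[role] = RoleSpec(fillers, required)
    return out


_GRN_ENTITIES = frozenset({
    "Gene", "Protein", "Promoter", "Site", "Regulon",
    "GeneFamily", "ProteinFamily", "ProteinComplex", "PolymeraseComplex",
})

_GENE_LIKE = ("Gene", "Protein", "GeneFamily", "ProteinFamily",
              "ProteinComplex", "PolymeraseComplex")
_AGENTS = _GENE_LIKE + ("event:*",)

GRN_SCHEMA = TaskSchema(
    name="GRN",
    entity_types=_GRN_ENTITIES,
    events={
        **{etype: _roles(Agent=_AGENTS, Target=_GENE_LIKE + ("Promoter", "Site", "event:*"))
           for etype in INTERACTION_TYPES},
        "Transcription": _roles(Target=_GENE_LIKE, Agent=_AGENTS + (None,)),
        "Bind_to": _roles(Agent=_GENE_LIKE, Target=("Site", "Promoter")),
        "Site_of": _roles(Agent=("Site",), Target=("Promoter",) + _GENE_LIKE),
        "Promoter_of": _roles(Agent=("Promoter",), Target=_GENE_LIKE),
        "Master_of_Promoter": _roles(Agent=_GENE_LIKE, Target=("Promoter",)),
        "Transcription_by": _roles(Transcription=("event:Transcription",), Agent=_GENE_LIKE),
        "Transcription_from": _roles(Transcription=("event:Transcription",),
                                     Site=("Promoter", "Site")),
        "Master_of_Regulon": _roles(Agent=_GENE_LIKE, Target=("Regulon",)),
        "Member_of_Regulon": _roles(Agent=_GENE_LIKE, Target=("Regulon",)),
    },
)

_BB_ENTITIES = frozenset({"Bacterium", "Bacteria", "Habitat", "Geographical"})
_BACTERIA = ("Bacterium", "Bacteria")
_BIOTOPES = ("Habitat", "Geographical")

BB_SCHEMA = TaskSchema(
    name="BB",
    entity_types=_BB_ENTITIES,
    events={
        "Localization": _roles(Bacterium=_BACTERIA, Localization=_BIOTOPES),
        "PartOf": _roles(Host=("Habitat",), Part=("Habitat",)),
    },
)

SCHEMAS = {"GRN": GRN_SCHEMA, "BB": BB_SCHEMA}


def get_schema(name: str) -> TaskSchema:
    try:
        return SCHEMAS[name.upper()]
    except KeyError:
        raise SchemaError(f"unknown schema {name!r}; expected one of {sorted(SCHEMAS)}")


def validate_document(doc: AnnotatedDocument, schema: TaskSchema | str) -> list[str]:
    """Check a document against a task schema.

    Returns a list of human-readable violations, empty iff the document
    conforms.  Each violation names the offending annotation id.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    violations: list[str] = []

    for ent in doc.entities.values():
        if ent.etype not in schema.entity_types:
            violations.append(f"{ent.id}: unknown entity type {ent.etype!r}")
        if ent.end > len(doc.text):
            violations.append(f"{ent.id}: span extends past end of text")

    for ev in doc.events.values():
        sig = schema.events.get(ev.etype)
        if sig is None:
            violations.append(f"{ev.id}: unknown event type {ev.etype!r}")
            continue
        violations.extend(_check_event(doc, ev, sig))

    for group in doc.equivalences:
        types = {doc.entities[e].etype for e in group if e in doc.entities}
        if len(types) > 1:
            violations.append(
                f"equivalence set {sorted(group)}: mixed entity types {sorted(types)}")

    return violations


def _check_event(doc: AnnotatedDocument,
                 ev: EventAnnotation,
                 sig: dict[str, RoleSpec]) -> list[str]:
    out = []
    seen_roles = set()
    for role, arg in ev.args:
        base = role.rstrip("0123456789")  # Role2, Role3 ... share Role's spec
        spec = sig.get(role) or sig.get(base)
        if spec is None:
            out.append(f"{ev.id}: unexpected role {role!r} for {ev.etype}")
            continue
        seen_roles.add(sig.get(role) and role or base)
        if not spec.admits(doc, arg):
            filler = doc.entities.get(arg) or doc.events.get(arg)
            have = filler.etype if filler is not None else "<unresolved>"
            out.append(f"{ev.id}: role {role} of {ev.etype} cannot be filled "
                       f"by {arg} of type {have}")
    for role, spec in sig.items():
        if spec.required and role not in seen_roles:
            out.append(f"{ev.id}: missing required role {role!r} for {ev.etype}")
    return out
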