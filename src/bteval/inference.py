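"""Two-step derivation of a regulation network from event annotations.

Step one rewrites low-level molecular events (binding sites, promoters,
regulons) into biological interaction events; step two projects every
``Interaction:<label>`` event onto gene-to-gene arcs by reducing each
argument to the set of genes it involves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .network import RegulationNetwork
from .standoff import AnnotatedDocument, EventAnnotation, ResolutionError

logger = logging.getLogger(__name__)

#: entity types that stand directly for a gene (a protein stands for the
#: gene encoding it; families/complexes carry their member normalizations)
GENE_LIKE_TYPES = frozenset({
    "Gene", "Protein", "GeneFamily", "ProteinFamily",
    "ProteinComplex", "PolymeraseComplex",
})

#: entity types resolved through an attachment event (Promoter_of / Site_of)
ATTACHED_TYPES = {"Promoter": "Promoter_of", "Site": "Site_of"}

#: event roles that never carry participants
MODALITY_ROLES = frozenset({"Modality", "Cue", "Negation", "Speculation"})

MAX_REDUCTION_DEPTH = 10


class ReductionError(ValueError):
    pass


def reduce_to_genes(doc: AnnotatedDocument, arg_id: str,
                    _depth: int = 0) -> frozenset[str]:
    """Reduce an annotation (entity or event) to its participating genes.

    Gene-like entities map to their normalized name(s), falling back to
    the surface string when no normalization is attached.  Promoters and
    sites map to the gene they are attached to via their ``*_of`` event
    when one exists.  Events reduce to the union over their non-modality
    arguments, recursively.
    """
    if _depth > MAX_REDUCTION_DEPTH:
        raise ReductionError(f"{doc.doc_id}: reduction of {arg_id} exceeds depth "
                             f"{MAX_REDUCTION_DEPTH} (cyclic nesting?)")
    if arg_id in doc.entities:
        ent = doc.entities[arg_id]
        if ent.etype in GENE_LIKE_TYPES:
            names = doc.normalizations.get(arg_id)
            return frozenset(names) if names else frozenset({ent.surface})
        attach = ATTACHED_TYPES.get(ent.etype)
        if attach is not None:
            genes: set[str] = set()
            for ev in doc.events.values():
                if ev.etype == attach and ev.role("Agent") == arg_id:
                    target = ev.role("Target")
                    if target is not None:
                        genes |= reduce_to_genes(doc, target, _depth + 1)
            return frozenset(genes)
        return frozenset()
    if arg_id in doc.events:
        genes = set()
        for role, arg in doc.events[arg_id].args:
            if role not in MODALITY_ROLES:
                genes |= reduce_to_genes(doc, arg, _depth + 1)
        return frozenset(genes)
    raise ReductionError(f"{doc.doc_id}: cannot reduce unknown id {arg_id!r}")


# ---------------------------------------------------------------------------
# declarative molecular -> biological rules


@dataclass(frozen=True)
class Premise:
    etype: str
    roles: tuple[tuple[str, str], ...]  # (role name, variable)


@dataclass(frozen=True)
class InferenceRule:
    name: str
    premises: tuple[Premise, ...]
    conclusion_type: str
    conclusion_roles: tuple[tuple[str, str], ...]  # (role name, variable)
    provisional: bool = False


def _rule(name: str, premises: list[tuple[str, dict[str, str]]],
          conclusion: tuple[str, dict[str, str]], provisional: bool = False) -> InferenceRule:
    return InferenceRule(
        name=name,
        premises=tuple(Premise(et, tuple(rs.items())) for et, rs in premises),
        conclusion_type=conclusion[0],
        conclusion_roles=tuple(conclusion[1].items()),
        provisional=provisional,
    )


#: every rule illustrated or named in the task description; provisional
#: entries cover underspecified cases and are off by default
RULE_REGISTRY: tuple[InferenceRule, ...] = (
    _rule("master_of_promoter_from_binding_site",
          [("Bind_to", {"Agent": "P", "Target": "S"}),
           ("Site_of", {"Agent": "S", "Target": "Pr"})],
          ("Master_of_Promoter", {"Agent": "P", "Target": "Pr"})),
    _rule("binding_interaction_from_promoter_master",
          [("Master_of_Promoter", {"Agent": "P", "Target": "Pr"}),
           ("Promoter_of", {"Agent": "Pr", "Target": "G"})],
          ("Interaction:Binding", {"Agent": "P", "Target": "G"})),
    _rule("transcription_interaction_from_promoter_transcription",
          [("Transcription_from", {"Transcription": "T", "Site": "Pr"}),
           ("Promoter_of", {"Agent": "Pr", "Target": "G"}),
           ("Transcription_by", {"Transcription": "T", "Agent": "P"})],
          ("Interaction:Transcription", {"Agent": "P", "Target": "G"})),
    _rule("regulation_interaction_from_regulon_membership",
          [("Master_of_Regulon", {"Agent": "P", "Target": "R"}),
           ("Member_of_Regulon", {"Agent": "G", "Target": "R"})],
          ("Interaction:Regulation", {"Agent": "P", "Target": "G"})),
    # Transcription_by with no promoter in sight: plausible but not
    # spelled out by the annotation model, hence provisional.
    _rule("transcription_interaction_from_bare_transcription_by",
          [("Transcription_by", {"Transcription": "T", "Agent": "P"})],
          ("Interaction:Transcription", {"Agent": "P", "Target": "T"}),
          provisional=True),
)


def _match(doc: AnnotatedDocument, premises: tuple[Premise, ...]) -> list[dict[str, str]]:
    """All variable bindings satisfying every premise (nested-loop join)."""
    bindings: list[dict[str, str]] = [{}]
    for prem in premises:
        candidates = [ev for ev in doc.events.values() if ev.etype == prem.etype]
        new_bindings = []
        for binding in bindings:
            for ev in candidates:
                trial = dict(binding)
                ok = True
                for role, var in prem.roles:
                    val = ev.role(role)
                    if val is None or trial.get(var, val) != val:
                        ok = False
                        break
                    trial[var] = val
                if ok:
                    new_bindings.append(trial)
        bindings = new_bindings
        if not bindings:
            break
    return bindings


def apply_molecular_rules(doc: AnnotatedDocument,
                          rules: tuple[InferenceRule, ...] | None = None,
                          include_provisional: bool = False) -> AnnotatedDocument:
    """Add every event derivable from the rule registry; idempotent.

    The input document is not modified; derived events get ids ``ER1``,
    ``ER2``, ... and duplicates of existing events are not added.
    """
    if rules is None:
        rules = tuple(r for r in RULE_REGISTRY
                      if include_provisional or not r.provisional)
    events = dict(doc.events)
    existing = {(ev.etype, frozenset(ev.args)) for ev in events.values()}
    counter = itertools.count(1)
    out = replace_events(doc, events)

    changed = True
    while changed:
        changed = False
        for rule in rules:
            for binding in _match(out, rule.premises):
                args = tuple((role, binding[var]) for role, var in rule.conclusion_roles)
                key = (rule.conclusion_type, frozenset(args))
                if key in existing:
                    continue
                eid = f"ER{next(counter)}"
                while eid in events or eid in doc.entities:
                    eid = f"ER{next(counter)}"
                events[eid] = EventAnnotation(eid, rule.conclusion_type, args)
                existing.add(key)
                changed = True
                logger.debug("%s: rule %s derived %s", doc.doc_id, rule.name, eid)
        out = replace_events(doc, events)
    return out


def replace_events(doc: AnnotatedDocument,
                   events: dict[str, EventAnnotation]) -> AnnotatedDocument:
    return AnnotatedDocument(
        doc_id=doc.doc_id, text=doc.text, entities=doc.entities,
        events=dict(events), normalizations=doc.normalizations,
        equivalences=doc.equivalences, sentence_spans=doc.sentence_spans,
        extras=doc.extras,
    )


# ---------------------------------------------------------------------------
# network projection


def infer_network(corpus: list[AnnotatedDocument] | AnnotatedDocument) -> RegulationNetwork:
    """Project Interaction events of a corpus onto a regulation network.

    Every (agent gene, target gene, label) combination becomes one arc;
    repetitions across documents collapse.  Self-loops are kept but
    logged — autoregulation is real biology.
    """
    if isinstance(corpus, AnnotatedDocument):
        corpus = [corpus]
    net = RegulationNetwork()
    for doc in corpus:
        for ev in doc.events.values():
            if not ev.etype.startswith("Interaction:"):
                continue
            label = ev.etype.split(":", 1)[1]
            agent_arg, target_arg = ev.role("Agent"), ev.role("Target")
            if agent_arg is None or target_arg is None:
                raise ResolutionError(
                    f"{doc.doc_id}: event {ev.id} lacks Agent/Target roles")
            for agent in sorted(reduce_to_genes(doc, agent_arg)):
                for target in sorted(reduce_to_genes(doc, target_arg)):
                    if agent == target:
                        logger.warning("%s: self-loop arc on %s from event %s",
                                       doc.doc_id, agent, ev.id)
                    net.add(agent, target, label)
    return net


def build_network(corpus: list[AnnotatedDocument],
                  include_provisional: bool = False) -> RegulationNetwork:
    """Convenience: molecular rules then network projection."""
    return infer_network([apply_molecular_rules(d, include_provisional=include_provisional)
                          for d in corpus])
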