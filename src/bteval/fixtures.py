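"""Synthetic ontologies, documents, networks and error-injected predictions.

Everything here is deterministic given a seed (one ``numpy`` Generator
per call, no global state) and produces artifacts that validate against
the task schemas, so that downstream scorers can be exercised against
*known* ground-truth error counts.  Fixture text is English-like filler:
only offsets, types and structure matter to the scorers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RegulationNetwork
from .ontology import Ontology, OntologyConcept
from .schemas import ARC_LABELS, BB_SCHEMA, validate_document
from .standoff import (AnnotatedDocument, EventAnnotation, Fragment,
                       TextBoundEntity)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorSpec:
    """Exact error counts to inject into a prediction."""

    n_delete: int = 0
    n_insert: int = 0
    n_substitute: int = 0
    n_invert: int = 0            # networks only
    boundary_jitter: int = 0     # entities only: max offset shift
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_delete", "n_insert", "n_substitute", "n_invert",
                     "boundary_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FixtureProfile:
    """Shape of the synthetic corpus; defaults mirror the corpus-level
    statistics of the real data (3:1 Localization:PartOf, 54%
    intra-sentence Localization arguments, ~2% discontinuous spans)."""

    n_docs: int = 10
    entities_per_doc: int = 8
    events_per_doc: int = 4
    discontinuity_rate: float = 0.018
    intra_sentence_rate: float = 0.54
    equivalence_rate: float = 0.2
    partof_rate: float = 0.25
    ontology_depth: int = 4
    ontology_branching: int = 3

    def __post_init__(self) -> None:
        for name in ("discontinuity_rate", "intra_sentence_rate",
                     "equivalence_rate", "partof_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


_SYLLABLES = ["ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "na",
              "po", "ra", "se", "ti", "vu", "wa", "xi", "yo", "zu", "qe"]


def _word(rng: np.random.Generator, n_syll: int = 2) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))


# ---------------------------------------------------------------------------
# ontology generation


def generate_ontology(depth: int, branching: int, seed: int = 0,
                      cross_link_rate: float = 0.0) -> Ontology:
    """A rooted is_a tree of the given depth and branching factor,
    optionally DAG-ified by extra cross links between levels."""
    if depth < 1 or branching < 1:
        raise FixtureError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    concepts: list[OntologyConcept] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"OBT:{counter:07d}"

    levels: list[list[str]] = []
    root = next_id()
    concepts.append(OntologyConcept(root, name=_word(rng, 3)))
    levels.append([root])
    for _ in range(depth - 1):
        level = []
        for parent in levels[-1]:
            for _ in range(branching):
                cid = next_id()
                parents = [("is_a", parent)]
                if cross_link_rate and len(levels) > 1 and rng.random() < cross_link_rate:
                    extra = str(rng.choice(levels[-1]))
                    if extra != parent:
                        parents.append(("is_a", extra))
                concepts.append(OntologyConcept(
                    cid, name=_word(rng, 2) + " " + _word(rng, 2),
                    parents=tuple(parents)))
                level.append(cid)
        levels.append(level)
    return Ontology(concepts)


# ---------------------------------------------------------------------------
# document generation


class _DocBuilder:
    """Accumulates text while tracking entity offsets."""

    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.chunks: list[str] = []
        self.pos = 0
        self.entities: dict[str, TextBoundEntity] = {}
        self.events: dict[str, EventAnnotation] = {}
        self.normalizations: dict[str, frozenset[str]] = {}
        self.equivalences: list[set[str]] = []
        self.sentences: list[Fragment] = []
        self._sentence_start = 0
        self._t = 0
        self._e = 0

    def text(self, s: str) -> None:
        self.chunks.append(s)
        self.pos += len(s)

    def entity(self, etype: str, surface: str,
               concept: str | None = None) -> TextBoundEntity:
        frag = Fragment(self.pos, self.pos + len(surface))
        self.text(surface)
        return self._register(etype, (frag,), surface, concept)

    def discontinuous_entity(self, etype: str, head_mod: str, other_mod: str,
                             head: str, concept: str | None = None,
                             other_concept: str | None = None,
                             ) -> tuple[TextBoundEntity, TextBoundEntity]:
        """Emit ``"<head_mod> and <other_mod> <head>"``; the first entity
        ({head_mod, head}) is discontinuous, the second is contiguous."""
        f1 = Fragment(self.pos, self.pos + len(head_mod))
        self.text(head_mod + " and ")
        other_start = self.pos
        self.text(other_mod + " ")
        f_head = Fragment(self.pos, self.pos + len(head))
        f_other = Fragment(other_start, self.pos + len(head))
        self.text(head)
        disc = self._register(etype, (f1, f_head), f"{head_mod} {head}", concept)
        cont = self._register(etype, (f_other,), f"{other_mod} {head}", other_concept)
        return disc, cont

    def _register(self, etype: str, frags: tuple[Fragment, ...], surface: str,
                  concept: str | None) -> TextBoundEntity:
        self._t += 1
        ent = TextBoundEntity(f"T{self._t}", etype, frags, surface)
        self.entities[ent.id] = ent
        if concept is not None:
            self.normalizations[ent.id] = frozenset({concept})
        return ent

    def event(self, etype: str, **roles: TextBoundEntity) -> EventAnnotation:
        self._e += 1
        ev = EventAnnotation(f"E{self._e}", etype,
                             tuple((r, e.id) for r, e in roles.items()))
        self.events[ev.id] = ev
        return ev

    def end_sentence(self) -> None:
        self.text(".")
        self.sentences.append(Fragment(self._sentence_start, self.pos))
        self.text(" ")
        self._sentence_start = self.pos

    def build(self) -> AnnotatedDocument:
        return AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self.chunks),
            entities=self.entities,
            events=self.events,
            normalizations=self.normalizations,
            equivalences=frozenset(frozenset(g) for g in self.equivalences),
            sentence_spans=tuple(self.sentences),
        )


def _bacterium_name(rng: np.random.Generator) -> str:
    return _word(rng, 3).capitalize() + " " + _word(rng, 3)


def generate_bb_document(profile: FixtureProfile, onto: Ontology,
                         seed: int = 0, doc_id: str = "bbdoc") -> AnnotatedDocument:
    """One synthetic biotope document with Localization / PartOf events,
    optional discontinuous habitats, equivalence sets and concept
    normalizations; always validates against the BB schema."""
    if not len(onto):
        raise FixtureError("ontology is empty")
    rng = np.random.default_rng(seed)
    b = _DocBuilder(doc_id)
    concept_ids = sorted(onto.concepts)

    def concept() -> str:
        return str(rng.choice(concept_ids))

    last_bacterium: TextBoundEntity | None = None
    n_events = max(1, profile.events_per_doc)
    for k in range(n_events):
        want_partof = rng.random() < profile.partof_rate
        if want_partof:
            b.text("The ")
            part = b.entity("Habitat", _word(rng, 2), concept())
            b.text(" of the ")
            host = b.entity("Habitat", _word(rng, 2), concept())
            b.text(" is colonized")
            b.event("PartOf", Host=host, Part=part)
            b.end_sentence()
            continue

        intra = rng.random() < profile.intra_sentence_rate
        if intra:
            bact = b.entity("Bacterium", _bacterium_name(rng))
            b.text(" was isolated from the ")
        else:
            if last_bacterium is None:
                bact = b.entity("Bacterium", _bacterium_name(rng))
                b.text(" was studied")
                b.end_sentence()
                last_bacterium = bact
            bact = last_bacterium
            b.text("Strains were recovered from the ")
        if rng.random() < profile.discontinuity_rate:
            habitat, other = b.discontinuous_entity(
                "Habitat", _word(rng, 2), _word(rng, 2), _word(rng, 2),
                concept(), concept())
        else:
            habitat = b.entity("Habitat", _word(rng, 2) + " " + _word(rng, 2),
                               concept())
        b.event("Localization", Bacterium=bact, Localization=habitat)
        b.end_sentence()
        if intra:
            last_bacterium = bact
            if rng.random() < profile.equivalence_rate:
                twin = b.entity("Bacterium", bact.surface)
                b.text(" grows at various temperatures")
                b.end_sentence()
                b.equivalences.append({bact.id, twin.id})

    # filler entities not involved in any event
    extra = max(0, profile.entities_per_doc - len(b.entities))
    for _ in range(extra):
        kind = str(rng.choice(["Habitat", "Geographical", "Bacterium"]))
        b.text("Samples came from the ")
        if kind == "Habitat":
            b.entity("Habitat", _word(rng, 2), concept())
        elif kind == "Geographical":
            b.entity("Geographical", _word(rng, 2).capitalize())
        else:
            b.entity("Bacterium", _bacterium_name(rng))
        b.end_sentence()

    doc = b.build()
    problems = validate_document(doc, BB_SCHEMA)
    if problems:  # pragma: no cover - generator bug guard
        raise FixtureError(f"{doc_id}: generated document is invalid: {problems}")
    return doc


def generate_bb_corpus(profile: FixtureProfile, onto: Ontology,
                       seed: int = 0) -> list[AnnotatedDocument]:
    rng = np.random.default_rng(seed)
    return [generate_bb_document(profile, onto,
                                 seed=int(rng.integers(0, 2**31)),
                                 doc_id=f"bbdoc{i:03d}")
            for i in range(profile.n_docs)]


# ---------------------------------------------------------------------------
# network generation


def generate_network(n_genes: int = 10, n_arcs: int = 12,
                     seed: int = 0) -> RegulationNetwork:
    """Random regulation network; arcs are unique (agent, target, label)
    triples over distinct gene pairs."""
    if n_genes < 2:
        raise FixtureError("need at least two genes")
    max_arcs = n_genes * (n_genes - 1)
    if n_arcs > max_arcs:
        raise FixtureError(f"cannot place {n_arcs} arcs over {n_genes} genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{_word(rng, 2)}{i}" for i in range(n_genes)]
    net = RegulationNetwork(nodes=set(genes))
    pairs = [(a, t) for a in genes for t in genes if a != t]
    order = rng.permutation(len(pairs))
    for idx in order[:n_arcs]:
        agent, target = pairs[idx]
        net.add(agent, target, str(rng.choice(ARC_LABELS)))
    return net


def generate_grn_document(net: RegulationNetwork, seed: int = 0,
                          doc_id: str = "grndoc") -> AnnotatedDocument:
    """A document carrying one flat Interaction event per network arc, so
    that inference over it reproduces ``net`` exactly."""
    rng = np.random.default_rng(seed)
    b = _DocBuilder(doc_id)
    for arc in net.sorted_arcs():
        agent = b.entity("Protein", arc.agent.capitalize())
        b.text(" regulates ")
        target = b.entity("Gene", arc.target)
        b.normalizations[agent.id] = frozenset({arc.agent})
        b.normalizations[target.id] = frozenset({arc.target})
        b.event(f"Interaction:{arc.label}", Agent=agent, Target=target)
        b.end_sentence()
    return b.build()


# ---------------------------------------------------------------------------
# error injection


def perturb_network(net: RegulationNetwork, spec: ErrorSpec,
                    ) -> tuple[RegulationNetwork, dict[str, int]]:
    """Apply exactly the requested deletions / substitutions / inversions /
    insertions to a copy of ``net``.

    Returns the perturbed network together with the ground-truth counts a
    scorer must recover under the default (del-ins) inversion policy:
    ``S = n_substitute``, ``D = n_delete + n_invert``,
    ``I = n_insert + n_invert``.
    """
    rng = np.random.default_rng(spec.seed)
    arcs = net.sorted_arcs()
    n_touch = spec.n_delete + spec.n_substitute + spec.n_invert
    if n_touch > len(arcs):
        raise FixtureError(
            f"cannot touch {n_touch} arcs, reference only has {len(arcs)}")

    order = [arcs[i] for i in rng.permutation(len(arcs))]
    to_delete = set(order[:spec.n_delete])
    to_substitute = order[spec.n_delete:spec.n_delete + spec.n_substitute]
    invert_pool = order[spec.n_delete + spec.n_substitute:]

    pred = net.copy()
    for arc in to_delete:
        pred.arcs.discard(arc)

    for arc in to_substitute:
        ref_labels = net.labels(arc.agent, arc.target)
        pred_labels = pred.labels(arc.agent, arc.target)
        options = [l for l in ARC_LABELS if l not in ref_labels and l not in pred_labels]
        if not options:
            raise FixtureError(f"no spare label for substitution on "
                               f"({arc.agent}, {arc.target})")
        pred.arcs.discard(arc)
        pred.add(arc.agent, arc.target, str(rng.choice(options)))

    inverted = 0
    for arc in invert_pool:
        if inverted == spec.n_invert:
            break
        # the reverse pair must be empty on both sides for the flip to
        # score as a clean inversion
        if net.labels(arc.target, arc.agent) or pred.labels(arc.target, arc.agent):
            continue
        pred.arcs.discard(arc)
        pred.add(arc.target, arc.agent, arc.label)
        inverted += 1
    if inverted < spec.n_invert:
        raise FixtureError(f"could only place {inverted} of {spec.n_invert} inversions")

    for k in range(spec.n_insert):
        # fresh nodes guarantee the arc lands on an untouched pair
        pred.add(f"spurious{k}a", f"spurious{k}b", str(rng.choice(ARC_LABELS)))

    truth = {
        "matches": len(net.arcs) - n_touch,
        "substitutions": spec.n_substitute,
        "deletions": spec.n_delete + spec.n_invert,
        "insertions": spec.n_insert + spec.n_invert,
        "inversions": spec.n_invert,
        "n_reference": len(net.arcs),
        "n_predicted": len(pred.arcs),
    }
    return pred, truth


def perturb_document(doc: AnnotatedDocument, spec: ErrorSpec,
                     onto: Ontology | None = None,
                     entity_types: tuple[str, ...] = ("Habitat",),
                     ) -> tuple[AnnotatedDocument, dict[str, int]]:
    """Entity-level error injection for sub-task 1 style scoring.

    Deletions drop entities, insertions add entities overlapping nothing,
    substitutions jitter boundaries (when ``boundary_jitter`` > 0) and/or
    swap the assigned concept (when an ontology is given).  Jittered
    spans are kept overlapping their original and clear of every other
    reference entity, so injected counts are recovered exactly.
    """
    rng = np.random.default_rng(spec.seed)
    targets = sorted((e for e in doc.entities.values() if e.etype in entity_types),
                     key=lambda e: e.id)
    if spec.n_delete + spec.n_substitute > len(targets):
        raise FixtureError("not enough entities to delete/substitute")
    if spec.n_substitute and not spec.boundary_jitter and onto is None:
        raise FixtureError("substitutions need boundary_jitter > 0 or an ontology")

    order = [targets[i] for i in rng.permutation(len(targets))]
    to_delete = {e.id for e in order[:spec.n_delete]}
    to_substitute = [e.id for e in order[spec.n_delete:spec.n_delete + spec.n_substitute]]

    entities = {k: v for k, v in doc.entities.items() if k not in to_delete}
    normalizations = {k: v for k, v in doc.normalizations.items() if k not in to_delete}

    ref_offsets: dict[str, frozenset[int]] = {
        e.id: e.offsets() for e in doc.entities.values()}

    for eid in to_substitute:
        ent = entities[eid]
        if spec.boundary_jitter:
            entities[eid] = _jitter(doc, ent, spec.boundary_jitter, ref_offsets, rng)
        if onto is not None:
            current = normalizations.get(eid, frozenset())
            choices = [c for c in sorted(onto.concepts) if c not in current]
            if not choices:
                raise FixtureError("ontology too small to swap a concept")
            normalizations[eid] = frozenset({str(rng.choice(choices))})

    forbidden = set().union(*ref_offsets.values()) if ref_offsets else set()
    inserted = []
    for k in range(spec.n_insert):
        frag = _free_span(doc.text, forbidden, rng)
        ent = TextBoundEntity(f"TI{k + 1}", entity_types[0], (frag,),
                              doc.text[frag.start:frag.end])
        forbidden.update(frag.offsets())
        entities[ent.id] = ent
        inserted.append(ent.id)
        if onto is not None and doc.normalizations:
            normalizations[ent.id] = frozenset({str(rng.choice(sorted(onto.concepts)))})

    pred = AnnotatedDocument(
        doc_id=doc.doc_id, text=doc.text, entities=entities,
        events={}, normalizations=normalizations,
        equivalences=frozenset(), sentence_spans=doc.sentence_spans,
    )
    truth = {
        "deletions": spec.n_delete,
        "insertions": spec.n_insert,
        "substitutions": spec.n_substitute,
        "n_reference": len(targets),
    }
    return pred, truth


def _jitter(doc: AnnotatedDocument, ent: TextBoundEntity, jitter: int,
            ref_offsets: dict[str, frozenset[int]],
            rng: np.random.Generator) -> TextBoundEntity:
    others = frozenset().union(*(off for eid, off in ref_offsets.items()
                                 if eid != ent.id)) if len(ref_offsets) > 1 else frozenset()
    frags = list(ent.fragments)
    last = frags[-1]
    shifts = [s for s in range(-jitter, jitter + 1) if s != 0]
    rng.shuffle(shifts)
    for shift in shifts:
        new_end = last.end + shift
        if not (last.start < new_end <= len(doc.text)):
            continue
        cand = Fragment(last.start, new_end)
        if set(cand.offsets()) & others:
            continue
        new_frags = tuple(frags[:-1]) + (cand,)
        new = TextBoundEntity(ent.id, ent.etype, new_frags,
                              doc.surface_of(new_frags))
        if new.offsets() != ent.offsets():
            return new
    raise FixtureError(f"cannot jitter entity {ent.id} without side effects")


def _free_span(text: str, forbidden: set[int], rng: np.random.Generator,
               length: int = 4) -> Fragment:
    starts = [s for s in range(0, len(text) - length)
              if not any(o in forbidden for o in range(s, s + length))]
    if not starts:
        raise FixtureError("no room left to insert an entity")
    s = int(rng.choice(starts))
    return Fragment(s, s + length)


def perturb(reference, spec: ErrorSpec, **kwargs):
    """Dispatch on reference kind: network or annotated document."""
    if isinstance(reference, RegulationNetwork):
        return perturb_network(reference, spec)
    if isinstance(reference, AnnotatedDocument):
        return perturb_document(reference, spec, **kwargs)
    raise TypeError(f"cannot perturb {type(reference).__name__}")
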