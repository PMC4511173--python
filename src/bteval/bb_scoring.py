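"""Scorers for biotope entity categorization and event extraction.

Sub-task 1 grades each (reference, prediction) habitat pair by the
product of a boundary similarity Se (a Jaccard index over the character
positions covered by the — possibly discontinuous — spans) and a
category similarity Sc (Wang similarity between the assigned ontology
concepts).  Reference and predicted entities are paired one-to-one so as
to maximize the total similarity; unpaired references are deletions,
unpaired predictions insertions, and each pair contributes 1 - Sc*Se as
a fractional substitution to the SER.

Sub-tasks 2 and 3 score Localization / PartOf event predictions: the
bacterium argument must match exactly (any member of the reference's
equivalence set is accepted), biotope arguments are graded by Se, and
events are paired one-to-one maximizing the total credit, from which
recall / precision / F1 follow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ontology import Ontology, WangConfig, wang_similarity
from .standoff import AnnotatedDocument, EventAnnotation, Fragment, TextBoundEntity

#: pairing eligibility / tie-break epsilon: prefers matching an
#: overlapping pair over leaving it unmatched when total S ties
_EPS = 1e-9

BACTERIA_TYPES = frozenset({"Bacterium", "Bacteria"})
BIOTOPE_TYPES = frozenset({"Habitat", "Geographical"})
EVENT_TYPES = ("Localization", "PartOf")

#: event roles holding the strictly-matched bacterium argument
STRICT_ROLES = frozenset({"Bacterium"})


class Subtask1Mode(str, Enum):
    OFFICIAL = "official"          # S = Sc * Se
    DETECTION = "detection"        # boundaries only: S = Se
    CATEGORIZATION = "categorization"  # categories only: S = Sc on paired entities


class ConceptAggregation(str, Enum):
    MEAN_OF_MAX = "mean-of-max"
    MAX_MATCHING = "max-matching"


@dataclass(frozen=True)
class EntitySimilarity:
    se: float
    sc: float

    @property
    def s(self) -> float:
        return self.sc * self.se


@dataclass
class Pairing:
    pairs: list[tuple[TextBoundEntity, TextBoundEntity, float]]
    unmatched_ref: list[TextBoundEntity]
    unmatched_pred: list[TextBoundEntity]

    @property
    def total(self) -> float:
        return sum(s for _, _, s in self.pairs)


@dataclass(frozen=True)
class EntityScore:
    ser: float
    recall: float
    precision: float
    f1: float
    n_reference: int
    n_predicted: int
    deletions: int
    insertions: int
    substitution_mass: float     # sum of (1 - S) over paired entities
    similarity_total: float      # sum of S over paired entities
    mode: Subtask1Mode = Subtask1Mode.OFFICIAL

    def as_dict(self) -> dict:
        return {
            "mode": self.mode.value, "SER": self.ser, "recall": self.recall,
            "precision": self.precision, "f1": self.f1,
            "N": self.n_reference, "P": self.n_predicted,
            "deletions": self.deletions, "insertions": self.insertions,
            "substitutions": self.substitution_mass,
            "similarity_total": self.similarity_total,
        }


@dataclass(frozen=True)
class EventTypeScore:
    recall: float
    precision: float
    f1: float
    n_reference: int
    n_predicted: int
    total_score: float


@dataclass(frozen=True)
class EventScore:
    recall: float
    precision: float
    f1: float
    n_reference: int
    n_predicted: int
    total_score: float
    per_type: dict[str, EventTypeScore] = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "recall": self.recall, "precision": self.precision, "f1": self.f1,
            "N": self.n_reference, "P": self.n_predicted,
            "total_score": self.total_score,
            "per_type": {t: {"recall": s.recall, "precision": s.precision,
                             "f1": s.f1, "N": s.n_reference, "P": s.n_predicted}
                         for t, s in self.per_type.items()},
            "flags": list(self.flags),
        }


def _f1(recall: float, precision: float) -> float:
    return 2 * recall * precision / (recall + precision) if recall + precision else 0.0


# ---------------------------------------------------------------------------
# similarities


def segment_similarity(a: TextBoundEntity, b: TextBoundEntity) -> float:
    """Jaccard index over covered character positions; handles
    discontinuous spans by enumerating every fragment's offsets."""
    oa, ob = a.offsets(), b.offsets()
    union = len(oa | ob)
    return len(oa & ob) / union if union else 0.0


def entities_overlap(a: TextBoundEntity, b: TextBoundEntity) -> bool:
    return any(fa.overlaps(fb) for fa in a.fragments for fb in b.fragments)


def category_similarity(
    onto: Ontology,
    ref_concepts: Iterable[str],
    pred_concepts: Iterable[str],
    cfg: WangConfig | None = None,
    aggregation: ConceptAggregation | str = ConceptAggregation.MEAN_OF_MAX,
) -> float:
    """Similarity between two concept-label sets.

    Singletons reduce to plain Wang similarity.  For multi-label sets the
    default is the mean over reference concepts of the best similarity to
    any predicted concept; ``max-matching`` instead takes an optimal
    one-to-one concept matching normalized by the larger set size.
    An empty prediction against a non-empty reference scores 0; two
    empty sets score 1 (nothing to categorize, nothing wrong).
    """
    refs, preds = sorted(set(ref_concepts)), sorted(set(pred_concepts))
    if not refs and not preds:
        return 1.0
    if not refs or not preds:
        return 0.0
    cfg = cfg or WangConfig()
    sim = [[wang_similarity(onto, r, p, cfg) for p in preds] for r in refs]
    if ConceptAggregation(aggregation) is ConceptAggregation.MEAN_OF_MAX:
        return float(np.mean([max(row) for row in sim]))
    cost = -np.asarray(sim)
    rows, cols = linear_sum_assignment(cost)
    return float(-cost[rows, cols].sum() / max(len(refs), len(preds)))


# ---------------------------------------------------------------------------
# optimal one-to-one pairing


def pair_entities(
    refs: Sequence[TextBoundEntity],
    preds: Sequence[TextBoundEntity],
    similarity: Callable[[TextBoundEntity, TextBoundEntity], float],
) -> Pairing:
    """One-to-one matching over overlapping pairs maximizing total
    similarity (Hungarian assignment); non-overlapping pairs never
    match."""
    if not refs or not preds:
        return Pairing([], list(refs), list(preds))
    cost = np.zeros((len(refs), len(preds)))
    allowed = np.zeros_like(cost, dtype=bool)
    for i, r in enumerate(refs):
        for j, p in enumerate(preds):
            if entities_overlap(r, p):
                allowed[i, j] = True
                cost[i, j] = -(similarity(r, p) + _EPS)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_r: set[int] = set()
    matched_p: set[int] = set()
    for i, j in zip(rows, cols):
        if allowed[i, j]:
            pairs.append((refs[i], preds[j], -cost[i, j] - _EPS))
            matched_r.add(i)
            matched_p.add(j)
    return Pairing(
        pairs=pairs,
        unmatched_ref=[r for i, r in enumerate(refs) if i not in matched_r],
        unmatched_pred=[p for j, p in enumerate(preds) if j not in matched_p],
    )


# ---------------------------------------------------------------------------
# sub-task 1


def score_subtask1(
    ref_doc: AnnotatedDocument,
    pred_doc: AnnotatedDocument,
    onto: Ontology,
    cfg: WangConfig | None = None,
    mode: Subtask1Mode | str = Subtask1Mode.OFFICIAL,
    entity_types: Iterable[str] = ("Habitat",),
    aggregation: ConceptAggregation | str = ConceptAggregation.MEAN_OF_MAX,
) -> EntityScore:
    """Detection + categorization score for one document pair."""
    mode = Subtask1Mode(mode)
    types = set(entity_types)
    refs = [e for e in ref_doc.entities.values() if e.etype in types]
    preds = [e for e in pred_doc.entities.values() if e.etype in types]
    if not refs:
        raise ValueError(f"{ref_doc.doc_id}: no reference entities; SER undefined")

    def sim(r: TextBoundEntity, p: TextBoundEntity) -> float:
        se = segment_similarity(r, p)
        if mode is Subtask1Mode.DETECTION:
            return se
        sc = category_similarity(onto,
                                 ref_doc.normalizations.get(r.id, frozenset()),
                                 pred_doc.normalizations.get(p.id, frozenset()),
                                 cfg, aggregation)
        if mode is Subtask1Mode.CATEGORIZATION:
            return sc        # boundaries relaxed: Se := 1 on paired entities
        return sc * se

    pairing = pair_entities(refs, preds, sim)
    return _entity_score_from_pairing(pairing, len(refs), len(preds), mode)


def _entity_score_from_pairing(pairing: Pairing, n: int, p: int,
                               mode: Subtask1Mode) -> EntityScore:
    total = pairing.total
    deletions = len(pairing.unmatched_ref)
    insertions = len(pairing.unmatched_pred)
    sub_mass = sum(1.0 - s for _, _, s in pairing.pairs)
    ser = (sub_mass + deletions + insertions) / n
    recall = total / n
    precision = total / p if p else 0.0
    return EntityScore(ser=ser, recall=recall, precision=precision,
                       f1=_f1(recall, precision), n_reference=n, n_predicted=p,
                       deletions=deletions, insertions=insertions,
                       substitution_mass=sub_mass, similarity_total=total,
                       mode=mode)


def aggregate_entity_scores(scores: Sequence[EntityScore],
                            macro: bool = False) -> EntityScore:
    """Corpus-level roll-up; micro (default) sums counts before dividing."""
    if not scores:
        raise ValueError("nothing to aggregate")
    if macro:
        recall = float(np.mean([s.recall for s in scores]))
        precision = float(np.mean([s.precision for s in scores]))
        return EntityScore(
            ser=float(np.mean([s.ser for s in scores])), recall=recall,
            precision=precision, f1=_f1(recall, precision),
            n_reference=sum(s.n_reference for s in scores),
            n_predicted=sum(s.n_predicted for s in scores),
            deletions=sum(s.deletions for s in scores),
            insertions=sum(s.insertions for s in scores),
            substitution_mass=sum(s.substitution_mass for s in scores),
            similarity_total=sum(s.similarity_total for s in scores),
            mode=scores[0].mode)
    n = sum(s.n_reference for s in scores)
    p = sum(s.n_predicted for s in scores)
    total = sum(s.similarity_total for s in scores)
    sub = sum(s.substitution_mass for s in scores)
    dele = sum(s.deletions for s in scores)
    ins = sum(s.insertions for s in scores)
    recall = total / n
    precision = total / p if p else 0.0
    return EntityScore(ser=(sub + dele + ins) / n, recall=recall,
                       precision=precision, f1=_f1(recall, precision),
                       n_reference=n, n_predicted=p, deletions=dele,
                       insertions=ins, substitution_mass=sub,
                       similarity_total=total, mode=scores[0].mode)


# ---------------------------------------------------------------------------
# sub-tasks 2 and 3 (event extraction)


@dataclass(frozen=True)
class EventScoringOptions:
    relax_boundaries: bool = False   # biotope Se := 1 on any overlap
    relax_bacteria: bool = False     # bacterium matches on any overlap
    intra_sentence: bool = False     # keep only events local to one sentence

    def flags(self) -> tuple[str, ...]:
        out = []
        if self.relax_boundaries:
            out.append("relaxed-biotope-boundaries")
        if self.relax_bacteria:
            out.append("relaxed-bacteria-boundaries")
        if self.intra_sentence:
            out.append("intra-sentence")
        return tuple(out)


_SENTENCE_RE = re.compile(r"[^.!?]+(?:[.!?]+|\Z)", re.S)


def heuristic_sentence_spans(text: str) -> tuple[Fragment, ...]:
    """Crude period-based splitter used only when gold spans are absent."""
    spans = []
    for m in _SENTENCE_RE.finditer(text):
        start, end = m.start(), m.end()
        while start < end and text[start].isspace():
            start += 1
        if start < end:
            spans.append(Fragment(start, end))
    return tuple(spans)


def event_in_one_sentence(doc: AnnotatedDocument, ev: EventAnnotation,
                          spans: Sequence[Fragment]) -> bool:
    ents = [doc.entities[a] for _, a in ev.args if a in doc.entities]
    return any(all(e.start >= s.start and e.end <= s.end for e in ents)
               for s in spans)


def _event_pair_score(
    ref_doc: AnnotatedDocument, ref_ev: EventAnnotation,
    pred_doc: AnnotatedDocument, pred_ev: EventAnnotation,
    options: EventScoringOptions,
) -> float:
    """Credit in [0, 1] for predicting ``ref_ev`` as ``pred_ev``.

    Strict (bacterium) roles contribute 1 or 0; graded (biotope) roles
    contribute their boundary similarity; factors multiply.
    """
    if ref_ev.etype != pred_ev.etype:
        return 0.0
    score = 1.0
    ref_roles = dict(ref_ev.args)
    pred_roles = dict(pred_ev.args)
    if set(ref_roles) != set(pred_roles):
        return 0.0
    for role, ref_arg in ref_roles.items():
        ref_ent = ref_doc.entities.get(ref_arg)
        pred_ent = pred_doc.entities.get(pred_roles[role])
        if ref_ent is None or pred_ent is None:
            return 0.0
        if role in STRICT_ROLES:
            score *= _bacteria_factor(ref_doc, ref_ent, pred_ent, options)
        else:
            se = segment_similarity(ref_ent, pred_ent)
            if options.relax_boundaries:
                se = 1.0 if entities_overlap(ref_ent, pred_ent) else 0.0
            score *= se
        if score == 0.0:
            return 0.0
    return score


def _bacteria_factor(ref_doc: AnnotatedDocument, ref_ent: TextBoundEntity,
                     pred_ent: TextBoundEntity,
                     options: EventScoringOptions) -> float:
    members = [ref_doc.entities[i] for i in ref_doc.equivalents(ref_ent.id)
               if i in ref_doc.entities]
    if options.relax_bacteria:
        return 1.0 if any(entities_overlap(m, pred_ent) for m in members) else 0.0
    keys = {m.span_key() for m in members}
    return 1.0 if pred_ent.span_key() in keys else 0.0


def score_events(
    ref_doc: AnnotatedDocument,
    pred_doc: AnnotatedDocument,
    subtask: int = 2,
    options: EventScoringOptions | None = None,
    sentence_spans: Sequence[Fragment] | None = None,
) -> EventScore:
    """Event-extraction score for one document pair (sub-task 2 or 3).

    Sub-task 2 predictions reference the provided gold entities;
    sub-task 3 predictions carry their own entities — both cases match
    arguments by exact span, so the same scorer covers them.
    """
    if subtask not in (2, 3):
        raise ValueError(f"subtask must be 2 or 3, got {subtask}")
    options = options or EventScoringOptions()
    flags = list(options.flags())

    refs = [e for e in ref_doc.events.values() if e.etype in EVENT_TYPES]
    preds = [e for e in pred_doc.events.values() if e.etype in EVENT_TYPES]

    if options.intra_sentence:
        spans = sentence_spans if sentence_spans is not None else ref_doc.sentence_spans
        if spans is None:
            spans = heuristic_sentence_spans(ref_doc.text)
            flags.append("heuristic-sentence-splitter")
        refs = [e for e in refs if event_in_one_sentence(ref_doc, e, spans)]
        preds = [e for e in preds if event_in_one_sentence(pred_doc, e, spans)]

    per_type: dict[str, EventTypeScore] = {}
    total = 0.0
    for etype in EVENT_TYPES:
        t_refs = [e for e in refs if e.etype == etype]
        t_preds = [e for e in preds if e.etype == etype]
        t_total = _pair_events_total(ref_doc, t_refs, pred_doc, t_preds, options)
        recall = t_total / len(t_refs) if t_refs else 0.0
        precision = t_total / len(t_preds) if t_preds else 0.0
        per_type[etype] = EventTypeScore(
            recall=recall, precision=precision, f1=_f1(recall, precision),
            n_reference=len(t_refs), n_predicted=len(t_preds), total_score=t_total)
        total += t_total

    n, p = len(refs), len(preds)
    recall = total / n if n else 0.0
    precision = total / p if p else 0.0
    return EventScore(recall=recall, precision=precision,
                      f1=_f1(recall, precision), n_reference=n, n_predicted=p,
                      total_score=total, per_type=per_type, flags=tuple(flags))


def _pair_events_total(ref_doc: AnnotatedDocument, refs: list[EventAnnotation],
                       pred_doc: AnnotatedDocument, preds: list[EventAnnotation],
                       options: EventScoringOptions) -> float:
    if not refs or not preds:
        return 0.0
    score = np.zeros((len(refs), len(preds)))
    for i, r in enumerate(refs):
        for j, p in enumerate(preds):
            score[i, j] = _event_pair_score(ref_doc, r, pred_doc, p, options)
    rows, cols = linear_sum_assignment(-score)
    return float(score[rows, cols].sum())


def aggregate_event_scores(scores: Sequence[EventScore],
                           macro: bool = False) -> EventScore:
    if not scores:
        raise ValueError("nothing to aggregate")
    flags = tuple(sorted({f for s in scores for f in s.flags}))
    if macro:
        recall = float(np.mean([s.recall for s in scores]))
        precision = float(np.mean([s.precision for s in scores]))
        return EventScore(recall=recall, precision=precision,
                          f1=_f1(recall, precision),
                          n_reference=sum(s.n_reference for s in scores),
                          n_predicted=sum(s.n_predicted for s in scores),
                          total_score=sum(s.total_score for s in scores),
                          per_type={}, flags=flags)
    per_type: dict[str, EventTypeScore] = {}
    for etype in EVENT_TYPES:
        n = sum(s.per_type[etype].n_reference for s in scores if etype in s.per_type)
        p = sum(s.per_type[etype].n_predicted for s in scores if etype in s.per_type)
        tot = sum(s.per_type[etype].total_score for s in scores if etype in s.per_type)
        recall = tot / n if n else 0.0
        precision = tot / p if p else 0.0
        per_type[etype] = EventTypeScore(recall, precision, _f1(recall, precision),
                                         n, p, tot)
    n = sum(s.n_reference for s in scores)
    p = sum(s.n_predicted for s in scores)
    tot = sum(s.total_score for s in scores)
    recall = tot / n if n else 0.0
    precision = tot / p if p else 0.0
    return EventScore(recall=recall, precision=precision,
                      f1=_f1(recall, precision), n_reference=n, n_predicted=p,
                      total_score=tot, per_type=per_type, flags=flags)
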