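"""Arc-by-arc comparison of regulation networks: SER, recall, precision.

Errors are counted per ordered gene pair and summed: an arc present in
both networks is a match, a same-pair arc with the wrong label is a
substitution, a reference arc with no counterpart is a deletion and a
predicted arc with no counterpart is an insertion.  SER = (S+D+I)/N is
0 for a perfect prediction and unbounded above.

A predicted arc whose direction is reversed relative to the reference is
flagged as an inversion.  Two folding policies exist: ``del-ins`` (the
default; the reversal counts as one deletion plus one insertion on the
two ordered pairs) and ``substitution`` (one substitution).  The
inversion count is reported separately under either policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .network import SHAPE_LABEL, Arc, RegulationNetwork
from .schemas import EFFECT_LABELS, MECHANISM_LABELS


class InversionPolicy(str, Enum):
    DEL_INS = "del-ins"
    SUBSTITUTION = "substitution"


class ScoringMode(str, Enum):
    OFFICIAL = "official"
    SHAPE = "shape"
    EFFECT = "effect"


@dataclass
class ArcDiff:
    matches: int = 0
    substitutions: int = 0
    deletions: int = 0
    insertions: int = 0
    inversions: int = 0
    n_reference: int = 0
    n_predicted: int = 0
    substitution_detail: list[tuple[tuple[str, str], str, str]] = field(default_factory=list)

    @property
    def errors(self) -> int:
        return self.substitutions + self.deletions + self.insertions


@dataclass(frozen=True)
class NetworkScore:
    ser: float
    recall: float
    precision: float
    f1: float
    diff: ArcDiff
    mode: ScoringMode = ScoringMode.OFFICIAL

    def as_dict(self) -> dict:
        d = self.diff
        return {
            "mode": self.mode.value,
            "SER": self.ser, "recall": self.recall,
            "precision": self.precision, "f1": self.f1,
            "matches": d.matches, "substitutions": d.substitutions,
            "deletions": d.deletions, "insertions": d.insertions,
            "inversions": d.inversions,
            "N": d.n_reference, "P": d.n_predicted,
        }


def diff_networks(ref: RegulationNetwork, pred: RegulationNetwork,
                  inversion_policy: InversionPolicy | str = InversionPolicy.DEL_INS,
                  ) -> ArcDiff:
    """Per-pair labeled graph diff; M + S + D == N under both policies."""
    policy = InversionPolicy(inversion_policy)
    diff = ArcDiff(n_reference=len(ref.arcs), n_predicted=len(pred.arcs))

    ref_deleted: set[Arc] = set()
    pred_inserted: set[Arc] = set()
    pairs = ref.pairs() | pred.pairs()
    for pair in sorted(pairs):
        agent, target = pair
        ref_labels = ref.labels(agent, target)
        pred_labels = pred.labels(agent, target)
        diff.matches += len(ref_labels & pred_labels)
        lost = sorted(ref_labels - pred_labels)
        spurious = sorted(pred_labels - ref_labels)
        n_sub = min(len(lost), len(spurious))
        diff.substitutions += n_sub
        for ref_label, pred_label in zip(lost, spurious):
            diff.substitution_detail.append((pair, ref_label, pred_label))
        ref_deleted.update(Arc(agent, target, l) for l in lost[n_sub:])
        pred_inserted.update(Arc(agent, target, l) for l in spurious[n_sub:])

    # an unexplained reference arc whose exact reverse is an unexplained
    # predicted arc is a direction confusion
    inversions: list[tuple[Arc, Arc]] = []
    for arc in sorted(ref_deleted):
        rev = arc.reversed()
        if rev in pred_inserted:
            inversions.append((arc, rev))
            pred_inserted.discard(rev)
    for arc, rev in inversions:
        ref_deleted.discard(arc)
    diff.inversions = len(inversions)

    diff.deletions = len(ref_deleted)
    diff.insertions = len(pred_inserted)
    if policy is InversionPolicy.SUBSTITUTION:
        diff.substitutions += diff.inversions
        for arc, rev in inversions:
            diff.substitution_detail.append(((arc.agent, arc.target), arc.label,
                                             f"inverted:{rev.label}"))
    else:
        diff.deletions += diff.inversions
        diff.insertions += diff.inversions
    return diff


def score_network(diff: ArcDiff, mode: ScoringMode | str = ScoringMode.OFFICIAL) -> NetworkScore:
    """SER/recall/precision/F1 from a diff; requires a non-empty reference."""
    if diff.n_reference == 0:
        raise ValueError("reference network has no arcs; SER is undefined")
    ser = diff.errors / diff.n_reference
    recall = diff.matches / diff.n_reference
    precision = diff.matches / diff.n_predicted if diff.n_predicted else 0.0
    f1 = (2 * recall * precision / (recall + precision)) if recall + precision else 0.0
    return NetworkScore(ser=ser, recall=recall, precision=precision, f1=f1,
                        diff=diff, mode=ScoringMode(mode))


def compare_networks(ref: RegulationNetwork, pred: RegulationNetwork,
                     mode: ScoringMode | str = ScoringMode.OFFICIAL,
                     inversion_policy: InversionPolicy | str = InversionPolicy.DEL_INS,
                     undirected_shape: bool = False) -> NetworkScore:
    """Apply the mode transform to both sides, then diff and score."""
    mode = ScoringMode(mode)
    if mode is ScoringMode.SHAPE:
        ref = shape_transform(ref, undirected=undirected_shape)
        pred = shape_transform(pred, undirected=undirected_shape)
    elif mode is ScoringMode.EFFECT:
        ref = effect_transform(ref)
        pred = effect_transform(pred)
    return score_network(diff_networks(ref, pred, inversion_policy), mode)


# ---------------------------------------------------------------------------
# mode transforms


def shape_transform(net: RegulationNetwork, undirected: bool = False) -> RegulationNetwork:
    """Erase regulation types: at most one neutrally-labeled arc per gene
    pair, so substitutions can no longer occur."""
    out = RegulationNetwork(nodes=set(net.nodes))
    for arc in net.arcs:
        agent, target = arc.agent, arc.target
        if undirected and target < agent:
            agent, target = target, agent
        out.add(agent, target, SHAPE_LABEL)
    return out


def effect_transform(net: RegulationNetwork) -> RegulationNetwork:
    """Keep only effect-type regulations.

    Per ordered gene pair: mechanism arcs (Binding, Transcription) alone
    become a single generic Regulation arc; when effect arcs are present
    the mechanism arcs are dropped (their Regulation relabeling would be
    redundant).  Effect arcs pass through untouched.
    """
    out = RegulationNetwork(nodes=set(net.nodes))
    for agent, target in net.pairs():
        labels = net.labels(agent, target)
        effects = labels & set(EFFECT_LABELS)
        mechanisms = labels & set(MECHANISM_LABELS)
        for label in effects:
            out.add(agent, target, label)
        if mechanisms and not effects:
            out.add(agent, target, "Regulation")
    return out
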