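"""OBO ontology loading and Wang semantic similarity.

Concept-to-concept similarity follows the weighted ancestor-contribution
scheme: each concept spreads an "S-value" up its ancestor closure,
attenuated by a per-relation factor in (0, 1), and two concepts are
compared through the S-values of their shared ancestors.  The measure is
1 for identical concepts, favors ancestors over siblings, and decays
geometrically along pure ``is_a`` chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

__all__ = [
    "OntologyConcept", "Ontology", "WangConfig", "OntologyError",
    "load_obo", "dump_obo", "load_json", "dump_json", "wang_similarity",
]


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class OntologyConcept:
    id: str
    name: str = ""
    synonyms: tuple[str, ...] = ()
    parents: tuple[tuple[str, str], ...] = ()  # (relation, parent id)


class Ontology:
    """A rooted DAG of concepts with named hierarchical relations."""

    def __init__(self, concepts: Iterable[OntologyConcept]):
        self.concepts: dict[str, OntologyConcept] = {}
        for c in concepts:
            if c.id in self.concepts:
                raise OntologyError(f"duplicate concept id {c.id!r}")
            self.concepts[c.id] = c
        for c in self.concepts.values():
            for _, pid in c.parents:
                if pid not in self.concepts:
                    raise OntologyError(f"{c.id}: unresolved parent {pid!r}")
        self._children: dict[str, list[tuple[str, str]]] = {c: [] for c in self.concepts}
        for c in self.concepts.values():
            for rel, pid in c.parents:
                self._children[pid].append((rel, c.id))
        self._check_acyclic()

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __getitem__(self, cid: str) -> OntologyConcept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise OntologyError(f"unknown concept id {cid!r}") from None

    @property
    def roots(self) -> list[str]:
        return [c.id for c in self.concepts.values() if not c.parents]

    def children(self, cid: str) -> list[tuple[str, str]]:
        """(relation, child id) pairs for concepts naming ``cid`` a parent."""
        self[cid]
        return list(self._children[cid])

    def ancestor_closure(self, cid: str) -> frozenset[str]:
        """``cid`` plus every concept reachable through parent links."""
        self[cid]
        seen: set[str] = set()
        stack = [cid]
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(pid for _, pid in self.concepts[cur].parents)
        return frozenset(seen)

    def depth(self, cid: str) -> int:
        """Length (in nodes) of the longest path from ``cid`` to a root."""
        best = 1
        for _, pid in self[cid].parents:
            best = max(best, 1 + self.depth(pid))
        return best

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(cid: str, chain: tuple[str, ...]) -> None:
            if state.get(cid) == 2:
                return
            if state.get(cid) == 1:
                cycle = chain[chain.index(cid):] + (cid,)
                raise OntologyError("cycle detected: " + " -> ".join(cycle))
            state[cid] = 1
            for _, pid in self.concepts[cid].parents:
                visit(pid, chain + (cid,))
            state[cid] = 2

        for cid in self.concepts:
            visit(cid, ())


@dataclass(frozen=True)
class WangConfig:
    """Per-relation attenuation factors; all must lie in (0, 1)."""

    weights: Mapping[str, float] = field(default_factory=lambda: {"is_a": 0.8})
    default_weight: float = 0.8

    def __post_init__(self) -> None:
        for rel, w in list(self.weights.items()) + [("<default>", self.default_weight)]:
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight for {rel!r} must be in (0,1), got {w}")

    def weight(self, relation: str) -> float:
        return self.weights.get(relation, self.default_weight)

    def _key(self) -> tuple:
        return (tuple(sorted(self.weights.items())), self.default_weight)


def _svalues(onto: Ontology, cid: str, cfg: WangConfig) -> dict[str, float]:
    """S-values of every ancestor of ``cid`` (including itself).

    S(cid) = 1; S(t) = max over children c of t inside the closure of
    w(relation) * S(c).  Computed bottom-up; memoization is per call via
    the closure restriction, and the DAG guarantee makes recursion safe.
    """
    closure = onto.ancestor_closure(cid)
    sv: dict[str, float] = {cid: 1.0}

    def value(t: str) -> float:
        if t in sv:
            return sv[t]
        best = 0.0
        for rel, child in onto.children(t):
            if child in closure:
                best = max(best, cfg.weight(rel) * value(child))
        sv[t] = best
        return best

    for t in closure:
        value(t)
    return sv


def wang_similarity(onto: Ontology, a: str, b: str,
                    cfg: WangConfig | None = None) -> float:
    """Similarity in (0, 1] between concepts ``a`` and ``b``.

    sim = sum over shared ancestors t of (S_a(t) + S_b(t)), divided by
    (sum of all S_a) + (sum of all S_b).  Symmetric; exactly 1 iff the
    two ancestor closures carry identical S-values (in particular a==b).
    """
    cfg = cfg or WangConfig()
    onto[a], onto[b]
    if a == b:
        return 1.0
    sa = _svalues(onto, a, cfg)
    sb = _svalues(onto, b, cfg)
    common = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


# ---------------------------------------------------------------------------
# OBO 1.2 input / output


def load_obo(stream: str | IO[str]) -> Ontology:
    """Load ``[Term]`` stanzas from an OBO 1.2 stream; obsolete terms are
    dropped, as are parent links pointing at obsolete terms."""
    text = stream.read() if hasattr(stream, "read") else str(stream)
    terms: list[dict] = []
    cur: dict | None = None
    in_term = False
    for raw in text.splitlines():
        line = raw.split("!", 1)[0].strip() if not raw.strip().startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            if in_term:
                cur = {"id": None, "name": "", "synonyms": [], "parents": [],
                       "obsolete": False}
                terms.append(cur)
            continue
        if not in_term or cur is None or ":" not in line:
            continue
        tag, value = (s.strip() for s in line.split(":", 1))
        if tag == "id":
            cur["id"] = value
        elif tag == "name":
            cur["name"] = value
        elif tag == "is_a":
            cur["parents"].append(("is_a", value.split()[0]))
        elif tag == "relationship":
            bits = value.split()
            if len(bits) >= 2:
                cur["parents"].append((bits[0], bits[1]))
        elif tag == "synonym":
            if '"' in value:
                cur["synonyms"].append(value.split('"')[1])
        elif tag == "is_obsolete" and value.lower().startswith("true"):
            cur["obsolete"] = True

    keep = {t["id"] for t in terms if not t["obsolete"] and t["id"]}
    concepts = [
        OntologyConcept(
            id=t["id"],
            name=t["name"],
            synonyms=tuple(t["synonyms"]),
            parents=tuple((rel, pid) for rel, pid in t["parents"] if pid in keep),
        )
        for t in terms if t["id"] in keep
    ]
    return Ontology(concepts)


def dump_obo(onto: Ontology) -> str:
    chunks = ["format-version: 1.2\n"]
    for cid in sorted(onto.concepts):
        c = onto.concepts[cid]
        lines = ["[Term]", f"id: {c.id}", f"name: {c.name}"]
        lines += [f'synonym: "{s}" EXACT []' for s in c.synonyms]
        for rel, pid in c.parents:
            if rel == "is_a":
                lines.append(f"is_a: {pid} ! {onto.concepts[pid].name}")
            else:
                lines.append(f"relationship: {rel} {pid} ! {onto.concepts[pid].name}")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


def load_json(stream: str | IO[str]) -> Ontology:
    data = json.load(stream) if hasattr(stream, "read") else json.loads(stream)
    return Ontology(
        OntologyConcept(
            id=t["id"], name=t.get("name", ""),
            synonyms=tuple(t.get("synonyms", ())),
            parents=tuple((rel, pid) for rel, pid in t.get("parents", ())),
        )
        for t in data["concepts"]
    )


def dump_json(onto: Ontology) -> str:
    return json.dumps({"concepts": [
        {"id": c.id, "name": c.name, "synonyms": list(c.synonyms),
         "parents": [list(p) for p in c.parents]}
        for c in onto.concepts.values()
    ]}, indent=1)
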