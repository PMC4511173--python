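"""Directed labeled regulation networks and their exchange formats."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterator

import networkx as nx

from .schemas import ARC_LABELS

SHAPE_LABEL = "Arc"  # neutral label used once regulation types are erased


class NetworkError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Arc:
    agent: str
    target: str
    label: str

    def reversed(self) -> "Arc":
        return Arc(self.target, self.agent, self.label)


@dataclass
class RegulationNetwork:
    """Gene nodes plus (agent, target, label) arcs.

    At most one arc per exact (agent, target, label) triple; several
    labels may connect the same ordered gene pair.  Node names are exact
    strings — normalization happens upstream.
    """

    nodes: set[str] = field(default_factory=set)
    arcs: set[Arc] = field(default_factory=set)

    def __post_init__(self) -> None:
        for arc in self.arcs:
            self.nodes.add(arc.agent)
            self.nodes.add(arc.target)

    def __len__(self) -> int:
        return len(self.arcs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulationNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.arcs == other.arcs

    def add(self, agent: str, target: str, label: str) -> None:
        if not agent or not target:
            raise NetworkError("gene names must be non-empty")
        self.nodes.update((agent, target))
        self.arcs.add(Arc(agent, target, label))

    def labels(self, agent: str, target: str) -> set[str]:
        return {a.label for a in self.arcs if a.agent == agent and a.target == target}

    def pairs(self) -> set[tuple[str, str]]:
        return {(a.agent, a.target) for a in self.arcs}

    def sorted_arcs(self) -> list[Arc]:
        return sorted(self.arcs)

    def copy(self) -> "RegulationNetwork":
        return RegulationNetwork(set(self.nodes), set(self.arcs))


# ---------------------------------------------------------------------------
# TSV arc lists


def parse_network_tsv(stream: str | IO[str]) -> RegulationNetwork:
    """Read an ``agent<TAB>label<TAB>target`` arc list; ``#`` comments and
    blank lines are ignored; a line with a single field declares an
    isolated node."""
    text = stream.read() if hasattr(stream, "read") else str(stream)
    net = RegulationNetwork()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        bits = line.split("\t")
        if len(bits) == 1:
            net.nodes.add(bits[0])
        elif len(bits) == 3:
            agent, label, target = bits
            if label not in ARC_LABELS and label != SHAPE_LABEL:
                raise NetworkError(f"line {lineno}: unknown arc label {label!r}")
            net.add(agent, target, label)
        else:
            raise NetworkError(f"line {lineno}: expected agent<TAB>label<TAB>target")
    return net


def serialize_network_tsv(net: RegulationNetwork) -> str:
    lines = [f"{a.agent}\t{a.label}\t{a.target}" for a in net.sorted_arcs()]
    linked = {n for a in net.arcs for n in (a.agent, a.target)}
    lines += sorted(net.nodes - linked)
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# GraphML


def to_graphml(net: RegulationNetwork) -> str:
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(net.nodes))
    for arc in net.sorted_arcs():
        g.add_edge(arc.agent, arc.target, label=arc.label)
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode("utf-8")

def from_graphml(stream: str | IO[str]) -> RegulationNetwork:
    data = stream.read() if hasattr(stream, "read") else str(stream)
    g = nx.read_graphml(io.BytesIO(data.encode("utf-8")))
    net = RegulationNetwork(nodes=set(g.nodes))
    for u, v, attrs in g.edges(data=True):
        net.add(str(u), str(v), str(attrs.get("label", SHAPE_LABEL)))
    return net


def load_network(path: str) -> RegulationNetwork:
    """Dispatch on extension: ``.graphml`` vs TSV arc list."""
    with open(path, "r", encoding="utf-8") as fh:
        if path.endswith(".graphml") or path.endswith(".xml"):
            return from_graphml(fh)
        return parse_network_tsv(fh)


def iter_arcs(net: RegulationNetwork) -> Iterator[tuple[str, str, str]]:
    for a in net.sorted_arcs():
        yield a.agent, a.target, a.label
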