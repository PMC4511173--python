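"""Reading, writing and validating standoff annotation files.

The dialect is the usual tab-separated one used by event-extraction
shared tasks: a plain-text document file plus annotation lines of four
kinds.

* text-bound entities::

      T1<TAB>Habitat 0 6;17 26<TAB>animal intestine

  The span may be discontinuous; fragments are separated by ``;`` and
  each fragment is ``START END`` with 0-based half-open character
  offsets counted in Unicode code points.

* events / relations::

      E1<TAB>Localization Bacterium:T3 Localization:T1

  Arguments are ``Role:Id`` pairs and may point at entities or at other
  events (nesting).

* equivalence sets::

      *<TAB>Equiv T3 T8 T12

* normalizations (concept references)::

      N1<TAB>Reference T1 Referent:OBT:0000123

  Several lines for the same entity, or a comma-separated referent list,
  both denote a multi-concept assignment.

Unknown line kinds are kept verbatim (and re-emitted on serialization)
so that heterogeneous submissions survive a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

SURFACE_JOIN = " "


class StandoffError(ValueError):
    """Base class for annotation stream problems."""


class StandoffParseError(StandoffError):
    """A malformed annotation line; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)


class ResolutionError(StandoffError):
    """A dangling reference to an annotation id."""


class SchemaError(StandoffError):
    """An unknown or inconsistent task schema."""


@dataclass(frozen=True, order=True)
class Fragment:
    """A contiguous character span, 0-based and half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def offsets(self) -> range:
        return range(self.start, self.end)

    def overlaps(self, other: "Fragment") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TextBoundEntity:
    """An annotation anchored to one or more character spans."""

    id: str
    etype: str
    fragments: tuple[Fragment, ...]
    surface: str = ""

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"{self.id}: entity needs at least one fragment")
        frags = tuple(sorted(self.fragments))
        for a, b in zip(frags, frags[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.id}: overlapping fragments {a} / {b}")
        object.__setattr__(self, "fragments", frags)

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def end(self) -> int:
        return self.fragments[-1].end

    def offsets(self) -> frozenset[int]:
        """Set of character positions covered by all fragments."""
        out: set[int] = set()
        for f in self.fragments:
            out.update(f.offsets())
        return frozenset(out)

    def span_key(self) -> tuple[str, tuple[tuple[int, int], ...]]:
        """Identity across documents: type plus exact fragment list."""
        return (self.etype, tuple((f.start, f.end) for f in self.fragments))


@dataclass(frozen=True)
class EventAnnotation:
    """An n-ary event; argument values are annotation ids."""

    id: str
    etype: str
    args: tuple[tuple[str, str], ...]

    def role(self, name: str) -> str | None:
        for r, a in self.args:
            if r == name:
                return a
        return None

    def roles(self, name: str) -> list[str]:
        return [a for r, a in self.args if r == name]


@dataclass
class AnnotatedDocument:
    """A document text with its resolved standoff annotations.

    ``normalizations`` maps entity id to the set of ontology concept ids
    assigned to it.  ``equivalences`` is kept transitively closed: sets
    sharing a member are merged at construction time.
    """

    doc_id: str
    text: str
    entities: dict[str, TextBoundEntity] = field(default_factory=dict)
    events: dict[str, EventAnnotation] = field(default_factory=dict)
    normalizations: dict[str, frozenset[str]] = field(default_factory=dict)
    equivalences: frozenset[frozenset[str]] = field(default_factory=frozenset)
    sentence_spans: tuple[Fragment, ...] | None = None
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.equivalences = merge_equivalences(self.equivalences)

    def annotation(self, aid: str) -> TextBoundEntity | EventAnnotation:
        if aid in self.entities:
            return self.entities[aid]
        if aid in self.events:
            return self.events[aid]
        raise ResolutionError(f"{self.doc_id}: unknown annotation id {aid!r}")

    def equivalents(self, entity_id: str) -> frozenset[str]:
        """All ids interchangeable with ``entity_id`` (including itself)."""
        for group in self.equivalences:
            if entity_id in group:
                return group
        return frozenset({entity_id})

    def surface_of(self, fragments: Iterable[Fragment]) -> str:
        return SURFACE_JOIN.join(self.text[f.start:f.end] for f in sorted(fragments))


def merge_equivalences(groups: Iterable[Iterable[str]]) -> frozenset[frozenset[str]]:
    """Union-find closure: groups sharing any member are merged."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: set[str] = set()
    for group in groups:
        ids = list(group)
        members.update(ids)
        for other in ids[1:]:
            parent[find(ids[0])] = find(other)
    clusters: dict[str, set[str]] = {}
    for m in members:
        clusters.setdefault(find(m), set()).add(m)
    return frozenset(frozenset(c) for c in clusters.values() if len(c) >= 2)


# ---------------------------------------------------------------------------
# parsing


def _as_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    elif hasattr(stream, "read"):
        yield from stream.read().splitlines()
    else:
        for chunk in stream:
            yield from str(chunk).splitlines()


def parse_fragments(spec: str, lineno: int | None = None) -> tuple[Fragment, ...]:
    """Parse ``"0 6;17 26"`` into Fragment tuples."""
    frags = []
    for part in spec.split(";"):
        bits = part.split()
        if len(bits) != 2:
            raise StandoffParseError(f"bad fragment {part!r}", lineno)
        try:
            frags.append(Fragment(int(bits[0]), int(bits[1])))
        except ValueError as exc:
            raise StandoffParseError(str(exc), lineno) from None
    return tuple(frags)


def parse_standoff_document(
    text_stream: str | IO[str],
    annotation_streams: str | IO[str] | Sequence[str | IO[str]],
    doc_id: str = "doc",
    sentence_spans: Sequence[Fragment] | None = None,
) -> AnnotatedDocument:
    """Parse a document text and one or more annotation streams.

    Raises :class:`StandoffParseError` on a malformed line and
    :class:`ResolutionError` when an argument id does not resolve.
    """
    text = text_stream.read() if hasattr(text_stream, "read") else str(text_stream)
    if isinstance(annotation_streams, (str, bytes)) or hasattr(annotation_streams, "read"):
        annotation_streams = [annotation_streams]  # type: ignore[list-item]

    entities: dict[str, TextBoundEntity] = {}
    events: dict[str, EventAnnotation] = {}
    normalizations: dict[str, set[str]] = {}
    equivalences: list[set[str]] = []
    extras: list[str] = []

    for stream in annotation_streams:
        for lineno, raw in enumerate(_as_lines(stream), start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise StandoffParseError("expected at least 2 tab-separated fields", lineno)
            aid, body = fields[0], fields[1]
            tokens = body.split()
            if not tokens:
                raise StandoffParseError("empty annotation body", lineno)
            kind = tokens[0]

            if aid == "*":
                if kind != "Equiv" or len(tokens) < 3:
                    raise StandoffParseError(f"bad equivalence line {line!r}", lineno)
                equivalences.append(set(tokens[1:]))
            elif kind == "Reference" or any(t.startswith("Referent:") for t in tokens[1:]):
                ent, concepts = _parse_reference(tokens, lineno)
                normalizations.setdefault(ent, set()).update(concepts)
            elif len(tokens) > 1 and _looks_like_span(body.split(None, 1)[1]):
                if aid in entities or aid in events:
                    raise StandoffParseError(f"duplicate annotation id {aid!r}", lineno)
                frags = parse_fragments(body.split(None, 1)[1], lineno)
                surface = fields[2] if len(fields) >= 3 else ""
                entities[aid] = TextBoundEntity(aid, kind, frags, surface)
            elif all(":" in t for t in tokens[1:]) and len(tokens) > 1:
                if aid in entities or aid in events:
                    raise StandoffParseError(f"duplicate annotation id {aid!r}", lineno)
                args = tuple(tuple(t.split(":", 1)) for t in tokens[1:])
                events[aid] = EventAnnotation(aid, kind, args)  # type: ignore[arg-type]
            elif aid[:1] == "T":
                raise StandoffParseError(f"malformed entity line {line!r}", lineno)
            elif aid[:1] in ("E", "R"):
                raise StandoffParseError(f"malformed event line {line!r}", lineno)
            elif aid[:1] == "N":
                raise StandoffParseError(f"malformed normalization line {line!r}", lineno)
            else:
                # heterogeneous submissions carry extra annotation kinds;
                # keep them verbatim rather than reject the stream
                logger.warning("%s: keeping unknown annotation line %r", doc_id, line)
                extras.append(line)

    doc = AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        entities=entities,
        events=events,
        normalizations={k: frozenset(v) for k, v in normalizations.items()},
        equivalences=frozenset(frozenset(g) for g in equivalences),
        sentence_spans=tuple(sentence_spans) if sentence_spans is not None else None,
        extras=tuple(extras),
    )
    _resolve(doc)
    return _fill_surfaces(doc)


def _looks_like_span(rest: str) -> bool:
    parts = rest.split(";")
    for part in parts:
        bits = part.split()
        if len(bits) != 2 or not all(b.lstrip("-").isdigit() for b in bits):
            return False
    return True


def _parse_reference_entity(token: str) -> str:
    return token.split(":", 1)[1] if token.split(":", 1)[0] in ("Arg", "Annotation") else token


def _parse_reference(tokens: Sequence[str], lineno: int) -> tuple[str, set[str]]:
    if len(tokens) < 3:
        raise StandoffParseError("normalization needs an entity and a referent", lineno)
    ent = _parse_reference_entity(tokens[1])
    concepts: set[str] = set()
    for tok in tokens[2:]:
        if not tok.startswith("Referent:"):
            raise StandoffParseError(f"bad referent token {tok!r}", lineno)
        concepts.update(c for c in tok[len("Referent:"):].split(",") if c)
    if not concepts:
        raise StandoffParseError("empty referent list", lineno)
    return ent, concepts


def _resolve(doc: AnnotatedDocument) -> None:
    for ev in doc.events.values():
        for role, arg in ev.args:
            if arg not in doc.entities and arg not in doc.events:
                raise ResolutionError(
                    f"{doc.doc_id}: event {ev.id} role {role} references unknown id {arg!r}")
    for ent_id in doc.normalizations:
        if ent_id not in doc.entities:
            raise ResolutionError(
                f"{doc.doc_id}: normalization references unknown entity {ent_id!r}")
    for group in doc.equivalences:
        for ent_id in group:
            if ent_id not in doc.entities:
                raise ResolutionError(
                    f"{doc.doc_id}: equivalence references unknown entity {ent_id!r}")
    for ent in doc.entities.values():
        if ent.end > len(doc.text):
            raise ResolutionError(
                f"{doc.doc_id}: entity {ent.id} extends past end of text")
    _check_acyclic(doc)


def _check_acyclic(doc: AnnotatedDocument) -> None:
    state: dict[str, int] = {}  # 1 = visiting, 2 = done

    def visit(eid: str, chain: tuple[str, ...]) -> None:
        if state.get(eid) == 2:
            return
        if state.get(eid) == 1:
            raise ResolutionError(
                f"{doc.doc_id}: cyclic event nesting through {' -> '.join(chain + (eid,))}")
        state[eid] = 1
        for _, arg in doc.events[eid].args:
            if arg in doc.events:
                visit(arg, chain + (eid,))
        state[eid] = 2

    for eid in doc.events:
        visit(eid, ())


def _fill_surfaces(doc: AnnotatedDocument) -> AnnotatedDocument:
    fixed = {}
    for aid, ent in doc.entities.items():
        expected = doc.surface_of(ent.fragments)
        if ent.surface and ent.surface != expected:
            logger.warning("%s: surface of %s is %r, text says %r",
                           doc.doc_id, aid, ent.surface, expected)
        fixed[aid] = replace(ent, surface=expected)
    doc.entities = fixed
    return doc


# ---------------------------------------------------------------------------
# serialization


def serialize_document(doc: AnnotatedDocument) -> str:
    """Emit the annotation stream; inverse of :func:`parse_standoff_document`.

    Multi-concept normalizations are written one line per concept.
    """
    lines: list[str] = []
    for ent in doc.entities.values():
        spans = ";".join(f"{f.start} {f.end}" for f in ent.fragments)
        lines.append(f"{ent.id}\t{ent.etype} {spans}\t{ent.surface}")
    for ev in doc.events.values():
        args = " ".join(f"{role}:{arg}" for role, arg in ev.args)
        lines.append(f"{ev.id}\t{ev.etype} {args}".rstrip())
    n = 0
    for ent_id in sorted(doc.normalizations):
        for concept in sorted(doc.normalizations[ent_id]):
            n += 1
            lines.append(f"N{n}\tReference {ent_id} Referent:{concept}")
    for group in sorted(doc.equivalences, key=sorted):
        lines.append("*\tEquiv " + " ".join(sorted(group)))
    lines.extend(doc.extras)
    return "\n".join(lines) + ("\n" if lines else "")


def load_sentence_spans(stream: str | IO[str]) -> dict[str, list[Fragment]]:
    """Read a ``doc_id<TAB>start<TAB>end`` TSV of sentence spans."""
    spans: dict[str, list[Fragment]] = {}
    for lineno, line in enumerate(_as_lines(stream), start=1):
        if not line.strip():
            continue
        bits = line.split("\t")
        if len(bits) != 3:
            raise StandoffParseError("expected doc_id<TAB>start<TAB>end", lineno)
        spans.setdefault(bits[0], []).append(Fragment(int(bits[1]), int(bits[2])))
    for doc_spans in spans.values():
        doc_spans.sort()
    return spans


def serialize_sentence_spans(spans: Mapping[str, Sequence[Fragment]]) -> str:
    lines = []
    for doc_id in sorted(spans):
        for frag in spans[doc_id]:
            lines.append(f"{doc_id}\t{frag.start}\t{frag.end}")
    return "\n".join(lines) + ("\n" if lines else "")
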