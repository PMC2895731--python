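"""Reading, writing and querying ontologies in the OBO Flatfile Format.

This module implements the 1.2 dialect of the line-oriented OBO exchange
format: a header of ``tag: value`` lines followed by stanzas introduced by a
bracketed header line (``[Term]``, ``[Typedef]``).  Everything after an
unquoted ``!`` is a comment and is stripped before tag/value interpretation.
Identifiers are treated as opaque prefixed strings (``HP:0000364``); no
ID-space validation is performed.

Only ``is_a`` edges form the subsumption backbone used by
:func:`ancestors`/:func:`descendants`; named relationships (``part_of`` ...)
are kept on the term and can be added to traversal explicitly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

logger = logging.getLogger(__name__)

#: synonym scope tags admitted by the format; unscoped synonyms default to
#: RELATED, the weakest scope.
SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")
DEFAULT_SYNONYM_SCOPE = "RELATED"

# tags handled structurally during parsing; anything else is preserved
# verbatim in OntologyTerm.extras so serialization is lossless.
_KNOWN_TERM_TAGS = {
    "id", "name", "def", "synonym", "is_a", "relationship",
    "namespace", "is_obsolete",
}


class OboParseError(ValueError):
    """Raised for malformed OBO input; the message names the line number."""


class UnknownIdError(KeyError):
    """Raised when a term identifier does not resolve in the ontology."""


@dataclass
class OntologyTerm:
    """One ontology category parsed from a ``[Term]`` stanza."""

    id: str
    name: str = ""
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    definition: str = ""
    parents: list[str] = field(default_factory=list)
    other_relationships: list[tuple[str, str]] = field(default_factory=list)
    namespace: str = ""
    is_obsolete: bool = False
    extras: dict[str, list[str]] = field(default_factory=dict)

    def labels(self, scopes: Iterable[str] | None = None) -> list[str]:
        """Name plus synonym texts, optionally restricted to scope tags."""
        out = [self.name] if self.name else []
        wanted = None if scopes is None else set(scopes)
        for text, scope in self.synonyms:
            if wanted is None or scope in wanted:
                out.append(text)
        return out


@dataclass
class Typedef:
    """A relation declaration from a ``[Typedef]`` stanza.

    ``holds_over_chain`` entries are tuples of relation ids: the declared
    relation holds whenever the chained relations hold in sequence.
    """

    id: str
    name: str = ""
    holds_over_chain: list[tuple[str, ...]] = field(default_factory=list)
    extras: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class Ontology:
    """A parsed OBO document: header metadata plus terms indexed by id."""

    header: dict[str, list[str]] = field(default_factory=dict)
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    typedefs: list[Typedef] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownIdError(term_id) from None

    def add(self, term: OntologyTerm) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def dangling_references(self) -> set[str]:
        """Parent ids referenced by some term but not defined here."""
        out: set[str] = set()
        for term in self.terms.values():
            out.update(p for p in term.parents if p not in self.terms)
        return out

    def children_index(self) -> dict[str, list[str]]:
        """Map parent id -> ids of terms that assert ``is_a`` to it."""
        index: dict[str, list[str]] = {}
        for term in self.terms.values():
            for parent in term.parents:
                index.setdefault(parent, []).append(term.id)
        return index


# ---------------------------------------------------------------------------
# parsing


def strip_comment(line: str) -> str:
    """Remove an unquoted trailing ``! comment`` from a line.

    ``!`` inside a double-quoted string is not a comment delimiter;
    backslash-escaped quotes do not close the string.
    """
    in_quote = False
    escaped = False
    for i, ch in enumerate(line):
        if escaped:
            escaped = False
            continue
        if ch == "\\":
            escaped = True
        elif ch == '"':
            in_quote = not in_quote
        elif ch == "!" and not in_quote:
            return line[:i]
    return line


def _parse_synonym(value: str, lineno: int) -> tuple[str, str]:
    value = value.strip()
    if not value.startswith('"'):
        # unquoted synonym (pre-1.2 laxity): whole value, default scope
        return value, DEFAULT_SYNONYM_SCOPE
    text_chars: list[str] = []
    i = 1
    escaped = False
    while i < len(value):
        ch = value[i]
        if escaped:
            text_chars.append(ch)
            escaped = False
        elif ch == "\\":
            escaped = True
        elif ch == '"':
            break
        else:
            text_chars.append(ch)
        i += 1
    else:
        raise OboParseError(f"line {lineno}: unterminated synonym string")
    rest = value[i + 1:].strip()
    scope = rest.split()[0] if rest else ""
    if scope not in SYNONYM_SCOPES:
        scope = DEFAULT_SYNONYM_SCOPE
    return "".join(text_chars), scope


def _parse_def(value: str) -> str:
    value = value.strip()
    if value.startswith('"'):
        out: list[str] = []
        escaped = False
        for ch in value[1:]:
            if escaped:
                out.append(ch)
                escaped = False
            elif ch == "\\":
                escaped = True
            elif ch == '"':
                break
            else:
                out.append(ch)
        return "".join(out)
    return value


def _iter_stanzas(stream: TextIO) -> Iterator[tuple[str, int, list[tuple[int, str, str]]]]:
    """Yield (stanza_type, header_lineno, [(lineno, tag, value), ...]).

    The document header is yielded first with stanza_type ``""``.
    """
    stanza_type = ""
    header_lineno = 0
    lines: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = strip_comment(raw.rstrip("\n")).strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            yield stanza_type, header_lineno, lines
            stanza_type = line[1:-1]
            header_lineno = lineno
            lines = []
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, _, value = line.partition(":")
        lines.append((lineno, tag.strip(), value.strip()))
    yield stanza_type, header_lineno, lines


def parse_obo(source: TextIO | str) -> Ontology:
    """Parse OBO Flatfile text into an :class:`Ontology`.

    ``source`` may be a text stream or the document itself.  One
    :class:`OntologyTerm` is created per ``[Term]`` stanza and one
    :class:`Typedef` per ``[Typedef]`` stanza; other stanza types are ignored
    with a warning.  Raises :class:`OboParseError` for a missing ``id`` tag, a
    tag line preceding any stanza interpreted as an unknown header tag is
    fine, and for duplicate ids (the error names both stanzas' lines).
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    ontology = Ontology()
    seen_at: dict[str, int] = {}
    for stanza_type, header_lineno, lines in _iter_stanzas(stream):
        if stanza_type == "":
            for _, tag, value in lines:
                ontology.header.setdefault(tag, []).append(value)
            continue
        if stanza_type == "Term":
            term, lineno = _build_term(header_lineno, lines)
            if term.id in seen_at:
                raise OboParseError(
                    f"duplicate id {term.id!r}: stanzas at lines "
                    f"{seen_at[term.id]} and {header_lineno}"
                )
            seen_at[term.id] = header_lineno
            ontology.terms[term.id] = term
        elif stanza_type == "Typedef":
            ontology.typedefs.append(_build_typedef(header_lineno, lines))
        else:
            logger.warning(
                "ignoring [%s] stanza at line %d", stanza_type, header_lineno
            )
    return ontology


def _build_term(header_lineno: int, lines: list[tuple[int, str, str]]) -> tuple[OntologyTerm, int]:
    term_id = ""
    for lineno, tag, value in lines:
        if tag == "id":
            term_id = value
            break
    if not term_id:
        raise OboParseError(f"line {header_lineno}: [Term] stanza has no id tag")
    term = OntologyTerm(id=term_id)
    for lineno, tag, value in lines:
        if tag == "id":
            continue
        if tag == "name":
            term.name = value
        elif tag == "def":
            term.definition = _parse_def(value)
        elif tag == "synonym":
            term.synonyms.append(_parse_synonym(value, lineno))
        elif tag == "is_a":
            target = value.split()[0] if value.split() else ""
            if not target:
                raise OboParseError(f"line {lineno}: empty is_a target")
            term.parents.append(target)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"line {lineno}: relationship needs 'relation target'"
                )
            term.other_relationships.append((parts[0], parts[1]))
        elif tag == "namespace":
            term.namespace = value
        elif tag == "is_obsolete":
            term.is_obsolete = value.lower() == "true"
        else:
            term.extras.setdefault(tag, []).append(value)
    if term.is_obsolete and term.parents:
        # obsolete terms carry no live subsumption links
        logger.warning("obsolete term %s has is_a parents; dropping them", term.id)
        term.parents = []
    return term, header_lineno


def _build_typedef(header_lineno: int, lines: list[tuple[int, str, str]]) -> Typedef:
    typedef_id = ""
    for _, tag, value in lines:
        if tag == "id":
            typedef_id = value
            break
    if not typedef_id:
        raise OboParseError(f"line {header_lineno}: [Typedef] stanza has no id tag")
    typedef = Typedef(id=typedef_id)
    for _, tag, value in lines:
        if tag == "id":
            continue
        if tag == "name":
            typedef.name = value
        elif tag == "holds_over_chain":
            typedef.holds_over_chain.append(tuple(value.split()))
        else:
            typedef.extras.setdefault(tag, []).append(value)
    return typedef


# ---------------------------------------------------------------------------
# serialization


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def serialize_obo(ontology: Ontology) -> str:
    """Serialize an :class:`Ontology` to OBO Flatfile text.

    Output is byte-deterministic: terms are sorted by id and the tag order
    within a stanza is fixed (id, name, namespace, def, synonym, is_a,
    relationship, is_obsolete, extras sorted by tag).  Synonyms, parents and
    relationships keep their stored order; header tags keep insertion order.
    """
    out: list[str] = []
    for tag, values in ontology.header.items():
        for value in values:
            out.append(f"{tag}: {value}")
    if out:
        out.append("")
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        if term.definition:
            out.append(f"def: {_quote(term.definition)} []")
        for text, scope in term.synonyms:
            out.append(f"synonym: {_quote(text)} {scope} []")
        for parent in term.parents:
            out.append(f"is_a: {parent}")
        for relation, target in term.other_relationships:
            out.append(f"relationship: {relation} {target}")
        if term.is_obsolete:
            out.append("is_obsolete: true")
        for tag in sorted(term.extras):
            for value in term.extras[tag]:
                out.append(f"{tag}: {value}")
        out.append("")
    for typedef in sorted(ontology.typedefs, key=lambda t: t.id):
        out.append("[Typedef]")
        out.append(f"id: {typedef.id}")
        if typedef.name:
            out.append(f"name: {typedef.name}")
        for chain in typedef.holds_over_chain:
            out.append(f"holds_over_chain: {' '.join(chain)}")
        for tag in sorted(typedef.extras):
            for value in typedef.extras[tag]:
                out.append(f"{tag}: {value}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# subsumption queries


def ancestors(
    ontology: Ontology,
    term_id: str,
    include_self: bool = False,
    relations: Iterable[str] = (),
) -> set[str]:
    """Transitive closure over ``is_a`` edges (the sub-category relation).

    ``relations`` names additional relationship types (e.g. ``part_of``) to
    traverse alongside ``is_a``.  Cycles are tolerated (each node is reported
    once); parent references that do not resolve are skipped with a warning.
    """
    if term_id not in ontology.terms:
        raise UnknownIdError(term_id)
    extra = set(relations)
    seen: set[str] = set()
    stack = [term_id]
    while stack:
        current = stack.pop()
        term = ontology.terms[current]
        targets = list(term.parents)
        if extra:
            targets += [t for rel, t in term.other_relationships if rel in extra]
        for parent in targets:
            if parent not in ontology.terms:
                logger.warning("dangling reference %s from %s", parent, current)
                continue
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    if include_self:
        seen.add(term_id)
    elif term_id in seen:  # cycle through the query term
        seen.discard(term_id)
    return seen


def descendants(
    ontology: Ontology, term_id: str, include_self: bool = False
) -> set[str]:
    """Transitive closure over inverse ``is_a`` edges; cycle-tolerant."""
    if term_id not in ontology.terms:
        raise UnknownIdError(term_id)
    index = ontology.children_index()
    seen: set[str] = set()
    stack = [term_id]
    while stack:
        current = stack.pop()
        for child in index.get(current, ()):
            if child not in seen:
                seen.add(child)
                stack.append(child)
    if include_self:
        seen.add(term_id)
    else:
        seen.discard(term_id)
    return seen
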