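"""Category-level (CC) and individual-level (II) function relations.

A function inheres in its bearer the way a property does: the heart has the
function "to pump blood" even while it is not pumping, and even when it
cannot pump.  A *functioning* is a process realizing a function; a function
may exist unrealized.  Relations between *categories* (CC-relations) are
defined by quantifying relations between *individuals* (II-relations) over
the categories' extensions:

- ``CC-has-function(E, F)``: every instance x of E has some function
  instance y in F (an II-has-function edge x -> y).
- ``CC-realized-by(F, P)``: whenever an instance x of F is realized by some
  y, that y is an instance of P.  Unrealized function instances never
  falsify this — realization is not required, only constrained in kind.
- ``CC-has-function-realized-by(E, P)``: some function category F exists
  with CC-has-function(E, F) and CC-realized-by(F, P).  This links an
  anatomical structure category directly to the process category realizing
  its (implicit) function, without naming the function.
- ``II-has-function-realized-by(x, p)``: x bears a function instance that is
  in fact (and currently) realized by the process individual p — a two-edge
  path, and deliberately much stronger than the CC relation.

The CC relation is expressible in OWL2 as a property chain over the two
constituent relations; :func:`emit_property_chain_axiom` emits that axiom in
functional syntax together with the equivalent OBO ``holds_over_chain``
Typedef stanza.

Checking is extensional over finite :class:`InstanceModel`\\ s: categories
are concrete sets of individuals, the existential F in the composed relation
ranges over the categories present in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import yaml


class UnknownCategoryError(KeyError):
    """A category id is not a key of the model's extensions."""


class UnknownIndividualError(KeyError):
    """An individual name is not declared in the model."""


@dataclass
class InstanceModel:
    """A finite model: individuals, category extensions and relation edges."""

    individuals: set[str] = field(default_factory=set)
    extensions: dict[str, set[str]] = field(default_factory=dict)
    has_function_edges: set[tuple[str, str]] = field(default_factory=set)
    realized_by_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Every individual mentioned anywhere must be declared."""
        mentioned: set[str] = set()
        for ext in self.extensions.values():
            mentioned |= ext
        for a, b in self.has_function_edges | self.realized_by_edges:
            mentioned.add(a)
            mentioned.add(b)
        stray = mentioned - self.individuals
        if stray:
            raise ValueError(f"undeclared individuals: {sorted(stray)}")

    def extension(self, category: str) -> set[str]:
        try:
            return self.extensions[category]
        except KeyError:
            raise UnknownCategoryError(category) from None

    def _check_individual(self, name: str) -> None:
        if name not in self.individuals:
            raise UnknownIndividualError(name)

    @classmethod
    def from_yaml(cls, path) -> "InstanceModel":
        """Read a model from a YAML file with sections ``individuals``,
        ``extensions``, ``has_function`` and ``realized_by`` (edge lists as
        two-element lists)."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(
            individuals=set(data.get("individuals", [])),
            extensions={
                k: set(v or []) for k, v in (data.get("extensions") or {}).items()
            },
            has_function_edges={
                (a, b) for a, b in (data.get("has_function") or [])
            },
            realized_by_edges={
                (a, b) for a, b in (data.get("realized_by") or [])
            },
        )


def cc_has_function(model: InstanceModel, E: str, F: str) -> bool:
    """Every instance of E bears some function instance of F.

    Vacuously true when ext(E) is empty (universal quantification).
    """
    ext_f = model.extension(F)
    return all(
        any((x, y) in model.has_function_edges for y in ext_f)
        for x in model.extension(E)
    )


def cc_realized_by(model: InstanceModel, F: str, P: str) -> bool:
    """Whenever an instance of F is realized by something, that something is
    an instance of P.  A function instance with no realization never
    falsifies the relation."""
    ext_p = model.extension(P)
    for x in model.extension(F):
        for a, y in model.realized_by_edges:
            if a == x and y not in ext_p:
                return False
    return True


class HfrbResult(NamedTuple):
    """Outcome of a CC-has-function-realized-by check with its witness."""

    holds: bool
    witness: str | None

    def __bool__(self) -> bool:
        return self.holds


def cc_has_function_realized_by(model: InstanceModel, E: str, P: str) -> HfrbResult:
    """E bears some function category F that is realized by P.

    The existential F ranges over the categories present in the model; on
    success the smallest witnessing category id is reported.
    """
    model.extension(E)
    model.extension(P)
    for F in sorted(model.extensions):
        if cc_has_function(model, E, F) and cc_realized_by(model, F, P):
            return HfrbResult(True, F)
    return HfrbResult(False, None)


def ii_has_function_realized_by(model: InstanceModel, x: str, p: str) -> bool:
    """x bears a function instance currently realized by the process p."""
    model._check_individual(x)
    model._check_individual(p)
    return any(
        (x, f) in model.has_function_edges and (f, p) in model.realized_by_edges
        for f in model.individuals
    )


# ---------------------------------------------------------------------------
# OWL2 property chain


def emit_property_chain_axiom(
    has_function: str = "has_function",
    realized_by: str = "realized_by",
    chain: str = "has_function_realized_by",
) -> str:
    """Emit the property-chain definition of the composed relation.

    Returns OWL2 functional syntax stating ``chain`` is a super-property of
    the chain ``has_function o realized_by``, followed by the equivalent OBO
    Typedef stanza with a ``holds_over_chain`` tag.  Output is
    byte-deterministic.
    """
    for name in (has_function, realized_by, chain):
        if not name or any(ch.isspace() for ch in name):
            raise ValueError(f"invalid property name {name!r}")
    owl = (
        "SubObjectPropertyOf(\n"
        f"    ObjectPropertyChain(:{has_function} :{realized_by})\n"
        f"    :{chain}\n"
        ")\n"
    )
    obo = (
        "[Typedef]\n"
        f"id: {chain}\n"
        f"name: {chain.replace('_', ' ')}\n"
        f"holds_over_chain: {has_function} {realized_by}\n"
    )
    return owl + "\n" + obo
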