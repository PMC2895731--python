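"""Synthetic OBO fixture ontologies with known ground truth.

Two generators make every other module testable without downloading real
ontology releases:

- :func:`make_worked_example_fixture` rebuilds the hand-traceable triple
  around "Hearing abnormality": a phenotype ontology holding the hearing
  terms and the naming-problem examples the linter targets, a process
  ontology with "sensory perception of sound" (synonym "hearing") and the
  three excluded roots, and an anatomy ontology with "Ear".
- :func:`make_random_fixture` plants a configurable number of true
  structure/process pattern instances in randomized ontologies, together
  with distractors that each violate exactly one part of the pattern, and
  returns the planted truth alongside.  Extraction under the default
  configuration must recover the planted pairs exactly.

Distractor kinds (one per pattern condition / filter):

- ``no_keyword`` — a fully wired pattern instance whose phenotype label
  lacks every abnormality keyword (like disease-named categories);
- ``not_delimited`` — the process word appears only fused into a longer
  token, so whitespace-delimited containment fails;
- ``excluded_process`` — the matched process sits under an excluded root
  (``is_a GO:0032502``);
- ``anatomy_not_ancestor`` — the anatomy name occurs only in phenotype
  terms that are not ancestors of the matching category.

All randomness flows from one ``random.Random(seed)``; generation is
byte-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .lexical import pluralize
from .obo_io import Ontology, OntologyTerm

DISTRACTOR_KINDS = (
    "no_keyword", "not_delimited", "excluded_process", "anatomy_not_ancestor",
)

_KEYWORDS = ("abnormal", "impaired", "decreased", "increased")

# realistic vocabulary (anatomy words with regular and irregular morphology,
# process words) plus nonsense words that cannot collide with anything
_STRUCTURE_WORDS = (
    "blood", "pancreas", "uterus", "heart", "kidney", "liver", "lung",
    "spleen", "retina", "cornea", "trachea", "larynx", "artery", "vertebra",
    "bronchus", "thymus", "mammary gland", "esophagus", "tooth", "ovary",
    "zorbule", "flimber", "crandel", "plomba", "quirnex", "dravule",
    "smorfin", "glandrix", "vorpal organ", "trunnel duct",
)
_PROCESS_WORDS = (
    "coagulation", "lactation", "angiogenesis", "secretion", "fertilization",
    "migration", "diestrus", "respiration", "digestion", "filtration",
    "contraction", "absorption", "excretion", "perfusion", "gestation",
    "blinkration", "snorfulation", "cravitation", "plimming", "dextrosis",
    "morbulation", "franditure", "gleaning flux", "zantering", "quopsis",
)

EXCLUDED_ROOT_TERMS = (
    ("GO:0032502", "developmental process"),
    ("GO:0043473", "pigmentation"),
    ("GO:0001503", "ossification"),
)


@dataclass
class PlantedTruth:
    """Ground truth for a generated fixture triple."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    distractor_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def _term(term_id: str, name: str, parents: list[str] | None = None,
          synonyms: list[tuple[str, str]] | None = None) -> OntologyTerm:
    return OntologyTerm(
        id=term_id, name=name,
        parents=list(parents or []),
        synonyms=list(synonyms or []),
    )


def _new_ontology() -> Ontology:
    return Ontology(header={"format-version": ["1.2"]})


def make_worked_example_fixture() -> tuple[Ontology, Ontology, Ontology]:
    """The deterministic hand-checkable fixture triple.

    Extraction must yield exactly (FMA:52780 Ear, GO:0007605 sensory
    perception of sound) with the evidence chain HP:0000364 -> HP:0000598;
    linting the phenotype ontology must flag the plural mix on the ear-lobe
    pair, the disjunctive tear-gland label and the impaired-hearing /
    hearing-impairment permutation.
    """
    phenotype = _new_ontology()
    phenotype.add(_term("HP:0000598", "Abnormality of the ears"))
    phenotype.add(_term("HP:0000364", "Hearing abnormality",
                        parents=["HP:0000598"]))
    phenotype.add(_term("HP:0000251",
                        "Abnormality of tear glands OR tear production"))
    phenotype.add(_term("MP:0003677", "abnormal ear lobe"))
    phenotype.add(_term("MP:0003678", "absent ear lobes",
                        parents=["MP:0003677"]))
    phenotype.add(_term("MP:0001963", "abnormal hearing physiology"))
    phenotype.add(_term("MP:0001965", "abnormal hearing",
                        synonyms=[("hearing disability", "EXACT"),
                                  ("hearing impairment", "EXACT")]))
    phenotype.add(_term("MP:0001967", "deafness"))
    phenotype.add(_term("MP:0006325", "impaired hearing"))

    process = _new_ontology()
    process.add(_term("GO:0007605", "sensory perception of sound",
                      synonyms=[("hearing", "EXACT")]))
    for go_id, go_name in EXCLUDED_ROOT_TERMS:
        process.add(_term(go_id, go_name))

    anatomy = _new_ontology()
    anatomy.add(_term("FMA:52780", "Ear"))
    return phenotype, anatomy, process


class _Ids:
    def __init__(self, prefix: str) -> None:
        self.prefix = prefix
        self.n = 0

    def __call__(self) -> str:
        self.n += 1
        return f"{self.prefix}:{self.n:07d}"


def _pluralize_phrase(phrase: str) -> str:
    words = phrase.split()
    return " ".join(words[:-1] + [pluralize(words[-1])])


def _draw(rng: random.Random, pool: list[str], fallback: str, counter: _Ids) -> str:
    """Pop a random word; synthesize a unique nonsense word when exhausted."""
    if pool:
        return pool.pop(rng.randrange(len(pool)))
    return f"{fallback}{counter()[-7:]}"


def make_random_fixture(
    seed: int, n_pairs: int = 6, n_distractors: int = 8
) -> tuple[Ontology, Ontology, Ontology, PlantedTruth]:
    """Generate a (phenotype, anatomy, process) triple with planted truth.

    Every planted instance wires all four pattern conditions: a phenotype
    category "<keyword> <structure> <process>" (the structure word randomly
    inflected) below "abnormality of the <structure-plural>", an anatomy
    term for the structure and a process term for the process (the process
    word sometimes only reachable through an exact synonym).  Word
    assignments never repeat within a fixture, so planted instances and
    distractors cannot interact.  Distractor kinds are assigned round-robin
    from :data:`DISTRACTOR_KINDS`.
    """
    if n_pairs < 0 or n_distractors < 0:
        raise ValueError("counts must be >= 0")
    rng = random.Random(seed)
    structure_pool = [w for w in _STRUCTURE_WORDS]
    process_pool = [w for w in _PROCESS_WORDS]
    phen_ids, anat_ids, proc_ids = _Ids("PHEN"), _Ids("ANAT"), _Ids("PROC")

    phenotype, anatomy, process = _new_ontology(), _new_ontology(), _new_ontology()
    root_id = "PHEN:0000001"
    phen_ids.n = 1
    phenotype.add(_term(root_id, "phenotypic abnormality"))
    for go_id, go_name in EXCLUDED_ROOT_TERMS:
        process.add(_term(go_id, go_name))

    truth = PlantedTruth(seed=seed,
                         distractor_counts={k: 0 for k in DISTRACTOR_KINDS})

    def add_anatomy(word: str) -> str:
        term_id = anat_ids()
        anatomy.add(_term(term_id, word))
        return term_id

    def add_process(word: str, parent: str | None = None) -> str:
        term_id = proc_ids()
        if rng.random() < 0.5:
            term = _term(term_id, word, parents=[parent] if parent else None)
        else:
            # process word reachable only through an exact synonym
            term = _term(term_id, f"{word} dynamics",
                         parents=[parent] if parent else None,
                         synonyms=[(word, "EXACT")])
        process.add(term)
        return term_id

    def add_parent_e(structure: str) -> str:
        e_id = phen_ids()
        phenotype.add(_term(
            e_id, f"abnormality of the {_pluralize_phrase(structure)}",
            parents=[root_id],
        ))
        return e_id

    for _ in range(n_pairs):
        s = _draw(rng, structure_pool, "struct", phen_ids)
        p = _draw(rng, process_pool, "proc", phen_ids)
        anat_id = add_anatomy(s)
        proc_id = add_process(p)
        e_id = add_parent_e(s)
        kw = rng.choice(_KEYWORDS)
        s_inflected = _pluralize_phrase(s) if rng.random() < 0.5 else s
        c_id = phen_ids()
        phenotype.add(_term(c_id, f"{kw} {s_inflected} {p}", parents=[e_id]))
        truth.pairs.append((anat_id, proc_id))

    for i in range(n_distractors):
        kind = DISTRACTOR_KINDS[i % len(DISTRACTOR_KINDS)]
        truth.distractor_counts[kind] += 1
        s = _draw(rng, structure_pool, "struct", phen_ids)
        p = _draw(rng, process_pool, "proc", phen_ids)
        if kind == "no_keyword":
            add_anatomy(s)
            add_process(p)
            e_id = add_parent_e(s)
            phenotype.add(_term(phen_ids(), f"{s} {p} anomaly",
                                parents=[e_id]))
        elif kind == "not_delimited":
            add_anatomy(s)
            add_process(p)
            e_id = add_parent_e(s)
            kw = rng.choice(_KEYWORDS)
            phenotype.add(_term(phen_ids(), f"{kw} {s} {p}oid",
                                parents=[e_id]))
        elif kind == "excluded_process":
            add_anatomy(s)
            excluded_root = rng.choice(EXCLUDED_ROOT_TERMS)[0]
            add_process(p, parent=excluded_root)
            e_id = add_parent_e(s)
            kw = rng.choice(_KEYWORDS)
            phenotype.add(_term(phen_ids(), f"{kw} {s} {p}", parents=[e_id]))
        else:  # anatomy_not_ancestor
            add_anatomy(s)
            add_process(p)
            # the anatomy word occurs only in a term unrelated to C
            phenotype.add(_term(
                phen_ids(),
                f"abnormality of the {_pluralize_phrase(s)}",
                parents=[root_id],
            ))
            blank = _draw(rng, structure_pool, "struct", phen_ids)
            e_id = phen_ids()
            phenotype.add(_term(
                e_id, f"abnormality of the {_pluralize_phrase(blank)}",
                parents=[root_id],
            ))
            kw = rng.choice(_KEYWORDS)
            phenotype.add(_term(phen_ids(), f"{kw} {s} {p}", parents=[e_id]))

    truth.pairs.sort()
    return phenotype, anatomy, process, truth


def truth_to_tsv(truth: PlantedTruth) -> str:
    """Serialize a :class:`PlantedTruth` as a small TSV table."""
    rows = ["structure_id\tprocess_id"]
    rows += [f"{s}\t{p}" for s, p in truth.pairs]
    return "\n".join(rows) + "\n"
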