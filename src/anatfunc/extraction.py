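"""Extraction of structure/process pairs from an ontology triple.

Phenotype ontologies classify abnormal functionings underneath abnormalities
of the structure that bears the impaired function ("Hearing abnormality"
is_a "Abnormality of the ears").  That taxonomic convention, together with
the compositional naming of phenotype categories, lets the implicit link
between an anatomical structure and the process realizing its function be
harvested lexically.  The pattern has four conditions:

1. a phenotype category C with a name/synonyms,
2. the name or a synonym of a process category D occurs whitespace-delimited
   inside a name or synonym of C,
3. C is a sub-category (transitive is_a) of a phenotype category E,
4. the name or a synonym of an anatomy category F occurs whitespace-delimited
   inside a name or synonym of E.

Every (F, D) pair so found is a candidate for the category-level
has-function-realized-by relation between the structure F and the process D.
Two filters remove systematic noise: only phenotype categories whose name or
synonyms contain one of the abnormality keywords (abnormal, impaired,
decreased, increased — as character substrings, so "abnormal" matches
"abnormality") are considered, which drops disease-named categories like
"Deafness"; and process categories under the polysemous subtrees
developmental process (GO:0032502), pigmentation (GO:0043473) and
ossification (GO:0001503) are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from .lexical import NormalizedLabel, contains_delimited, normalize_label
from .obo_io import Ontology, OntologyTerm, ancestors, descendants

logger = logging.getLogger(__name__)

#: keywords marking a phenotype category as describing an abnormality
DEFAULT_ABNORMALITY_KEYWORDS = ("abnormal", "impaired", "decreased", "increased")

#: process subtrees excluded for state/process polysemy of their labels
DEFAULT_EXCLUDED_PROCESS_ROOTS = ("GO:0032502", "GO:0043473", "GO:0001503")


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the extraction pattern."""

    abnormality_keywords: tuple[str, ...] = DEFAULT_ABNORMALITY_KEYWORDS
    excluded_process_roots: tuple[str, ...] = DEFAULT_EXCLUDED_PROCESS_ROOTS
    exclude_descendants: bool = True
    synonym_scopes_used: tuple[str, ...] | None = None  # None = all scopes
    include_self_as_ancestor: bool = False

    def __post_init__(self) -> None:
        if not self.abnormality_keywords:
            raise ValueError("abnormality keyword list must be non-empty")
        if any(k != k.lower() for k in self.abnormality_keywords):
            raise ValueError("abnormality keywords must be lowercase")

    @classmethod
    def from_yaml(cls, path) -> "ExtractionConfig":
        """Load a config from a YAML mapping mirroring the field names."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        kwargs = {}
        for key in (
            "abnormality_keywords",
            "excluded_process_roots",
            "synonym_scopes_used",
        ):
            if data.get(key) is not None:
                kwargs[key] = tuple(data[key])
        for key in ("exclude_descendants", "include_self_as_ancestor"):
            if key in data:
                kwargs[key] = bool(data[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class Evidence:
    """One occurrence of the pattern supporting a pair."""

    phenotype_id: str  # C
    ancestor_id: str   # E
    matched_process_text: str
    matched_structure_text: str


@dataclass
class StructureProcessPair:
    """An extracted (anatomy structure, process) pair with evidence."""

    structure_id: str
    structure_name: str
    process_id: str
    process_name: str
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.process_id)


def filter_abnormality_terms(
    phenotype: Ontology, config: ExtractionConfig | None = None
) -> set[str]:
    """Ids of non-obsolete phenotype terms naming an abnormality.

    A term qualifies when its lowercased name or any lowercased synonym
    contains at least one keyword as a character substring ("abnormal"
    matches "Abnormality of the ears").
    """
    config = config or ExtractionConfig()
    keep: set[str] = set()
    for term in phenotype.terms.values():
        if term.is_obsolete:
            continue
        texts = [term.name.lower()] + [text.lower() for text, _ in term.synonyms]
        if any(kw in text for kw in config.abnormality_keywords for text in texts):
            keep.add(term.id)
    return keep


def excluded_process_ids(
    process: Ontology, config: ExtractionConfig | None = None
) -> set[str]:
    """Process ids removed from matching: the configured roots and, by
    default, their whole is_a subtrees.  Roots absent from the ontology are
    ignored with a warning."""
    config = config or ExtractionConfig()
    excluded: set[str] = set()
    for root in config.excluded_process_roots:
        if root not in process.terms:
            logger.warning("excluded process root %s not in ontology", root)
            continue
        excluded.add(root)
        if config.exclude_descendants:
            excluded.update(descendants(process, root))
    return excluded


def _term_labels(term: OntologyTerm, config: ExtractionConfig) -> list[str]:
    return term.labels(scopes=config.synonym_scopes_used)


def match_terms(
    label_owner: OntologyTerm,
    target: Ontology,
    excluded: set[str] | None = None,
    config: ExtractionConfig | None = None,
) -> list[tuple[str, str]]:
    """Target terms whose name/synonym occurs delimited in the owner's labels.

    Tests every name/in-scope synonym of every non-obsolete, non-excluded
    target term against every name/in-scope synonym of ``label_owner`` using
    normalized token containment.  Hits are deduplicated per target id,
    keeping the longest matched text; the result is sorted by target id.
    """
    config = config or ExtractionConfig()
    excluded = excluded or set()
    owner_labels = [normalize_label(t) for t in _term_labels(label_owner, config)]
    owner_labels = [lab for lab in owner_labels if lab]
    hits: dict[str, str] = {}
    for target_id in target.terms:
        if target_id in excluded:
            continue
        term = target.terms[target_id]
        if term.is_obsolete:
            continue
        for text in _term_labels(term, config):
            needle = normalize_label(text)
            if not needle:
                continue
            if any(contains_delimited(hay, needle) for hay in owner_labels):
                best = hits.get(target_id)
                if best is None or _match_rank(text) > _match_rank(best):
                    hits[target_id] = text
    return sorted(hits.items())


def _match_rank(text: str) -> tuple[int, int, str]:
    lab = normalize_label(text)
    return (len(lab.tokens), len(text), text)


def extract_pairs(
    phenotype: Ontology,
    anatomy: Ontology,
    process: Ontology,
    config: ExtractionConfig | None = None,
) -> list[StructureProcessPair]:
    """Run the four-condition pattern over an ontology triple.

    For each phenotype term C passing the abnormality-keyword filter and
    matching a non-excluded process term D, and each is_a ancestor E of C
    matching an anatomy term F, the pair (F, D) is emitted with the evidence
    chain (C, E, matched texts).  Pairs are unique on (structure, process)
    with merged evidence, ordered by (structure_id, process_id).
    """
    config = config or ExtractionConfig()
    candidates = filter_abnormality_terms(phenotype, config)
    excluded = excluded_process_ids(process, config)
    logger.info(
        "extraction: %d phenotype terms, %d pass keyword filter; "
        "%d anatomy terms; %d process terms (%d excluded)",
        len(phenotype.terms), len(candidates),
        len(anatomy.terms), len(process.terms), len(excluded),
    )
    anatomy_hits_cache: dict[str, list[tuple[str, str]]] = {}
    pairs: dict[tuple[str, str], StructureProcessPair] = {}
    n_process_matches = 0
    for c_id in sorted(candidates):
        c_term = phenotype.terms[c_id]
        process_hits = match_terms(c_term, process, excluded, config)
        if not process_hits:
            continue
        n_process_matches += 1
        ancestor_ids = ancestors(
            phenotype, c_id, include_self=config.include_self_as_ancestor
        )
        for e_id in sorted(ancestor_ids):
            if e_id not in anatomy_hits_cache:
                anatomy_hits_cache[e_id] = match_terms(
                    phenotype.terms[e_id], anatomy, None, config
                )
            for f_id, f_text in anatomy_hits_cache[e_id]:
                for d_id, d_text in process_hits:
                    pair = pairs.get((f_id, d_id))
                    if pair is None:
                        pair = StructureProcessPair(
                            structure_id=f_id,
                            structure_name=anatomy.terms[f_id].name,
                            process_id=d_id,
                            process_name=process.terms[d_id].name,
                        )
                        pairs[(f_id, d_id)] = pair
                    ev = Evidence(c_id, e_id, d_text, f_text)
                    if ev not in pair.evidence:
                        pair.evidence.append(ev)
    result = [pairs[key] for key in sorted(pairs)]
    for pair in result:
        pair.evidence.sort(key=lambda e: (e.phenotype_id, e.ancestor_id))
    logger.info(
        "extraction: %d phenotype terms matched a process, %d pairs emitted",
        n_process_matches, len(result),
    )
    return result


TSV_COLUMNS = (
    "structure_id", "structure_name", "process_id", "process_name",
    "phenotype_id", "ancestor_id", "matched_process_text",
    "matched_structure_text",
)


def pairs_to_tsv(pairs: list[StructureProcessPair]) -> str:
    """Render pairs as a TSV table, one row per evidence item."""
    rows = ["\t".join(TSV_COLUMNS)]
    for pair in pairs:
        for ev in pair.evidence:
            rows.append("\t".join((
                pair.structure_id, pair.structure_name,
                pair.process_id, pair.process_name,
                ev.phenotype_id, ev.ancestor_id,
                ev.matched_process_text, ev.matched_structure_text,
            )))
    return "\n".join(rows) + "\n"
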