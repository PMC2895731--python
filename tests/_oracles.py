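"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's graph traversal, matching and
extraction code paths: reachability is computed by repeated edge expansion
of a boolean matrix, containment by scanning every start offset, and pair
extraction by enumerating every (C, D, E, F) quadruple and checking the
four pattern conditions plus the keyword and exclusion filters directly.
"""

from __future__ import annotations

from anatfunc.extraction import ExtractionConfig
from anatfunc.lexical import normalize_label
from anatfunc.obo_io import Ontology, OntologyTerm


def offset_scan_contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    """Token containment by explicit enumeration of all start offsets."""
    if len(needle) == 0:
        return False
    found = False
    for start in range(len(haystack)):
        window = haystack[start:start + len(needle)]
        if len(window) == len(needle):
            if all(a == b for a, b in zip(window, needle)):
                found = True
    return found


def expansion_reachability(edges: set[tuple[str, str]], nodes: set[str]) -> dict[str, set[str]]:
    """Transitive reachability by repeated edge expansion to a fixed point."""
    reach: dict[str, set[str]] = {n: {b for a, b in edges if a == n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for n in nodes:
            extra: set[str] = set()
            for m in reach[n]:
                extra |= reach.get(m, set())
            if not extra <= reach[n]:
                reach[n] |= extra
                changed = True
    return reach


def _isa_reachability(ontology: Ontology) -> dict[str, set[str]]:
    nodes = set(ontology.terms)
    edges = {
        (t.id, p)
        for t in ontology.terms.values()
        for p in t.parents
        if p in ontology.terms
    }
    return expansion_reachability(edges, nodes)


def _labels(term: OntologyTerm, config: ExtractionConfig) -> list[str]:
    out = [term.name] if term.name else []
    for text, scope in term.synonyms:
        if config.synonym_scopes_used is None or scope in config.synonym_scopes_used:
            out.append(text)
    return out


def _delimited_label_match(owner: OntologyTerm, target: OntologyTerm,
                           config: ExtractionConfig) -> bool:
    for owner_text in _labels(owner, config):
        hay = normalize_label(owner_text).tokens
        for target_text in _labels(target, config):
            needle = normalize_label(target_text).tokens
            if offset_scan_contains(hay, needle):
                return True
    return False


def brute_force_pairs(
    phenotype: Ontology,
    anatomy: Ontology,
    process: Ontology,
    config: ExtractionConfig | None = None,
) -> set[tuple[str, str]]:
    """All (structure id, process id) pairs licensed by direct evaluation of
    the four pattern conditions over every quadruple."""
    config = config or ExtractionConfig()
    reach = _isa_reachability(phenotype)
    proc_reach = _isa_reachability(process)
    excluded = set()
    for root in config.excluded_process_roots:
        if root in process.terms:
            excluded.add(root)
            if config.exclude_descendants:
                excluded |= {
                    t for t in process.terms if root in proc_reach[t]
                }
    pairs: set[tuple[str, str]] = set()
    for c_id, c in phenotype.terms.items():
        if c.is_obsolete:
            continue
        texts = [t.lower() for t in [c.name] + [s for s, _ in c.synonyms]]
        if not any(kw in t for kw in config.abnormality_keywords for t in texts):
            continue
        for d_id, d in process.terms.items():
            if d.is_obsolete or d_id in excluded:
                continue
            if not _delimited_label_match(c, d, config):
                continue
            for e_id in phenotype.terms:
                if e_id == c_id:
                    # the query term itself counts only when configured to
                    is_ancestor = config.include_self_as_ancestor
                else:
                    is_ancestor = e_id in reach[c_id]
                if not is_ancestor:
                    continue
                e = phenotype.terms[e_id]
                for f_id, f in anatomy.terms.items():
                    if f.is_obsolete:
                        continue
                    if _delimited_label_match(e, f, config):
                        pairs.add((f_id, d_id))
    return pairs
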