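"""Naming-convention lint for phenotype ontologies.

Lexical harvesting of structure/process pairs is only as good as the
labels it reads, and phenotype ontologies mix naming styles in ways that
systematically break it.  The rules here flag the recurring problems:

- **R1 plural_mix** — plural and singular forms of the same word used
  between a term and its is_a ancestor/descendant ("abnormal ear lobe"
  above "absent ear lobes").
- **R2 or_label** — a disjunctive label mixing structural and functional
  abnormalities ("abnormality of tear glands OR tear production"); such
  categories should be split.
- **R3 absent_quality** — "absent" used as if it were a quality.  A quality
  inheres in a bearer; "absent" asserts there is no bearer, so "absent X"
  labels (and definitions referencing PATO:0000462) are flagged for review.
- **R4 label_permutation** — two terms whose labels are word permutations or
  derivational variants of each other ("impaired hearing" vs the synonym
  "hearing impairment"), signalling duplicated or un-coordinated naming.

All findings are warnings — these are curation suggestions, not format
errors — and linting never mutates the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .lexical import normalize_label, singularize, tokenize
from .obo_io import Ontology, ancestors

ALL_RULES = ("R1", "R2", "R3", "R4")

PATO_ABSENT = "PATO:0000462"

#: derivational suffixes stripped (longest first) for R4's permutation test,
#: applied after singularization; min stem length 3 keeps "ring" -> "ring".
_DERIVATIONAL_SUFFIXES = ("ation", "ment", "ity", "ed", "ing")


@dataclass(frozen=True)
class LintFinding:
    """One rule violation: rule id, offending term id(s), message."""

    rule: str
    term_ids: tuple[str, ...]
    message: str
    severity: str = "warning"


class UnknownRuleError(ValueError):
    """An enabled rule id is not one of R1-R4."""


def _derivational_stem(token: str) -> str:
    token = singularize(token)
    for suffix in _DERIVATIONAL_SUFFIXES:
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    return token


def run_lint(
    ontology: Ontology,
    rules: set[str] | None = None,
    r1_global: bool = False,
) -> list[LintFinding]:
    """Apply the enabled rules; findings sorted by (rule, first term id).

    ``r1_global`` widens R1 from is_a neighborhoods to all term pairs.
    """
    enabled = set(ALL_RULES) if rules is None else set(rules)
    unknown = enabled - set(ALL_RULES)
    if unknown:
        raise UnknownRuleError(f"unknown lint rule(s): {sorted(unknown)}")
    findings: list[LintFinding] = []
    if "R1" in enabled:
        findings += _rule_plural_mix(ontology, global_pairs=r1_global)
    if "R2" in enabled:
        findings += _rule_or_label(ontology)
    if "R3" in enabled:
        findings += _rule_absent_quality(ontology)
    if "R4" in enabled:
        findings += _rule_label_permutation(ontology)
    findings.sort(key=lambda f: (f.rule, f.term_ids))
    return findings


def _rule_plural_mix(ontology: Ontology, global_pairs: bool = False) -> list[LintFinding]:
    """R1: a token appears in singular form in one label and plural in a
    subsumption-related label.  With ``global_pairs`` every term pair is
    compared instead of only is_a neighborhoods."""
    findings = []
    term_ids = sorted(ontology.terms)
    if global_pairs:
        candidate_pairs = combinations(term_ids, 2)
    else:
        candidate_pairs = (
            (tid, anc)
            for tid in term_ids
            for anc in sorted(ancestors(ontology, tid))
        )
    for a_id, b_id in candidate_pairs:
        a_label = ontology.terms[a_id].name
        b_label = ontology.terms[b_id].name
        clash = _plurality_clash(a_label, b_label)
        if clash:
            singular, plural = clash
            findings.append(LintFinding(
                rule="R1",
                term_ids=tuple(sorted((a_id, b_id))),
                message=(
                    f'singular "{singular}" and plural "{plural}" mixed '
                    f'between related labels "{a_label}" and "{b_label}"'
                ),
            ))
    return findings


def _plurality_clash(label_a: str, label_b: str) -> tuple[str, str] | None:
    tokens_a = tokenize(label_a)
    tokens_b = tokenize(label_b)
    for ta in tokens_a:
        for tb in tokens_b:
            if ta != tb and singularize(ta) == singularize(tb):
                singular, plural = (ta, tb) if ta == singularize(ta) else (tb, ta)
                return singular, plural
    return None


def _rule_or_label(ontology: Ontology) -> list[LintFinding]:
    """R2: a standalone token "or" marks a disjunctive label."""
    findings = []
    for term_id in sorted(ontology.terms):
        name = ontology.terms[term_id].name
        if "or" in tokenize(name):
            findings.append(LintFinding(
                rule="R2",
                term_ids=(term_id,),
                message=f'disjunctive label "{name}" mixes abnormality kinds; '
                        f"consider splitting the category",
            ))
    return findings


def _rule_absent_quality(ontology: Ontology) -> list[LintFinding]:
    """R3: "absent" used as a quality, by label or by PATO:0000462 reference."""
    findings = []
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        tokens = normalize_label(term.name).tokens
        by_label = bool(tokens) and tokens[0] == "absent"
        by_reference = PATO_ABSENT in term.definition or any(
            PATO_ABSENT in value
            for values in term.extras.values()
            for value in values
        )
        if by_label or by_reference:
            findings.append(LintFinding(
                rule="R3",
                term_ids=(term_id,),
                message=f'"{term.name}": "absent" is not a quality '
                        f"(no bearer to inhere in); model as a lacks-relation",
            ))
    return findings


def _rule_label_permutation(ontology: Ontology) -> list[LintFinding]:
    """R4: two distinct terms whose labels agree as multisets of
    derivational stems ("impaired hearing" / "hearing impairment")."""
    by_stems: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        for text in term.labels():
            stems = tuple(sorted(_derivational_stem(t) for t in tokenize(text)))
            if stems:
                entry = (term_id, text)
                if entry not in by_stems.setdefault(stems, []):
                    by_stems[stems].append(entry)
    findings = []
    seen: set[tuple[str, ...]] = set()
    for entries in by_stems.values():
        ids = sorted({term_id for term_id, _ in entries})
        if len(ids) < 2:
            continue
        key = tuple(ids)
        if key in seen:
            continue
        seen.add(key)
        texts = sorted({text for _, text in entries})
        findings.append(LintFinding(
            rule="R4",
            term_ids=key,
            message="equivalent labels across distinct terms: "
                    + "; ".join(f'"{t}"' for t in texts),
        ))
    return findings


def findings_to_tsv(findings: list[LintFinding]) -> str:
    """Render findings as a TSV table (rule, comma-joined ids, message)."""
    rows = ["rule\tterm_ids\tmessage"]
    for f in findings:
        rows.append(f"{f.rule}\t{','.join(f.term_ids)}\t{f.message}")
    return "\n".join(rows) + "\n"
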