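"""The four-condition pattern, its filters, and oracle equivalence."""

import dataclasses

import pytest

from anatfunc.extraction import (
    ExtractionConfig,
    excluded_process_ids,
    extract_pairs,
    filter_abnormality_terms,
    match_terms,
    pairs_to_tsv,
)
from anatfunc.fixtures import make_random_fixture
from anatfunc.obo_io import Ontology, OntologyTerm, ancestors, parse_obo

from _oracles import brute_force_pairs


def _ontology(*terms):
    ont = Ontology()
    for term in terms:
        ont.add(term)
    return ont


def T(term_id, name, parents=(), synonyms=(), obsolete=False):
    return OntologyTerm(id=term_id, name=name, parents=list(parents),
                        synonyms=list(synonyms), is_obsolete=obsolete)


# --- keyword filter --------------------------------------------------------


def test_keyword_filter_matches_substring_and_synonyms():
    phen = _ontology(
        T("P:1", "Hearing abnormality"),
        T("P:2", "Deafness"),
        T("P:3", "Tinnitus", synonyms=[("decreased hearing", "RELATED")]),
        T("P:4", "Impaired balance", obsolete=True),
    )
    assert filter_abnormality_terms(phen) == {"P:1", "P:3"}


def test_keyword_filter_empty_ontology():
    assert filter_abnormality_terms(Ontology()) == set()


def test_config_rejects_empty_or_uppercase_keywords():
    with pytest.raises(ValueError):
        ExtractionConfig(abnormality_keywords=())
    with pytest.raises(ValueError):
        ExtractionConfig(abnormality_keywords=("Abnormal",))


# --- process exclusion -----------------------------------------------------


def _process_with_subtree():
    return _ontology(
        T("GO:0001503", "ossification"),
        T("GO:0036072", "direct ossification", parents=["GO:0001503"]),
        T("GO:0007605", "sensory perception of sound"),
    )


def test_excluded_ids_cover_subtree_by_default():
    assert excluded_process_ids(_process_with_subtree()) == {
        "GO:0001503", "GO:0036072",
    }


def test_excluded_ids_root_only_when_flagged():
    config = ExtractionConfig(exclude_descendants=False)
    assert excluded_process_ids(_process_with_subtree(), config) == {
        "GO:0001503",
    }


def test_excluded_ids_missing_root_warns(caplog):
    ont = _ontology(T("GO:0007605", "sensory perception of sound"))
    assert excluded_process_ids(ont) == set()
    assert "GO:0032502" in caplog.text


@pytest.mark.parametrize("seed", range(10))
def test_excluded_ids_equal_bruteforce_reachability(seed):
    _, _, process, _ = make_random_fixture(seed)
    from _oracles import expansion_reachability
    edges = {(t.id, p) for t in process.terms.values()
             for p in t.parents if p in process.terms}
    reach = expansion_reachability(edges, set(process.terms))
    roots = set(ExtractionConfig().excluded_process_roots) & set(process.terms)
    expected = set(roots)
    for tid in process.terms:
        if reach[tid] & roots:
            expected.add(tid)
    assert excluded_process_ids(process) == expected


# --- label matching --------------------------------------------------------


def test_match_terms_by_synonym_and_singularization():
    owner = T("P:1", "Hearing abnormality")
    target = _ontology(
        T("GO:0007605", "sensory perception of sound",
          synonyms=[("hearing", "EXACT")]),
    )
    assert match_terms(owner, target) == [("GO:0007605", "hearing")]

    owner = T("P:2", "Abnormality of the ears")
    anatomy = _ontology(T("FMA:52780", "Ear"))
    assert match_terms(owner, anatomy) == [("FMA:52780", "Ear")]


def test_match_terms_skips_excluded_and_obsolete():
    owner = T("P:1", "abnormal ossification of bone")
    target = _ontology(
        T("GO:0001503", "ossification"),
        T("GO:X", "bone", obsolete=True),
    )
    assert match_terms(owner, target, excluded={"GO:0001503"}) == []


def test_match_terms_keeps_longest_text_per_target():
    owner = T("P:1", "abnormal sensory perception of sound")
    target = _ontology(
        T("GO:0007605", "sensory perception of sound",
          synonyms=[("perception of sound", "EXACT")]),
    )
    assert match_terms(owner, target) == [
        ("GO:0007605", "sensory perception of sound"),
    ]


def test_match_terms_respects_synonym_scope_config():
    owner = T("P:1", "Hearing abnormality")
    target = _ontology(
        T("GO:0007605", "sensory perception of sound",
          synonyms=[("hearing", "BROAD")]),
    )
    config = ExtractionConfig(synonym_scopes_used=("EXACT",))
    assert match_terms(owner, target, config=config) == []
    assert match_terms(owner, target) == [("GO:0007605", "hearing")]


# --- full pattern ----------------------------------------------------------


def test_worked_example_yields_exactly_ear_hearing(worked_triple):
    phenotype, anatomy, process = worked_triple
    pairs = extract_pairs(phenotype, anatomy, process)
    assert [p.key for p in pairs] == [("FMA:52780", "GO:0007605")]
    (pair,) = pairs
    assert [(e.phenotype_id, e.ancestor_id) for e in pair.evidence] == [
        ("HP:0000364", "HP:0000598"),
    ]


def test_empty_phenotype_yields_no_pairs(worked_triple):
    _, anatomy, process = worked_triple
    assert extract_pairs(Ontology(), anatomy, process) == []


def test_table_style_blood_coagulation_fixture():
    phenotype = _ontology(
        T("MP:E", "abnormal blood"),
        T("MP:C", "abnormal blood coagulation", parents=["MP:E"]),
    )
    anatomy = _ontology(T("MA:BLOOD", "blood"))
    process = _ontology(T("GO:COAG", "coagulation"))
    pairs = extract_pairs(phenotype, anatomy, process)
    assert ("MA:BLOOD", "GO:COAG") in {p.key for p in pairs}


def test_include_self_as_ancestor_single_label_case():
    phenotype = _ontology(T("MP:C", "abnormal pancreas insulin secretion"))
    anatomy = _ontology(T("MA:PANC", "pancreas"))
    process = _ontology(T("GO:SECR", "insulin secretion"))
    assert extract_pairs(phenotype, anatomy, process) == []
    config = ExtractionConfig(include_self_as_ancestor=True)
    pairs = extract_pairs(phenotype, anatomy, process, config)
    assert [p.key for p in pairs] == [("MA:PANC", "GO:SECR")]


@pytest.mark.parametrize("seed", range(15))
def test_extract_pairs_equals_quadruple_enumeration(seed):
    phenotype, anatomy, process, _ = make_random_fixture(seed)
    got = {p.key for p in extract_pairs(phenotype, anatomy, process)}
    assert got == brute_force_pairs(phenotype, anatomy, process)


@pytest.mark.parametrize("seed", range(15))
def test_planted_pairs_recovered_exactly(seed):
    phenotype, anatomy, process, truth = make_random_fixture(seed)
    got = sorted(p.key for p in extract_pairs(phenotype, anatomy, process))
    assert got == truth.pairs


def test_removing_a_keyword_never_adds_pairs():
    phenotype, anatomy, process, _ = make_random_fixture(7)
    full = {p.key for p in extract_pairs(phenotype, anatomy, process)}
    for kw in ExtractionConfig().abnormality_keywords:
        reduced = tuple(
            k for k in ExtractionConfig().abnormality_keywords if k != kw
        )
        config = ExtractionConfig(abnormality_keywords=reduced)
        subset = {p.key for p in extract_pairs(phenotype, anatomy, process,
                                               config)}
        assert subset <= full


def test_evidence_invariants_hold():
    phenotype, anatomy, process, _ = make_random_fixture(11)
    config = ExtractionConfig()
    keyword_pass = filter_abnormality_terms(phenotype, config)
    for pair in extract_pairs(phenotype, anatomy, process, config):
        assert pair.evidence
        for ev in pair.evidence:
            assert ev.phenotype_id in keyword_pass
            assert ev.ancestor_id in ancestors(phenotype, ev.phenotype_id)


def test_pairs_to_tsv_one_row_per_evidence(worked_triple):
    pairs = extract_pairs(*worked_triple)
    text = pairs_to_tsv(pairs)
    lines = text.strip().split("\n")
    assert lines[0].startswith("structure_id\tstructure_name")
    assert len(lines) == 1 + sum(len(p.evidence) for p in pairs)
    assert "FMA:52780\tEar\tGO:0007605" in lines[1]


def test_config_roundtrips_through_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "abnormality_keywords: [abnormal, impaired]\n"
        "exclude_descendants: false\n"
        "include_self_as_ancestor: true\n"
    )
    config = ExtractionConfig.from_yaml(path)
    assert config.abnormality_keywords == ("abnormal", "impaired")
    assert config.exclude_descendants is False
    assert config.include_self_as_ancestor is True
    # untouched fields keep their defaults
    assert config.excluded_process_roots == ExtractionConfig().excluded_process_roots
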