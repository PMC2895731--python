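# anatfunc

Harvest anatomical **structure/process function pairs** from a phenotype
ontology, an anatomy ontology and a process ontology — and check the
category-level function relations that justify them.

Phenotype ontologies (HPO, MPO) classify abnormal *functionings* under
abnormalities of the *structure* that bears the impaired function:
"Hearing abnormality" (HP:0000364) is_a "Abnormality of the ears"
(HP:0000598).  Because no public ontology of anatomical functions exists,
that taxonomic convention is the best available record of which process
realizes which structure's function.  `anatfunc` extracts it with a
four-condition lexical pattern: a phenotype category C whose label contains
(whitespace-delimited, after lowercasing and singularization) the name or a
synonym of a process category D, below an ancestor E whose label contains
an anatomy category F — here "Hearing" (GO:0007605, synonym of "sensory
perception of sound") in C and "Ear" (FMA:52780) in E, proposing the pair
(Ear, sensory perception of sound).

Phenotype categories without an abnormality keyword (`abnormal`,
`impaired`, `decreased`, `increased` as substrings of name or synonyms) are
skipped — this drops disease-named categories such as "Deafness" — and the
state/process-polysemous GO subtrees `developmental process`,
`pigmentation` and `ossification` are excluded from matching.

Each pair (F, D) is a proposal that F and D stand in the category-level
**has-function-realized-by** relation:

    cc_has_function(E, F):  ∀x ∈ ext(E) ∃y ∈ ext(F): has_function(x, y)
    cc_realized_by(F, P):   ∀x ∈ ext(F) ∀y: realized_by(x, y) → y ∈ ext(P)
    cc_hfrb(E, P):          ∃F: cc_has_function(E, F) ∧ cc_realized_by(F, P)

so a structure is linked to the kind of process that realizes its function
without the function category ever being named.  The package evaluates
these relations (and their much stronger individual-level counterpart)
over finite instance models, emits the OWL2 property-chain axiom
`hasFunctionRealizedBy ⊒ hasFunction ∘ realizedBy`, and lints the
phenotype-ontology naming problems (plural/singular mixing, disjunctive
"OR" labels, "absent" used as a quality, permuted duplicate labels) that
degrade the harvest.  See `docs/methods.md` for the full method.

Intended users: bio-ontology engineers curating phenotype/anatomy
cross-products, and anyone needing a clean OBO round-tripping toolkit with
deterministic serialization.

## Worked example

```python
from anatfunc import make_worked_example_fixture, extract_pairs, run_lint

phenotype, anatomy, process = make_worked_example_fixture()

for pair in extract_pairs(phenotype, anatomy, process):
    print(f"{pair.structure_id} ({pair.structure_name}) has-function-realized-by "
          f"{pair.process_id} ({pair.process_name})")
    for ev in pair.evidence:
        print(f"  evidence: {ev.phenotype_id} is_a {ev.ancestor_id}; "
              f"matched {ev.matched_process_text!r} / {ev.matched_structure_text!r}")

for finding in run_lint(phenotype):
    print(finding.rule, ",".join(finding.term_ids), "--", finding.message)
```

prints

```
FMA:52780 (Ear) has-function-realized-by GO:0007605 (sensory perception of sound)
  evidence: HP:0000364 is_a HP:0000598; matched 'hearing' / 'Ear'
R1 MP:0003677,MP:0003678 -- singular "lobe" and plural "lobes" mixed between related labels "absent ear lobes" and "abnormal ear lobe"
R2 HP:0000251 -- disjunctive label "Abnormality of tear glands OR tear production" mixes abnormality kinds; consider splitting the category
R3 MP:0003678 -- "absent ear lobes": "absent" is not a quality (no bearer to inhere in); model as a lacks-relation
R4 HP:0000364,MP:0001965 -- equivalent labels across distinct terms: "Hearing abnormality"; "abnormal hearing"
R4 MP:0001965,MP:0006325 -- equivalent labels across distinct terms: "hearing impairment"; "impaired hearing"
```

Exactly one structure/process pair survives the filters — (Ear, sensory
perception of sound), justified by the subsumption of HP:0000364 under
HP:0000598 — while the linter reports the plural mixing on the ear-lobe
pair, the disjunctive tear-gland label, an "absent" quality use, and the
permuted "impaired hearing"/"hearing impairment" duplicates.

The same pipeline runs from the shell:

```sh
anatfunc fixture --kind worked --out-dir fx
anatfunc -v extract --phenotype fx/phenotype.obo --anatomy fx/anatomy.obo \
    --process fx/process.obo --out pairs.tsv
anatfunc lint fx/phenotype.obo
anatfunc chain-axiom
```

A recipe for running against current HPO/MPO/MA/GO releases is in
`docs/methods.md`; expect pair counts to differ from historical runs as the
ontologies evolve.

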