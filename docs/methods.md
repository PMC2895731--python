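# Methods

## The problem and the pattern

Anatomy ontologies describe anatomical *structure*; process ontologies such
as the Gene Ontology's Biological Process branch describe the *processes*
those structures carry out; no public ontology links the two through
anatomical *function*.  Phenotype ontologies (HPO for human, MPO for mouse)
encode that missing link implicitly: they classify abnormal functionings
underneath abnormalities of the structure bearing the impaired function —
"Hearing abnormality" (HP:0000364) sits below "Abnormality of the ears"
(HP:0000598).  `anatfunc` harvests that implicit link lexically.

A candidate structure/process pair (F, D) is emitted whenever

1. a phenotype category C exists,
2. the name or a synonym of a process category D occurs, delimited by
   whitespace, inside a name or synonym of C,
3. C is a sub-category (transitive `is_a`) of a phenotype category E, and
4. the name or a synonym of an anatomy category F occurs, delimited by
   whitespace, inside a name or synonym of E.

Two filters suppress systematic noise:

- **Abnormality keywords.**  Only phenotype categories whose name or
  synonyms contain one of `abnormal`, `impaired`, `decreased`, `increased`
  as a *character substring* take part (so "abnormal" matches
  "Abnormality of the ears").  This drops disease-named categories such as
  "Deafness", whose labels carry no process or structure vocabulary.
- **Excluded process subtrees.**  `developmental process` (GO:0032502),
  `pigmentation` (GO:0043473) and `ossification` (GO:0001503) are removed
  before matching.  Their labels are state/process polysemous ("skull
  ossification" names the *state* of the skull, not an ossification
  process), so matches in these subtrees are unreliable.  By default the
  whole `is_a` subtree of each root is excluded, because the polysemy that
  motivates the exclusion pervades the subtrees ("direct ossification" is
  no less ambiguous than its parent); `exclude_descendants=False` restores
  root-only exclusion.

Each emitted pair carries its evidence chain — every (C, E) combination and
the matched label texts — so a curator can audit why the pair was proposed.
Pairs are deduplicated on (structure id, process id) with merged evidence
and ordered deterministically.

## Label normalization

Labels only match across ontologies after normalization: lowercase, split
on whitespace *and hyphens* (MPO writes both "t-cell apoptosis" and "T cell
apoptosis"), strip edge punctuation, singularize each token.  "Delimited by
whitespaces" containment is then decided on token sequences — the needle's
tokens must appear as a contiguous run of the haystack's tokens.  Token
subsequence matching, rather than raw substring matching, is the only
faithful reading of whitespace delimitation once tokens have been rewritten
by singularization ("ear" matches in "abnormality of the ears", never
inside "heart").

Singularization is a rule table, not a statistical stemmer: an irregulars
table (`uteri -> uterus`, `teeth -> tooth`, ~110 entries), an
invariant-words table (`pancreas`, `species`, ...), then ordered suffix
rules (`-ies -> -y`; sibilant `-es` stripping that distinguishes
"glasses -> glass" from "noses -> nose"; a final `-s` strip that leaves
`-ss`/`-us`/`-is` alone).  Every mapping is auditable and the tables are
plain-text files overridable through `lexical.load_tables`.  The rules are
validated against a shipped reference list of 229 plural/singular pairs
covering regular, Latin/Greek and irregular English morphology.  Tokens the
rules do not recognise pass through unchanged, which is the correct
behaviour for the nonsense vocabulary in synthetic fixtures and for
identifiers.

## Relation semantics

The pair (F, D) extracted above is a proposal that F and D stand in the
category-level **has-function-realized-by** relation.  The relations are
defined by quantifying individual-level (II) relations over category
extensions (CC-relations):

- `cc_has_function(E, F)`: every instance x of E bears some function
  instance y in F.  Universally quantified, hence vacuously true for an
  empty extension of E.
- `cc_realized_by(F, P)`: whenever an instance of F is realized by
  something, that something is an instance of P.  Crucially, a function
  instance with *no* realization never falsifies this: functions can exist
  unrealized (the heart has "to pump blood" during transplantation), so
  realization is constrained in kind, never required.
- `cc_has_function_realized_by(E, P)`: some category F exists with
  `cc_has_function(E, F)` and `cc_realized_by(F, P)`.  This lets structure
  and process be related without ever naming the function category — the
  reason the relation is worth having is that it avoids duplicating, in a
  new function ontology, every process the process ontology already names.
- `ii_has_function_realized_by(x, p)`: x bears a function instance that is
  currently realized by the process individual p — a two-edge path, and
  deliberately much stronger than the CC composition.  Models where the CC
  relation holds but the II relation holds for no instance pair are exactly
  the unrealized-function cases; the test suite constructs one.

In OWL2 the CC composition is a property chain,
`hasFunctionRealizedBy ⊒ hasFunction ∘ realizedBy`;
`emit_property_chain_axiom` emits that axiom in functional syntax together
with the equivalent OBO `holds_over_chain` Typedef.

Checking is extensional over finite instance models (YAML files with
individuals, category extensions and the two edge sets).  The existential F
ranges over the categories *present in the model*, not over arbitrary
subsets of individuals — quantifying over all subsets would make the
relation trivially satisfiable, since for any (E, P) with the right edges a
tailor-made singleton category always exists.  The exhaustive verification
enumerates every model with two individuals per sort and two candidate
function categories (4^4 extension choices x 2^4 has-function edge sets x
2^4 realized-by edge sets = 65,536 models) and compares the implementation
against an independently written direct evaluation of the quantified
definition; two per sort keeps the space exhaustively enumerable in
seconds, and the quantifier structure involves no threshold that three
individuals would exercise differently.

## Lint rules

The same naming conventions the extractor relies on are routinely violated;
the linter reports the violations as curation warnings (never errors):

- **R1 plural_mix** — a term and an `is_a` ancestor/descendant whose labels
  contain a token pair differing in surface plurality but singularizing
  identically ("abnormal ear lobe" above "absent ear lobes").  The
  comparison runs within subsumption neighborhoods because that is where
  mixed plurality breaks classification reading; `r1_global=True` compares
  all pairs.  Plurality mismatch is detected token-wise rather than by
  whole-label equality, since the related labels usually differ in their
  qualifier words as well.
- **R2 or_label** — a standalone token "or" marks a disjunctive label
  mixing structural and functional abnormalities ("abnormality of tear
  glands OR tear production"); the category should be split.
- **R3 absent_quality** — a label beginning with "absent", or a
  definition/cross-reference mentioning PATO:0000462.  A quality inheres in
  a bearer; "absent" asserts the bearer (or process) does not exist, so it
  is not a quality and should be modelled with a lacks-style relation.
  The rule fires for structure terms and process-referencing terms alike.
- **R4 label_permutation** — two distinct terms whose labels (names or
  synonyms) are equal as multisets of *derivational stems*: tokens are
  singularized and then stripped of `-ation/-ment/-ity/-ed/-ing` (minimum
  stem length 3).  Plain token-multiset equality misses the canonical
  duplication pattern — "impaired hearing" vs "hearing impairment" share no
  surface token multiset — while the stem multiset {hear, impair} captures
  it without semantic resources.  The stripper is scoped to R4; extraction
  matching never uses it.

State/process polysemy itself ("ossification", "pigmentation") is not
lexically detectable and is handled by the subtree exclusions above; the
suggested remedy — suffixing labels with "process" or "state" — is a
curation action outside this tool's scope.

## Synthetic fixtures

`make_worked_example_fixture()` rebuilds the hand-traceable triple: the
hearing terms (HP:0000364 under HP:0000598; GO:0007605 with exact synonym
"hearing"; FMA:52780 "Ear"), the three excluded GO roots, and the
naming-problem terms the linter targets (the MP ear-lobe pair, the
disjunctive HP:0000251 label, MP:0001965 with its "hearing disability" /
"hearing impairment" synonyms, MP:0006325 "impaired hearing", MP:0001967
"deafness").  MP:0001965's primary label is not fixed by its published
synonyms; the fixture names it "abnormal hearing".

`make_random_fixture(seed, n_pairs=6, n_distractors=8)` plants pattern
instances in randomized ontologies.  Each planted instance wires all four
conditions: C = "\<keyword> \<structure> \<process>" (structure word randomly
inflected for number) below E = "abnormality of the \<structure-plural>",
with an anatomy term for the structure and a process term whose matching
label is, half the time, reachable only through an exact synonym.  The word
pool mixes real anatomical/process vocabulary with irregular morphology
(uterus/uteri, tooth/teeth, larynx/larynges) and nonsense words; within one
fixture no word is used twice, so planted instances and distractors cannot
interact and the planted truth is exact by construction.  Four distractor
kinds each break exactly one condition or filter, making every filter
independently falsifiable:

| kind | breaks |
| --- | --- |
| `no_keyword` | abnormality-keyword filter (fully wired otherwise) |
| `not_delimited` | whitespace delimitation (process word fused into a longer token) |
| `excluded_process` | exclusion filter (process planted under GO:0032502) |
| `anatomy_not_ancestor` | condition 3/4 interplay (anatomy word only in non-ancestor terms) |

Default sizes (6 planted pairs, 8 distractors, ≲40 phenotype terms per
triple) keep a 100-fixture brute-force comparison under a few seconds while
exercising every code path.  What the generator does **not** emulate:
real ontologies' scale (10^4–10^5 terms), definition text, non-`is_a`
relationship richness, multiple inheritance depth, and — most importantly —
the *borderline* lexical collisions of real vocabulary (e.g. "ossification"
as both state and process, anatomy words embedded in unrelated multi-word
labels).  Passing the planted-recovery properties therefore shows the
pattern logic and filters are implemented correctly, not that precision on
real ontology releases will be high; the published experience with 2010-era
releases was ~75% precision under manual review, and current releases will
behave differently again.

## Numerical and procedural choices

- **OBO dialect.**  `[Term]` and `[Typedef]` stanzas of format-version 1.2;
  other stanza types are skipped with a warning.  `!` starts a comment
  except inside double quotes; identifiers are opaque prefixed strings.
  Serialization sorts terms by id and fixes tag order (id, name, namespace,
  def, synonym, is_a, relationship, is_obsolete, extras alphabetically), so
  output is byte-deterministic and parse∘serialize is the identity on the
  parsed representation.  Unknown tags survive round-trips in a per-term
  extras map.  Cycles in `is_a` are tolerated during traversal (each node
  reported once) so that a malformed export degrades to a warning rather
  than a crash; dangling parent references are skipped with a warning and
  surfaced via `Ontology.dangling_references()`.
- **Subsumption = `is_a` only.**  Condition 3 reads "sub-category", i.e.
  subsumption; `ancestors(..., relations=["part_of"])` can widen traversal
  explicitly, but no named relation participates by default.
- **Synonym scopes.**  All scopes (EXACT/BROAD/NARROW/RELATED) participate
  in matching by default, because the pattern speaks of "name or synonym"
  without restriction; `synonym_scopes_used` narrows this.
- **C as its own ancestor.**  Off by default — the pattern names distinct C
  and E.  `include_self_as_ancestor=True` handles single-label cases like
  "abnormal pancreas insulin secretion", where one label carries both the
  structure and the process.
- **Nested matches.**  When an owner label contains several nested matching
  labels of different targets, all targets are kept (pair-level
  deduplication absorbs redundancy); within one target id only the longest
  matched text is retained.
- **Tie-breaks and ordering.**  Everything user-visible is sorted: pairs by
  (structure id, process id), evidence by (C, E), lint findings by (rule,
  term ids), matches by target id.  Reported quantities are counts and
  exact rational ratios; no floating-point tolerances are involved.

## Limitations

- Matching is purely lexical; it inherits every naming defect the linter
  flags and discovers no pair whose process vocabulary is missing from the
  process ontology (e.g. "tear production" has no GO category).
- Part/whole mismatches produce systematically debatable pairs: the ears'
  function is realized by a *part* of hearing processes (GO:0050910
  "detection of mechanical stimulus involved in sensory perception of
  sound"), yet the phenotype ontology's placement licenses the pair
  (Ear, sensory perception of sound).  Decomposing functions along
  `part_of` is out of scope.
- The extractor proposes a *skeleton* for curation, not a finished function
  ontology; precision on real releases requires manual review.

## Running against current ontology releases

The test suite never downloads anything.  To run the extractor on current
real releases (an offline-unfriendly, several-minute computation on inputs
of 10^4–10^5 terms):

```sh
curl -LO http://purl.obolibrary.org/obo/hp.obo
curl -LO http://purl.obolibrary.org/obo/go.obo
curl -LO http://purl.obolibrary.org/obo/ma.obo      # or an FMA OBO export
curl -LO http://purl.obolibrary.org/obo/mp.obo

# human: HPO phenotypes x FMA/UBERON anatomy x GO biological process
anatfunc -v extract --phenotype hp.obo --anatomy fma.obo --process go.obo \
    --out hp_pairs.tsv

# mouse: MPO phenotypes x adult mouse anatomy x GO biological process
anatfunc -v extract --phenotype mp.obo --anatomy ma.obo --process go.obo \
    --out mp_pairs.tsv

anatfunc lint hp.obo --out hp_findings.tsv
```

Historical runs of this pattern on 2010-era releases produced 25 HPO/FMA
and 331 MPO/MA pairs; counts obtained from current releases **will differ**
— ontologies have gained terms, synonyms and restructured subtrees since —
so treat the TSV as input to curation, not as a reproduction target.
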