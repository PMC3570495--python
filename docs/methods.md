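# Methods

## The inference model

`phenoassert` treats a genome's annotation as three layers of evidence and
propagates uncertainty explicitly through all of them.

**Functional terms.** A term links a gene product to its mature functional
form (plain protein product, covalently/non-covalently modified protein, or
a protein complex). Per genome, a term's state is a Kleene truth value:

- `TRUE` — at least one gene carries the term with *manual* or *propagated*
  provenance;
- `UNKNOWN` — only *candidate* genes cover it;
- `FALSE` — no evidence at all.

**Reactions and pathways.** A reaction is an OR over alternative
implementations, each an AND-set of terms (all subunits of a complex;
substrate/product terms are ordinary AND members — they carry no special
semantics here). A pathway is an ordered list of steps, each an OR-set of
alternative reactions; its status is the Kleene value of the AND-of-ORs
formula, mapped `TRUE→asserted`, `UNKNOWN→unknown`, `FALSE→not_asserted`.
Step order is kept for display; evaluation is a pure conjunction, so it is
order-independent. Because the formula is monotone (no negation) and each
term state enters independently, the Kleene value coincides with the
completion semantics: *asserted* iff every TRUE/FALSE completion of the
candidate-covered terms satisfies the formula, *not asserted* iff none
does. This is the reading we adopt for "unknown": every term still needed
on some satisfying path must at least have candidate coverage. A
permissive variant (any single candidate suffices) is deliberately not
offered, to avoid two subtly different statuses in one system. Manual
overrides (`asserted`, `absent`) replace the computed status and are
flagged `source=manual`; `absent` exists only as a manual verdict and
enters phenotype rules as `FALSE`.

**Phenotype rules.** Rules are boolean expressions over pathway
identifiers (grammar: `NOT` > `AND` > `OR`, left-associative, parentheses
allowed; keywords case-insensitive, identifiers case-sensitive). They are
evaluated bottom-up with the strong-Kleene truth tables, yielding a
three-way verdict: *predicted*, *not predicted*, or *unknown*. We expose
the unknown verdict rather than suppressing it — hiding it would discard
the information the three-valued core exists to carry. Unmapped pathway
identifiers raise an error in strict mode (default) or evaluate to
`UNKNOWN` in lenient mode, with the identifier reported in the evidence.

## Assignment thresholds

Term propagation and candidate detection implement the standard operating
procedure with **strict** inequalities throughout — boundary equality never
satisfies a threshold:

| parameter | default | meaning |
|---|---|---|
| `min_homologs` | 5 | qualifying homologs required before propagation |
| `min_identity_pct` | 50 | percent identity, exclusive |
| `min_coverage_frac` | 0.70 | alignment fraction of *both* proteins, exclusive |
| `min_supporting` | 2 | term carriers among the top `min_homologs` |
| `top_k_bbh` | 5 | BBH partners considered for candidacy |
| `min_best_identity_pct` | 25 | best term-bearing BBH partner identity, exclusive |

Support is counted among the top-ranked qualifying homologs only (ranking:
identity desc, score desc, gene id asc — the ascending id tie-break makes
runs deterministic). If several terms reach the support threshold for one
gene, all are assigned and a warning is logged; the data model allows
multi-term genes, so guessing a single winner would silently discard
evidence. Propagation is single-round by default; `iterate=True` repeats
to a fixpoint with a cap of 10 rounds. "Best hit" for BBH is highest
score, then higher identity, then lexicographically smaller subject id.
Candidates never override confirmed assignments, and the store rejects a
candidate row coexisting with a confirmed row for the same (gene, term).

## Consistency reports

A gene's family combination is the triple of its *sets* of COG, Pfam and
TIGRfam ids (any may be empty). Using per-gene sets rather than individual
ids is what lets one KO with a single COG and two Pfams produce four
distinct combinations. Combination detail counts are query-anchored:
combinations are enumerated from genes carrying the query KO, and per
combination the four classes (query KO; any other KO including multi-KO
genes with the query; other KO and not the query; no KO) are counted over
all genes sharing it. The first, third and fourth classes partition the
sharing genes — an invariant the tests recheck against a naive recount.

**Paralog clustering.** Within each genome, genes are clustered with the
Markov Cluster Algorithm on the similarity graph (edge weight = hit score,
max over the two directed records). MCL iterates expansion (matrix square)
and inflation (entry-wise power, column renormalization) on the
column-stochastic matrix, with self-loops set to each node's maximum
incident weight; defaults inflation 2.0, max 100 iterations, tolerance
1e-6 — standard MCL practice. Clusters are connected components of the
limit matrix's support; only clusters of ≥ 2 genes define paralogs. Edge
filters for the paralog graph default to > 30% identity and > 0.5 coverage
and are exposed as flags, since no canonical values exist for this step.
Average paralog identity uses the hit table's percent identity per
same-cluster same-KO pair; pairs without a hit record are skipped with a
warning rather than imputed.

## Synthetic data

The fixture generator emulates the *structure* of a curated microbial
annotation database: 8 genomes × 25 genes by default, one quarter draft,
with planted pathway plans (`complete`, `candidate_only`, `missing`), a
propagation neighborhood (five homologs at 55–95% identity, three
carrying the term), two 2-gene paralog groups per genome (60–90%
identity), a 10% KO-inconsistency rate among filler genes, and decoy
cross-genome hits at 15–22% identity / 0.6 coverage that must never
produce evidence. Candidate neighborhoods draw partner identities from
30–45% — above the candidate floor, below the propagation threshold. The
shipped definition file contains the three-step
6-phosphogluconate-via-gluconate pathway with its four step-1 alternatives
verbatim, the amino-acid pathway set behind the
histidine/phenylalanine/lysine rules, the four-branch
cellulose-via-cellobiose rule, and an aerobe rule tied to plastoquinol
oxidation. Intended statuses and verdicts are written to `truth.tsv`.

What the generator does **not** emulate: real sequence divergence
(identities are sampled, not aligned), alignment-length asymmetries
(coverage is symmetric per hit), e-value structure, contamination or
frameshift artifacts, and genuinely ambiguous orthology. Passing the
end-to-end recovery tests therefore demonstrates that the inference
machinery is correct with respect to its definitions, not that the
thresholds are well-calibrated for any particular real dataset — the
thresholds are taken as given, not fitted.

## Numerical and design notes

- All TSV readers require headers; duplicate rows collapse on load;
  duplicate ordered hit pairs keep the highest score; self-hits are
  dropped. Coverage columns may be supplied as percentages via
  `*_coverage_pct` headers.
- Every ranking has a documented total order (ids as final tie-break), so
  permuting input rows never changes output, and same-seed fixture runs
  are byte-identical.
- Profile gene counts are of distinct genes, not (gene, term) pairs.
- Problem sizes in the test suite are deliberately small (stores ≤ 200
  genes, graphs ≤ 14 nodes, 1000 random expressions against the
  completion oracle); every check is exact, so scale adds nothing beyond
  runtime.
- Known limitations: no e-value modelling (hit tables are taken as
  given), no synteny or phylogenetic refinement of orthology, no
  stoichiometric/flux modelling — the rule-based approach trades those for
  applicability to partial genomes.
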