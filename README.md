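# phenoassert

Annotation-consistency auditing and rule-based phenotype inference for
microbial genomes.

Comparative microbial genomics depends on annotations being *consistent*
(genes with the same activity carry the same functional role) and *complete*
(the organism's functional catalog is covered). `phenoassert` is a workbench
for both problems, aimed at curators and bioinformaticians who maintain
genome annotation sets. It provides:

- **Three-valued logic core** — pathway presence is *asserted*, *not
  asserted*, or *unknown*; rules over pathways are evaluated under strong
  Kleene semantics (`AND`, `OR`, `NOT` with an `UNKNOWN` value), so a
  phenotype is only called when the annotation evidence forces it.
- **Strict term propagation** — a gene inherits a functional term when it
  has ≥ 5 homologs at > 50% identity with the alignment covering > 70% of
  both proteins, and ≥ 2 of the top 5 homologs already carry the term.
- **Candidate-gene detection** — a weaker evidence tier via bidirectional
  best hits (BBH): a gene is a *candidate* for a term when ≥ 2 of its top-5
  BBH partners carry it, overlap exceeds 70%, and at least one term-bearing
  partner exceeds 25% identity. Candidate-only coverage yields pathway
  status *unknown* instead of *not asserted*.
- **Pathway assertion** — pathways are ordered steps of alternative
  reactions; each reaction is an OR of AND-sets of terms (protein-complex
  subunits require all members). A genome's status is the Kleene value of
  this AND-of-ORs formula, with manual *asserted*/*absent* overrides.
- **Phenotype prediction and metadata checks** — boolean rules over pathway
  identifiers predict traits (prototrophy/auxotrophy, aerobicity, carbon
  utilization); positive predictions are compared against GOLD-style genome
  metadata (agree / conflict / no-metadata).
- **Consistency reports** — KO-term distribution across (COG, Pfam,
  TIGRfam) combinations, and across genomes and within-genome paralog
  clusters computed with the Markov Cluster Algorithm (MCL).
- **Synthetic fixture generator** — deterministic input sets with planted
  ground truth for every pathway status and phenotype verdict.

## Worked example

Generate a synthetic annotation set and run the full pipeline:

```bash
phenoassert generate-fixture --seed 1 --out fixture/
phenoassert run-pipeline --store fixture --hits fixture/hits.tsv \
    --definitions fixture/pathways.dsl --rules fixture/rules.tsv --out results/
```

which prints

```
fixture written to fixture/
168 assertions, 56 predictions -> results/
```

168 assertions are the 8 genomes × 21 pathways, each *asserted*, *unknown*,
*not asserted*, or manually *absent*; 56 predictions are 8 genomes × 7
phenotype rules. `results/assertions.tsv` lists, per genome and pathway,
the status with the missing and candidate-only terms behind it;
`results/predictions.tsv` gives each rule's verdict with the per-pathway
evidence. For instance the 6-phosphogluconate-via-gluconate pathway `P_339`
(steps `[R_977|R_978|R_979|R_980] -> [R_981] -> [R_982]`) comes out
`asserted` for `G_001` (all three steps have confirmed genes), `unknown`
for `G_003` (the gluconate kinase term is covered only by a BBH candidate),
and `not_asserted` for `G_005`.

Checking predictions against metadata:

```bash
phenoassert check-metadata --predictions results/predictions.tsv \
    --rules fixture/rules.tsv --metadata fixture/metadata.tsv --out report.tsv
```

flags the Aerobe prediction for `G_006` as `agree` (metadata
`Oxygen Requirement=aerobic`), `G_007` as `conflict` (`anaerobic`), and
`G_008` as `no_metadata` — conflicts like `G_007` are exactly the cases a
curator should inspect.

Library use mirrors the CLI:

```python
from phenoassert import (AnnotationStore, HitTable, PathwayEngine,
                         parse_definitions, propagate_terms)

store = AnnotationStore.load("fixture")
hits = HitTable.load("fixture/hits.tsv")
store.add_term_assignments(propagate_terms(store, hits))
engine = PathwayEngine(store, parse_definitions("fixture/pathways.dsl"))
print(engine.assert_pathway("G_001", "P_339").status)   # asserted
```

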