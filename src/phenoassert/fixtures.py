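"""Deterministic synthetic-fixture generator.

The generator emulates the input side of a microbial annotation database:
genomes with protein-coding genes, family assignments (COG/Pfam/TIGRfam/KO),
manually curated functional-term assignments, a pairwise similarity hit
table, pathway/reaction/term definitions, phenotype rules, and GOLD-style
genome metadata.  No sequences are materialized — similarity values are
sampled directly, since no analysis consumes residues.

Each genome receives a *plan* per planted pathway:

* ``complete`` — manual genes for every required term: status *asserted*;
* ``candidate_only`` — one required term covered only through a
  bidirectional-best-hit candidate neighborhood (partner identities drawn
  between 30 and 45%, below the strict propagation threshold): *unknown*;
* ``missing`` — no genes and no candidate evidence: *not asserted*.

A separate propagation group plants an unassigned gene with five homologs
above the strict thresholds (identities 55-95%) so term propagation fires.
The intended status of every (genome, pathway) pair and the resulting
phenotype verdicts are written to ``truth.tsv`` for end-to-end checks.

Same config and seed produce byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .logic import STATUS_TO_TRISTATE, evaluate_rule, parse_rule
from .store import (
    FAMILY_COLS,
    GENE_COLS,
    GENOME_COLS,
    HIT_COLS,
    METADATA_COLS,
    TERM_COLS,
)

# ---------------------------------------------------------------------------
# Shipped definitions: the 6-phosphogluconate-via-gluconate pathway (P_339),
# amino-acid biosynthesis pathways referenced by the phenotype rules, the
# cellulose-utilization pathway set, plastoquinol oxidation (P_0770), and a
# propagation-demonstration pathway.

DEFINITIONS_DSL = '''\
# --- functional terms -------------------------------------------------------
term T_0977 "glucose 1-dehydrogenase (NADP+)" kind=protein_product
term T_0978 "glucose 1-dehydrogenase (NAD+)" kind=protein_product
term T_0979 "glucose oxidase" kind=protein_product
term T_0980 "quinoprotein glucose dehydrogenase" kind=protein_product
term T_0981 "gluconolactonase" kind=protein_product
term T_0982 "gluconate kinase" kind=protein_product
term T_0162 "histidine biosynthesis pathway protein" kind=protein_product
term T_0146 "chorismate synthesis I enzyme" kind=protein_product
term T_0519 "chorismate synthesis II enzyme" kind=protein_product
term T_0272 "phenylalanine from chorismate I enzyme" kind=protein_product
term T_0147 "phenylalanine from chorismate II enzyme" kind=protein_product
term T_0169 "lysine biosynthesis via diaminopimelate (succinylase)" kind=protein_product
term T_0170 "lysine biosynthesis via diaminopimelate (acetylase)" kind=protein_product
term T_0171 "lysine biosynthesis via diaminopimelate (aminotransferase)" kind=protein_product
term T_0199 "lysine biosynthesis via diaminopimelate (dehydrogenase)" kind=protein_product
term T_0333 "lysine biosynthesis via alpha-aminoadipate (LysW)" kind=protein_product
term T_0465 "lysine biosynthesis via alpha-aminoadipate (saccharopine)" kind=protein_product
term T_CELA "endoglucanase" kind=protein_product
term T_CELB "cellobiohydrolase" kind=protein_product
term T_ABC1 "cellobiose ABC transporter, permease subunit" kind=protein_product
term T_ABC2 "cellobiose ABC transporter, ATPase subunit" kind=protein_product
term T_BGLU "beta-glucosidase" kind=protein_product
term T_CBP "cellobiose phosphorylase" kind=protein_product
term T_BGK "beta-glucoside kinase" kind=protein_product
term T_PBGL "6-phospho-beta-glucosidase" kind=protein_product
term T_PTSA "cellobiose PTS transporter, EIIC component" kind=protein_product
term T_PTSB "cellobiose PTS transporter, EIIB component" kind=protein_product
term T_0770 "plastoquinol terminal oxidase" kind=protein_product
term T_PROP "propagation demonstration enzyme" kind=protein_product

# --- reactions --------------------------------------------------------------
reaction R_977 "D-glucose + NADP+ <=> D-glucono-1,5-lactone + NADPH + H+" requires (T_0977)
reaction R_978 "D-glucose + NAD+ <=> D-glucono-1,5-lactone + NADH + H+" requires (T_0978)
reaction R_979 "D-glucose + O2 <=> D-glucono-1,5-lactone + H2O2" requires (T_0979)
reaction R_980 "D-glucose + ubiquinone <=> D-glucono-1,5-lactone + ubiquinol" requires (T_0980)
reaction R_981 "D-glucono-1,5-lactone + H2O <=> D-gluconic acid" requires (T_0981)
reaction R_982 "ATP + D-gluconic acid <=> ADP + 6-phospho-D-gluconate" requires (T_0982)
reaction R_162 "histidine biosynthesis from PRPP" requires (T_0162)
reaction R_146 "chorismate synthesis I" requires (T_0146)
reaction R_519 "chorismate synthesis II" requires (T_0519)
reaction R_272 "phenylalanine synthesis from chorismate I" requires (T_0272)
reaction R_147 "phenylalanine synthesis from chorismate II" requires (T_0147)
reaction R_169 "lysine biosynthesis DAP succinylase route" requires (T_0169)
reaction R_170 "lysine biosynthesis DAP acetylase route" requires (T_0170)
reaction R_171 "lysine biosynthesis DAP aminotransferase route" requires (T_0171)
reaction R_199 "lysine biosynthesis DAP dehydrogenase route" requires (T_0199)
reaction R_333 "lysine biosynthesis AAA LysW route" requires (T_0333)
reaction R_465 "lysine biosynthesis AAA saccharopine route" requires (T_0465)
reaction R_CDC "cellulose degradation to cellobiose" requires (T_CELA) | (T_CELB)
reaction R_ABC "ATP-dependent cellobiose uptake" requires (T_ABC1 & T_ABC2)
reaction R_CBH "cellobiose + H2O => 2 D-glucose" requires (T_BGLU)
reaction R_CG1P "cellobiose + Pi => D-glucose + alpha-D-glucose 1-phosphate" requires (T_CBP)
reaction R_BGK "cellobiose + ATP => cellobiose 6-phosphate + ADP" requires (T_BGK)
reaction R_C6P "cellobiose 6-phosphate + H2O => D-glucose + D-glucose 6-phosphate" requires (T_PBGL)
reaction R_PTS "cellobiose uptake via phosphotransferase system" requires (T_PTSA & T_PTSB)
reaction R_770 "plastoquinol oxidation with oxygen" requires (T_0770)
reaction R_PROP "propagation demonstration reaction" requires (T_PROP)

# --- pathways ---------------------------------------------------------------
pathway P_339 "6-phosphogluconate synthesis via gluconate" steps: [R_977|R_978|R_979|R_980] -> [R_981] -> [R_982]
pathway P_162 "histidine biosynthesis" steps: [R_162]
pathway P_146 "chorismate synthesis I" steps: [R_146]
pathway P_519 "chorismate synthesis II" steps: [R_519]
pathway P_272 "phenylalanine from chorismate I" steps: [R_272]
pathway P_147 "phenylalanine from chorismate II" steps: [R_147]
pathway P_169 "lysine biosynthesis via DAP, succinylase" steps: [R_169]
pathway P_170 "lysine biosynthesis via DAP, acetylase" steps: [R_170]
pathway P_0171 "lysine biosynthesis via DAP, aminotransferase" steps: [R_171]
pathway P_199 "lysine biosynthesis via DAP, dehydrogenase" steps: [R_199]
pathway P_333 "lysine biosynthesis via AAA, LysW" steps: [R_333]
pathway P_465 "lysine biosynthesis via AAA, saccharopine" steps: [R_465]
pathway P_CDC "cellulose degradation to cellobiose" steps: [R_CDC]
pathway P_ABC "ATP-dependent cellobiose uptake" steps: [R_ABC]
pathway P_CBH "cellobiose hydrolysis" steps: [R_CBH]
pathway P_CG1P "cellobiose conversion to glucose and glucose 1-phosphate" steps: [R_CG1P]
pathway P_BGK "cellobiose phosphorylation via beta-glucoside kinase" steps: [R_BGK]
pathway P_C6P "cellobiose 6-phosphate conversion to glucose and glucose 6-phosphate" steps: [R_C6P]
pathway P_PTS "cellobiose uptake via phosphotransferase system" steps: [R_PTS]
pathway P_0770 "plastoquinol oxidation with oxygen" steps: [R_770]
pathway P_PROP "propagation demonstration pathway" steps: [R_PROP]

# --- manual overrides -------------------------------------------------------
override genome=G_008 pathway=P_339 status=absent
'''

#: Growth on cellulose via cellobiose: four alternative pathway combinations
#: (hydrolysis, phosphorolysis, or kinase routes behind an ABC transporter,
#: or the phosphotransferase-system route).
CELLULOSE_RULE = (
    "(P_CDC AND P_ABC AND P_CBH)"
    " OR (P_CDC AND P_ABC AND P_CG1P)"
    " OR (P_CDC AND P_ABC AND P_BGK AND P_C6P)"
    " OR (P_CDC AND P_PTS AND P_C6P)"
)

RULES_ROWS: list[tuple[str, str, str, str, str]] = [
    ("R_HIS_P", "L-histidine prototroph", "Amino Acid Synthesis", "histidine prototroph", "P_162"),
    ("R_HIS_A", "L-histidine auxotroph", "Amino Acid Synthesis", "histidine auxotroph", "NOT P_162"),
    (
        "R_PHE_P",
        "L-phenylalanine prototroph",
        "Amino Acid Synthesis",
        "phenylalanine prototroph",
        "(P_146 OR P_519) AND (P_272 OR P_147)",
    ),
    (
        "R_LYS_P",
        "L-lysine prototroph",
        "Amino Acid Synthesis",
        "lysine prototroph",
        "(P_169 OR P_170 OR P_0171 OR P_199 OR P_333 OR P_465)",
    ),
    (
        "R_LYS_A",
        "L-lysine auxotroph",
        "Amino Acid Synthesis",
        "lysine auxotroph",
        "(NOT P_169) AND (NOT P_170) AND (NOT P_0171) AND (NOT P_199)"
        " AND (NOT P_333) AND (NOT P_465)",
    ),
    ("R_CELL", "Growth on cellulose via cellobiose", "Metabolism", "cellulose degrader", CELLULOSE_RULE),
    ("R_AER", "Aerobe", "Oxygen Requirement", "aerobic", "P_0770"),
]

#: Default per-pathway plans; genomes are G_001..G_008.  The four
#: cellulose-rule branches are exercised by G_001..G_004.
DEFAULT_PLANS: dict[str, dict[str, str]] = {
    "P_339": {"G_001": "complete", "G_006": "complete", "G_003": "candidate_only", "G_005": "missing"},
    "P_162": {"G_001": "complete", "G_004": "complete", "G_005": "candidate_only", "G_002": "missing"},
    "P_146": {"G_001": "complete", "G_006": "complete"},
    "P_272": {"G_001": "complete", "G_004": "complete", "G_006": "candidate_only"},
    "P_147": {"G_001": "missing"},
    "P_169": {"G_004": "complete"},
    "P_CDC": {"G_001": "complete", "G_002": "complete", "G_003": "complete", "G_004": "complete"},
    "P_ABC": {"G_001": "complete", "G_002": "complete", "G_003": "complete"},
    "P_CBH": {"G_001": "complete"},
    "P_CG1P": {"G_002": "complete"},
    "P_BGK": {"G_003": "complete"},
    "P_C6P": {"G_003": "complete", "G_004": "complete"},
    "P_PTS": {"G_004": "complete"},
    "P_0770": {"G_006": "complete", "G_007": "complete", "G_008": "complete"},
}

DEFAULT_METADATA: list[tuple[str, str, str]] = [
    ("G_001", "Oxygen Requirement", "aerobic"),
    ("G_001", "Temperature Range", "mesophile"),
    ("G_001", "Habitat", "soil"),
    ("G_002", "Oxygen Requirement", "anaerobic"),
    ("G_002", "Temperature Range", "mesophile"),
    ("G_003", "Oxygen Requirement", "facultative"),
    ("G_003", "Temperature Range", "thermophile"),
    ("G_004", "Oxygen Requirement", "aerobic"),
    ("G_004", "Temperature Range", "mesophile"),
    ("G_004", "Habitat", "marine"),
    ("G_005", "Temperature Range", "psychrophile"),
    ("G_006", "Oxygen Requirement", "aerobic"),
    ("G_006", "Temperature Range", "mesophile"),
    ("G_007", "Oxygen Requirement", "anaerobic"),
    ("G_008", "Temperature Range", "mesophile"),
]

_COG_POOL = [f"COG{i:04d}" for i in range(1, 11)]
_PFAM_POOL = [f"pfam{i:05d}" for i in range(1, 16)]
_TIGR_POOL = [f"TIGR{i:05d}" for i in range(1, 9)]
_KO_POOL = [f"K{i:05d}" for i in range(1, 13)]


@dataclass
class FixtureConfig:
    """Configuration for the synthetic fixture.

    Defaults define the standard study conditions: 8 genomes of 25 genes
    (one quarter draft), the default pathway plans above, two planted
    paralog groups per genome, and a 10% KO-inconsistency rate.
    """

    n_genomes: int = 8
    genes_per_genome: int = 25
    fraction_draft: float = 0.25
    planted_pathways: dict[str, dict[str, str]] = field(
        default_factory=lambda: {p: dict(g) for p, g in DEFAULT_PLANS.items()}
    )
    planted_propagation: dict[str, str] = field(
        default_factory=lambda: {"G_004": "P_PROP"}
    )
    planted_paralog_groups: int = 2
    ko_inconsistency_rate: float = 0.10
    seed: int = 0

    def genome_ids(self) -> list[str]:
        return [f"G_{i:03d}" for i in range(1, self.n_genomes + 1)]

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        if not 0 <= self.fraction_draft <= 1:
            raise ValueError("fraction_draft must be in [0, 1]")
        if not 0 <= self.ko_inconsistency_rate <= 1:
            raise ValueError("ko_inconsistency_rate must be in [0, 1]")
        genomes = set(self.genome_ids())
        for pwy, plans in self.planted_pathways.items():
            for g, plan in plans.items():
                if g not in genomes:
                    raise ValueError(f"plan for {pwy} references unknown genome {g}")
                if plan not in ("complete", "candidate_only", "missing"):
                    raise ValueError(f"unknown plan {plan!r} for {g}/{pwy}")
        for g in self.planted_propagation:
            if g not in genomes:
                raise ValueError(f"propagation plan references unknown genome {g}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_genomes": self.n_genomes,
            "genes_per_genome": self.genes_per_genome,
            "fraction_draft": self.fraction_draft,
            "planted_pathways": self.planted_pathways,
            "planted_propagation": self.planted_propagation,
            "planted_paralog_groups": self.planted_paralog_groups,
            "ko_inconsistency_rate": self.ko_inconsistency_rate,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


class _Builder:
    def __init__(self, config: FixtureConfig):
        from .pathways import parse_definitions

        config.validate()
        self.config = config
        self.rng = random.Random(config.seed)
        self.defs = parse_definitions(DEFINITIONS_DSL)
        self.genomes = config.genome_ids()
        self.gene_rows: list[list] = []
        self.family_rows: list[list] = []
        self.term_rows: list[list] = []
        self.hit_rows: list[list] = []
        self._counter: dict[str, int] = {g: 0 for g in self.genomes}
        # (genome, term) -> gene carrying it manually
        self.term_gene: dict[tuple[str, str], str] = {}

    def new_gene(self, genome: str, product: str, length: int | None = None) -> str:
        self._counter[genome] += 1
        gene_id = f"{genome}_g{self._counter[genome]:04d}"
        length = length if length is not None else self.rng.randint(120, 600)
        self.gene_rows.append([gene_id, genome, product, length])
        return gene_id

    def add_hit(self, q: str, s: str, ident: float, cov: float, score: float) -> None:
        self.hit_rows.append([q, s, round(ident, 1), round(cov, 2), round(cov, 2), round(score, 1)])

    def add_mutual_hit(self, a: str, b: str, ident: float, cov: float, score: float) -> None:
        self.add_hit(a, b, ident, cov, score)
        self.add_hit(b, a, ident, cov, score)

    # -- pathway planting --------------------------------------------------

    def required_terms(self, pathway_id: str) -> list[str]:
        """Terms of the deterministic 'chosen implementation': first
        alternative reaction of each step, first requirement alternative."""
        pwy = self.defs.pathways[pathway_id]
        terms: list[str] = []
        for step in pwy.steps:
            rid = sorted(step)[0]
            alt = self.defs.reactions[rid].requirements[0]
            terms.extend(sorted(alt))
        return terms

    def plant_complete(self, genome: str, pathway_id: str) -> None:
        for term in self.required_terms(pathway_id):
            key = (genome, term)
            if key in self.term_gene:
                continue
            name = self.defs.terms[term].name
            gene = self.new_gene(genome, name)
            self.term_rows.append([gene, term, "manual"])
            self.term_gene[key] = gene

    def plant_candidate(self, genome: str, pathway_id: str) -> None:
        """All chosen terms manual except the last, which is covered only by
        a BBH candidate neighborhood below the propagation thresholds."""
        terms = self.required_terms(pathway_id)
        cand_term = terms[-1]
        for term in terms[:-1]:
            key = (genome, term)
            if key in self.term_gene:
                continue
            gene = self.new_gene(genome, self.defs.terms[term].name)
            self.term_rows.append([gene, term, "manual"])
            self.term_gene[key] = gene
        donors = [
            self.term_gene[(g, cand_term)]
            for g in self.genomes
            if g != genome and (g, cand_term) in self.term_gene
        ]
        if len(donors) < 2:
            raise ValueError(
                f"candidate plan for {genome}/{pathway_id} needs term {cand_term} "
                "manually planted in at least two other genomes"
            )
        gene = self.new_gene(genome, "hypothetical protein")
        for donor in donors[:2]:
            ident = self.rng.uniform(30.0, 45.0)
            self.add_mutual_hit(gene, donor, ident, 0.8, ident * 10)

    def plant_propagation(self, genome: str, pathway_id: str) -> None:
        """Unassigned gene with five strict-threshold homologs, three of them
        carrying the pathway's term, in five distinct other genomes."""
        term = self.required_terms(pathway_id)[0]
        others = [g for g in self.genomes if g != genome][:5]
        if len(others) < 5:
            raise ValueError("propagation planting needs at least six genomes")
        gene = self.new_gene(genome, "hypothetical protein")
        idents = sorted((self.rng.uniform(55.0, 95.0) for _ in range(5)), reverse=True)
        for i, (other, ident) in enumerate(zip(others, idents, strict=True)):
            donor = self.new_gene(other, self.defs.terms[term].name)
            if i < 3:  # three carriers: support above the two-homolog minimum
                self.term_rows.append([donor, term, "manual"])
                self.term_gene.setdefault((other, term), donor)
            self.add_mutual_hit(gene, donor, ident, 0.8, ident * 10)

    # -- background annotation ---------------------------------------------

    def plant_paralog_groups(self) -> None:
        for genome in self.genomes:
            for k in range(self.config.planted_paralog_groups):
                ko = _KO_POOL[(self.genomes.index(genome) + k) % len(_KO_POOL)]
                cog = _COG_POOL[k % len(_COG_POOL)]
                pfam = _PFAM_POOL[k % len(_PFAM_POOL)]
                members = [
                    self.new_gene(genome, "paralogous family protein") for _ in range(2)
                ]
                for g in members:
                    self.family_rows.append([g, "KO", ko])
                    self.family_rows.append([g, "COG", cog])
                    self.family_rows.append([g, "Pfam", pfam])
                a, b = members
                ident = self.rng.uniform(60.0, 90.0)
                self.add_mutual_hit(a, b, ident, 0.8, ident * 12)

    def pad_fillers(self) -> None:
        for genome in self.genomes:
            while self._counter[genome] < self.config.genes_per_genome:
                gene = self.new_gene(genome, "hypothetical protein")
                ci = self.rng.randrange(len(_COG_POOL))
                self.family_rows.append([gene, "COG", _COG_POOL[ci]])
                self.family_rows.append(
                    [gene, "Pfam", _PFAM_POOL[ci % len(_PFAM_POOL)]]
                )
                if self.rng.random() < 0.3:
                    self.family_rows.append(
                        [gene, "TIGRfam", _TIGR_POOL[ci % len(_TIGR_POOL)]]
                    )
                if self.rng.random() < 0.6:
                    ko = _KO_POOL[ci % len(_KO_POOL)]
                    if self.rng.random() < self.config.ko_inconsistency_rate:
                        ko = _KO_POOL[(ci + 3) % len(_KO_POOL)]
                    self.family_rows.append([gene, "KO", ko])

    def add_decoy_hits(self) -> None:
        """Low-identity cross-genome hits that must never produce evidence."""
        for i, genome in enumerate(self.genomes):
            other = self.genomes[(i + 1) % len(self.genomes)]
            mine = [r[0] for r in self.gene_rows if r[1] == genome]
            theirs = [r[0] for r in self.gene_rows if r[1] == other]
            if mine and theirs:
                ident = self.rng.uniform(15.0, 22.0)
                self.add_mutual_hit(mine[-1], theirs[-1], ident, 0.6, ident * 5)

    # -- ground truth -------------------------------------------------------

    def truth(self) -> pd.DataFrame:
        cfg = self.config
        rows = []
        statuses: dict[str, dict[str, str]] = {g: {} for g in self.genomes}
        for pathway_id in sorted(self.defs.pathways):
            for genome in self.genomes:
                ov = self.defs.override_for(genome, pathway_id)
                if ov is not None:
                    status = ov.status
                elif cfg.planted_propagation.get(genome) == pathway_id:
                    status = "asserted"
                elif pathway_id in {
                    p for g2, p in cfg.planted_propagation.items() if g2 != genome
                } and (genome, self.required_terms(pathway_id)[0]) in self.term_gene:
                    status = "asserted"  # propagation donor carries the term
                else:
                    plan = cfg.planted_pathways.get(pathway_id, {}).get(genome)
                    status = {
                        "complete": "asserted",
                        "candidate_only": "unknown",
                        "missing": "not_asserted",
                        None: "not_asserted",
                    }[plan]
                statuses[genome][pathway_id] = status
                rows.append(["pathway", genome, pathway_id, status])
        verdict_of = {"true": "predicted", "false": "not_predicted", "unknown": "unknown"}
        for rule_id, _, _, _, expression in RULES_ROWS:
            expr = parse_rule(expression)
            for genome in self.genomes:
                env = {p: STATUS_TO_TRISTATE[s] for p, s in statuses[genome].items()}
                value = evaluate_rule(expr, env)
                rows.append(["phenotype", genome, rule_id, verdict_of[value.value]])
        return pd.DataFrame(rows, columns=["kind", "genome_id", "target_id", "expected"])

    # -- assembly -----------------------------------------------------------

    def build(self) -> dict[str, pd.DataFrame]:
        cfg = self.config
        n_draft = round(cfg.n_genomes * cfg.fraction_draft)
        genome_rows = [
            [
                g,
                f"Synthetic organism {g}",
                "draft" if i >= cfg.n_genomes - n_draft else "finished",
            ]
            for i, g in enumerate(self.genomes)
        ]
        for pathway_id in sorted(cfg.planted_pathways):
            for genome in self.genomes:
                if cfg.planted_pathways[pathway_id].get(genome) == "complete":
                    self.plant_complete(genome, pathway_id)
        for genome in sorted(cfg.planted_propagation):
            self.plant_propagation(genome, cfg.planted_propagation[genome])
        for pathway_id in sorted(cfg.planted_pathways):
            for genome in self.genomes:
                if cfg.planted_pathways[pathway_id].get(genome) == "candidate_only":
                    self.plant_candidate(genome, pathway_id)
        self.plant_paralog_groups()
        self.pad_fillers()
        self.add_decoy_hits()
        return {
            "genomes": pd.DataFrame(genome_rows, columns=GENOME_COLS),
            "genes": pd.DataFrame(self.gene_rows, columns=GENE_COLS),
            "family_assignments": pd.DataFrame(self.family_rows, columns=FAMILY_COLS),
            "term_assignments": pd.DataFrame(self.term_rows, columns=TERM_COLS),
            "metadata": pd.DataFrame(
                [m for m in DEFAULT_METADATA if m[0] in set(self.genomes)],
                columns=METADATA_COLS,
            ),
            "hits": pd.DataFrame(self.hit_rows, columns=HIT_COLS),
            "truth": self.truth(),
        }


def generate_fixture(config: FixtureConfig, out_dir: str | Path) -> Path:
    """Write the full fixture file set to *out_dir* and return the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = _Builder(config).build()
    frames["genomes"].to_csv(out / "genomes.tsv", sep="\t", index=False)
    frames["genes"].to_csv(out / "genes.tsv", sep="\t", index=False)
    frames["family_assignments"].to_csv(out / "family_assignments.tsv", sep="\t", index=False)
    frames["term_assignments"].to_csv(out / "term_assignments.tsv", sep="\t", index=False)
    frames["metadata"].to_csv(out / "metadata.tsv", sep="\t", index=False)
    frames["hits"].to_csv(out / "hits.tsv", sep="\t", index=False)
    frames["truth"].to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "pathways.dsl").write_text(DEFINITIONS_DSL, encoding="utf-8")
    rules = pd.DataFrame(
        RULES_ROWS,
        columns=["rule_id", "phenotype_name", "category", "category_value", "expression"],
    )
    rules.to_csv(out / "rules.tsv", sep="\t", index=False)
    config.to_yaml(out / "fixture.yaml")
    return out
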