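"""Data model and TSV readers/writers for genomes, genes, assignments and hits.

Every downstream analysis consumes an :class:`AnnotationStore` (genomes,
genes, protein-family assignments, functional-term assignments, genome
metadata) plus a :class:`HitTable` of pairwise protein similarities.  All
files are plain TSV with a header row; identifiers are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

FAMILY_NAMESPACES = ("COG", "Pfam", "TIGRfam", "KO", "FIGfam")
TERM_PROVENANCES = ("manual", "propagated", "candidate")
COMPLETENESS_VALUES = ("finished", "draft")

GENOME_COLS = ["genome_id", "name", "completeness"]
GENE_COLS = ["gene_id", "genome_id", "product_name", "length_aa"]
FAMILY_COLS = ["gene_id", "namespace", "family_id"]
TERM_COLS = ["gene_id", "term_id", "provenance"]
HIT_COLS = [
    "query_gene_id",
    "subject_gene_id",
    "percent_identity",
    "query_coverage",
    "subject_coverage",
    "score",
]
METADATA_COLS = ["genome_id", "attribute", "value"]

STORE_FILES = {
    "genomes": "genomes.tsv",
    "genes": "genes.tsv",
    "family_assignments": "family_assignments.tsv",
    "term_assignments": "term_assignments.tsv",
    "metadata": "metadata.tsv",
}


class SchemaError(ValueError):
    """A TSV file does not conform to its declared schema."""


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df[list(df.columns)]


@dataclass
class AnnotationStore:
    """In-memory annotation database with referential integrity enforced."""

    genomes: pd.DataFrame
    genes: pd.DataFrame
    family_assignments: pd.DataFrame
    term_assignments: pd.DataFrame
    metadata: pd.DataFrame
    _gene_genome: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()
        self._gene_genome = dict(
            zip(self.genes["gene_id"], self.genes["genome_id"], strict=True)
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls) -> "AnnotationStore":
        return cls(
            genomes=pd.DataFrame(columns=GENOME_COLS),
            genes=pd.DataFrame(columns=GENE_COLS),
            family_assignments=pd.DataFrame(columns=FAMILY_COLS),
            term_assignments=pd.DataFrame(columns=TERM_COLS),
            metadata=pd.DataFrame(columns=METADATA_COLS),
        )

    def validate(self) -> None:
        g = self.genomes
        if g["genome_id"].duplicated().any():
            dup = g.loc[g["genome_id"].duplicated(), "genome_id"].iloc[0]
            raise SchemaError(f"duplicate genome_id {dup!r}")
        bad = ~g["completeness"].isin(COMPLETENESS_VALUES)
        if bad.any():
            raise SchemaError(
                f"invalid completeness value {g.loc[bad, 'completeness'].iloc[0]!r}"
            )
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise SchemaError(f"duplicate gene_id {dup!r}")
        known_genomes = set(g["genome_id"])
        dangling = ~self.genes["genome_id"].isin(known_genomes)
        if dangling.any():
            row = self.genes.loc[dangling].iloc[0]
            raise SchemaError(
                f"gene {row['gene_id']!r} references undeclared genome {row['genome_id']!r}"
            )
        lengths = pd.to_numeric(self.genes["length_aa"], errors="coerce")
        if len(lengths) and (lengths.isna() | (lengths <= 0)).any():
            bad_gene = self.genes.loc[lengths.isna() | (lengths <= 0), "gene_id"].iloc[0]
            raise SchemaError(f"gene {bad_gene!r}: length_aa must be a positive integer")
        known_genes = set(self.genes["gene_id"])
        for name, df, col in (
            ("family_assignments", self.family_assignments, "gene_id"),
            ("term_assignments", self.term_assignments, "gene_id"),
        ):
            dangling = ~df[col].isin(known_genes)
            if dangling.any():
                raise SchemaError(
                    f"{name}: unknown gene_id {df.loc[dangling, col].iloc[0]!r}"
                )
        bad_ns = ~self.family_assignments["namespace"].isin(FAMILY_NAMESPACES)
        if bad_ns.any():
            raise SchemaError(
                "invalid namespace "
                f"{self.family_assignments.loc[bad_ns, 'namespace'].iloc[0]!r}"
            )
        bad_prov = ~self.term_assignments["provenance"].isin(TERM_PROVENANCES)
        if bad_prov.any():
            raise SchemaError(
                "invalid provenance "
                f"{self.term_assignments.loc[bad_prov, 'provenance'].iloc[0]!r}"
            )
        dangling = ~self.metadata["genome_id"].isin(known_genomes)
        if dangling.any():
            raise SchemaError(
                f"metadata: unknown genome_id {self.metadata.loc[dangling, 'genome_id'].iloc[0]!r}"
            )
        # A candidate assignment must never coexist with a confirmed one for
        # the same (gene, term) pair.
        ta = self.term_assignments
        if len(ta):
            confirmed = set(
                map(
                    tuple,
                    ta.loc[ta["provenance"] != "candidate", ["gene_id", "term_id"]].values,
                )
            )
            cand = ta.loc[ta["provenance"] == "candidate", ["gene_id", "term_id"]]
            clash = [t for t in map(tuple, cand.values) if t in confirmed]
            if clash:
                raise SchemaError(
                    f"candidate assignment coexists with confirmed one for {clash[0]}"
                )

    # -- queries -----------------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genome_of(self, gene_id: str) -> str:
        return self._gene_genome[gene_id]

    def genome_of_map(self) -> dict[str, str]:
        return dict(self._gene_genome)

    def genes_of_genome(self, genome_id: str) -> list[str]:
        sel = self.genes.loc[self.genes["genome_id"] == genome_id, "gene_id"]
        return sel.tolist()

    def confirmed_terms(self) -> pd.DataFrame:
        """Term assignments with manual or propagated provenance."""
        ta = self.term_assignments
        return ta.loc[ta["provenance"].isin(("manual", "propagated"))]

    def terms_of_gene(self, gene_id: str, *, include_candidates: bool = False) -> set[str]:
        ta = self.term_assignments
        sel = ta["gene_id"] == gene_id
        if not include_candidates:
            sel &= ta["provenance"] != "candidate"
        return set(ta.loc[sel, "term_id"])

    def add_term_assignments(self, rows: pd.DataFrame) -> int:
        """Merge new assignment rows, dropping duplicates; returns rows added."""
        if not len(rows):
            return 0
        merged = pd.concat([self.term_assignments, rows[TERM_COLS]], ignore_index=True)
        merged = merged.drop_duplicates(subset=TERM_COLS, ignore_index=True)
        added = len(merged) - len(self.term_assignments)
        self.term_assignments = merged
        self.validate()
        return added

    # -- IO ----------------------------------------------------------------

    @classmethod
    def load(cls, directory: str | Path) -> "AnnotationStore":
        """Read all store TSVs from *directory*; duplicate rows are collapsed."""
        d = Path(directory)
        frames = {}
        for key, fname in STORE_FILES.items():
            cols = {
                "genomes": GENOME_COLS,
                "genes": GENE_COLS,
                "family_assignments": FAMILY_COLS,
                "term_assignments": TERM_COLS,
                "metadata": METADATA_COLS,
            }[key]
            path = d / fname
            if key == "metadata" and not path.exists():
                frames[key] = pd.DataFrame(columns=cols)
                continue
            frames[key] = _read_tsv(path, cols).drop_duplicates(ignore_index=True)
        return cls(
            genomes=frames["genomes"],
            genes=frames["genes"],
            family_assignments=frames["family_assignments"],
            term_assignments=frames["term_assignments"],
            metadata=frames["metadata"],
        )

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for key, fname in STORE_FILES.items():
            df: pd.DataFrame = getattr(self, key)
            df.to_csv(d / fname, sep="\t", index=False)

    def equals(self, other: "AnnotationStore") -> bool:
        for key in STORE_FILES:
            a = getattr(self, key).reset_index(drop=True).astype(str)
            b = getattr(other, key).reset_index(drop=True).astype(str)
            if not a.equals(b):
                return False
        return True


# ---------------------------------------------------------------------------
# Hit table


@dataclass
class HitTable:
    """Pairwise protein-similarity records.

    One row per ordered (query, subject) pair; self-hits removed; percent
    identity on the 0-100 scale, coverages as 0-1 fractions of the query and
    subject lengths.
    """

    hits: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.hits.copy()
        for col in ("percent_identity", "query_coverage", "subject_coverage", "score"):
            df[col] = pd.to_numeric(df[col])
        bad = (df["percent_identity"] < 0) | (df["percent_identity"] > 100)
        if bad.any():
            raise SchemaError(
                f"percent_identity out of [0, 100]: {df.loc[bad, 'percent_identity'].iloc[0]}"
            )
        for col in ("query_coverage", "subject_coverage"):
            bad = (df[col] < 0) | (df[col] > 1)
            if bad.any():
                raise SchemaError(f"{col} out of [0, 1]: {df.loc[bad, col].iloc[0]}")
        if (df["score"] < 0).any():
            raise SchemaError("negative score in hit table")
        df = df.loc[df["query_gene_id"] != df["subject_gene_id"]]
        # duplicate ordered pairs: keep the highest-scoring record
        df = df.sort_values(
            ["query_gene_id", "subject_gene_id", "score"],
            ascending=[True, True, False],
            kind="mergesort",
        )
        df = df.drop_duplicates(subset=["query_gene_id", "subject_gene_id"], keep="first")
        self.hits = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.hits)

    @classmethod
    def load(cls, path: str | Path) -> "HitTable":
        """Read hits.tsv.

        Coverage columns may alternatively be named ``query_coverage_pct`` /
        ``subject_coverage_pct`` to supply percentages, which are converted
        to fractions.
        """
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for side in ("query", "subject"):
            pct = f"{side}_coverage_pct"
            if pct in df.columns:
                df[f"{side}_coverage"] = pd.to_numeric(df[pct]) / 100.0
                df = df.drop(columns=[pct])
        missing = [c for c in HIT_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        return cls(hits=df[HIT_COLS])

    def write(self, path: str | Path) -> None:
        self.hits.to_csv(path, sep="\t", index=False)

    def identity_of(self, a: str, b: str) -> float | None:
        """Percent identity for an unordered pair; max over the two directed
        records when both exist, None if neither exists."""
        df = self.hits
        sel = ((df["query_gene_id"] == a) & (df["subject_gene_id"] == b)) | (
            (df["query_gene_id"] == b) & (df["subject_gene_id"] == a)
        )
        vals = df.loc[sel, "percent_identity"]
        return float(vals.max()) if len(vals) else None


def load_store(directory: str | Path) -> AnnotationStore:
    return AnnotationStore.load(directory)


def load_hits(path: str | Path) -> HitTable:
    return HitTable.load(path)
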