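import random

import pandas as pd
import pytest

from phenoassert.fixtures import FixtureConfig, generate_fixture
from phenoassert.pipeline import run_pipeline
from phenoassert.store import (
    FAMILY_COLS,
    GENE_COLS,
    GENOME_COLS,
    HIT_COLS,
    METADATA_COLS,
    TERM_COLS,
    AnnotationStore,
    HitTable,
)


def make_store(genomes, genes, families=(), terms=(), metadata=()):
    """Build an AnnotationStore from plain row tuples.

    genomes: (genome_id, name, completeness); genes: (gene_id, genome_id,
    product, length); families: (gene_id, namespace, family_id); terms:
    (gene_id, term_id, provenance); metadata: (genome_id, attribute, value).
    """
    return AnnotationStore(
        genomes=pd.DataFrame(list(genomes), columns=GENOME_COLS),
        genes=pd.DataFrame(list(genes), columns=GENE_COLS),
        family_assignments=pd.DataFrame(list(families), columns=FAMILY_COLS),
        term_assignments=pd.DataFrame(list(terms), columns=TERM_COLS),
        metadata=pd.DataFrame(list(metadata), columns=METADATA_COLS),
    )


def make_hits(rows):
    """HitTable from (query, subject, identity, qcov, scov, score) tuples."""
    return HitTable(hits=pd.DataFrame(list(rows), columns=HIT_COLS))


def simple_store(n_genomes, genes_per_genome, prefix="G"):
    """Store of empty-annotation genes, useful as a scaffold for hit tables."""
    genomes = [(f"{prefix}{i}", f"genome {i}", "finished") for i in range(n_genomes)]
    genes = [
        (f"{prefix}{i}_g{j}", f"{prefix}{i}", "protein", 300)
        for i in range(n_genomes)
        for j in range(genes_per_genome)
    ]
    return make_store(genomes, genes)


def random_store(rng: random.Random, max_genes: int = 200) -> AnnotationStore:
    """Random small store with COG/Pfam/TIGRfam/KO assignments, including
    multi-KO genes and unannotated genes."""
    n_genomes = rng.randint(1, 4)
    n_genes = rng.randint(5, max_genes)
    genomes = [(f"G{i}", f"g{i}", "finished") for i in range(n_genomes)]
    genes = [
        (f"g{j:04d}", f"G{rng.randrange(n_genomes)}", "p", 100 + j) for j in range(n_genes)
    ]
    cogs = [f"COG{i}" for i in range(4)]
    pfams = [f"pf{i}" for i in range(6)]
    tigrs = [f"TIGR{i}" for i in range(3)]
    kos = [f"K{i}" for i in range(5)]
    families = []
    for gene_id, *_ in genes:
        for ns, pool, p in (("COG", cogs, 0.7), ("Pfam", pfams, 0.8), ("TIGRfam", tigrs, 0.3)):
            k = rng.randint(1, 2) if rng.random() < p else 0
            for fam in rng.sample(pool, k):
                families.append((gene_id, ns, fam))
        if rng.random() < 0.6:
            for ko in rng.sample(kos, rng.randint(1, 2)):
                families.append((gene_id, "KO", ko))
    return make_store(genomes, genes, families=families)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    generate_fixture(FixtureConfig(seed=7), d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(
        fixture_dir,
        fixture_dir / "hits.tsv",
        fixture_dir / "pathways.dsl",
        fixture_dir / "rules.tsv",
        out,
    )


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir):
    return pd.read_csv(fixture_dir / "truth.tsv", sep="\t", dtype=str)
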