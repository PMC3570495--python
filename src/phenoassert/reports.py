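"""Annotation-coherence reports.

Two audits flag functional-annotation inconsistencies:

* **KO x protein-family cross-classification** — for each KEGG Orthology
  (KO) term, how many distinct COGs, Pfams and TIGRfams its genes are
  co-assigned to, and how many unique (COG-set, Pfam-set, TIGRfam-set)
  combinations occur.  A KO spread across many combinations either lacks
  assignment consistency or its companion families are broad enough to cover
  several paralogous activities.

* **KO x genome / paralog-cluster distribution** — paralog clusters are
  computed per genome from the pairwise similarity graph with the Markov
  Cluster Algorithm (MCL).  A KO assigned to several genes of one genome, or
  to low-identity paralogs within a cluster, is a likely over-annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import AnnotationStore, HitTable

logger = logging.getLogger(__name__)

FAMILY_TRIPLE = ("COG", "Pfam", "TIGRfam")


@dataclass(frozen=True)
class FamilyCombination:
    """Per-gene sets of COG / Pfam / TIGRfam assignments (any may be empty)."""

    cog_ids: frozenset[str]
    pfam_ids: frozenset[str]
    tigrfam_ids: frozenset[str]

    def label(self) -> str:
        def fmt(ids: frozenset[str]) -> str:
            return ",".join(sorted(ids)) if ids else "-"

        return f"{fmt(self.cog_ids)}|{fmt(self.pfam_ids)}|{fmt(self.tigrfam_ids)}"


def _families_by_gene(store: AnnotationStore) -> dict[str, dict[str, set[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    for gene_id, namespace, family_id in store.family_assignments[
        ["gene_id", "namespace", "family_id"]
    ].values:
        out.setdefault(gene_id, {}).setdefault(namespace, set()).add(family_id)
    return out


def gene_combination(store: AnnotationStore, gene_id: str) -> FamilyCombination:
    fams = _families_by_gene(store).get(gene_id, {})
    return FamilyCombination(
        frozenset(fams.get("COG", ())),
        frozenset(fams.get("Pfam", ())),
        frozenset(fams.get("TIGRfam", ())),
    )


def _combinations_by_gene(store: AnnotationStore) -> dict[str, FamilyCombination]:
    fams = _families_by_gene(store)
    out = {}
    for gene_id in store.genes["gene_id"]:
        f = fams.get(gene_id, {})
        out[gene_id] = FamilyCombination(
            frozenset(f.get("COG", ())),
            frozenset(f.get("Pfam", ())),
            frozenset(f.get("TIGRfam", ())),
        )
    return out


def _kos_by_gene(store: AnnotationStore) -> dict[str, set[str]]:
    fa = store.family_assignments
    ko = fa.loc[fa["namespace"] == "KO"]
    out: dict[str, set[str]] = {}
    for gene_id, family_id in ko[["gene_id", "family_id"]].values:
        out.setdefault(gene_id, set()).add(family_id)
    return out


def ko_family_summary(store: AnnotationStore) -> pd.DataFrame:
    """Per-KO counts of co-assigned families and unique combinations.

    Columns: ko_id, n_genes, n_cogs, n_pfams, n_tigrfams, n_combinations.
    """
    combos = _combinations_by_gene(store)
    kos = _kos_by_gene(store)
    genes_by_ko: dict[str, list[str]] = {}
    for gene_id, ids in kos.items():
        for ko in ids:
            genes_by_ko.setdefault(ko, []).append(gene_id)
    rows = []
    for ko in sorted(genes_by_ko):
        genes = genes_by_ko[ko]
        cogs: set[str] = set()
        pfams: set[str] = set()
        tigrfams: set[str] = set()
        combo_set: set[FamilyCombination] = set()
        for g in genes:
            c = combos[g]
            cogs |= c.cog_ids
            pfams |= c.pfam_ids
            tigrfams |= c.tigrfam_ids
            combo_set.add(c)
        rows.append(
            {
                "ko_id": ko,
                "n_genes": len(set(genes)),
                "n_cogs": len(cogs),
                "n_pfams": len(pfams),
                "n_tigrfams": len(tigrfams),
                "n_combinations": len(combo_set),
            }
        )
    cols = ["ko_id", "n_genes", "n_cogs", "n_pfams", "n_tigrfams", "n_combinations"]
    return pd.DataFrame(rows, columns=cols)


def ko_combination_details(store: AnnotationStore, ko_id: str) -> pd.DataFrame:
    """Per-combination gene counts for one query KO.

    Combinations are enumerated from the genes carrying the query KO; the
    four counts are taken over *all* genes sharing that combination:

    - ``n_with_query_ko``: genes with the combination and the query KO;
    - ``n_with_other_ko_incl_query``: genes with the combination and any KO
      different from the query (genes carrying both the query KO and another
      one count here too);
    - ``n_with_other_ko_excl_query``: genes with the combination, some other
      KO, and *not* the query KO;
    - ``n_without_ko``: genes with the combination and no KO at all.
    """
    combos = _combinations_by_gene(store)
    kos = _kos_by_gene(store)
    query_genes = sorted(g for g, ids in kos.items() if ko_id in ids)
    if not query_genes:
        raise KeyError(f"no genes carry KO term {ko_id!r}")
    query_combos = sorted({combos[g] for g in query_genes}, key=lambda c: c.label())
    genes_by_combo: dict[FamilyCombination, list[str]] = {}
    for gene_id, combo in combos.items():
        genes_by_combo.setdefault(combo, []).append(gene_id)
    rows = []
    for combo in query_combos:
        genes = genes_by_combo[combo]
        a = b = c = d = 0
        for g in genes:
            gene_kos = kos.get(g, set())
            if ko_id in gene_kos:
                a += 1
            if gene_kos - {ko_id}:
                b += 1
                if ko_id not in gene_kos:
                    c += 1
            if not gene_kos:
                d += 1
        rows.append(
            {
                "combination": combo.label(),
                "n_with_query_ko": a,
                "n_with_other_ko_incl_query": b,
                "n_with_other_ko_excl_query": c,
                "n_without_ko": d,
            }
        )
    cols = [
        "combination",
        "n_with_query_ko",
        "n_with_other_ko_incl_query",
        "n_with_other_ko_excl_query",
        "n_without_ko",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Markov Cluster Algorithm


@dataclass(frozen=True)
class ParalogCluster:
    genome_id: str
    member_gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("a paralog cluster needs at least two members")


def mcl_cluster(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    *,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[frozenset[str]]:
    """Markov clustering of an undirected weighted graph.

    The column-stochastic transition matrix is alternately squared
    (expansion) and raised entry-wise to ``inflation`` with column
    renormalization, until the largest entry change falls below ``tol`` or
    ``max_iter`` is reached (a warning is logged on non-convergence).
    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1.0 for isolated nodes).  Clusters are the connected
    components of the limit matrix's non-zero pattern; all nodes are
    returned, singletons included.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    order = sorted(set(nodes))
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    if n == 0:
        return []
    M = np.zeros((n, n), dtype=float)
    for u, v, w in edges:
        if u == v:
            continue
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        i, j = index[u], index[v]
        M[i, j] = max(M[i, j], w)
        M[j, i] = max(M[j, i], w)
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated = inflated / colsum
        if np.abs(inflated - M).max() < tol:
            M = inflated
            converged = True
            break
        M = inflated
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    # connected components of the limit matrix's support
    support = (M > max(tol, 1e-9)) | (M.T > max(tol, 1e-9))
    seen = [False] * n
    clusters: list[frozenset[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(support[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        clusters.append(frozenset(order[i] for i in comp))
    return sorted(clusters, key=lambda c: sorted(c)[0])


def build_paralog_clusters(
    store: AnnotationStore,
    hits: HitTable,
    *,
    min_identity_pct: float = 30.0,
    min_coverage_frac: float = 0.5,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[ParalogCluster]:
    """MCL paralog clusters per genome from intra-genome similarity edges.

    Edges connect same-genome gene pairs whose hit passes the identity and
    bidirectional-coverage filters; the edge weight is the hit score (max
    over the two directed records).  Only clusters of two or more genes are
    returned.
    """
    genome_of = store.genome_of_map()
    df = hits.hits
    df = df.loc[
        df["query_gene_id"].isin(genome_of) & df["subject_gene_id"].isin(genome_of)
    ]
    df = df.loc[
        (df["percent_identity"] > min_identity_pct)
        & (df["query_coverage"] > min_coverage_frac)
        & (df["subject_coverage"] > min_coverage_frac)
    ]
    edges_by_genome: dict[str, dict[frozenset[str], float]] = {}
    for q, s, score in df[["query_gene_id", "subject_gene_id", "score"]].values:
        if genome_of[q] != genome_of[s]:
            continue
        gmap = edges_by_genome.setdefault(genome_of[q], {})
        key = frozenset((q, s))
        gmap[key] = max(gmap.get(key, 0.0), float(score))
    clusters: list[ParalogCluster] = []
    for genome_id in sorted(edges_by_genome):
        edge_map = edges_by_genome[genome_id]
        nodes = sorted({g for pair in edge_map for g in pair})
        edges = [(*sorted(pair), w) for pair, w in edge_map.items()]
        edges.sort()
        for members in mcl_cluster(
            nodes, edges, inflation=inflation, max_iter=max_iter, tol=tol
        ):
            if len(members) >= 2:
                clusters.append(ParalogCluster(genome_id, members))
    return clusters


def ko_genome_paralog_summary(
    store: AnnotationStore,
    clusters: list[ParalogCluster],
    hits: HitTable,
) -> pd.DataFrame:
    """Per-KO distribution across genomes and paralog clusters.

    Columns: ko_id, n_genes, n_genomes, avg_genes_per_genome,
    n_genes_in_paralog_clusters, n_genes_with_same_ko_paralog,
    avg_identity_same_ko_paralogs (empty string when there are no same-KO
    paralog pairs).
    """
    genome_of = store.genome_of_map()
    kos = _kos_by_gene(store)
    genes_by_ko: dict[str, set[str]] = {}
    for gene_id, ids in kos.items():
        for ko in ids:
            genes_by_ko.setdefault(ko, set()).add(gene_id)
    cluster_of: dict[str, frozenset[str]] = {}
    for cl in clusters:
        for g in cl.member_gene_ids:
            cluster_of[g] = cl.member_gene_ids
    rows = []
    for ko in sorted(genes_by_ko):
        genes = sorted(genes_by_ko[ko])
        genomes = {genome_of[g] for g in genes}
        in_clusters = [g for g in genes if g in cluster_of]
        with_same_ko: list[str] = []
        pair_idents: list[float] = []
        seen_pairs: set[frozenset[str]] = set()
        for g in genes:
            members = cluster_of.get(g)
            if members is None:
                continue
            mates = [m for m in members if m != g and ko in kos.get(m, set())]
            if mates:
                with_same_ko.append(g)
                for m in mates:
                    pair = frozenset((g, m))
                    if pair in seen_pairs:
                        continue
                    seen_pairs.add(pair)
                    ident = hits.identity_of(g, m)
                    if ident is None:
                        logger.warning(
                            "no hit record for same-KO paralog pair %s/%s; skipped", g, m
                        )
                        continue
                    pair_idents.append(ident)
        rows.append(
            {
                "ko_id": ko,
                "n_genes": len(genes),
                "n_genomes": len(genomes),
                "avg_genes_per_genome": round(len(genes) / len(genomes), 4) if genomes else 0.0,
                "n_genes_in_paralog_clusters": len(in_clusters),
                "n_genes_with_same_ko_paralog": len(with_same_ko),
                "avg_identity_same_ko_paralogs": (
                    round(float(np.mean(pair_idents)), 4) if pair_idents else ""
                ),
            }
        )
    cols = [
        "ko_id",
        "n_genes",
        "n_genomes",
        "avg_genes_per_genome",
        "n_genes_in_paralog_clusters",
        "n_genes_with_same_ko_paralog",
        "avg_identity_same_ko_paralogs",
    ]
    return pd.DataFrame(rows, columns=cols)
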