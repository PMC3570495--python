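"""KO cross-classification reports and MCL paralog clustering."""

import random

import pandas as pd
import pytest

from conftest import make_hits, make_store, random_store, simple_store
from phenoassert.reports import (
    ParalogCluster,
    build_paralog_clusters,
    ko_combination_details,
    ko_family_summary,
    ko_genome_paralog_summary,
    mcl_cluster,
)


def _fig2_style_store():
    """One KO (K00005) spanning 1 COG, 2 Pfams, 0 TIGRfams in 4 distinct
    per-gene combinations."""
    genomes = [("G1", "one", "finished")]
    genes = [(f"g{i}", "G1", "glycerol dehydrogenase", 300) for i in range(4)]
    families = [(f"g{i}", "KO", "K00005") for i in range(4)]
    families += [
        ("g0", "COG", "COG0371"), ("g0", "Pfam", "pfA"),
        ("g1", "COG", "COG0371"), ("g1", "Pfam", "pfB"),
        ("g2", "COG", "COG0371"), ("g2", "Pfam", "pfA"), ("g2", "Pfam", "pfB"),
        ("g3", "COG", "COG0371"),
    ]
    return make_store(genomes, genes, families=families)


def test_ko_family_summary_counts_sets_and_combinations():
    summary = ko_family_summary(_fig2_style_store())
    row = summary.set_index("ko_id").loc["K00005"]
    assert (row["n_cogs"], row["n_pfams"], row["n_tigrfams"], row["n_combinations"]) == (1, 2, 0, 4)


def test_ko_family_summary_identical_genes_one_combination():
    genomes = [("G1", "one", "finished")]
    genes = [(f"g{i}", "G1", "p", 100) for i in range(3)]
    families = [(f"g{i}", "KO", "K1") for i in range(3)]
    families += [(f"g{i}", "COG", "C1") for i in range(3)]
    summary = ko_family_summary(make_store(genomes, genes, families=families))
    assert summary.set_index("ko_id").loc["K1", "n_combinations"] == 1


def test_ko_family_summary_no_ko_genes():
    store = make_store([("G1", "one", "finished")], [("g0", "G1", "p", 100)])
    assert len(ko_family_summary(store)) == 0


def test_combination_details_toy_counts():
    """g1(K1, combo C), g2(K2, combo C), g3(no KO, combo C) -> (1, 1, 1, 1)."""
    genomes = [("G1", "one", "finished")]
    genes = [(g, "G1", "p", 100) for g in ["g1", "g2", "g3"]]
    families = [
        ("g1", "KO", "K1"), ("g2", "KO", "K2"),
        ("g1", "COG", "C"), ("g2", "COG", "C"), ("g3", "COG", "C"),
    ]
    details = ko_combination_details(make_store(genomes, genes, families=families), "K1")
    row = details.iloc[0]
    assert (
        row["n_with_query_ko"],
        row["n_with_other_ko_incl_query"],
        row["n_with_other_ko_excl_query"],
        row["n_without_ko"],
    ) == (1, 1, 1, 1)


def test_combination_details_multi_ko_gene_classification():
    """A gene with KOs {K1, K2}, query K1: counted with the query KO and as
    'other KO including query', never as 'other KO excluding query'."""
    genomes = [("G1", "one", "finished")]
    genes = [("g1", "G1", "p", 100)]
    families = [("g1", "KO", "K1"), ("g1", "KO", "K2"), ("g1", "COG", "C")]
    details = ko_combination_details(make_store(genomes, genes, families=families), "K1")
    row = details.iloc[0]
    assert (
        row["n_with_query_ko"],
        row["n_with_other_ko_incl_query"],
        row["n_with_other_ko_excl_query"],
        row["n_without_ko"],
    ) == (1, 1, 0, 0)


def test_combination_details_unknown_ko_errors():
    with pytest.raises(KeyError):
        ko_combination_details(_fig2_style_store(), "K99999")


def _naive_summary(store, ko):
    """Quadruple-loop recount, independent of the report implementation."""
    fams = {}
    kos = {}
    for gene_id, ns, fam in store.family_assignments.values.tolist():
        if ns == "KO":
            kos.setdefault(gene_id, set()).add(fam)
        else:
            fams.setdefault(gene_id, {}).setdefault(ns, set()).add(fam)

    def combo(g):
        f = fams.get(g, {})
        return (
            frozenset(f.get("COG", ())),
            frozenset(f.get("Pfam", ())),
            frozenset(f.get("TIGRfam", ())),
        )

    genes = store.genes["gene_id"].tolist()
    ko_genes = [g for g in genes if ko in kos.get(g, set())]
    out = {}
    for c in {combo(g) for g in ko_genes}:
        sharing = [g for g in genes if combo(g) == c]
        a = sum(1 for g in sharing if ko in kos.get(g, set()))
        b = sum(1 for g in sharing if kos.get(g, set()) - {ko})
        cc = sum(1 for g in sharing if kos.get(g, set()) - {ko} and ko not in kos.get(g, set()))
        d = sum(1 for g in sharing if not kos.get(g, set()))
        out[c] = (a, b, cc, d, len(sharing))
    return out


def test_report_counts_match_naive_recount_on_random_stores():
    """On random stores the report counts equal a brute-force recount, and
    per combination the disjoint classes partition the sharing genes."""
    rng = random.Random(11)
    for _ in range(10):
        store = random_store(rng, max_genes=60)
        summary = ko_family_summary(store)
        for ko in summary["ko_id"]:
            naive = _naive_summary(store, ko)
            details = ko_combination_details(store, ko).set_index("combination")
            assert len(details) == len(naive)
            for combo, (a, b, c, d, n_sharing) in naive.items():
                label = "|".join(",".join(sorted(part)) if part else "-" for part in combo)
                row = details.loc[label]
                assert (
                    row["n_with_query_ko"],
                    row["n_with_other_ko_incl_query"],
                    row["n_with_other_ko_excl_query"],
                    row["n_without_ko"],
                ) == (a, b, c, d)
                # count conservation: the three disjoint classes partition
                assert a + c + d == n_sharing


# ---------------------------------------------------------------------------
# MCL


def test_mcl_recovers_disjoint_cliques():
    edges = [
        ("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
        ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
    ]
    clusters = mcl_cluster(["a", "b", "c", "x", "y", "z"], edges)
    assert set(clusters) == {frozenset("abc"), frozenset("xyz")}


def test_mcl_weighted_path_splits_at_weak_edge():
    clusters = mcl_cluster(
        ["a", "b", "c", "d"],
        [("a", "b", 10.0), ("b", "c", 1.0), ("c", "d", 10.0)],
        inflation=2.0,
    )
    assert set(clusters) == {frozenset("ab"), frozenset("cd")}


def test_mcl_single_node_and_partition_property():
    assert mcl_cluster(["solo"], []) == [frozenset({"solo"})]
    rng = random.Random(31)
    for _ in range(10):
        n = rng.randint(2, 12)
        nodes = [f"n{i}" for i in range(n)]
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j], rng.uniform(1, 10)))
        clusters = mcl_cluster(nodes, edges)
        members = [g for c in clusters for g in c]
        assert sorted(members) == sorted(nodes)  # a partition of all nodes
        # node-order invariance
        shuffled_nodes = nodes[::-1]
        shuffled_edges = edges[::-1]
        assert set(mcl_cluster(shuffled_nodes, shuffled_edges)) == set(clusters)


def test_build_paralog_clusters_same_genome_only():
    store = simple_store(2, 3)
    hits = make_hits(
        [
            ("G0_g0", "G0_g1", 80, 0.9, 0.9, 100),
            ("G0_g1", "G0_g0", 80, 0.9, 0.9, 100),
            ("G0_g2", "G1_g0", 85, 0.9, 0.9, 120),  # cross-genome: ignored
            ("G1_g0", "G0_g2", 85, 0.9, 0.9, 120),
        ]
    )
    clusters = build_paralog_clusters(store, hits)
    assert len(clusters) == 1
    assert clusters[0].genome_id == "G0"
    assert clusters[0].member_gene_ids == frozenset({"G0_g0", "G0_g1"})


def test_build_paralog_clusters_filters_and_no_hits():
    store = simple_store(1, 4)
    assert build_paralog_clusters(store, make_hits([])) == []
    weak = make_hits(
        [("G0_g0", "G0_g1", 20, 0.9, 0.9, 10), ("G0_g1", "G0_g0", 20, 0.9, 0.9, 10)]
    )
    assert build_paralog_clusters(store, weak, min_identity_pct=30) == []


def test_paralog_cluster_requires_two_members():
    with pytest.raises(ValueError):
        ParalogCluster("G1", frozenset({"only"}))


# ---------------------------------------------------------------------------
# KO x genome / paralog summary


def test_ko_genome_paralog_summary_averages():
    """4 genes in 2 genomes -> avg 2.0; a clustered same-KO pair at 80%%
    identity reports 2 genes with a same-KO paralog and avg identity 80."""
    store = simple_store(2, 3)
    fam = [(g, "KO", "K1") for g in ["G0_g0", "G0_g1", "G1_g0", "G1_g1"]]
    store.family_assignments = pd.DataFrame(fam, columns=["gene_id", "namespace", "family_id"])
    store.validate()
    hits = make_hits(
        [("G0_g0", "G0_g1", 80, 0.9, 0.9, 100), ("G0_g1", "G0_g0", 80, 0.9, 0.9, 100)]
    )
    clusters = build_paralog_clusters(store, hits)
    summary = ko_genome_paralog_summary(store, clusters, hits).set_index("ko_id")
    row = summary.loc["K1"]
    assert row["n_genes"] == 4 and row["n_genomes"] == 2
    assert row["avg_genes_per_genome"] == 2.0
    assert row["n_genes_in_paralog_clusters"] == 2
    assert row["n_genes_with_same_ko_paralog"] == 2
    assert row["avg_identity_same_ko_paralogs"] == 80.0


def test_ko_summary_singleton_genes_have_empty_paralog_columns():
    store = simple_store(1, 2)
    store.family_assignments = pd.DataFrame(
        [("G0_g0", "KO", "K1")], columns=["gene_id", "namespace", "family_id"]
    )
    store.validate()
    summary = ko_genome_paralog_summary(store, [], make_hits([])).set_index("ko_id")
    row = summary.loc["K1"]
    assert row["n_genes_in_paralog_clusters"] == 0
    assert row["n_genes_with_same_ko_paralog"] == 0
    assert row["avg_identity_same_ko_paralogs"] == ""
    assert row["avg_genes_per_genome"] >= 1
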