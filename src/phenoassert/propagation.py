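"""Automated functional-term propagation and candidate-gene detection.

Two evidence tiers drive term assignment beyond manual curation:

* **Propagation** — a gene inherits a term when it has at least
  ``min_homologs`` homologs above strict identity/coverage thresholds and at
  least ``min_supporting`` of the top-ranked ones already carry the term.
  Thresholds are exclusive (``>``), so boundary equality never qualifies.
* **Candidate detection** — a weaker tier based on bidirectional best hits
  (BBH) across genomes: a gene becomes a *candidate* for a term when enough
  of its top BBH partners carry it.  Candidates never override confirmed
  assignments; downstream pathway inference treats candidate-only evidence
  as status UNKNOWN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .store import TERM_COLS, AnnotationStore, HitTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationParams:
    """Thresholds for strict term propagation.

    Defaults implement the standard operating procedure: at least five
    homologs with >50% identity, alignment covering >70% of both proteins,
    and at least two of the top five homologs already carrying the term.
    """

    min_homologs: int = 5
    min_identity_pct: float = 50.0
    min_coverage_frac: float = 0.70
    min_supporting: int = 2


@dataclass(frozen=True)
class CandidateParams:
    """Thresholds for candidate-gene detection: at least two of the top five
    BBH partners carry the term, overlap >70% on both sides, and at least one
    term-bearing partner with >25% identity."""

    top_k_bbh: int = 5
    min_supporting: int = 2
    min_coverage_frac: float = 0.70
    min_best_identity_pct: float = 25.0


def _confirmed_terms_by_gene(store: AnnotationStore) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene_id, term_id in store.confirmed_terms()[["gene_id", "term_id"]].values:
        out.setdefault(gene_id, set()).add(term_id)
    return out


def propagate_terms(
    store: AnnotationStore,
    hits: HitTable,
    params: PropagationParams = PropagationParams(),
    *,
    iterate: bool = False,
    max_rounds: int = 10,
) -> pd.DataFrame:
    """Return new term assignments with provenance ``propagated``.

    For each gene with no confirmed (manual/propagated) term, qualifying
    homologs are hits with identity > ``min_identity_pct`` and both coverage
    fractions > ``min_coverage_frac``.  If at least ``min_homologs`` qualify,
    they are ranked by identity, then score (both descending), then subject
    id, and any term carried by >= ``min_supporting`` of the top
    ``min_homologs`` is assigned.  With ``iterate=True`` rounds repeat, each
    treating the previous round's output as confirmed, until a fixpoint or
    ``max_rounds``.

    The result is deterministic and order-invariant in the input rows.
    """
    terms_by_gene = _confirmed_terms_by_gene(store)
    df = hits.hits
    qualifying = df.loc[
        (df["percent_identity"] > params.min_identity_pct)
        & (df["query_coverage"] > params.min_coverage_frac)
        & (df["subject_coverage"] > params.min_coverage_frac)
    ]

    all_new: list[tuple[str, str]] = []
    for round_no in range(max_rounds if iterate else 1):
        round_new: list[tuple[str, str]] = []
        for gene_id, group in qualifying.groupby("query_gene_id", sort=True):
            if terms_by_gene.get(gene_id):
                continue  # already has a confirmed term
            if len(group) < params.min_homologs:
                continue
            ranked = group.sort_values(
                ["percent_identity", "score", "subject_gene_id"],
                ascending=[False, False, True],
                kind="mergesort",
            )
            top = ranked["subject_gene_id"].head(params.min_homologs)
            support: dict[str, int] = {}
            for subject in top:
                for term in terms_by_gene.get(subject, ()):
                    support[term] = support.get(term, 0) + 1
            winners = sorted(t for t, n in support.items() if n >= params.min_supporting)
            if len(winners) > 1:
                logger.warning(
                    "gene %s: multiple terms reach support threshold: %s",
                    gene_id,
                    ", ".join(winners),
                )
            for term in winners:
                round_new.append((gene_id, term))
        if not round_new:
            break
        for gene_id, term in round_new:
            terms_by_gene.setdefault(gene_id, set()).add(term)
        all_new.extend(round_new)
        if not iterate:
            break

    out = pd.DataFrame(sorted(set(all_new)), columns=["gene_id", "term_id"])
    out["provenance"] = "propagated"
    return out[TERM_COLS] if len(out) else pd.DataFrame(columns=TERM_COLS)


def compute_bbh(hits: HitTable, genome_of: Mapping[str, str]) -> set[frozenset[str]]:
    """Bidirectional best hits across genomes.

    For each (gene, target genome), the best hit is the highest-scoring one,
    ties broken by higher identity then lexicographically smaller subject id.
    A pair {a, b} is a BBH iff the two genes sit in different genomes and
    each is the other's best hit in its genome.
    """
    df = hits.hits
    df = df.loc[
        df["query_gene_id"].isin(genome_of) & df["subject_gene_id"].isin(genome_of)
    ].copy()
    if not len(df):
        return set()
    df["query_genome"] = df["query_gene_id"].map(genome_of)
    df["subject_genome"] = df["subject_gene_id"].map(genome_of)
    df = df.loc[df["query_genome"] != df["subject_genome"]]
    df = df.sort_values(
        ["query_gene_id", "subject_genome", "score", "percent_identity", "subject_gene_id"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    best = df.drop_duplicates(subset=["query_gene_id", "subject_genome"], keep="first")
    best_of: dict[tuple[str, str], str] = {
        (q, g): s
        for q, g, s in best[["query_gene_id", "subject_genome", "subject_gene_id"]].values
    }
    pairs: set[frozenset[str]] = set()
    for (query, _target_genome), subject in best_of.items():
        back = best_of.get((subject, genome_of[query]))
        if back == query:
            pairs.add(frozenset((query, subject)))
    return pairs


def detect_candidates(
    store: AnnotationStore,
    hits: HitTable,
    params: CandidateParams = CandidateParams(),
    *,
    bbh_pairs: set[frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Return candidate term assignments (provenance ``candidate``).

    For each gene, BBH partners with both coverage fractions >
    ``min_coverage_frac`` are ranked by identity (descending, gene id
    tie-break) and the top ``top_k_bbh`` kept.  The gene becomes a candidate
    for term *t* iff at least ``min_supporting`` of those partners carry *t*
    (confirmed provenance) and at least one of the *t*-bearing partners has
    identity > ``min_best_identity_pct``.  Pairs already confirmed for the
    gene are never emitted.
    """
    genome_of = store.genome_of_map()
    if bbh_pairs is None:
        bbh_pairs = compute_bbh(hits, genome_of)
    if not bbh_pairs:
        return pd.DataFrame(columns=TERM_COLS)
    terms_by_gene = _confirmed_terms_by_gene(store)

    # identity/coverage per unordered pair: best directed record
    pair_info: dict[frozenset[str], tuple[float, float, float]] = {}
    for q, s, ident, qc, sc in hits.hits[
        ["query_gene_id", "subject_gene_id", "percent_identity", "query_coverage", "subject_coverage"]
    ].values:
        key = frozenset((q, s))
        if key not in bbh_pairs:
            continue
        prev = pair_info.get(key)
        rec = (float(ident), float(qc), float(sc))
        if prev is None or rec[0] > prev[0]:
            pair_info[key] = rec

    partners: dict[str, list[tuple[float, str]]] = {}
    for pair in bbh_pairs:
        a, b = sorted(pair)
        info = pair_info.get(pair)
        if info is None:
            continue
        ident, qc, sc = info
        if qc <= params.min_coverage_frac or sc <= params.min_coverage_frac:
            continue
        partners.setdefault(a, []).append((ident, b))
        partners.setdefault(b, []).append((ident, a))

    rows: list[tuple[str, str]] = []
    for gene_id in sorted(partners):
        ranked = sorted(partners[gene_id], key=lambda t: (-t[0], t[1]))
        top = ranked[: params.top_k_bbh]
        by_term: dict[str, list[float]] = {}
        for ident, partner in top:
            for term in terms_by_gene.get(partner, ()):
                by_term.setdefault(term, []).append(ident)
        own = terms_by_gene.get(gene_id, set())
        for term in sorted(by_term):
            if term in own:
                continue
            idents = by_term[term]
            if len(idents) >= params.min_supporting and max(idents) > params.min_best_identity_pct:
                rows.append((gene_id, term))

    out = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    out["provenance"] = "candidate"
    return out[TERM_COLS] if len(out) else pd.DataFrame(columns=TERM_COLS)
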