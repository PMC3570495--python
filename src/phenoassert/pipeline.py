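"""End-to-end orchestration: propagation -> candidates -> assertions ->
phenotype predictions -> metadata comparison -> consistency reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import phenotypes as ph
from . import propagation as prop
from . import reports as rep
from .pathways import DefinitionSet, PathwayEngine, assertions_to_frame, parse_definitions
from .store import AnnotationStore, HitTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    store: AnnotationStore
    assertions: pd.DataFrame
    predictions: pd.DataFrame
    metadata_report: pd.DataFrame
    ko_families: pd.DataFrame
    ko_paralogs: pd.DataFrame


def run_pipeline(
    store_dir: str | Path,
    hits_path: str | Path,
    definitions_path: str | Path,
    rules_path: str | Path,
    out_dir: str | Path,
    *,
    iterate_propagation: bool = False,
    strict: bool = True,
    propagation_params: prop.PropagationParams = prop.PropagationParams(),
    candidate_params: prop.CandidateParams = prop.CandidateParams(),
    inflation: float = 2.0,
) -> PipelineResult:
    """Run every stage on one input set, writing TSV artifacts to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store = AnnotationStore.load(store_dir)
    hits = HitTable.load(hits_path)
    logger.info("loaded %d genomes, %d genes, %d hits", store.n_genomes, store.n_genes, len(hits))

    propagated = prop.propagate_terms(
        store, hits, propagation_params, iterate=iterate_propagation
    )
    logger.info("propagated %d term assignments", len(propagated))
    store.add_term_assignments(propagated)

    candidates = prop.detect_candidates(store, hits, candidate_params)
    logger.info("detected %d candidate assignments", len(candidates))
    store.add_term_assignments(candidates)
    store.term_assignments.to_csv(out / "term_assignments.tsv", sep="\t", index=False)

    defs: DefinitionSet = parse_definitions(Path(definitions_path))
    engine = PathwayEngine(store, defs)
    records = engine.assert_all()
    assertions = assertions_to_frame(records)
    assertions.to_csv(out / "assertions.tsv", sep="\t", index=False)

    rules = ph.load_rules(rules_path)
    preds = ph.predict_phenotypes(records, rules, strict=strict)
    predictions = ph.predictions_to_frame(preds)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)

    metadata_report = ph.compare_with_metadata(preds, rules, store.metadata)
    metadata_report.to_csv(out / "metadata_report.tsv", sep="\t", index=False)

    ko_families = rep.ko_family_summary(store)
    ko_families.to_csv(out / "ko_family_summary.tsv", sep="\t", index=False)
    clusters = rep.build_paralog_clusters(store, hits, inflation=inflation)
    ko_paralogs = rep.ko_genome_paralog_summary(store, clusters, hits)
    ko_paralogs.to_csv(out / "ko_paralog_summary.tsv", sep="\t", index=False)

    return PipelineResult(
        store=store,
        assertions=assertions,
        predictions=predictions,
        metadata_report=metadata_report,
        ko_families=ko_families,
        ko_paralogs=ko_paralogs,
    )
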