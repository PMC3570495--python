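"""Phenotype rules, genome-level predictions, and metadata agreement checks.

A phenotype rule is a boolean AND/OR/NOT expression over pathway identifiers
(e.g. L-phenylalanine prototroph = ``(P_146 OR P_519) AND (P_272 OR P_147)``),
evaluated under three-valued logic against a genome's pathway assertion
statuses.  Each rule carries a metadata *category* and *category value*
(e.g. "Oxygen Requirement" / "aerobic") so that positive predictions can be
checked against recorded organism metadata.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .logic import (
    FALSE,
    STATUS_TO_TRISTATE,
    TRUE,
    RuleExpr,
    TriState,
    evaluate_rule,
    parse_rule,
)
from .pathways import AssertionRecord

RULE_COLS = ["rule_id", "phenotype_name", "category", "category_value", "expression"]
PREDICTION_COLS = ["genome_id", "rule_id", "verdict", "evidence"]

VERDICT_OF = {TRUE: "predicted", FALSE: "not_predicted"}

#: Default metadata-value synonym groups; user-extensible.
DEFAULT_SYNONYMS: tuple[tuple[str, ...], ...] = (
    ("aerobe", "aerobic"),
    ("anaerobe", "anaerobic"),
    ("facultative", "facultative anaerobe"),
    ("mesophile", "mesophilic"),
    ("thermophile", "thermophilic"),
    ("psychrophile", "psychrophilic"),
)


@dataclass(frozen=True)
class PhenotypeRule:
    rule_id: str
    phenotype_name: str
    category: str
    category_value: str
    expression: RuleExpr

    @classmethod
    def from_text(
        cls, rule_id: str, phenotype_name: str, category: str, category_value: str, text: str
    ) -> "PhenotypeRule":
        return cls(rule_id, phenotype_name, category, category_value, parse_rule(text))


@dataclass(frozen=True)
class PhenotypePrediction:
    genome_id: str
    rule_id: str
    verdict: str  # predicted | not_predicted | unknown
    evidence: dict[str, str] = field(hash=False)  # pathway id -> status used


def load_rules(path: str | Path) -> list[PhenotypeRule]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RULE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: rules file missing column(s) {missing}")
    return [
        PhenotypeRule.from_text(
            r["rule_id"], r["phenotype_name"], r["category"], r["category_value"], r["expression"]
        )
        for _, r in df.iterrows()
    ]


def write_rules(rules: list[PhenotypeRule], path: str | Path) -> None:
    rows = [
        [r.rule_id, r.phenotype_name, r.category, r.category_value, r.expression.unparse()]
        for r in rules
    ]
    pd.DataFrame(rows, columns=RULE_COLS).to_csv(path, sep="\t", index=False)


def _statuses_by_genome(assertions: list[AssertionRecord]) -> dict[str, dict[str, TriState]]:
    out: dict[str, dict[str, TriState]] = {}
    for rec in assertions:
        out.setdefault(rec.genome_id, {})[rec.pathway_id] = STATUS_TO_TRISTATE[rec.status]
    return out


def predict_phenotypes(
    assertions: list[AssertionRecord],
    rules: list[PhenotypeRule],
    *,
    strict: bool = True,
) -> list[PhenotypePrediction]:
    """One prediction per (genome, rule).

    The manual pathway status ``absent`` enters evaluation as FALSE.  In
    lenient mode a pathway with no assertion record evaluates UNKNOWN and is
    recorded in the evidence as ``unmapped``.
    """
    by_genome = _statuses_by_genome(assertions)
    preds: list[PhenotypePrediction] = []
    for genome_id in by_genome:
        statuses = by_genome[genome_id]
        for rule in rules:
            missing: set[str] = set()
            value = evaluate_rule(rule.expression, statuses, strict=strict, missing=missing)
            verdict = VERDICT_OF.get(value, "unknown")
            evidence = {
                pid: ("unmapped" if pid in missing else statuses[pid].value)
                for pid in rule.expression.variables()
            }
            preds.append(PhenotypePrediction(genome_id, rule.rule_id, verdict, evidence))
    return preds


def predictions_to_frame(preds: list[PhenotypePrediction]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": p.genome_id,
            "rule_id": p.rule_id,
            "verdict": p.verdict,
            "evidence": ";".join(f"{k}={v}" for k, v in sorted(p.evidence.items())),
        }
        for p in preds
    ]
    return pd.DataFrame(rows, columns=PREDICTION_COLS)


# ---------------------------------------------------------------------------
# Metadata comparison and search


class SynonymMap:
    """Case-insensitive metadata-value equivalence classes."""

    def __init__(self, groups: tuple[tuple[str, ...], ...] = DEFAULT_SYNONYMS):
        self._canon: dict[str, str] = {}
        for group in groups:
            canon = group[0].strip().lower()
            for value in group:
                self._canon[value.strip().lower()] = canon

    def canonical(self, value: str) -> str:
        v = value.strip().lower()
        return self._canon.get(v, v)

    def match(self, a: str, b: str) -> bool:
        return self.canonical(a) == self.canonical(b)


def compare_with_metadata(
    predictions: list[PhenotypePrediction],
    rules: list[PhenotypeRule],
    metadata: pd.DataFrame,
    synonyms: SynonymMap | None = None,
) -> pd.DataFrame:
    """Classify each positive prediction against genome metadata.

    Returns a frame with columns genome_id, rule_id, category,
    predicted_value, metadata_value, result in {agree, conflict, no_metadata}.
    Attribute names are compared after whitespace trimming; values through
    the synonym map, case-insensitively.
    """
    synonyms = synonyms or SynonymMap()
    rule_by_id = {r.rule_id: r for r in rules}
    md: dict[tuple[str, str], list[str]] = {}
    for genome_id, attribute, value in metadata[["genome_id", "attribute", "value"]].values:
        md.setdefault((genome_id, str(attribute).strip()), []).append(str(value))
    rows = []
    for p in predictions:
        if p.verdict != "predicted":
            continue
        rule = rule_by_id[p.rule_id]
        values = md.get((p.genome_id, rule.category.strip()))
        if not values:
            result, observed = "no_metadata", ""
        else:
            agree = any(synonyms.match(v, rule.category_value) for v in values)
            result, observed = ("agree" if agree else "conflict"), ";".join(values)
        rows.append(
            {
                "genome_id": p.genome_id,
                "rule_id": p.rule_id,
                "category": rule.category,
                "predicted_value": rule.category_value,
                "metadata_value": observed,
                "result": result,
            }
        )
    cols = ["genome_id", "rule_id", "category", "predicted_value", "metadata_value", "result"]
    return pd.DataFrame(rows, columns=cols)


def parse_metadata_query(text: str) -> list[tuple[str, str]]:
    """Parse ``Attr=value AND Attr2=value2`` into clause pairs."""
    text = text.strip()
    if not text:
        return []
    clauses = []
    for chunk in re.split(r"\s+AND\s+", text, flags=re.IGNORECASE):
        if "=" not in chunk:
            raise ValueError(f"metadata query clause missing '=': {chunk!r}")
        attr, value = chunk.split("=", 1)
        clauses.append((attr.strip(), value.strip()))
    return clauses


def search_genomes_by_metadata(
    metadata: pd.DataFrame,
    query: str | list[tuple[str, str]],
    *,
    all_genomes: list[str] | None = None,
    synonyms: SynonymMap | None = None,
) -> list[str]:
    """Genomes satisfying every ``attribute=value`` clause (case-insensitive,
    synonym-normalized).  An empty query returns all genomes."""
    synonyms = synonyms or SynonymMap()
    clauses = parse_metadata_query(query) if isinstance(query, str) else list(query)
    universe = (
        list(all_genomes)
        if all_genomes is not None
        else sorted(set(metadata["genome_id"]))
    )
    if not clauses:
        return universe
    known_attrs = {str(a).strip().lower() for a in metadata["attribute"]}
    for attr, _ in clauses:
        if attr.strip().lower() not in known_attrs:
            logging.getLogger(__name__).warning("unknown metadata attribute: %s", attr)
    md: dict[str, dict[str, list[str]]] = {}
    for genome_id, attribute, value in metadata[["genome_id", "attribute", "value"]].values:
        md.setdefault(genome_id, {}).setdefault(str(attribute).strip().lower(), []).append(
            str(value)
        )
    out = []
    for g in universe:
        attrs = md.get(g, {})
        if all(
            any(synonyms.match(v, want) for v in attrs.get(attr.strip().lower(), []))
            for attr, want in clauses
        ):
            out.append(g)
    return out
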