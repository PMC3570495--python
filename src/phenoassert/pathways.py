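"""Pathway assertion: functional terms -> reactions -> pathways.

A reaction is present when any one of its alternative implementations is
present, where each alternative is an AND-set of required terms (all subunits
of a protein complex, plus any required substrate/product terms).  A pathway
is an ordered sequence of steps, each step an OR-set of alternative
reactions; it is *asserted* when every step has a present reaction.

Evaluation is three-valued: a term covered only by candidate genes is
UNKNOWN, so a pathway whose only gaps are candidate-covered comes out
*unknown* rather than *not asserted*.  Domain experts may override the
computed status with a manual ``asserted`` or ``absent``.

Definition files use a small line-oriented DSL::

    term T_0001 "glucose dehydrogenase, NADP-dependent" kind=protein_product
    reaction R_977 "D-glucose + NADP+ <=> ..." requires (T_0001) | (T_0002 & T_0003)
    pathway P_339 "6-phosphogluconate synthesis via gluconate" steps: [R_977|R_978|R_979|R_980] -> [R_981] -> [R_982]
    override genome=G_001 pathway=P_339 status=asserted
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .logic import FALSE, TRUE, UNKNOWN, TriState, tri_all, tri_any
from .store import AnnotationStore

TRISTATE_TO_STATUS = {TRUE: "asserted", FALSE: "not_asserted", UNKNOWN: "unknown"}


@dataclass(frozen=True)
class TermDefinition:
    term_id: str
    name: str
    kind: str = "protein_product"  # protein_product | modified_protein | protein_complex


@dataclass(frozen=True)
class ReactionDefinition:
    """OR over alternative implementations, each an AND-set of term ids."""

    reaction_id: str
    name: str
    requirements: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.requirements or any(not alt for alt in self.requirements):
            raise DefinitionError(
                f"reaction {self.reaction_id}: requirements must be non-empty"
            )

    def term_ids(self) -> set[str]:
        return set().union(*self.requirements)


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered steps; each step a non-empty set of alternative reaction ids."""

    pathway_id: str
    name: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps or any(not s for s in self.steps):
            raise DefinitionError(f"pathway {self.pathway_id}: steps must be non-empty")

    def reaction_ids(self) -> set[str]:
        return set().union(*self.steps)


@dataclass(frozen=True)
class Override:
    genome_id: str
    pathway_id: str
    status: str  # asserted | absent


@dataclass
class DefinitionSet:
    terms: dict[str, TermDefinition] = field(default_factory=dict)
    reactions: dict[str, ReactionDefinition] = field(default_factory=dict)
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)
    overrides: list[Override] = field(default_factory=list)

    def override_for(self, genome_id: str, pathway_id: str) -> Override | None:
        # last matching override wins
        found = None
        for ov in self.overrides:
            if ov.genome_id == genome_id and ov.pathway_id == pathway_id:
                found = ov
        return found

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for term_id in sorted(rxn.term_ids()):
                if term_id not in self.terms:
                    raise DefinitionError(
                        f"reaction {rxn.reaction_id} references undefined term {term_id}"
                    )
        for pwy in self.pathways.values():
            for rid in sorted(pwy.reaction_ids()):
                if rid not in self.reactions:
                    raise DefinitionError(
                        f"pathway {pwy.pathway_id} references undefined reaction {rid}"
                    )
        for ov in self.overrides:
            if ov.pathway_id not in self.pathways:
                raise DefinitionError(
                    f"override references undefined pathway {ov.pathway_id}"
                )
            if ov.status not in ("asserted", "absent"):
                raise DefinitionError(
                    f"override status must be 'asserted' or 'absent', got {ov.status!r}"
                )


class DefinitionError(ValueError):
    """Malformed or referentially broken definition file."""


_TERM_RE = re.compile(
    r'^term\s+(?P<id>\S+)\s+"(?P<name>[^"]*)"(?:\s+kind=(?P<kind>\S+))?\s*$'
)
_REACTION_RE = re.compile(
    r'^reaction\s+(?P<id>\S+)\s+"(?P<name>[^"]*)"\s+requires\s+(?P<req>.+)$'
)
_PATHWAY_RE = re.compile(
    r'^pathway\s+(?P<id>\S+)\s+"(?P<name>[^"]*)"\s+steps:\s*(?P<steps>.+)$'
)
_OVERRIDE_RE = re.compile(
    r"^override\s+genome=(?P<genome>\S+)\s+pathway=(?P<pathway>\S+)\s+status=(?P<status>\S+)\s*$"
)


def _parse_requirements(text: str, lineno: int) -> tuple[frozenset[str], ...]:
    alts = []
    for chunk in text.split("|"):
        chunk = chunk.strip()
        if not (chunk.startswith("(") and chunk.endswith(")")):
            raise DefinitionError(
                f"line {lineno}: each requirement alternative must be parenthesized: {chunk!r}"
            )
        terms = [t.strip() for t in chunk[1:-1].split("&")]
        if any(not t for t in terms):
            raise DefinitionError(f"line {lineno}: empty term id in requirement {chunk!r}")
        alts.append(frozenset(terms))
    return tuple(alts)


def _parse_steps(text: str, lineno: int) -> tuple[frozenset[str], ...]:
    steps = []
    for chunk in text.split("->"):
        chunk = chunk.strip()
        if not (chunk.startswith("[") and chunk.endswith("]")):
            raise DefinitionError(
                f"line {lineno}: each step must be bracketed, e.g. [R_1|R_2]: {chunk!r}"
            )
        rids = [r.strip() for r in chunk[1:-1].split("|")]
        if any(not r for r in rids):
            raise DefinitionError(f"line {lineno}: empty reaction id in step {chunk!r}")
        steps.append(frozenset(rids))
    return tuple(steps)


def parse_definitions(source: str | Path) -> DefinitionSet:
    """Parse a definition file (path) or definition text into a DefinitionSet.

    Raises :class:`DefinitionError` with the offending line number on parse
    failure, and on dangling pathway->reaction->term references.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    defs = DefinitionSet()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("term "):
            m = _TERM_RE.match(line)
            if not m:
                raise DefinitionError(f"line {lineno}: malformed term line: {line!r}")
            kind = m.group("kind") or "protein_product"
            if kind not in ("protein_product", "modified_protein", "protein_complex"):
                raise DefinitionError(f"line {lineno}: unknown term kind {kind!r}")
            defs.terms[m.group("id")] = TermDefinition(m.group("id"), m.group("name"), kind)
        elif line.startswith("reaction "):
            m = _REACTION_RE.match(line)
            if not m:
                raise DefinitionError(f"line {lineno}: malformed reaction line: {line!r}")
            defs.reactions[m.group("id")] = ReactionDefinition(
                m.group("id"), m.group("name"), _parse_requirements(m.group("req"), lineno)
            )
        elif line.startswith("pathway "):
            m = _PATHWAY_RE.match(line)
            if not m:
                raise DefinitionError(f"line {lineno}: malformed pathway line: {line!r}")
            defs.pathways[m.group("id")] = PathwayDefinition(
                m.group("id"), m.group("name"), _parse_steps(m.group("steps"), lineno)
            )
        elif line.startswith("override "):
            m = _OVERRIDE_RE.match(line)
            if not m:
                raise DefinitionError(f"line {lineno}: malformed override line: {line!r}")
            defs.overrides.append(
                Override(m.group("genome"), m.group("pathway"), m.group("status"))
            )
        else:
            raise DefinitionError(f"line {lineno}: unrecognized directive: {line!r}")
    defs.validate()
    return defs


# ---------------------------------------------------------------------------
# Status evaluation


def _term_state_maps(store: AnnotationStore) -> tuple[dict, dict]:
    """(genome, term) -> confirmed gene set / candidate-only flag."""
    confirmed: dict[tuple[str, str], set[str]] = {}
    candidate: dict[tuple[str, str], set[str]] = {}
    genome_of = store.genome_of_map()
    for gene_id, term_id, prov in store.term_assignments[
        ["gene_id", "term_id", "provenance"]
    ].values:
        key = (genome_of[gene_id], term_id)
        if prov == "candidate":
            candidate.setdefault(key, set()).add(gene_id)
        else:
            confirmed.setdefault(key, set()).add(gene_id)
    return confirmed, candidate


class PathwayEngine:
    """Evaluates term, reaction and pathway statuses for one store."""

    def __init__(self, store: AnnotationStore, definitions: DefinitionSet):
        self.store = store
        self.definitions = definitions
        self._confirmed, self._candidate = _term_state_maps(store)

    def term_status(self, genome_id: str, term_id: str) -> TriState:
        """TRUE if a confirmed gene carries the term in this genome, UNKNOWN
        if only candidate genes do, else FALSE."""
        if term_id not in self.definitions.terms:
            raise DefinitionError(f"unknown term id {term_id!r}")
        if self._confirmed.get((genome_id, term_id)):
            return TRUE
        if self._candidate.get((genome_id, term_id)):
            return UNKNOWN
        return FALSE

    def reaction_status(self, genome_id: str, reaction_id: str) -> TriState:
        rxn = self.definitions.reactions.get(reaction_id)
        if rxn is None:
            raise DefinitionError(f"unknown reaction id {reaction_id!r}")
        return tri_any(
            tri_all(self.term_status(genome_id, t) for t in sorted(alt))
            for alt in rxn.requirements
        )

    def pathway_status(self, genome_id: str, pathway_id: str) -> TriState:
        pwy = self.definitions.pathways.get(pathway_id)
        if pwy is None:
            raise DefinitionError(f"unknown pathway id {pathway_id!r}")
        return tri_all(
            tri_any(self.reaction_status(genome_id, r) for r in sorted(step))
            for step in pwy.steps
        )

    def assert_pathway(self, genome_id: str, pathway_id: str) -> "AssertionRecord":
        pwy = self.definitions.pathways.get(pathway_id)
        if pwy is None:
            raise DefinitionError(f"unknown pathway id {pathway_id!r}")
        computed = TRISTATE_TO_STATUS[self.pathway_status(genome_id, pathway_id)]
        evidence = []
        for step in pwy.steps:
            step_terms = sorted(
                set().union(*(self.definitions.reactions[r].term_ids() for r in step))
            )
            satisfied = [t for t in step_terms if self.term_status(genome_id, t) is TRUE]
            cand = [t for t in step_terms if self.term_status(genome_id, t) is UNKNOWN]
            missing = [t for t in step_terms if self.term_status(genome_id, t) is FALSE]
            evidence.append(StepEvidence(satisfied, cand, missing))
        ov = self.definitions.override_for(genome_id, pathway_id)
        if ov is not None:
            return AssertionRecord(genome_id, pathway_id, ov.status, "manual", evidence)
        return AssertionRecord(genome_id, pathway_id, computed, "computed", evidence)

    def assert_all(
        self,
        genomes: list[str] | None = None,
        pathways: list[str] | None = None,
    ) -> list["AssertionRecord"]:
        genomes = genomes if genomes is not None else self.store.genomes["genome_id"].tolist()
        pathways = pathways if pathways is not None else list(self.definitions.pathways)
        return [self.assert_pathway(g, p) for g in genomes for p in pathways]

    def pathway_profile(
        self, genomes: list[str], pathways: list[str]
    ) -> "PathwayProfile":
        """Genome x pathway matrix of (status, distinct-gene count)."""
        status = pd.DataFrame(index=genomes, columns=pathways, dtype=object)
        counts = pd.DataFrame(0, index=genomes, columns=pathways, dtype=int)
        for p in pathways:
            pwy = self.definitions.pathways.get(p)
            if pwy is None:
                raise DefinitionError(f"unknown pathway id {p!r}")
            terms = set().union(
                *(self.definitions.reactions[r].term_ids() for r in pwy.reaction_ids())
            )
            for g in genomes:
                rec = self.assert_pathway(g, p)
                status.loc[g, p] = rec.status
                genes: set[str] = set()
                for t in terms:
                    genes |= self._confirmed.get((g, t), set())
                counts.loc[g, p] = len(genes)
        return PathwayProfile(status=status, gene_counts=counts)


@dataclass
class StepEvidence:
    satisfied_terms: list[str]
    candidate_terms: list[str]
    missing_terms: list[str]


@dataclass
class AssertionRecord:
    genome_id: str
    pathway_id: str
    status: str  # asserted | unknown | not_asserted | absent
    source: str  # computed | manual
    evidence: list[StepEvidence]

    def __post_init__(self) -> None:
        if self.status == "absent" and self.source != "manual":
            raise ValueError("status 'absent' requires source='manual'")

    @property
    def missing_terms(self) -> list[str]:
        out: list[str] = []
        for step in self.evidence:
            out.extend(t for t in step.missing_terms if t not in out)
        return out

    @property
    def candidate_terms(self) -> list[str]:
        out: list[str] = []
        for step in self.evidence:
            out.extend(t for t in step.candidate_terms if t not in out)
        return out


@dataclass
class PathwayProfile:
    status: pd.DataFrame
    gene_counts: pd.DataFrame

    def cell(self, genome_id: str, pathway_id: str) -> tuple[str, int]:
        return (
            self.status.loc[genome_id, pathway_id],
            int(self.gene_counts.loc[genome_id, pathway_id]),
        )


def assertions_to_frame(records: list[AssertionRecord]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": r.genome_id,
            "pathway_id": r.pathway_id,
            "status": r.status,
            "source": r.source,
            "missing_terms": ",".join(r.missing_terms),
            "candidate_terms": ",".join(r.candidate_terms),
        }
        for r in records
    ]
    cols = ["genome_id", "pathway_id", "status", "source", "missing_terms", "candidate_terms"]
    return pd.DataFrame(rows, columns=cols)
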