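"""Draft reconstruction from expression evidence, and gap analysis.

The draft step mirrors the classic expression-based extraction: a reference
reaction database (standing in for a curated human metabolic atlas) is
filtered by gene presence calls through each reaction's GPR rule, with the
usual boolean semantics — ``and`` means an enzyme complex (all subunits
required), ``or`` means isozymes (any suffices).  Completion then copies
transport and exchange reactions from the reference so that compartments are
connected, and the gap analysis finds dead-end metabolites: species that no
reaction, within its current bounds, can net-produce or net-consume.

Gap resolution is deterministic rather than manual: candidate repair
reactions are ranked by how few new metabolites they would introduce (ties
broken by reaction id), with acceptance left to the caller or the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    classify_reaction,
    metabolite_graph,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression evidence
# ---------------------------------------------------------------------------


@dataclass
class ExpressionEvidence:
    """Gene presence calls, optionally with intensity scores."""

    calls: Dict[str, bool] = field(default_factory=dict)
    scores: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "ExpressionEvidence":
        """Accepts {gene: bool}, {gene: score}, or {gene: {present, score}}."""
        calls: Dict[str, bool] = {}
        scores: Dict[str, float] = {}
        for gene, value in data.items():
            if not gene:
                raise ValueError("empty gene id in evidence")
            if isinstance(value, Mapping):
                if "present" in value:
                    calls[gene] = bool(value["present"])
                if "score" in value:
                    scores[gene] = float(value["score"])
            elif isinstance(value, bool):
                calls[gene] = value
            else:
                scores[gene] = float(value)
        return cls(calls=calls, scores=scores)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionEvidence":
        """Two-column TSV: gene, call-or-score (1/0/true/false or a number)."""
        data: Dict[str, object] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cells = line.split("\t")
                if len(cells) < 2:
                    raise ValueError(f"bad evidence row: {line!r}")
                gene, raw = cells[0].strip(), cells[1].strip()
                low = raw.lower()
                if low in {"true", "false"}:
                    data[gene] = low == "true"
                else:
                    data[gene] = float(raw)
        return cls.from_mapping(data)

    def present_genes(self, threshold: Optional[float] = None) -> Set[str]:
        """Presence set: score >= threshold if a threshold is given, else the calls.

        No default threshold is claimed: when working from intensity scores
        the caller must choose one explicitly.
        """
        if threshold is not None:
            return {g for g, s in self.scores.items() if s >= threshold}
        return {g for g, c in self.calls.items() if c}


# ---------------------------------------------------------------------------
# GPR evaluation (recursive descent over and/or/parentheses)
# ---------------------------------------------------------------------------


class GPRSyntaxError(ValueError):
    pass


def _tokenize(gpr: str) -> List[str]:
    out: List[str] = []
    token = ""
    for ch in gpr:
        if ch in "()":
            if token:
                out.append(token)
                token = ""
            out.append(ch)
        elif ch.isspace():
            if token:
                out.append(token)
                token = ""
        else:
            token += ch
    if token:
        out.append(token)
    return out


def evaluate_gpr(gpr: str, present: Set[str]) -> bool:
    """Evaluate a GPR rule under a set of present genes.

    ``and`` = complex (all required), ``or`` = isozymes (any).  Genes not in
    ``present`` — including genes never measured — count as absent.  An
    empty rule evaluates False (no gene support).
    """
    tokens = _tokenize(gpr or "")
    if not tokens:
        return False
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> bool:
        value = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            value = parse_and() or value
        return value

    def parse_and() -> bool:
        value = parse_atom()
        while peek() is not None and peek().lower() == "and":
            take()
            value = parse_atom() and value
        return value

    def parse_atom() -> bool:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR {gpr!r}")
        if tok == "(":
            take()
            value = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR {gpr!r}")
            take()
            return value
        if tok == ")" or tok.lower() in {"and", "or"}:
            raise GPRSyntaxError(f"misplaced token {tok!r} in GPR {gpr!r}")
        return take() in present

    result = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR {gpr!r}")
    return result


# ---------------------------------------------------------------------------
# Reference reaction database
# ---------------------------------------------------------------------------


class ReferenceReactionDB:
    """Reaction database indexed by metabolite for producer/consumer lookup."""

    def __init__(self, model: MetabolicModel) -> None:
        self.model = model
        self._producers: Dict[str, List[str]] = {}
        self._consumers: Dict[str, List[str]] = {}
        for rid, rxn in model.reactions.items():
            for mid, coef in rxn.stoichiometry.items():
                can_produce = (coef > 0 and rxn.upper_bound > 0) or (
                    coef < 0 and rxn.lower_bound < 0
                )
                can_consume = (coef < 0 and rxn.upper_bound > 0) or (
                    coef > 0 and rxn.lower_bound < 0
                )
                if can_produce:
                    self._producers.setdefault(mid, []).append(rid)
                if can_consume:
                    self._consumers.setdefault(mid, []).append(rid)

    def __len__(self) -> int:
        return len(self.model.reactions)

    def producers_of(self, metabolite_id: str) -> List[str]:
        return list(self._producers.get(metabolite_id, []))

    def consumers_of(self, metabolite_id: str) -> List[str]:
        return list(self._consumers.get(metabolite_id, []))

    def reaction(self, rid: str) -> Reaction:
        return self.model.reactions[rid]


def _copy_reaction_into(model: MetabolicModel, source: MetabolicModel, rid: str) -> None:
    rxn = source.reactions[rid]
    for mid in rxn.stoichiometry:
        if mid not in model.metabolites:
            met = source.metabolites.get(mid)
            model.add_metabolite(
                Metabolite(mid, met.name, met.compartment, met.formula, met.charge)
                if met is not None
                else Metabolite(mid, mid, mid.rsplit("__", 1)[-1] if "__" in mid else "c")
            )
    model.add_reaction(Reaction(
        rid, dict(rxn.stoichiometry), name=rxn.name,
        lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
        gpr=rxn.gpr, ec_numbers=list(rxn.ec_numbers), subsystem=rxn.subsystem,
    ))


# ---------------------------------------------------------------------------
# Stage 1: expression-based draft extraction
# ---------------------------------------------------------------------------


def extract_draft_network(
    evidence: ExpressionEvidence,
    db: ReferenceReactionDB,
    threshold: Optional[float] = None,
) -> MetabolicModel:
    """Draft model: every reference reaction whose GPR is satisfied.

    A reaction is included iff it carries a GPR and the rule evaluates true
    under the presence calls (or the score threshold, if one is given).
    Reactions without gene association are excluded at this stage; the
    completion step adds transport/exchange connectivity afterwards.  Genes
    mentioned in GPRs but absent from the evidence are treated as absent and
    logged.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    present = evidence.present_genes(threshold)
    known = set(evidence.calls) | set(evidence.scores)
    draft = MetabolicModel(compartments=db.model.compartments, name="draft")
    unmeasured: Set[str] = set()
    for rid, rxn in db.model.reactions.items():
        if not rxn.gpr.strip():
            continue
        genes = set(rxn.genes())
        unmeasured |= genes - known
        if evaluate_gpr(rxn.gpr, present):
            _copy_reaction_into(draft, db.model, rid)
    if unmeasured:
        logger.info(
            "%d GPR genes had no expression evidence and were treated as absent: %s",
            len(unmeasured), ", ".join(sorted(unmeasured)[:10]),
        )
    return draft


# ---------------------------------------------------------------------------
# Stage 2a: connectivity completion
# ---------------------------------------------------------------------------


def add_transport_and_exchange(
    model: MetabolicModel,
    db: ReferenceReactionDB,
    condition=None,
) -> Tuple[MetabolicModel, List[Dict[str, str]]]:
    """Copy connecting transport reactions and create condition exchanges.

    For every chemical species present in two or more compartments with no
    connecting transport in the model, a transport is copied from the
    reference if one exists (unconnectable pairs are logged).  Every
    extracellular metabolite named by the active condition (all of them, if
    no condition is given) gains an exchange reaction.  Additions carry the
    provenance tag ``completion`` in the returned log.  Running the
    operation on an already-connected model is a no-op.
    """
    out = model.copy()
    log: List[Dict[str, str]] = []

    def species_comps(m: MetabolicModel) -> Dict[str, Set[str]]:
        comps: Dict[str, Set[str]] = {}
        for met in m.metabolites.values():
            if met.compartment == "b":
                continue
            comps.setdefault(m.species_of(met.id), set()).add(met.compartment)
        return comps

    def connected_pairs(m: MetabolicModel) -> Set[Tuple[str, str, str]]:
        pairs: Set[Tuple[str, str, str]] = set()
        for rid in m.reactions:
            if classify_reaction(m, rid) != "transport":
                continue
            by_species: Dict[str, Set[str]] = {}
            for mid in m.reactions[rid].stoichiometry:
                met = m.metabolites.get(mid)
                if met is None:
                    continue
                by_species.setdefault(m.species_of(mid), set()).add(met.compartment)
            for sp, comps in by_species.items():
                comp_list = sorted(comps)
                for i, a in enumerate(comp_list):
                    for b in comp_list[i + 1:]:
                        pairs.add((sp, a, b))
        return pairs

    have = connected_pairs(out)
    db_pairs = connected_pairs(db.model)
    for species, comps in sorted(species_comps(out).items()):
        comp_list = sorted(comps)
        for i, a in enumerate(comp_list):
            for b_ in comp_list[i + 1:]:
                if (species, a, b_) in have:
                    continue
                # find a db transport connecting this pair
                candidates = sorted(
                    rid for rid in set(db.producers_of(f"{species}__{b_}"))
                    | set(db.consumers_of(f"{species}__{b_}"))
                    if (species, a, b_) in connected_pairs_of(db.model, rid)
                )
                if candidates:
                    rid = candidates[0]
                    if rid not in out.reactions:
                        _copy_reaction_into(out, db.model, rid)
                        log.append({"action": "add_transport", "id": rid,
                                    "species": species, "tag": "completion"})
                        have.add((species, a, b_))
                else:
                    log.append({"action": "unconnectable", "id": "",
                                "species": f"{species} [{a}<->{b_}]",
                                "tag": "completion"})

    # exchanges for extracellular species named by the condition
    wanted: Iterable[str]
    if condition is not None:
        wanted = [
            rid[3:] for rid in condition.overrides if rid.startswith("EX_")
        ]
    else:
        wanted = [
            out.species_of(m.id)
            for m in out.metabolites.values()
            if m.compartment == "x"
        ]
    for species in sorted(set(wanted)):
        mid = f"{species}__x"
        if mid not in out.metabolites:
            continue
        ex_id = f"EX_{species}"
        if ex_id in out.reactions:
            continue
        # any existing exchange touching this metabolite?
        if any(
            mid in out.reactions[rid].stoichiometry
            and classify_reaction(out, rid) == "exchange"
            for rid in out.reactions
        ):
            continue
        out.add_reaction(Reaction(
            ex_id, {mid: -1.0}, name=f"{species} exchange",
            lower_bound=-1000.0, upper_bound=1000.0, subsystem="exchange",
        ))
        log.append({"action": "add_exchange", "id": ex_id,
                    "species": species, "tag": "completion"})
    return out, log


def connected_pairs_of(model: MetabolicModel, rid: str) -> Set[Tuple[str, str, str]]:
    """(species, compartment a, compartment b) pairs connected by one reaction."""
    pairs: Set[Tuple[str, str, str]] = set()
    by_species: Dict[str, Set[str]] = {}
    for mid in model.reactions[rid].stoichiometry:
        met = model.metabolites.get(mid)
        if met is None:
            continue
        by_species.setdefault(model.species_of(mid), set()).add(met.compartment)
    for sp, comps in by_species.items():
        comp_list = sorted(comps)
        for i, a in enumerate(comp_list):
            for b in comp_list[i + 1:]:
                pairs.add((sp, a, b))
    return pairs


# ---------------------------------------------------------------------------
# Stage 2b: dead-end detection
# ---------------------------------------------------------------------------


@dataclass
class DeadEndEntry:
    metabolite: str
    kind: str  # never_produced | never_consumed | disconnected
    reactions: List[str]


@dataclass
class DeadEndReport:
    entries: List[DeadEndEntry]
    summary: Dict[str, int]
    model_metabolites: Set[str] = field(default_factory=set)

    @property
    def metabolites(self) -> List[str]:
        return [e.metabolite for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def find_dead_ends(model: MetabolicModel) -> DeadEndReport:
    """Bound-aware dead-end detection.

    A metabolite is ``never_produced`` when no reaction can achieve positive
    net production within its bounds (a reversible reaction serves both
    roles; a reaction fixed to zero serves neither), ``never_consumed``
    symmetrically, and ``disconnected`` when its connected component
    contains no exchange reaction.  Classes are mutually exclusive in that
    priority order.  Output is sorted by metabolite id.
    """
    producible: Dict[str, bool] = {}
    consumable: Dict[str, bool] = {}
    touching: Dict[str, List[str]] = {}
    for mid, met in model.metabolites.items():
        if met.compartment == "b":
            continue
        producible[mid] = False
        consumable[mid] = False
        touching[mid] = []
    for rid, rxn in model.reactions.items():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if mid not in producible:
                continue
            touching[mid].append(rid)
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producible[mid] = True
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumable[mid] = True

    # components without an exchange reaction; in a model with no exchanges
    # at all the notion of an isolated fragment is vacuous, so nothing is
    # flagged as disconnected there
    graph = metabolite_graph(model)
    exchange_mets: Set[str] = set()
    for rid in model.reactions:
        if classify_reaction(model, rid) == "exchange":
            exchange_mets.update(
                m for m in model.reactions[rid].stoichiometry if m in producible
            )
    component_ok: Dict[str, bool] = {}
    if exchange_mets:
        for comp in nx.connected_components(graph):
            ok = bool(comp & exchange_mets)
            for mid in comp:
                component_ok[mid] = ok

    entries: List[DeadEndEntry] = []
    for mid in sorted(producible):
        if not producible[mid]:
            kind = "never_produced"
        elif not consumable[mid]:
            kind = "never_consumed"
        elif not component_ok.get(mid, True):
            kind = "disconnected"
        else:
            continue
        entries.append(DeadEndEntry(mid, kind, sorted(touching[mid])))
    summary: Dict[str, int] = {}
    for e in entries:
        summary[e.kind] = summary.get(e.kind, 0) + 1
    return DeadEndReport(
        entries=entries,
        summary=summary,
        model_metabolites=set(producible),
    )


# ---------------------------------------------------------------------------
# Stage 2c: gap-fill suggestions
# ---------------------------------------------------------------------------


@dataclass
class GapFillSuggestion:
    metabolite: str
    kind: str
    candidates: List[Tuple[str, int]]  # (reaction id, new metabolites introduced)
    reason: str = ""


def suggest_gap_fills(
    report: DeadEndReport,
    db: ReferenceReactionDB,
    max_candidates: int = 5,
) -> List[GapFillSuggestion]:
    """Ranked repair candidates for each dead-end.

    For a ``never_consumed`` metabolite candidates must be able to consume
    it (within the reference reaction's bounds); for ``never_produced``, to
    produce it; a ``disconnected`` metabolite accepts either.  Candidates
    are ranked by the number of metabolites they would newly introduce into
    the model (ascending), ties broken lexicographically by reaction id.
    """
    out: List[GapFillSuggestion] = []
    known = report.model_metabolites
    for entry in report.entries:
        if entry.kind == "never_consumed":
            pool = db.consumers_of(entry.metabolite)
        elif entry.kind == "never_produced":
            pool = db.producers_of(entry.metabolite)
        else:
            pool = sorted(
                set(db.consumers_of(entry.metabolite))
                | set(db.producers_of(entry.metabolite))
            )
        scored: List[Tuple[int, str]] = []
        for rid in set(pool):
            rxn = db.reaction(rid)
            new_mets = sum(1 for m in rxn.stoichiometry if m not in known)
            scored.append((new_mets, rid))
        scored.sort()
        if scored:
            out.append(GapFillSuggestion(
                metabolite=entry.metabolite,
                kind=entry.kind,
                candidates=[(rid, score) for score, rid in scored[:max_candidates]],
            ))
        else:
            out.append(GapFillSuggestion(
                metabolite=entry.metabolite,
                kind=entry.kind,
                candidates=[],
                reason="no producing or consuming reaction in the reference database",
            ))
    return out


def apply_gap_fill(model: MetabolicModel, db: ReferenceReactionDB, rid: str) -> MetabolicModel:
    """Copy one accepted repair reaction into a model (returns a new model)."""
    out = model.copy()
    _copy_reaction_into(out, db.model, rid)
    return out
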