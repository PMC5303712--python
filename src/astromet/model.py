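"""Core domain objects for compartmentalised metabolic networks.

The central object is :class:`MetabolicModel`: an ordered list of reactions
over a set of compartmentalised metabolites, with flux bounds, gene–protein–
reaction (GPR) boolean rules, EC annotations and pathway labels.  Everything
downstream (draft extraction, gap analysis, FBA, sampling) transforms or
interrogates this object.

Conventions
-----------
* Stoichiometric coefficients are signed: negative = consumed, positive =
  produced.  ``S[i, j]`` is the coefficient of metabolite *i* in reaction *j*.
* Metabolites in the ``b`` (boundary) pseudo-compartment are excluded from
  mass balance, so exchange reactions written against them are imbalanced by
  construction.  Exchange reactions may equivalently be written one-sided
  (``glc[x] <=>`` with no products), which is how the built-in generator
  writes them.
* Exchange flux sign: positive = secretion to the boundary, negative =
  uptake.  An uptake capacity *r* therefore appears as a lower bound of −r.
* Default bounds where a format does not carry them: irreversible
  ``[0, 1000]``, reversible ``[-1000, 1000]`` μmol/g tissue/min.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import networkx as nx
from scipy import sparse

DEFAULT_BOUND = 1000.0

#: Default compartment table.  ``x`` is extracellular (the convention used
#: throughout astrocyte modelling, e.g. "Glutamate[x]"); note that other
#: reconstruction lineages use ``x`` for peroxisome, so the table is
#: configuration, not a constant of nature.
DEFAULT_COMPARTMENTS: Dict[str, str] = {
    "c": "cytosol",
    "m": "mitochondria",
    "x": "extracellular",
    "r": "endoplasmic reticulum",
    "g": "Golgi apparatus",
    "l": "lysosome",
    "p": "peroxisome",
    "n": "nucleus",
    "b": "boundary",
}

BOUNDARY_COMPARTMENT = "b"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

EC_CLASS_NAMES = {
    "1": "oxidoreductases",
    "2": "transferases",
    "3": "hydrolases",
    "4": "lyases",
    "5": "isomerases",
    "6": "ligases",
    "7": "translocases",
}


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into a counts dict."""
    if not formula:
        return {}
    counts: Dict[str, int] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        element, num = match.groups()
        counts[element] += int(num) if num else 1
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return dict(counts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def elements(self) -> Dict[str, int]:
        return parse_formula(self.formula) if self.formula else {}


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and annotations.

    ``stoichiometry`` maps metabolite id -> signed coefficient.  ``gpr`` is a
    boolean expression over gene ids using ``and``/``or`` and parentheses
    (COBRA convention: ``and`` = complex, ``or`` = isozymes).
    """

    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    ec_numbers: List[str] = field(default_factory=list)
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    def reactants(self) -> Dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> Dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def genes(self) -> List[str]:
        return gpr_genes(self.gpr)


_GPR_SPLIT = re.compile(r"\(|\)|\band\b|\bor\b|\bAND\b|\bOR\b")


def gpr_genes(gpr: str) -> List[str]:
    """Distinct gene ids mentioned in a GPR string, in order of appearance."""
    seen: Dict[str, None] = {}
    for token in _GPR_SPLIT.split(gpr or ""):
        token = token.strip()
        if token:
            seen.setdefault(token)
    return list(seen)


class ModelError(ValueError):
    """Raised for structural problems that make a model unusable."""


class MetabolicModel:
    """Compartmentalised metabolic network.

    Reactions keep their insertion order (column order of the stoichiometric
    matrix); metabolites are kept in a dict keyed by id.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        compartments: Optional[Mapping[str, str]] = None,
        name: str = "",
    ) -> None:
        self.name = name
        self.compartments: Dict[str, str] = dict(compartments or DEFAULT_COMPARTMENTS)
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ModelError(f"reaction {rxn.id!r} has empty stoichiometry")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        out = MetabolicModel(compartments=self.compartments, name=self.name)
        for met in self.metabolites.values():
            out.add_metabolite(Metabolite(met.id, met.name, met.compartment, met.formula, met.charge))
        for rxn in self.reactions.values():
            out.add_reaction(
                Reaction(
                    rxn.id,
                    dict(rxn.stoichiometry),
                    rxn.name,
                    rxn.lower_bound,
                    rxn.upper_bound,
                    rxn.gpr,
                    list(rxn.ec_numbers),
                    rxn.subsystem,
                )
            )
        return out

    # -- derived views ----------------------------------------------------
    @property
    def genes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for rxn in self.reactions.values():
            for g in rxn.genes():
                seen.setdefault(g)
        return list(seen)

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    def species_of(self, metabolite_id: str) -> str:
        """Compartment-free chemical species name of a metabolite id.

        The generator and the TSV dialect use ``<species>__<compartment>``
        ids; ids without the separator are their own species.
        """
        if "__" in metabolite_id:
            return metabolite_id.rsplit("__", 1)[0]
        return metabolite_id

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MetabolicModel {self.name or 'unnamed'}: "
            f"{len(self.reactions)} reactions, {len(self.metabolites)} metabolites>"
        )


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Sparse stoichiometric matrix S (m non-boundary metabolites × n reactions)."""

    S: sparse.csc_matrix
    row_index: Dict[str, int]
    col_index: Dict[str, int]

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def column(self, reaction_id: str) -> Dict[str, float]:
        j = self.col_index[reaction_id]
        col = self.S.getcol(j).tocoo()
        rows = {i: met for met, i in self.row_index.items()}
        return {rows[i]: v for i, v in zip(col.row, col.data)}


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S from a model; boundary metabolites are excluded from rows."""
    mets = [
        m.id
        for m in model.metabolites.values()
        if m.compartment != BOUNDARY_COMPARTMENT
    ]
    row_index = {mid: i for i, mid in enumerate(mets)}
    col_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows: List[int] = []
    cols: List[int] = []
    data: List[float] = []
    for rid, rxn in model.reactions.items():
        j = col_index[rid]
        for mid, coef in rxn.stoichiometry.items():
            i = row_index.get(mid)
            if i is not None and coef != 0.0:
                rows.append(i)
                cols.append(j)
                data.append(float(coef))
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(row_index), len(col_index))
    )
    return StoichiometricMatrix(S=S, row_index=row_index, col_index=col_index)


# ---------------------------------------------------------------------------
# Classification and composition summaries
# ---------------------------------------------------------------------------


def classify_reaction(model: MetabolicModel, reaction_id: str) -> str:
    """Classify a reaction as ``exchange``, ``transport`` or ``internal``.

    Exchange: touches a boundary-compartment metabolite, or has metabolites
    on only one side (a system-boundary pseudo-reaction).  Transport: moves
    the same chemical species between ≥2 compartments.  Everything else is
    internal.
    """
    try:
        rxn = model.reactions[reaction_id]
    except KeyError:
        raise KeyError(f"unknown reaction id {reaction_id!r}") from None
    comps_by_species: Dict[str, set] = defaultdict(set)
    has_boundary = False
    has_reactant = has_product = False
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolites.get(mid)
        comp = met.compartment if met is not None else "?"
        if comp == BOUNDARY_COMPARTMENT:
            has_boundary = True
        if coef < 0:
            has_reactant = True
        elif coef > 0:
            has_product = True
        comps_by_species[model.species_of(mid)].add(comp)
    if has_boundary or not (has_reactant and has_product):
        return "exchange"
    if any(len(comps) >= 2 for comps in comps_by_species.values()):
        return "transport"
    return "internal"


@dataclass
class CompositionSummary:
    """Composition breakdowns of a model (percentages and per-compartment counts)."""

    by_ec_class: Dict[str, float]
    by_kind: Dict[str, float]
    by_compartment: Dict[str, Dict[str, int]]
    by_subsystem: Dict[str, float]
    n_reactions: int = 0
    n_metabolites: int = 0
    n_genes: int = 0
    n_unique_species: int = 0
    n_distinct_ec: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"reactions: {self.n_reactions}",
            f"metabolites (compartmentalised, non-boundary): {self.n_metabolites}",
            f"unique chemical species: {self.n_unique_species}",
            f"genes: {self.n_genes}",
            f"distinct EC numbers: {self.n_distinct_ec}",
            "EC class percentages (of EC-annotated reactions):",
        ]
        for k, v in sorted(self.by_ec_class.items()):
            lines.append(f"  {k}: {v:.1f}%")
        lines.append("reaction kinds:")
        for k, v in sorted(self.by_kind.items()):
            lines.append(f"  {k}: {v:.1f}%")
        return "\n".join(lines)


def summarize_composition(model: MetabolicModel) -> CompositionSummary:
    """Composition summary: EC-class, kind/gene-association, compartment, pathway.

    EC-class percentages are computed over reactions carrying at least one EC
    number, so the class percentages always sum to ~100 regardless of how
    many reactions are unannotated (spontaneous, transport, exchange).
    """
    n = len(model.reactions)
    ec_counter: Counter = Counter()
    kind_counter: Counter = Counter()
    sub_counter: Counter = Counter()
    gene_assoc = 0
    distinct_ec = set()
    for rid, rxn in model.reactions.items():
        kind_counter[classify_reaction(model, rid)] += 1
        if rxn.gpr.strip():
            gene_assoc += 1
        if rxn.subsystem:
            sub_counter[rxn.subsystem] += 1
        classes = set()
        for ec in rxn.ec_numbers:
            distinct_ec.add(ec)
            top = ec.split(":")[-1].split(".")[0]
            if top in EC_CLASS_NAMES:
                classes.add(EC_CLASS_NAMES[top])
        for cls in classes:
            ec_counter[cls] += 1

    n_ec = sum(ec_counter.values())
    if n_ec == 0 and n > 0:
        warnings.warn("model has no EC annotations; by_ec_class is empty")
    by_ec = {k: 100.0 * v / n_ec for k, v in ec_counter.items()} if n_ec else {}
    by_kind = {k: 100.0 * v / n for k, v in kind_counter.items()} if n else {}
    if n:
        by_kind["gene_associated"] = 100.0 * gene_assoc / n
        by_kind["non_gene_associated"] = 100.0 * (n - gene_assoc) / n
    by_sub = {k: 100.0 * v / n for k, v in sub_counter.items()} if n else {}

    by_comp: Dict[str, Dict[str, int]] = {}
    for code in model.compartments:
        mets = [m for m in model.metabolites.values() if m.compartment == code]
        rxns = []
        genes: set = set()
        for rxn in model.reactions.values():
            comps = {
                model.metabolites[mid].compartment
                for mid in rxn.stoichiometry
                if mid in model.metabolites
            }
            if code in comps:
                rxns.append(rxn)
                genes.update(rxn.genes())
        if mets or rxns:
            by_comp[code] = {
                "metabolites": len(mets),
                "reactions": len(rxns),
                "genes": len(genes),
            }

    non_boundary = [
        m for m in model.metabolites.values() if m.compartment != BOUNDARY_COMPARTMENT
    ]
    species = {model.species_of(m.id) for m in model.metabolites.values()}
    return CompositionSummary(
        by_ec_class=by_ec,
        by_kind=by_kind,
        by_compartment=by_comp,
        by_subsystem=by_sub,
        n_reactions=n,
        n_metabolites=len(non_boundary),
        n_genes=len(model.genes),
        n_unique_species=len(species),
        n_distinct_ec=len(distinct_ec),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class Finding:
    kind: str
    subject: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.subject}: {self.detail}"


def validate(model: MetabolicModel) -> List[Finding]:
    """Structural validation; returns findings instead of raising.

    Checks: dangling metabolite references, bound order, unknown
    compartments, zero coefficients, and elemental balance of internal
    reactions whose metabolites all carry formulas.
    """
    findings: List[Finding] = []
    for met in model.metabolites.values():
        if met.compartment not in model.compartments:
            findings.append(
                Finding("unknown_compartment", met.id, f"compartment {met.compartment!r} not configured")
            )
        if met.formula:
            try:
                parse_formula(met.formula)
            except ValueError as exc:
                findings.append(Finding("bad_formula", met.id, str(exc)))

    for rid, rxn in model.reactions.items():
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                Finding(
                    "bound_order",
                    rid,
                    f"lower bound {rxn.lower_bound} exceeds upper bound {rxn.upper_bound}",
                )
            )
        dangling = [m for m in rxn.stoichiometry if m not in model.metabolites]
        for mid in dangling:
            findings.append(Finding("dangling_metabolite", rid, f"references unknown metabolite {mid!r}"))
        for mid, coef in rxn.stoichiometry.items():
            if coef == 0.0:
                findings.append(Finding("zero_coefficient", rid, f"zero coefficient for {mid!r}"))
        if dangling:
            continue
        if classify_reaction(model, rid) != "internal":
            continue
        mets = [model.metabolites[m] for m in rxn.stoichiometry]
        if all(m.formula for m in mets):
            balance: Counter = Counter()
            for mid, coef in rxn.stoichiometry.items():
                for el, cnt in model.metabolites[mid].elements().items():
                    balance[el] += coef * cnt
            off = {el: v for el, v in balance.items() if abs(v) > 1e-6}
            if off:
                findings.append(
                    Finding("elemental_imbalance", rid, f"unbalanced elements {off}")
                )
    return findings


# ---------------------------------------------------------------------------
# Connectivity helpers (used by gap analysis and dead-end classification)
# ---------------------------------------------------------------------------


def metabolite_graph(model: MetabolicModel) -> nx.Graph:
    """Bipartite-projected graph: metabolites connected when they share a reaction."""
    graph = nx.Graph()
    graph.add_nodes_from(
        m.id for m in model.metabolites.values() if m.compartment != BOUNDARY_COMPARTMENT
    )
    for rxn in model.reactions.values():
        mids = [
            m
            for m in rxn.stoichiometry
            if m in model.metabolites
            and model.metabolites[m].compartment != BOUNDARY_COMPARTMENT
        ]
        for a, b in zip(mids, mids[1:]):
            graph.add_edge(a, b)
    return graph
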