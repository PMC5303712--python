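"""Reading and writing metabolic models and condition tables.

Two model formats are supported:

* **SBML** Level 3 with the flux-balance-constraints (fbc) package —
  bounds, gene–product associations, formulas and charges travel in the
  standard places; EC numbers and subsystem labels travel in the reaction
  notes.  Parsing and serialisation go through python-libsbml.
* **TSV** — the package's normative tabular dialect, one reaction per row
  with columns ``id, name, equation, lower_bound, upper_bound, gpr,
  ec_numbers, subsystem``.  Equations use bracketed compartment codes, e.g.
  ``glc[x] -> glc[c]`` or ``2 A[c] + B[c] <=> C[m]``; a one-sided equation
  (``lac[x] ->``) denotes an exchange.  Metabolite ids are formed as
  ``<species>__<compartment>``.

Condition files are TSV with columns ``metabolite, rate, direction``
(direction ``uptake`` or ``release``); a rate written ``a-b`` is a range
whose upper value is used as the capacity.  Rates are μmol/g tissue/min.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import libsbml

from .model import (
    DEFAULT_BOUND,
    DEFAULT_COMPARTMENTS,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)
from .simulation import Condition


class ModelIOError(ValueError):
    """Raised for unparseable or invalid model / condition files."""


@dataclass
class ModelDocument:
    """A model plus where it came from."""

    model: MetabolicModel
    source_format: str  # sbml | tsv
    provenance: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Equation dialect
# ---------------------------------------------------------------------------

_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)\[(\w+)\]$")
_ARROWS = ("<=>", "<->", "=>", "->")


def _parse_side(side: str, sign: float, stoich: Dict[str, float]) -> None:
    side = side.strip()
    if not side:
        return
    for term in re.split(r"\s+\+\s+", side):
        term = term.strip()
        if not term:
            continue
        m = _MET_TOKEN.match(term)
        if not m:
            raise ModelIOError(f"cannot parse equation term {term!r}")
        coef, species, comp = m.groups()
        mid = f"{species}__{comp}"
        stoich[mid] = stoich.get(mid, 0.0) + sign * (float(coef) if coef else 1.0)


def parse_equation(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse a reaction equation; returns (stoichiometry, reversible)."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelIOError(f"no reaction arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}
    _parse_side(left, -1.0, stoich)
    _parse_side(right, +1.0, stoich)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise ModelIOError(f"equation {equation!r} has no net stoichiometry")
    return stoich, arrow in ("<=>", "<->")


def format_equation(model: MetabolicModel, rxn: Reaction) -> str:
    def term(mid: str, coef: float) -> str:
        met = model.metabolites.get(mid)
        comp = met.compartment if met else "?"
        species = model.species_of(mid)
        c = abs(coef)
        prefix = "" if c == 1.0 else (f"{int(c)} " if c == int(c) else f"{c:g} ")
        return f"{prefix}{species}[{comp}]"

    left = " + ".join(term(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c < 0)
    right = " + ".join(term(m, c) for m, c in sorted(rxn.stoichiometry.items()) if c > 0)
    arrow = "<=>" if rxn.reversible else "->"
    return f"{left} {arrow} {right}".strip()


# ---------------------------------------------------------------------------
# TSV model dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "id", "name", "equation", "lower_bound", "upper_bound",
    "gpr", "ec_numbers", "subsystem",
]


def _read_tsv_model(path: Path, compartments: Dict[str, str]) -> ModelDocument:
    model = MetabolicModel(compartments=compartments, name=path.stem)
    met_names: Dict[str, str] = {}
    n_rows = 0
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _TSV_COLUMNS[:5] if c not in header]
                if missing:
                    raise ModelIOError(
                        f"{path}: header lacks required columns {missing}"
                    )
                continue
            n_rows += 1
            row = dict(zip(header, cells))
            rid = row.get("id", "").strip()
            if not rid:
                raise ModelIOError(f"{path}:{lineno}: empty reaction id")
            try:
                stoich, reversible = parse_equation(row["equation"])
            except ModelIOError as exc:
                raise ModelIOError(f"{path}:{lineno}: {exc}") from None
            lb_raw = row.get("lower_bound", "").strip()
            ub_raw = row.get("upper_bound", "").strip()
            lb = float(lb_raw) if lb_raw else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_raw) if ub_raw else DEFAULT_BOUND
            ec = [e.strip() for e in row.get("ec_numbers", "").split(",") if e.strip()]
            for mid in stoich:
                if mid not in model.metabolites:
                    species, comp = mid.rsplit("__", 1)
                    if comp not in compartments:
                        raise ModelIOError(
                            f"{path}:{lineno}: unknown compartment code {comp!r} "
                            f"in metabolite {species}[{comp}]"
                        )
                    model.add_metabolite(Metabolite(mid, met_names.get(mid, species), comp))
            try:
                model.add_reaction(Reaction(
                    rid, stoich, name=row.get("name", "").strip(),
                    lower_bound=lb, upper_bound=ub,
                    gpr=row.get("gpr", "").strip(), ec_numbers=ec,
                    subsystem=row.get("subsystem", "").strip(),
                ))
            except ModelError as exc:
                raise ModelIOError(f"{path}:{lineno}: {exc}") from None
    if n_rows != len(model.reactions):  # pragma: no cover - defensive
        raise ModelIOError(
            f"{path}: read {n_rows} rows but built {len(model.reactions)} reactions"
        )
    return ModelDocument(
        model=model,
        source_format="tsv",
        provenance={"path": str(path), "rows": n_rows, "skipped": 0},
    )


def _write_tsv_model(doc: ModelDocument, path: Path) -> Path:
    model = doc.model
    lines = ["\t".join(_TSV_COLUMNS)]
    for rid, rxn in model.reactions.items():
        lines.append("\t".join([
            rid,
            rxn.name,
            format_equation(model, rxn),
            f"{rxn.lower_bound:g}",
            f"{rxn.upper_bound:g}",
            rxn.gpr,
            ",".join(rxn.ec_numbers),
            rxn.subsystem,
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------

_SBML_PREFIX_MET = "M_"
_SBML_PREFIX_RXN = "R_"
_SBML_PREFIX_GENE = "G_"

_NOTES_EC = re.compile(r"EC_NUMBERS:\s*([^<]*)")
_NOTES_SUB = re.compile(r"SUBSYSTEM:\s*([^<]*)")


def _sanitize(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", sid)


def _strip_outer_parens(expr: str) -> str:
    """Remove redundant enclosing parentheses added by infix serialisation."""
    while expr.startswith("(") and expr.endswith(")"):
        depth = 0
        for i, ch in enumerate(expr):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth == 0 and i != len(expr) - 1:
                    return expr
        expr = expr[1:-1].strip()
    return expr


def _write_sbml_model(doc: ModelDocument, path: Path) -> Path:
    model = doc.model
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    sbml_doc = libsbml.SBMLDocument(ns)
    sbml_doc.setPackageRequired("fbc", False)
    sm = sbml_doc.createModel()
    sm.setId(_sanitize(model.name or "model"))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    used_comps = {m.compartment for m in model.metabolites.values()}
    for code in sorted(used_comps):
        comp = sm.createCompartment()
        comp.setId(code)
        comp.setName(model.compartments.get(code, code))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_SBML_PREFIX_MET + _sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.compartment == "b")
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    for gene in model.genes:
        gp = mplug.createGeneProduct()
        gp.setId(_SBML_PREFIX_GENE + _sanitize(gene))
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid, rxn in model.reactions.items():
        sr = sm.createReaction()
        sr.setId(_SBML_PREFIX_RXN + _sanitize(rid))
        sr.setName(rxn.name or rid)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies(_SBML_PREFIX_MET + _sanitize(mid))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr.strip():
            gpa = rplug.createGeneProductAssociation()
            infix = re.sub(
                r"\b(?!and\b|or\b|AND\b|OR\b)([A-Za-z0-9_.-]+)\b",
                lambda m: _SBML_PREFIX_GENE + _sanitize(m.group(1)),
                rxn.gpr,
            )
            gpa.setAssociation(infix)
        if rxn.ec_numbers or rxn.subsystem:
            notes = (
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>EC_NUMBERS: {','.join(rxn.ec_numbers)}</p>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )
            sr.setNotes(notes)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(sbml_doc, str(path)):  # pragma: no cover
        raise ModelIOError(f"could not write SBML to {path}")
    return path


def _read_sbml_model(path: Path, compartments: Dict[str, str]) -> ModelDocument:
    sbml_doc = libsbml.readSBMLFromFile(str(path))
    if sbml_doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = sbml_doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = sbml_doc.getModel()
    if sm is None:
        raise ModelIOError(f"{path}: file contains no SBML model")

    comp_map = dict(DEFAULT_COMPARTMENTS)
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        comp_map.setdefault(comp.getId(), comp.getName() or comp.getId())
    model = MetabolicModel(compartments=comp_map, name=sm.getId() or path.stem)

    gene_labels: Dict[str, str] = {}
    mplug = sm.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def strip_met(sid: str) -> str:
        return sid[len(_SBML_PREFIX_MET):] if sid.startswith(_SBML_PREFIX_MET) else sid

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(Metabolite(
            id=strip_met(sp.getId()),
            name=sp.getName() or strip_met(sp.getId()),
            compartment=sp.getCompartment(),
            formula=formula,
            charge=charge,
        ))

    unknown = sorted({
        m.compartment for m in model.metabolites.values()
        if m.compartment not in comp_map
    })
    if unknown:  # pragma: no cover - guarded by setdefault above
        raise ModelIOError(f"{path}: unknown compartment codes {unknown}")

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = sr.getId()
        if rid.startswith(_SBML_PREFIX_RXN):
            rid = rid[len(_SBML_PREFIX_RXN):]
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = strip_met(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = strip_met(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        gpr = ""
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                infix = gpa.getAssociation().toInfix()
                for gid, label in gene_labels.items():
                    infix = re.sub(rf"\b{re.escape(gid)}\b", label, infix)
                gpr = infix.replace("(", "( ").replace(")", " )")
                gpr = re.sub(r"\s+", " ", gpr).strip()
                gpr = gpr.replace("( ", "(").replace(" )", ")")
                gpr = _strip_outer_parens(gpr)
        ec: List[str] = []
        subsystem = ""
        if sr.isSetNotes():
            notes = sr.getNotesString()
            m_ec = _NOTES_EC.search(notes)
            if m_ec and m_ec.group(1).strip():
                ec = [e.strip() for e in m_ec.group(1).split(",") if e.strip()]
            m_sub = _NOTES_SUB.search(notes)
            if m_sub:
                subsystem = m_sub.group(1).strip()
        try:
            model.add_reaction(Reaction(
                rid, stoich, name=sr.getName() or rid,
                lower_bound=lb, upper_bound=ub, gpr=gpr,
                ec_numbers=ec, subsystem=subsystem,
            ))
        except ModelError as exc:
            raise ModelIOError(f"{path}: reaction {rid!r}: {exc}") from None

    return ModelDocument(
        model=model,
        source_format="sbml",
        provenance={"path": str(path), "rows": sm.getNumReactions(), "skipped": 0},
    )


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def read_model(
    path,
    format: str = "auto",
    compartments: Optional[Dict[str, str]] = None,
) -> ModelDocument:
    """Read a model from SBML or TSV.

    ``format='auto'`` sniffs the extension (``.xml``/``.sbml`` vs ``.tsv``)
    and falls back to content sniffing (an XML declaration or ``<sbml``
    root).  The compartment table is configurable because bracket-code
    conventions differ between reconstruction lineages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    comp = dict(compartments or DEFAULT_COMPARTMENTS)
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".xml", ".sbml"}:
            fmt = "sbml"
        elif suffix in {".tsv", ".txt"}:
            fmt = "tsv"
        else:
            head = path.read_text(errors="replace")[:200].lstrip()
            fmt = "sbml" if head.startswith("<") else "tsv"
    if fmt == "sbml":
        return _read_sbml_model(path, comp)
    if fmt == "tsv":
        return _read_tsv_model(path, comp)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(doc: ModelDocument, path, format: str = "auto") -> Path:
    """Write a model to SBML or TSV; the output is re-readable by read_model."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "tsv"
    if fmt == "sbml":
        return _write_sbml_model(doc, path)
    if fmt == "tsv":
        return _write_tsv_model(doc, path)
    raise ValueError(f"unknown model format {fmt!r}")


_RATE_RANGE = re.compile(r"^(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)$")


def read_condition(path) -> Condition:
    """Read a condition table (metabolite, rate, direction).

    Metabolite species ids are mapped to exchange reactions as
    ``EX_<species>``; whether that exchange actually exists is resolved when
    the condition is applied to a model (unknown ids produce a warning at
    application time, not here).  Negative rates are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cond = Condition(name=path.stem)
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in line.split("\t")]
            if header is None:
                if {"metabolite", "rate", "direction"} <= set(cells):
                    header = cells
                    continue
                header = ["metabolite", "rate", "direction"]
            row = dict(zip(header, cells))
            species = row.get("metabolite", "")
            rate_raw = row.get("rate", "")
            direction = row.get("direction", "").lower()
            if not species or not rate_raw or direction not in {"uptake", "release"}:
                raise ModelIOError(
                    f"{path}:{lineno}: expected 'metabolite<TAB>rate<TAB>uptake|release'"
                )
            m_range = _RATE_RANGE.match(rate_raw)
            if m_range:
                lo, hi = (float(m_range.group(1)), float(m_range.group(2)))
                rate = max(lo, hi)
            else:
                rate = float(rate_raw)
            if rate < 0 or math.isnan(rate):
                raise ModelIOError(f"{path}:{lineno}: negative rate {rate}")
            ex_id = f"EX_{species}"
            if direction == "uptake":
                cond.set_uptake(ex_id, rate)
            else:
                cond.set_release(ex_id, rate)
    return cond


def write_condition(cond: Condition, path) -> Path:
    """Write a condition back to the TSV dialect (lossy for two-sided overrides)."""
    path = Path(path)
    lines = ["metabolite\trate\tdirection"]
    for ex_id, (lo, hi) in sorted(cond.overrides.items()):
        species = ex_id[3:] if ex_id.startswith("EX_") else ex_id
        if lo is not None and lo <= 0:
            lines.append(f"{species}\t{-lo:g}\tuptake")
        if hi is not None and hi >= 0:
            lines.append(f"{species}\t{hi:g}\trelease")
    path.write_text("\n".join(lines) + "\n")
    return path
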