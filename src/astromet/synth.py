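"""Generator for the core astrocyte network and adversarial test fixtures.

The core network is a compact (~90 reaction) stand-in for a genome-scale
astrocyte reconstruction.  It covers the pathways that dominate astrocyte
energy metabolism — glycolysis, pentose phosphate pathway, TCA cycle,
oxidative phosphorylation with an explicit proton gradient, lactate and
acetate exchange, ketone-body utilisation, fatty-acid beta-oxidation, the
glutamate–glutamine cycle, ROS detoxification and the Na+/K+-ATPase — with
textbook stoichiometry, EC numbers and gene–protein–reaction rules, so that
every pipeline stage (extraction, gap analysis, FBA, sampling) is exercisable
without any external download.

Design features that shape the flux solutions (see docs/methods.md for the
full rationale):

* Oxidative phosphorylation is proton-explicit.  Complex I pumps
  ``4 * nadh_atp`` protons per NADH and the lumped complex III/IV pumps
  ``4 * fadh2_atp`` per quinol; the ATP synthase consumes 4 H+(c) and
  returns 3 H+(m) per ATP, so the P/O ratios are exactly the declared
  yields (defaults 2.5 / 1.5).
* Cytosolic NADH reaches the chain only through the glycerol-3-phosphate
  shuttle (astrocytes lack the aspartate–glutamate carrier needed for the
  malate–aspartate shuttle), entering at the quinone level.
* Mitochondrial pyruvate oxidation is capacity-limited
  (``pdh_capacity``, default 0.06 μmol/g/min — astrocytic PDH is largely
  phosphorylated/inactive), which is what makes the cell a net lactate
  exporter under saturating glucose.
* Glutamate taken up through the sodium-coupled EAAT costs one ATP of
  Na+/K+-ATPase work per glutamate and is deaminated by glutamate
  dehydrogenase; the resulting 2-oxoglutarate is exported (the core network
  deliberately omits PEPCK, and malic-enzyme flux is limited by the NADPH
  sink, so glutamate carbon is not fully oxidised).
* An ischemic ROS source is wired in: hypoxanthine (the purine-catabolism
  product that accumulates in energy-starved tissue) can be taken up and
  oxidised by xanthine oxidase to superoxide, feeding SOD, catalase and
  glutathione peroxidase.

Anaerobically (O2 uptake 0) the network yields exactly 2 ATP per glucose;
aerobically ~30 (glycerol-phosphate shuttle, declared P/O yields).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
    gpr_genes,
)

PATHWAYS = {
    "glycolysis",
    "ppp",
    "tca",
    "oxphos",
    "lactate",
    "acetate",
    "glu_gln",
    "ros_detox",
    "nak_atpase",
    "fa_oxidation",
}

#: pathway -> pathways it cannot function without (auto-included)
_PATHWAY_DEPS = {
    "acetate": {"tca"},
    "fa_oxidation": {"tca"},
    "tca": {"oxphos"},
    "ros_detox": {"ppp"},
    "glu_gln": {"nak_atpase", "oxphos"},
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic core astrocyte network.

    ``nadh_atp`` / ``fadh2_atp`` are the ATP-equivalents per reducing
    equivalent (P/O-style yields) realised through the proton stoichiometry.
    ``n_deadends`` (k) and ``expression_size`` parameterise the adversarial
    fixtures.  ``pdh_capacity`` is the mitochondrial pyruvate oxidation
    ceiling in μmol/g tissue/min.
    """

    pathways: Set[str] = field(default_factory=lambda: set(PATHWAYS))
    nadh_atp: float = 2.5
    fadh2_atp: float = 1.5
    seed: int = 20170213
    n_deadends: int = 3
    expression_size: int = 40
    pdh_capacity: float = 0.06

    def __post_init__(self) -> None:
        unknown = set(self.pathways) - PATHWAYS
        if unknown:
            raise ValueError(f"unknown pathways: {sorted(unknown)}")
        if self.nadh_atp <= 0 or self.fadh2_atp <= 0:
            raise ValueError("P/O yields must be positive")
        if self.n_deadends < 0:
            raise ValueError("n_deadends must be >= 0")
        if "glycolysis" not in self.pathways:
            raise ValueError(
                "pathway set must include glycolysis; the network is not "
                "exercisable without it"
            )

    def effective_pathways(self) -> Set[str]:
        out = set(self.pathways)
        changed = True
        while changed:
            changed = False
            for p in list(out):
                for dep in _PATHWAY_DEPS.get(p, ()):
                    if dep not in out:
                        out.add(dep)
                        changed = True
        return out


# ---------------------------------------------------------------------------
# Metabolite table: species id -> (name, formula)
# Formulas follow the usual reconstruction conventions (ionised species);
# only elemental composition is checked, not charge.
# ---------------------------------------------------------------------------

_SPECIES: Dict[str, Tuple[str, Optional[str]]] = {
    "glc": ("D-glucose", "C6H12O6"),
    "g6p": ("glucose 6-phosphate", "C6H11O9P"),
    "f6p": ("fructose 6-phosphate", "C6H11O9P"),
    "fdp": ("fructose 1,6-bisphosphate", "C6H10O12P2"),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P"),
    "gap": ("glyceraldehyde 3-phosphate", "C3H5O6P"),
    "bpg13": ("1,3-bisphosphoglycerate", "C3H4O10P2"),
    "pg3": ("3-phosphoglycerate", "C3H4O7P"),
    "pep": ("phosphoenolpyruvate", "C3H2O6P"),
    "pyr": ("pyruvate", "C3H3O3"),
    "lac": ("L-lactate", "C3H5O3"),
    "ru5p": ("ribulose 5-phosphate", "C5H9O8P"),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S"),
    "coa": ("coenzyme A", "C21H32N7O16P3S"),
    "cit": ("citrate", "C6H5O7"),
    "icit": ("isocitrate", "C6H5O7"),
    "akg": ("2-oxoglutarate", "C5H4O5"),
    "succoa": ("succinyl-CoA", "C25H35N7O19P3S"),
    "succ": ("succinate", "C4H4O4"),
    "fum": ("fumarate", "C4H2O4"),
    "mal": ("L-malate", "C4H4O5"),
    "oaa": ("oxaloacetate", "C4H2O5"),
    "glu": ("L-glutamate", "C5H8NO4"),
    "gln": ("L-glutamine", "C5H10N2O3"),
    "nh4": ("ammonium", "H4N"),
    "ac": ("acetate", "C2H3O2"),
    "acac": ("acetoacetate", "C4H5O3"),
    "aacoa": ("acetoacetyl-CoA", "C25H36N7O18P3S"),
    "lnlc": ("linoleate", "C18H31O2"),
    "lnlnca": ("alpha-linolenate", "C18H29O2"),
    "atp": ("ATP", "C10H12N5O13P3"),
    "adp": ("ADP", "C10H12N5O10P2"),
    "amp": ("AMP", "C10H12N5O7P"),
    "pi": ("orthophosphate", "HO4P"),
    "ppi": ("pyrophosphate", "HO7P2"),
    "nad": ("NAD+", "C21H26N7O14P2"),
    "nadh": ("NADH", "C21H27N7O14P2"),
    "nadp": ("NADP+", "C21H25N7O17P3"),
    "nadph": ("NADPH", "C21H26N7O17P3"),
    "q": ("ubiquinone-10", "C59H90O4"),
    "qh2": ("ubiquinol-10", "C59H92O4"),
    "o2": ("oxygen", "O2"),
    "co2": ("carbon dioxide", "CO2"),
    "h2o": ("water", "H2O"),
    "h": ("proton", "H"),
    "o2s": ("superoxide anion", "O2"),
    "h2o2": ("hydrogen peroxide", "H2O2"),
    "gthrd": ("reduced glutathione", "C10H16N3O6S"),
    "gthox": ("oxidised glutathione", "C20H30N6O12S2"),
    "hxan": ("hypoxanthine", "C5H4N4O"),
    "urate": ("urate", "C5H4N4O3"),
    "na": ("sodium ion", "Na"),
    "k": ("potassium ion", "K"),
}


def _met(species: str, comp: str) -> Metabolite:
    name, formula = _SPECIES[species]
    return Metabolite(id=f"{species}__{comp}", name=name, compartment=comp, formula=formula)


class _Builder:
    def __init__(self, spec: GeneratorSpec) -> None:
        self.spec = spec
        self.model = MetabolicModel(name="core_astrocyte")
        self.truth: Dict[str, Dict[str, int]] = {"ec_class_counts": {}}
        self._mets: Set[str] = set()

    def met(self, species: str, comp: str) -> str:
        mid = f"{species}__{comp}"
        if mid not in self._mets:
            self.model.add_metabolite(_met(species, comp))
            self._mets.add(mid)
        return mid

    def rxn(
        self,
        rid: str,
        name: str,
        stoich: Dict[Tuple[str, str], float],
        lb: float = 0.0,
        ub: float = DEFAULT_BOUND,
        gpr: str = "",
        ec: Sequence[str] = (),
        subsystem: str = "",
    ) -> None:
        coeffs = {self.met(sp, comp): c for (sp, comp), c in stoich.items()}
        self.model.add_reaction(
            Reaction(
                id=rid,
                name=name,
                stoichiometry=coeffs,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                ec_numbers=list(ec),
                subsystem=subsystem,
            )
        )
        for e in ec:
            top = e.split(":")[-1].split(".")[0]
            counts = self.truth["ec_class_counts"]
            counts[top] = counts.get(top, 0) + 1

    def exchange(self, species: str, lb: float, ub: float = DEFAULT_BOUND) -> None:
        self.rxn(
            f"EX_{species}",
            f"{_SPECIES[species][0]} exchange",
            {(species, "x"): -1.0},
            lb=lb,
            ub=ub,
            subsystem="exchange",
        )


def make_core_astrocyte_network(spec: Optional[GeneratorSpec] = None) -> MetabolicModel:
    """Build the core astrocyte network.

    The returned model is valid (``validate`` returns no findings), free of
    dead ends, feasible under the physiological exchange constraints and
    anaerobically exact (2 ATP per glucose).
    """
    spec = spec or GeneratorSpec()
    b = _Builder(spec)
    paths = spec.effective_pathways()
    R = b.rxn
    EB = DEFAULT_BOUND

    # protons pumped per oxidation event; synthase uses 4 H+ per ATP
    h_nadh = 4.0 * spec.nadh_atp
    h_qh2 = 4.0 * spec.fadh2_atp

    # ---- glycolysis (mandatory) ----
    g = "glycolysis"
    R("GLCt", "glucose transport (GLUT1)", {("glc", "x"): -1, ("glc", "c"): 1},
      lb=-EB, gpr="SLC2A1", subsystem=g)
    R("HEX1", "hexokinase", {("glc", "c"): -1, ("atp", "c"): -1, ("g6p", "c"): 1,
                             ("adp", "c"): 1, ("h", "c"): 1},
      gpr="HK1 or HK2", ec=["EC:2.7.1.1"], subsystem=g)
    R("PGI", "glucose-6-phosphate isomerase", {("g6p", "c"): -1, ("f6p", "c"): 1},
      lb=-EB, gpr="GPI", ec=["EC:5.3.1.9"], subsystem=g)
    R("PFK", "phosphofructokinase", {("f6p", "c"): -1, ("atp", "c"): -1,
                                     ("fdp", "c"): 1, ("adp", "c"): 1, ("h", "c"): 1},
      gpr="PFKL or PFKP", ec=["EC:2.7.1.11"], subsystem=g)
    R("FBA", "fructose-bisphosphate aldolase", {("fdp", "c"): -1, ("dhap", "c"): 1, ("gap", "c"): 1},
      lb=-EB, gpr="ALDOA or ALDOC", ec=["EC:4.1.2.13"], subsystem=g)
    R("TPI", "triose-phosphate isomerase", {("dhap", "c"): -1, ("gap", "c"): 1},
      lb=-EB, gpr="TPI1", ec=["EC:5.3.1.1"], subsystem=g)
    R("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
      {("gap", "c"): -1, ("nad", "c"): -1, ("pi", "c"): -1,
       ("bpg13", "c"): 1, ("nadh", "c"): 1, ("h", "c"): 1},
      lb=-EB, gpr="GAPDH", ec=["EC:1.2.1.12"], subsystem=g)
    R("PGK", "phosphoglycerate kinase", {("bpg13", "c"): -1, ("adp", "c"): -1,
                                         ("pg3", "c"): 1, ("atp", "c"): 1},
      lb=-EB, gpr="PGK1", ec=["EC:2.7.2.3"], subsystem=g)
    R("ENO", "phosphoglycerate mutase + enolase (lumped)",
      {("pg3", "c"): -1, ("pep", "c"): 1, ("h2o", "c"): 1},
      lb=-EB, gpr="PGAM1 and ENO1", ec=["EC:5.4.2.11", "EC:4.2.1.11"], subsystem=g)
    R("PYK", "pyruvate kinase", {("pep", "c"): -1, ("adp", "c"): -1, ("h", "c"): -1,
                                 ("pyr", "c"): 1, ("atp", "c"): 1},
      gpr="PKM", ec=["EC:2.7.1.40"], subsystem=g)
    b.exchange("glc", lb=0.0)

    # core currency exchanges (freely available / disposable)
    for sp in ("h2o", "h", "pi", "nh4", "co2", "o2"):
        b.exchange(sp, lb=-EB)
    R("H2Ot", "water diffusion (AQP4)", {("h2o", "x"): -1, ("h2o", "c"): 1},
      lb=-EB, gpr="AQP4", subsystem="transport")
    R("H2Otm", "water diffusion, mitochondrial", {("h2o", "c"): -1, ("h2o", "m"): 1},
      lb=-EB, subsystem="transport")
    R("Ht", "proton exchange, plasma membrane", {("h", "x"): -1, ("h", "c"): 1},
      lb=-EB, subsystem="transport")
    R("PIt", "phosphate uptake", {("pi", "x"): -1, ("pi", "c"): 1},
      lb=-EB, gpr="SLC20A1", subsystem="transport")
    R("NH4t", "ammonium diffusion", {("nh4", "x"): -1, ("nh4", "c"): 1},
      lb=-EB, subsystem="transport")
    R("O2t", "oxygen diffusion", {("o2", "x"): -1, ("o2", "c"): 1},
      lb=-EB, subsystem="transport")
    R("CO2t", "carbon dioxide diffusion", {("co2", "c"): -1, ("co2", "x"): 1},
      lb=-EB, subsystem="transport")

    # cytosolic ATP demand (non-pump maintenance drain)
    R("DM_atp", "ATP demand (cytosolic drain)",
      {("atp", "c"): -1, ("h2o", "c"): -1, ("adp", "c"): 1, ("pi", "c"): 1, ("h", "c"): 1},
      subsystem="energy demand")

    if "lactate" in paths:
        R("LDH", "lactate dehydrogenase",
          {("pyr", "c"): -1, ("nadh", "c"): -1, ("h", "c"): -1,
           ("lac", "c"): 1, ("nad", "c"): 1},
          lb=-EB, gpr="LDHA or LDHB", ec=["EC:1.1.1.27"], subsystem="lactate")
        R("LACt", "lactate transport (MCT1)", {("lac", "c"): -1, ("lac", "x"): 1},
          lb=-EB, gpr="SLC16A1", subsystem="lactate")
        b.exchange("lac", lb=0.0)
    R("PYRt", "pyruvate transport (MCT)", {("pyr", "x"): -1, ("pyr", "c"): 1},
      lb=-EB, gpr="SLC16A1", subsystem="transport")
    # pyruvate can be taken up (a condition opens the lower bound) but is not
    # secreted: the astrocyte monocarboxylate efflux is lactate
    b.exchange("pyr", lb=0.0, ub=0.0)

    if "ppp" in paths:
        R("G6PD", "oxidative pentose phosphate branch (G6PD + 6PGD, lumped)",
          {("g6p", "c"): -1, ("nadp", "c"): -2, ("h2o", "c"): -1,
           ("ru5p", "c"): 1, ("nadph", "c"): 2, ("co2", "c"): 1, ("h", "c"): 2},
          gpr="G6PD and PGD", ec=["EC:1.1.1.49", "EC:1.1.1.44"], subsystem="ppp")
        R("PPPNOX", "non-oxidative pentose phosphate branch (TK/TA, lumped)",
          {("ru5p", "c"): -3, ("f6p", "c"): 2, ("gap", "c"): 1},
          lb=-EB, gpr="TKT and TALDO1", ec=["EC:2.2.1.1", "EC:2.2.1.2"], subsystem="ppp")

    if "oxphos" in paths:
        o = "oxphos"
        R("O2tm", "oxygen diffusion, mitochondrial", {("o2", "c"): -1, ("o2", "m"): 1},
          lb=-EB, subsystem="transport")
        R("CO2tm", "carbon dioxide diffusion, mitochondrial",
          {("co2", "m"): -1, ("co2", "c"): 1}, lb=-EB, subsystem="transport")
        R("NADH_DH", "NADH dehydrogenase (complex I)",
          {("nadh", "m"): -1, ("h", "m"): -(1 + h_nadh - h_qh2), ("q", "m"): -1,
           ("nad", "m"): 1, ("qh2", "m"): 1, ("h", "c"): h_nadh - h_qh2},
          gpr="NDUFS1 and NDUFV1", ec=["EC:1.6.5.3"], subsystem=o)
        R("CYOO", "cytochrome pathway (complex III + IV, lumped)",
          {("qh2", "m"): -1, ("o2", "m"): -0.5, ("h", "m"): -h_qh2,
           ("q", "m"): 1, ("h2o", "m"): 1, ("h", "c"): h_qh2},
          gpr="UQCRC1 and CYC1 and COX4I1", ec=["EC:1.10.2.2", "EC:1.9.3.1"], subsystem=o)
        R("ATPS", "ATP synthase",
          {("adp", "m"): -1, ("h", "c"): -4, ("pi", "m"): -1,
           ("atp", "m"): 1, ("h", "m"): 3, ("h2o", "m"): 1},
          gpr="ATP5F1A and ATP5F1B", ec=["EC:7.1.2.2"], subsystem=o)
        R("ATPtm", "adenine nucleotide translocase",
          {("atp", "m"): -1, ("adp", "c"): -1, ("atp", "c"): 1, ("adp", "m"): 1},
          gpr="SLC25A4", subsystem="transport")
        R("PItm", "mitochondrial phosphate carrier (electroneutral)",
          {("pi", "c"): -1, ("pi", "m"): 1}, lb=-EB, gpr="SLC25A3", subsystem="transport")
        R("HLEAK", "inner-membrane proton leak", {("h", "c"): -1, ("h", "m"): 1},
          subsystem=o)
        R("GPSHUTTLE", "glycerol-3-phosphate shuttle (lumped)",
          {("nadh", "c"): -1, ("h", "c"): -1, ("q", "m"): -1,
           ("nad", "c"): 1, ("qh2", "m"): 1},
          gpr="GPD1 and GPD2", ec=["EC:1.1.5.3"], subsystem=o)

    if "tca" in paths:
        t = "tca"
        R("PYRtm", "mitochondrial pyruvate carrier",
          {("pyr", "c"): -1, ("h", "c"): -1, ("pyr", "m"): 1, ("h", "m"): 1},
          gpr="MPC1 and MPC2", subsystem="transport")
        R("PDH", "pyruvate dehydrogenase complex",
          {("pyr", "m"): -1, ("coa", "m"): -1, ("nad", "m"): -1,
           ("accoa", "m"): 1, ("co2", "m"): 1, ("nadh", "m"): 1},
          ub=spec.pdh_capacity,
          gpr="PDHA1 and PDHB and DLAT and DLD", ec=["EC:1.2.4.1"], subsystem=t)
        R("CS", "citrate synthase",
          {("accoa", "m"): -1, ("oaa", "m"): -1, ("h2o", "m"): -1,
           ("cit", "m"): 1, ("coa", "m"): 1, ("h", "m"): 1},
          gpr="CS", ec=["EC:2.3.3.1"], subsystem=t)
        R("ACONT", "aconitase", {("cit", "m"): -1, ("icit", "m"): 1},
          lb=-EB, gpr="ACO2", ec=["EC:4.2.1.3"], subsystem=t)
        R("ICDH", "isocitrate dehydrogenase",
          {("icit", "m"): -1, ("nad", "m"): -1,
           ("akg", "m"): 1, ("co2", "m"): 1, ("nadh", "m"): 1},
          gpr="IDH2", ec=["EC:1.1.1.42"], subsystem=t)
        R("AKGDH", "2-oxoglutarate dehydrogenase complex",
          {("akg", "m"): -1, ("coa", "m"): -1, ("nad", "m"): -1,
           ("succoa", "m"): 1, ("co2", "m"): 1, ("nadh", "m"): 1},
          gpr="OGDH and DLST and DLD", ec=["EC:1.2.4.2"], subsystem=t)
        R("SUCOAS", "succinyl-CoA synthetase",
          {("succoa", "m"): -1, ("adp", "m"): -1, ("pi", "m"): -1,
           ("succ", "m"): 1, ("coa", "m"): 1, ("atp", "m"): 1},
          lb=-EB, gpr="SUCLG1 and SUCLA2", ec=["EC:6.2.1.5"], subsystem=t)
        R("SUCD", "succinate dehydrogenase",
          {("succ", "m"): -1, ("q", "m"): -1, ("fum", "m"): 1, ("qh2", "m"): 1},
          gpr="SDHA and SDHB and SDHC and SDHD", ec=["EC:1.3.5.1"], subsystem=t)
        R("FUM", "fumarase", {("fum", "m"): -1, ("h2o", "m"): -1, ("mal", "m"): 1},
          lb=-EB, gpr="FH", ec=["EC:4.2.1.2"], subsystem=t)
        R("MDH", "malate dehydrogenase",
          {("mal", "m"): -1, ("nad", "m"): -1,
           ("oaa", "m"): 1, ("nadh", "m"): 1, ("h", "m"): 1},
          lb=-EB, gpr="MDH2", ec=["EC:1.1.1.37"], subsystem=t)
        R("PC", "pyruvate carboxylase (anaplerosis)",
          {("pyr", "m"): -1, ("atp", "m"): -1, ("co2", "m"): -1, ("h2o", "m"): -1,
           ("oaa", "m"): 1, ("adp", "m"): 1, ("pi", "m"): 1, ("h", "m"): 2},
          gpr="PC", ec=["EC:6.4.1.1"], subsystem=t)
        # anaplerotic pyruvate recycling is a minor flux in astrocytes; the
        # capacity keeps glutamate carbon from being bulk-oxidised
        R("ME2", "malic enzyme, mitochondrial NAD-linked",
          {("mal", "m"): -1, ("nad", "m"): -1,
           ("pyr", "m"): 1, ("co2", "m"): 1, ("nadh", "m"): 1},
          ub=0.01, gpr="ME2", ec=["EC:1.1.1.38"], subsystem=t)

    if "glu_gln" in paths:
        gg = "glu_gln"
        b.exchange("glu", lb=-EB)
        b.exchange("gln", lb=0.0)
        b.exchange("akg", lb=0.0)
        R("GLUT_EAAT", "glutamate uptake (EAAT, 3 Na+ symport)",
          {("glu", "x"): -1, ("na", "x"): -3, ("glu", "c"): 1, ("na", "c"): 3},
          gpr="SLC1A2 or SLC1A3", subsystem=gg)
        R("GLUtm", "mitochondrial glutamate carrier (H+ symport)",
          {("glu", "c"): -1, ("h", "c"): -1, ("glu", "m"): 1, ("h", "m"): 1},
          gpr="SLC25A18", subsystem="transport")
        R("GDH", "glutamate dehydrogenase",
          {("glu", "m"): -1, ("h2o", "m"): -1, ("nad", "m"): -1,
           ("akg", "m"): 1, ("nh4", "m"): 1, ("nadh", "m"): 1, ("h", "m"): 1},
          lb=-EB, gpr="GLUD1", ec=["EC:1.4.1.3"], subsystem=gg)
        R("GLNS", "glutamine synthetase",
          {("glu", "c"): -1, ("nh4", "c"): -1, ("atp", "c"): -1,
           ("gln", "c"): 1, ("adp", "c"): 1, ("pi", "c"): 1, ("h", "c"): 1},
          gpr="GLUL", ec=["EC:6.3.1.2"], subsystem=gg)
        R("GLNt", "glutamine efflux (SNAT3)", {("gln", "c"): -1, ("gln", "x"): 1},
          gpr="SLC38A3", subsystem=gg)
        R("AKGtm", "2-oxoglutarate carrier", {("akg", "m"): -1, ("akg", "c"): 1},
          lb=-EB, gpr="SLC25A11", subsystem="transport")
        R("AKGt", "2-oxoglutarate efflux", {("akg", "c"): -1, ("akg", "x"): 1},
          subsystem="transport")
        R("NH4tm", "ammonium diffusion, mitochondrial",
          {("nh4", "m"): -1, ("nh4", "c"): 1}, lb=-EB, subsystem="transport")
        R("GLUGLN_CYCLE", "glutamate/glutamine cycle pseudo-reaction",
          {("glu", "x"): -1, ("gln", "c"): -1, ("glu", "c"): 1, ("gln", "x"): 1},
          subsystem=gg)

    if "nak_atpase" in paths:
        R("NAK", "Na+/K+-ATPase",
          {("atp", "c"): -1, ("h2o", "c"): -1, ("na", "c"): -3, ("k", "x"): -2,
           ("adp", "c"): 1, ("pi", "c"): 1, ("h", "c"): 1, ("na", "x"): 3, ("k", "c"): 2},
          gpr="ATP1A2 and ATP1B2", ec=["EC:7.2.2.13"], subsystem="nak_atpase")
        R("NAt", "sodium leak channel", {("na", "x"): -1, ("na", "c"): 1},
          subsystem="nak_atpase")
        R("Kt", "potassium leak channel", {("k", "c"): -1, ("k", "x"): 1},
          subsystem="nak_atpase")

    if "acetate" in paths:
        a = "acetate"
        b.exchange("ac", lb=0.0)
        b.exchange("acac", lb=0.0)
        R("ACt", "acetate transport (MCT)", {("ac", "x"): -1, ("ac", "c"): 1},
          lb=-EB, gpr="SLC16A1", subsystem=a)
        R("ACtm", "acetate diffusion, mitochondrial", {("ac", "c"): -1, ("ac", "m"): 1},
          lb=-EB, subsystem="transport")
        R("ACS", "acetyl-CoA synthetase",
          {("ac", "m"): -1, ("atp", "m"): -1, ("coa", "m"): -1,
           ("accoa", "m"): 1, ("amp", "m"): 1, ("ppi", "m"): 1},
          gpr="ACSS1", ec=["EC:6.2.1.1"], subsystem=a)
        R("ADK1m", "adenylate kinase, mitochondrial",
          {("amp", "m"): -1, ("atp", "m"): -1, ("adp", "m"): 2},
          lb=-EB, gpr="AK2", ec=["EC:2.7.4.3"], subsystem=a)
        R("PPAm", "inorganic pyrophosphatase, mitochondrial",
          {("ppi", "m"): -1, ("h2o", "m"): -1, ("pi", "m"): 2, ("h", "m"): 1},
          gpr="PPA2", ec=["EC:3.6.1.1"], subsystem=a)
        R("ACACt", "acetoacetate transport (MCT)", {("acac", "x"): -1, ("acac", "c"): 1},
          lb=-EB, gpr="SLC16A1", subsystem=a)
        R("ACACtm", "acetoacetate diffusion, mitochondrial",
          {("acac", "c"): -1, ("acac", "m"): 1}, lb=-EB, subsystem="transport")
        R("OCOAT", "succinyl-CoA:3-oxoacid CoA transferase (SCOT)",
          {("acac", "m"): -1, ("succoa", "m"): -1, ("aacoa", "m"): 1, ("succ", "m"): 1},
          gpr="OXCT1", ec=["EC:2.8.3.5"], subsystem=a)
        R("ACAT", "acetoacetyl-CoA thiolase",
          {("aacoa", "m"): -1, ("coa", "m"): -1, ("accoa", "m"): 2},
          gpr="ACAT1", ec=["EC:2.3.1.9"], subsystem=a)

    if "fa_oxidation" in paths:
        f = "fa_oxidation"
        if "acetate" not in paths:
            # AMP/PPi recycling is shared with the acetate pathway
            R("ADK1m", "adenylate kinase, mitochondrial",
              {("amp", "m"): -1, ("atp", "m"): -1, ("adp", "m"): 2},
              lb=-EB, gpr="AK2", ec=["EC:2.7.4.3"], subsystem=f)
            R("PPAm", "inorganic pyrophosphatase, mitochondrial",
              {("ppi", "m"): -1, ("h2o", "m"): -1, ("pi", "m"): 2, ("h", "m"): 1},
              gpr="PPA2", ec=["EC:3.6.1.1"], subsystem=f)
        for sp, n_q, ec in (("lnlc", 6.0, "EC:1.3.8.8"), ("lnlnca", 5.0, "EC:1.3.8.8")):
            b.exchange(sp, lb=0.0)
            R(f"{sp.upper()}t", f"{_SPECIES[sp][0]} uptake",
              {(sp, "x"): -1, (sp, "c"): 1}, lb=-EB, gpr="SLC27A1", subsystem=f)
            R(f"{sp.upper()}tm", f"{_SPECIES[sp][0]} carnitine shuttle (lumped)",
              {(sp, "c"): -1, (sp, "m"): 1}, gpr="CPT1A and CPT2", subsystem="transport")
            R(f"FAOX_{sp.upper()}", f"beta-oxidation of {_SPECIES[sp][0]} (lumped)",
              {(sp, "m"): -1, ("atp", "m"): -1, ("coa", "m"): -9,
               ("q", "m"): -n_q, ("nad", "m"): -8, ("h2o", "m"): -8,
               ("accoa", "m"): 9, ("amp", "m"): 1, ("ppi", "m"): 1,
               ("qh2", "m"): n_q, ("nadh", "m"): 8, ("h", "m"): 8},
              gpr="ACSL1 and ACADVL and HADHA and HADHB", ec=[ec], subsystem=f)

    if "ros_detox" in paths:
        r = "ros_detox"
        b.exchange("hxan", lb=0.0)
        b.exchange("urate", lb=0.0)
        R("HXANt", "hypoxanthine transport (ENT)", {("hxan", "x"): -1, ("hxan", "c"): 1},
          lb=-EB, gpr="SLC29A1", subsystem=r)
        R("XOX", "xanthine oxidase (hypoxanthine -> urate, lumped)",
          {("hxan", "c"): -1, ("o2", "c"): -2, ("h2o", "c"): -2,
           ("urate", "c"): 1, ("o2s", "c"): 2, ("h", "c"): 4},
          gpr="XDH", ec=["EC:1.17.3.2"], subsystem=r)
        R("URATEt", "urate efflux", {("urate", "c"): -1, ("urate", "x"): 1},
          gpr="SLC22A12", subsystem=r)
        R("SPODM", "superoxide dismutase",
          {("o2s", "c"): -2, ("h", "c"): -2, ("h2o2", "c"): 1, ("o2", "c"): 1},
          gpr="SOD1", ec=["EC:1.15.1.1"], subsystem=r)
        R("CATr", "catalase", {("h2o2", "c"): -2, ("h2o", "c"): 2, ("o2", "c"): 1},
          gpr="CAT", ec=["EC:1.11.1.6"], subsystem=r)
        R("GPX", "glutathione peroxidase",
          {("h2o2", "c"): -1, ("gthrd", "c"): -2, ("gthox", "c"): 1, ("h2o", "c"): 2},
          gpr="GPX1", ec=["EC:1.11.1.9"], subsystem=r)
        R("GR", "glutathione reductase",
          {("gthox", "c"): -1, ("nadph", "c"): -1, ("h", "c"): -1,
           ("gthrd", "c"): 2, ("nadp", "c"): 1},
          gpr="GSR", ec=["EC:1.8.1.7"], subsystem=r)

    return b.model


def core_ground_truth(spec: Optional[GeneratorSpec] = None) -> Dict[str, Dict[str, int]]:
    """EC-class annotation tally recorded while building the core network."""
    spec = spec or GeneratorSpec()
    model = make_core_astrocyte_network(spec)
    counts: Dict[str, int] = {}
    for rxn in model.reactions.values():
        tops = {e.split(":")[-1].split(".")[0] for e in rxn.ec_numbers}
        for top in tops:
            counts[top] = counts.get(top, 0) + 1
    # counts per reaction (a reaction with two ECs of the same class counts once)
    return {"ec_class_reactions": counts}


# ---------------------------------------------------------------------------
# Adversarial fixtures
# ---------------------------------------------------------------------------


def make_deadend_fixture(
    spec: Optional[GeneratorSpec] = None,
) -> Tuple[MetabolicModel, List[str]]:
    """Core network plus ``spec.n_deadends`` designed dead-end branches.

    Each branch is a two-step linear pathway hanging off glucose 6-phosphate
    and terminating in a metabolite with no consumer (class
    ``never_consumed``).  Returns the model and the ground-truth dead-end
    metabolite ids, sorted.
    """
    spec = spec or GeneratorSpec()
    model = make_core_astrocyte_network(spec)
    truth: List[str] = []
    for i in range(1, spec.n_deadends + 1):
        mid_int = f"dd{i}_int__c"
        mid_end = f"dd{i}_end__c"
        model.add_metabolite(Metabolite(mid_int, f"designed intermediate {i}", "c"))
        model.add_metabolite(Metabolite(mid_end, f"designed dead-end {i}", "c"))
        model.add_reaction(Reaction(
            f"DDSRC{i}", {"g6p__c": -1.0, mid_int: 1.0},
            name=f"designed branch {i}, step 1", subsystem="designed_gap"))
        model.add_reaction(Reaction(
            f"DDSTEP{i}", {mid_int: -1.0, mid_end: 1.0},
            name=f"designed branch {i}, step 2", subsystem="designed_gap"))
        truth.append(mid_end)
    return model, sorted(truth)


def make_gapfill_db(spec: Optional[GeneratorSpec] = None) -> MetabolicModel:
    """Reference reactions that repair the designed dead-ends.

    For each designed dead-end the database contains a consuming reaction
    back into the core network (introducing no new metabolites), plus a
    decoy that introduces a new metabolite and therefore ranks second.
    """
    spec = spec or GeneratorSpec()
    db = MetabolicModel(name="gapfill_reference")
    for i in range(1, spec.n_deadends + 1):
        mid_end = f"dd{i}_end__c"
        db.add_metabolite(Metabolite(mid_end, f"designed dead-end {i}", "c"))
        if "pyr__c" not in db.metabolites:
            db.add_metabolite(_met("pyr", "c"))
        db.add_reaction(Reaction(
            f"FIX{i}", {mid_end: -1.0, "pyr__c": 1.0},
            name=f"repair for designed dead-end {i}", gpr=f"FIXG{i}",
            subsystem="designed_gap"))
        decoy = f"decoy{i}__c"
        db.add_metabolite(Metabolite(decoy, f"decoy metabolite {i}", "c"))
        db.add_reaction(Reaction(
            f"ZFIX{i}", {mid_end: -1.0, decoy: 1.0},
            name=f"decoy repair {i} (introduces a new metabolite)",
            subsystem="designed_gap"))
    return db


def _eval_gpr_reference(gpr: str, present: Set[str]) -> bool:
    """Independent GPR evaluation via Python's own expression parser.

    Used for generator bookkeeping (and as a second route in tests); the
    pipeline's evaluator in :mod:`astromet.reconstruction` is a hand-written
    recursive-descent parser, so the two never share code.
    """
    if not gpr.strip():
        return False
    expr = re.sub(
        r"\b(?!and\b|or\b)([A-Za-z0-9_.-]+)\b",
        lambda m: "True" if m.group(1) in present else "False",
        gpr,
    )
    return bool(eval(expr, {"__builtins__": {}}, {}))  # noqa: S307 - generator-controlled input


def make_expression_fixture(
    spec: Optional[GeneratorSpec] = None,
) -> Tuple[Dict[str, object], MetabolicModel, Set[str]]:
    """Presence calls + reference reaction table with a known extraction result.

    Returns ``(evidence, reference_db, expected_reaction_ids)`` where
    ``evidence`` maps gene id -> {"present": bool, "score": float}.  The
    expected set is every GPR-bearing reference reaction whose rule evaluates
    true under the calls (AND = all subunits present, OR = any isozyme).
    Scores are drawn so that ``score >= 150`` reproduces the boolean call.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    db = make_core_astrocyte_network(spec)
    genes = sorted(db.genes)
    if spec.expression_size < 1:
        raise ValueError("expression_size must be >= 1")
    present = {g for g in genes if rng.random() < 0.7}
    evidence: Dict[str, object] = {}
    for g in genes:
        is_present = g in present
        score = float(rng.uniform(200, 1000) if is_present else rng.uniform(10, 100))
        evidence[g] = {"present": is_present, "score": round(score, 2)}
    expected = {
        rid
        for rid, rxn in db.reactions.items()
        if rxn.gpr.strip() and _eval_gpr_reference(rxn.gpr, present)
    }
    return evidence, db, expected
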