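# Methods

This note documents the models, numerical procedures and design choices
behind `astromet`: what the package computes, under which assumptions, and
what its tests do and do not demonstrate.

## Constraint-based model

A metabolic network with m metabolites and n reactions is represented by
its stoichiometric matrix S (m × n, negative coefficients = consumption).
Steady-state flux vectors v satisfy

    S · v = 0,     lb_i ≤ v_i ≤ ub_i ,

with all rates in μmol per g tissue per minute and default bounds
[−1000, 1000] for reversible and [0, 1000] for irreversible reactions.
Metabolites assigned to the boundary pseudo-compartment `b` are excluded
from the rows of S, and exchange reactions may equivalently be written
one-sided (`glc[x] <=>`), so exchanges are mass-imbalanced by construction.
Exchange flux is positive for secretion and negative for uptake; a
condition file row "glutamate, 0.232, uptake" therefore sets
lb(EX_glu) = −0.232. A rate written `0.515-0.530` is a literature range
whose upper value is used as the capacity.

Flux balance analysis (FBA) maximises an objective c·v over this polytope
with the HiGHS simplex (scipy). Objectives are solved lexicographically:
each optimum is locked in (relative slack 1e−9) as a linear constraint
before the next objective is solved. A parsimonious post-pass then
minimises Σ|v| at the joint optimum via flux splitting, which removes the
degeneracy of alternate optima and makes reported flux vectors
reproducible. Infeasible or unbounded problems are reported as such; no
fluxes are fabricated.

Numerical tolerances: mass-balance residual ≤ 1e−6 (flux units) and bound
violation ≤ 1e−9 on all accepted flux vectors; LP optimality is HiGHS
default.

## Objectives of the astrocyte analysis

Two metabolic tasks characterise the excitatory astrocyte:

* **ATP production.** The network carries the mitochondrial ATP synthase
  with the explicit proton stoichiometry
  `ADP[m] + 4 H+[c] + Pi[m] → ATP[m] + 3 H+[m] + H2O[m]`.
  Because the proton gradient is explicit, maximising synthase flux alone
  would ignore substrate-level phosphorylation and leave the glycolytic
  flux undetermined. Objective A therefore maximises the cytosolic ATP
  drain (`DM_atp`: ATP + H2O → ADP + Pi + H+), which counts oxidative and
  glycolytic ATP alike; the synthase remains the only route by which
  respiratory ATP reaches that drain.
* **Glutamate/glutamine cycling.** Objective B maximises the cycle
  pseudo-reaction `Glutamate[x] + Glutamine[c] → Glutamate[c] +
  Glutamine[x]`, which is classified as a transport reaction.

The default order is lexicographic — ATP first, then the cycle, then
parsimony — and is configurable. Under strict lexicographic ordering the
two objectives compete for the same glutamate and ATP: at the ATP optimum,
diverting glutamate from oxidative deamination to glutamine synthesis
(one ATP per glutamine) lowers ATP, so the cycle objective retains no
slack and its flux is zero in the combined solution. The cycle capability
itself is demonstrated by optimising objective B alone, which drives
glutamine release up to the glutamate uptake capacity.

## The core astrocyte network

The built-in generator produces a ~96-reaction, three-compartment
(extracellular/cytosol/mitochondria) network covering glycolysis, the
pentose phosphate pathway, the TCA cycle, proton-explicit oxidative
phosphorylation, lactate and acetate exchange, ketone-body utilisation,
lumped β-oxidation of linoleate/linolenate, the glutamate–glutamine cycle
with sodium-coupled uptake, a xanthine-oxidase/SOD/catalase/glutathione
ROS branch, and the Na+/K+-ATPase. Reactions carry textbook stoichiometry
with elemental formulas (internal reactions are exactly element-balanced,
which the validator checks), EC numbers and gene–protein–reaction rules.

Choices that shape the flux solutions, with their physiological reading:

* **P/O ratios by proton bookkeeping.** Complex I pumps 4·(NADH yield)
  protons per NADH and the lumped complex III/IV pumps 4·(FADH2 yield) per
  quinol; with the synthase's 4 H+ per ATP this realises the declared
  yields exactly (defaults 2.5 and 1.5 ATP per NADH/FADH2). Anaerobically
  the network yields exactly 2 ATP per glucose; aerobically ≈30.
* **Glycerol-3-phosphate shuttle only.** Astrocytes express little of the
  aspartate–glutamate carrier required by the malate–aspartate shuttle, so
  cytosolic NADH reaches the chain only at the quinone level.
* **Limited pyruvate oxidation.** Astrocytic pyruvate dehydrogenase is
  largely phosphorylated (inactive); the generator caps PDH at
  0.06 μmol/g/min (`pdh_capacity`). This, together with the redox coupling
  of glycolysis to lactate, is what makes the cell a net lactate exporter
  at saturating glucose.
* **Glutamate is deaminated, not fully oxidised.** Glutamate enters via
  EAAT (3 Na+ per glutamate; the sodium is re-exported by the
  Na+/K+-ATPase at one ATP per glutamate), is deaminated by GDH, and the
  resulting 2-oxoglutarate leaves through a dicarboxylate exchange. The
  core network omits PEPCK and caps the mitochondrial NAD-malic enzyme at
  0.01 μmol/g/min, so TCA carbon has no high-capacity exit and bulk
  oxidation of glutamate carbon cannot occur — consistent with the small
  measured TCA throughput (succinate dehydrogenase ≈0.06–0.09 μmol/g/min).
* **Monocarboxylate efflux is lactate.** The pyruvate exchange is
  uptake-only; with free pyruvate release an LP would decouple glycolytic
  redox and export pyruvate instead of lactate.
* **Ischemic ROS source.** Energy-starved tissue degrades adenine
  nucleotides to hypoxanthine, whose oxidation by xanthine oxidase
  produces superoxide. The ischemia grid ramps hypoxanthine availability
  from 0.005 (basal purine turnover) to 0.05 μmol/g/min at full
  deprivation; this is the mechanism through which the antioxidant
  enzymes (SOD, catalase, glutathione peroxidase) gain flux room under
  oxygen deprivation. Without an ischemia-linked ROS source no bounded
  network can raise antioxidant flux while O2 falls.

## Conditions

The packaged `normal_physiological.tsv` carries the literature uptake and
release rates verbatim (glucose 0.16, O2 0.515–0.530, CO2 release 0.530,
glutamate 0.232, plus amino-acid and fatty-acid rates). Species outside
the core network are skipped with a warning when a condition is applied —
deliberately, so the same table can constrain models of any coverage. Two
glucose figures coexist in the literature: the directly measured 0.16 and
the half share of the whole-brain excitatory intake, 0.980/2 = 0.490; the
flux analyses use the latter (`excitatory_condition()`), which is the rate
consistent with the hexokinase flux the analysis reproduces.

Ischemia is modelled as graded deprivation: fractions
{1.0, 0.8, 0.6, 0.4, 0.2, 0.0} scale the oxygen and glucose uptake
capacities jointly (default), or factorially one at a time
(`mode="oxygen"` / `"glucose"`). The ATP-capability grid uses the joint
mode; its optimum is non-increasing in deprivation and exactly zero at
complete deprivation. The sampling comparison behind the enzyme direction
calls uses the oxygen arm at fraction 0.2 with glucose intact: early
ischemic tissue is oxygen-limited before it is glucose-limited, and at
complete joint deprivation every flux is zero, so all comparisons
degenerate there. This is the regime in which the classic Pasteur
response (glycolysis up, TCA down) is defined.

## Flux-space sampling and the Z statistic

Differential activity between two conditions is quantified per reaction by

    Z_i = (E_b(v_i) − E_a(v_i)) / sqrt(Var_b(v_i) + Var_a(v_i)),

computed over two sets of n feasible flux samples. For independent
samples the null distribution of Z has standard deviation 1/√n, and the
default direction-call threshold is 3/√n (three sigma); the looser
historical preset 0.15 is also provided. Zero-variance reactions with a
mean shift report signed infinity and a forced call.

The sampler emits mutually independent samples by construction: warm-up
points are the flux-variability vertices (maximising and minimising every
reaction, so the warm set spans every face of the polytope), and each
sample is produced by its own short hit-and-run walk — started at a
Dirichlet-weighted mixture of the warm points and advanced for 8×d
artificially-centered steps, where d is the null-space dimension.
Independence makes the 1/√n null law hold by construction (measured
1.03×1/√n on the core network at n = 1000); a single long chain was
rejected during development because its integrated autocorrelation in the
near-optimal corridor was of order 10³ steps, inflating sd(Z) ninefold.
A pure random-objective vertex sampler (`method="corners"`) is retained as
a cross-check; it calibrates but under-weights interior volume and
therefore misses coordinated low-flux chains such as the glutathione
branch. Comparisons sample the near-optimal region (≥90 % of the maximal
ATP drain by default) — the standard assumption that cells operate near
their energetic capability; the raw polytope is sampled when no objective
is supplied. Every emitted sample satisfies S·v = 0 within 1e−6 and all
bounds within 1e−9 (samples are clipped to bounds; the induced balance
error is far below tolerance). One integer seed fully determines a sample
set; the default 20170213 is an arbitrary fixed constant.

## Reconstruction and gap analysis

Draft extraction includes a reference reaction iff it carries a GPR rule
that evaluates true under the presence calls (AND = complex, all subunits
required; OR = isozymes, any suffices — the standard convention). Genes
without evidence count as absent and are logged. No presence threshold is
claimed as a default: when working from intensity scores the caller must
choose one. Completion copies connecting transporters from the reference
for every species present in ≥2 compartments and creates exchanges for
the extracellular species named by the active condition.

A dead end is a metabolite that no reaction can net-produce, or none can
net-consume, *within its bounds* — a reversible reaction serves both
roles, a reaction pinned to zero serves neither. A third class flags
metabolites whose connected component contains no exchange reaction
(isolated fragments); in a model with no exchanges at all this notion is
vacuous and nothing is flagged. Gap-fill candidates are reference
reactions that serve the missing role, ranked by how few new metabolites
they introduce, ties broken lexicographically — a deterministic stand-in
for manual literature curation, with acceptance an explicit step.

## Problem sizes and verification

The shipped analyses run on the ~96-reaction core network: FBA and the
glutamate sweep complete in well under a second, sample sets of n = 1000
in a few seconds. The test suite verifies, among other properties: exact
anaerobic ATP yield (2 per glucose); monotone ATP decline to zero across
the deprivation grid; equality of the dead-end detector with a brute-force
oracle on all small fixtures; feasibility of every flux sample; the 1/√n
null calibration of Z at n = 1000; FBA agreement with an independent
solver (cobrapy) on the package's own SBML export; and recovery of the
known ischemic direction calls (hexokinase, GAPDH, catalase, superoxide
dismutase, glutathione peroxidase up; isocitrate dehydrogenase down).

## Limitations

The core network is a designed stand-in, not a subset of any genome-scale
reconstruction: pathway coverage, capacity parameters (PDH, malic enzyme)
and the hypoxanthine ramp are curation choices, so quantitative agreement
on it demonstrates the pipeline and the mechanism, not genome-scale
fidelity. The model is purely stoichiometric — no kinetics, no
thermodynamic loop constraints, no time course. The expression fixtures
use presence calls only and do not mimic microarray intensity
distributions. Glutamine release is zero under strict lexicographic
ATP-first optimisation (see Objectives); analyses of the cycle use
objective B alone or a custom objective order. Reduced pathway subsets of
the generator are intended as test fixtures and may legitimately contain
dead ends.
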