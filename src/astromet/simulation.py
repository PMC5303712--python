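"""Constraint-based simulation: conditions, FBA, ischemia grids, sampling.

Flux balance analysis solves ``max c·v  s.t.  S·v = 0, lb <= v <= ub`` with
the HiGHS solver (through :func:`scipy.optimize.linprog`).  Objectives are
optimised lexicographically — each objective is fixed at its optimum before
the next is solved — and an optional parsimonious post-pass minimises total
absolute flux at the final optimum so that reported flux vectors are
reproducible.

Flux-space sampling runs an independently restarted artificially-centered
hit-and-run walk in null-space coordinates, warm-started from
flux-variability vertices, so the emitted samples are mutually independent
(the Z statistic below then obeys its 1/sqrt(n) null law); a pure vertex
("corners") sampler is available as a cross-check.  Condition
comparisons are quantified by the per-reaction Z statistic

    Z_i = (E_b(V_i) − E_a(V_i)) / sqrt(Var_b(V_i) + Var_a(V_i)),

whose null distribution has standard deviation 1/sqrt(n) for n samples per
condition; the default direction-call threshold is 3/sqrt(n) (three sigma
under that null).  The looser historical threshold 0.15 is available as
:data:`Z_THRESHOLD_LOOSE`.

Units: all rates and bounds are μmol per g tissue per minute.  Exchange
fluxes are positive for secretion, negative for uptake.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

from .model import (
    MetabolicModel,
    build_stoichiometric_matrix,
    classify_reaction,
)

logger = logging.getLogger(__name__)

#: mass-balance residual tolerance for accepted flux vectors (flux units)
MASS_BALANCE_TOL = 1e-6
#: tolerated bound violation on sampled / reported fluxes
BOUND_TOL = 1e-9
#: loose direction-call preset (historical error bound)
Z_THRESHOLD_LOOSE = 0.15

DEFAULT_SEED = 20170213  # fixed arbitrary constant


class InfeasibleError(RuntimeError):
    """Raised when a requested condition admits no steady-state flux."""


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------


@dataclass
class Condition:
    """Named set of exchange-bound overrides.

    ``overrides`` maps an exchange-reaction id to a ``(lower, upper)`` pair;
    ``None`` leaves that bound at the model default.  The sign convention is
    the usual one: an uptake capacity r appears as ``lower = -r``, a release
    capacity r as ``upper = +r``.
    """

    name: str
    overrides: Dict[str, Tuple[Optional[float], Optional[float]]] = field(default_factory=dict)
    parent: Optional[str] = None

    def copy(self, name: Optional[str] = None) -> "Condition":
        return Condition(
            name=name or self.name,
            overrides={k: tuple(v) for k, v in self.overrides.items()},
            parent=self.parent,
        )

    def set_uptake(self, exchange_id: str, rate: float) -> None:
        if rate < 0:
            raise ValueError(f"uptake rate must be non-negative, got {rate}")
        lo, hi = self.overrides.get(exchange_id, (None, None))
        self.overrides[exchange_id] = (-rate, hi)

    def set_release(self, exchange_id: str, rate: float) -> None:
        if rate < 0:
            raise ValueError(f"release rate must be non-negative, got {rate}")
        lo, hi = self.overrides.get(exchange_id, (None, None))
        self.overrides[exchange_id] = (lo, rate)


def apply_condition(model: MetabolicModel, condition: Condition) -> MetabolicModel:
    """Return a copy of ``model`` with the condition's exchange bounds applied.

    Overrides that do not resolve to an exchange reaction are skipped with a
    warning (one per offending id); the model is otherwise untouched.
    """
    out = model.copy()
    for rid, (lo, hi) in condition.overrides.items():
        rxn = out.reactions.get(rid)
        if rxn is None:
            warnings.warn(
                f"condition {condition.name!r}: no reaction {rid!r} in model; skipped"
            )
            continue
        if classify_reaction(out, rid) != "exchange":
            warnings.warn(
                f"condition {condition.name!r}: {rid!r} is not an exchange reaction; skipped"
            )
            continue
        if lo is not None:
            rxn.lower_bound = float(lo)
        if hi is not None:
            rxn.upper_bound = float(hi)
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"condition {condition.name!r} leaves {rid!r} with lb > ub"
            )
    return out


DEFAULT_ISCHEMIA_STEPS = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)

#: hypoxanthine availability ramp: (normal turnover, full-deprivation surge).
#: Energy-starved tissue degrades adenine nucleotides to hypoxanthine, the
#: substrate of the xanthine-oxidase ROS burst.
HYPOXANTHINE_SURGE = (0.005, 0.05)


def make_ischemia_grid(
    base: Condition,
    steps: Optional[Sequence[float]] = None,
    mode: str = "joint",
    oxygen_exchange: str = "EX_o2",
    glucose_exchange: str = "EX_glc",
    hypoxanthine_exchange: str = "EX_hxan",
    hypoxanthine_surge: Optional[Tuple[float, float]] = HYPOXANTHINE_SURGE,
) -> List[Condition]:
    """Graded oxygen/glucose-deprivation conditions.

    One condition per fraction f: the uptake magnitudes of oxygen and glucose
    (``mode='joint'``), oxygen only (``'oxygen'``) or glucose only
    (``'glucose'``) are scaled by f; all other bounds are inherited.  If a
    hypoxanthine surge is configured, its uptake capacity ramps linearly from
    the normal turnover at f=1 to the surge value at f=0.
    """
    if mode not in {"joint", "oxygen", "glucose"}:
        raise ValueError(f"unknown deprivation mode {mode!r}")
    steps = DEFAULT_ISCHEMIA_STEPS if steps is None else tuple(steps)
    for f in steps:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"deprivation fraction {f} outside [0, 1]")

    def uptake_of(exchange_id: str) -> float:
        lo, _hi = base.overrides.get(exchange_id, (None, None))
        if lo is None:
            raise ValueError(
                f"base condition {base.name!r} does not constrain {exchange_id!r}; "
                "cannot scale an undefined maximum rate"
            )
        return -float(lo)

    o2_max = uptake_of(oxygen_exchange) if mode in {"joint", "oxygen"} else None
    glc_max = uptake_of(glucose_exchange) if mode in {"joint", "glucose"} else None

    grid: List[Condition] = []
    for f in steps:
        cond = base.copy(name=f"{base.name}_{mode}_f{f:g}")
        cond.parent = base.name
        if o2_max is not None:
            cond.set_uptake(oxygen_exchange, f * o2_max)
        if glc_max is not None:
            cond.set_uptake(glucose_exchange, f * glc_max)
        if hypoxanthine_surge is not None:
            h0, h1 = hypoxanthine_surge
            cond.set_uptake(hypoxanthine_exchange, h0 + (1.0 - f) * (h1 - h0))
        grid.append(cond)
    return grid


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


@dataclass
class ObjectiveFunction:
    name: str
    coefficients: Dict[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError(f"objective {self.name!r} has no non-zero coefficient")
        if self.sense not in {"maximize", "minimize"}:
            raise ValueError(f"bad sense {self.sense!r}")


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    objective_values: Dict[str, float]
    fluxes: Dict[str, float]
    active_condition: str = ""

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _lp_arrays(model: MetabolicModel):
    rids = model.reaction_ids()
    mat = build_stoichiometric_matrix(model)
    lb = np.array([model.reactions[r].lower_bound for r in rids])
    ub = np.array([model.reactions[r].upper_bound for r in rids])
    return rids, mat.S.tocsr(), lb, ub


def _objective_vector(rids: List[str], obj: ObjectiveFunction) -> np.ndarray:
    c = np.zeros(len(rids))
    index = {r: i for i, r in enumerate(rids)}
    for rid, w in obj.coefficients.items():
        if rid not in index:
            raise KeyError(f"objective {obj.name!r} references unknown reaction {rid!r}")
        c[index[rid]] = w
    return c


def run_fba(
    model: MetabolicModel,
    objectives: Sequence[ObjectiveFunction],
    parsimonious: bool = True,
    condition_name: str = "",
    optimum_tol: float = 1e-9,
) -> FBAResult:
    """Lexicographic FBA with optional parsimonious post-pass.

    Objectives are optimised in order; each optimum is fixed (within
    ``optimum_tol`` relative slack) as a constraint before the next solve.
    The parsimonious pass minimises total absolute flux at the joint optimum,
    making the reported vector v unique in practice.  An infeasible or
    unbounded problem is reported in ``status``; no fluxes are fabricated.
    """
    if not objectives:
        raise ValueError("at least one objective is required")
    rids, S, lb, ub = _lp_arrays(model)
    n = len(rids)
    A_eq = S
    b_eq = np.zeros(S.shape[0])
    extra_rows: List[np.ndarray] = []
    extra_rhs: List[float] = []
    obj_values: Dict[str, float] = {}
    x = None
    for obj in objectives:
        c = _objective_vector(rids, obj)
        sign = -1.0 if obj.sense == "maximize" else 1.0
        A_ub = np.vstack(extra_rows) if extra_rows else None
        b_ub = np.array(extra_rhs) if extra_rows else None
        res = optimize.linprog(
            sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
            bounds=list(zip(lb, ub)), method="highs",
        )
        if res.status != 0:
            return FBAResult(
                status=_STATUS.get(res.status, "failed"),
                objective_value=None,
                objective_values=obj_values,
                fluxes={},
                active_condition=condition_name,
            )
        opt = float(c @ res.x)
        obj_values[obj.name] = opt
        eps = optimum_tol * max(1.0, abs(opt)) + 1e-9
        # keep c·v within eps of the optimum for subsequent solves
        if obj.sense == "maximize":
            extra_rows.append(-c)
            extra_rhs.append(-(opt - eps))
        else:
            extra_rows.append(c)
            extra_rhs.append(opt + eps)
        x = res.x

    if parsimonious:
        # min sum(t) with -t <= v <= t, objectives held at their optima
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        eye = sparse.identity(n, format="csr")
        rows = [
            sparse.hstack([eye, -eye]),      # v - t <= 0
            sparse.hstack([-eye, -eye]),     # -v - t <= 0
        ]
        rhs = [np.zeros(n), np.zeros(n)]
        if extra_rows:
            rows.append(sparse.hstack([sparse.csr_matrix(np.vstack(extra_rows)),
                                       sparse.csr_matrix((len(extra_rows), n))]))
            rhs.append(np.array(extra_rhs))
        A_ub2 = sparse.vstack(rows, format="csr")
        b_ub2 = np.concatenate(rhs)
        A_eq2 = sparse.hstack([A_eq, sparse.csr_matrix((A_eq.shape[0], n))], format="csr")
        big = max(np.max(np.abs(lb)), np.max(np.abs(ub))) if n else 1.0
        bounds2 = list(zip(lb, ub)) + [(0.0, big)] * n
        res2 = optimize.linprog(
            c2, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq2, b_eq=b_eq,
            bounds=bounds2, method="highs",
        )
        if res2.status == 0:
            x = res2.x[:n]
        else:  # pragma: no cover - pFBA of a solved LP should not fail
            logger.warning("parsimonious pass failed (%s); reporting plain optimum", res2.status)

    fluxes = {rid: float(v) for rid, v in zip(rids, x)}
    primary = objectives[0].name
    return FBAResult(
        status="optimal",
        objective_value=obj_values[primary],
        objective_values=obj_values,
        fluxes=fluxes,
        active_condition=condition_name,
    )


# ---------------------------------------------------------------------------
# Objectives of the astrocyte analysis
# ---------------------------------------------------------------------------

ATP_SYNTHASE_ID = "ATPS"
ATP_DEMAND_ID = "DM_atp"
GLUGLN_CYCLE_ID = "GLUGLN_CYCLE"

#: species required to express the glutamate/glutamine cycle pseudo-reaction
_CYCLE_SPECIES = ("glu__x", "gln__c", "glu__c", "gln__x")
_SYNTHASE_STOICH = {
    "adp__m": -1.0, "h__c": -4.0, "pi__m": -1.0,
    "atp__m": 1.0, "h__m": 3.0, "h2o__m": 1.0,
}


def make_astrocyte_objectives(model: MetabolicModel) -> List[ObjectiveFunction]:
    """The two astrocyte objectives: ATP production, then glutamate/glutamine cycling.

    Ensures the model carries (inserting them if missing):

    * the mitochondrial ATP synthase written exactly as
      ``ADP[m] + 4 H+[c] + Pi[m] => ATP[m] + 3 H+[m] + H2O[m]``, and
    * the glutamate/glutamine cycle pseudo-reaction
      ``Glutamate[x] + Glutamine[c] => Glutamate[c] + Glutamine[x]``.

    Objective A maximises the total cytosolic ATP drain (the demand reaction
    ``DM_atp``): in a proton-explicit network this is the quantity that
    counts both oxidative ATP (delivered through the synthase above) and
    substrate-level ATP from glycolysis.  Objective B maximises the cycle
    pseudo-reaction.  Missing required species raise an error naming them.
    """
    from .model import Reaction  # local import to avoid cycle at module load

    missing = [m for m in _CYCLE_SPECIES if m not in model.metabolites]
    missing += [m for m in _SYNTHASE_STOICH if m not in model.metabolites]
    missing += [m for m in ("atp__c", "adp__c", "pi__c") if m not in model.metabolites]
    if missing:
        raise KeyError(
            "model lacks species required by the astrocyte objectives: "
            + ", ".join(sorted(set(missing)))
        )
    if ATP_SYNTHASE_ID not in model.reactions:
        model.add_reaction(Reaction(
            ATP_SYNTHASE_ID, dict(_SYNTHASE_STOICH), name="ATP synthase"))
    if GLUGLN_CYCLE_ID not in model.reactions:
        model.add_reaction(Reaction(
            GLUGLN_CYCLE_ID,
            {"glu__x": -1.0, "gln__c": -1.0, "glu__c": 1.0, "gln__x": 1.0},
            name="glutamate/glutamine cycle pseudo-reaction"))
    if ATP_DEMAND_ID not in model.reactions:
        model.add_reaction(Reaction(
            ATP_DEMAND_ID,
            {"atp__c": -1.0, "h2o__c": -1.0, "adp__c": 1.0, "pi__c": 1.0, "h__c": 1.0},
            name="ATP demand (cytosolic drain)"))
    return [
        ObjectiveFunction("atp_production", {ATP_DEMAND_ID: 1.0}),
        ObjectiveFunction("glu_gln_cycle", {GLUGLN_CYCLE_ID: 1.0}),
    ]


def sweep_glutamate(
    model: MetabolicModel,
    condition: Condition,
    uptake_values: Sequence[float],
    glutamate_exchange: str = "EX_glu",
) -> pd.DataFrame:
    """Lexicographic FBA across a grid of fixed glutamate uptake rates.

    At each grid point the glutamate exchange is pinned to the given uptake
    (lb = ub = −v) and the usual ATP-then-cycle lexicographic FBA (with
    parsimonious post-pass) is solved.  Reports glutamine release, lactate
    release, glucose uptake, net 2-oxoglutarate (AKG) production — the flux
    leaving through the AKG exchange — and the ATP-demand flux.  Infeasible
    points are reported as such and the sweep continues.
    """
    if any(v < 0 for v in uptake_values):
        raise ValueError("glutamate uptake values must be non-negative")
    rows = []
    for v in uptake_values:
        cond = condition.copy(name=f"{condition.name}_glu{v:g}")
        cond.overrides[glutamate_exchange] = (-float(v), -float(v))
        m = apply_condition(model, cond)
        objectives = make_astrocyte_objectives(m)
        res = run_fba(m, objectives, parsimonious=True, condition_name=cond.name)
        row = {"glutamate_uptake": v, "status": res.status}
        if res.status == "optimal":
            fx = res.fluxes
            row.update(
                glutamine_release=fx.get("EX_gln", 0.0),
                lactate_release=fx.get("EX_lac", 0.0),
                glucose_uptake=-fx.get("EX_glc", 0.0),
                akg_production=fx.get("EX_akg", 0.0),
                atp_demand=fx.get(ATP_DEMAND_ID, 0.0),
            )
        else:
            row.update(
                glutamine_release=np.nan, lactate_release=np.nan,
                glucose_uptake=np.nan, akg_production=np.nan, atp_demand=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flux-space sampling
# ---------------------------------------------------------------------------


@dataclass
class SampleSet:
    """Feasible flux samples for one condition, with cached moments."""

    condition: str
    n_samples: int
    reaction_ids: List[str]
    samples: np.ndarray  # (n_samples, n_reactions)
    mean: np.ndarray
    var: np.ndarray
    seed: int
    method: str

    def mean_of(self, reaction_id: str) -> float:
        return float(self.mean[self.reaction_ids.index(reaction_id)])


def _vertex(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    return res


def sample_flux_space(
    model: MetabolicModel,
    condition: Optional[Condition],
    n_samples: int,
    seed: int = DEFAULT_SEED,
    method: str = "achr",
    objective: Optional[ObjectiveFunction] = None,
    objective_fraction: float = 0.9,
    thinning: Optional[int] = None,
) -> SampleSet:
    """Sample the steady-state flux polytope of a model under a condition.

    Every returned sample satisfies S·v = 0 within :data:`MASS_BALANCE_TOL`
    and all bounds.  If ``objective`` is given, sampling is restricted to the
    region achieving at least ``objective_fraction`` of its optimum (the
    near-optimal flux space).  ``method='achr'`` emits one independently
    restarted hit-and-run walk per sample (``thinning`` sets the steps per
    walk, default 8× the polytope dimension); ``method='corners'`` returns
    independent random-objective vertices.  The integer ``seed`` fully
    determines the output.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if method not in {"achr", "corners"}:
        raise ValueError(f"unknown sampling method {method!r}")
    m = apply_condition(model, condition) if condition is not None else model.copy()
    rids, S, lb, ub = _lp_arrays(m)
    n = len(rids)
    bounds = list(zip(lb, ub))
    b_eq = np.zeros(S.shape[0])

    A_ub = None
    b_ub = None
    if objective is not None:
        c_obj = _objective_vector(rids, objective)
        base = run_fba(m, [objective], parsimonious=False)
        if base.status != "optimal":
            raise InfeasibleError(
                f"condition {getattr(condition, 'name', '?')!r} is {base.status}"
            )
        opt = base.objective_value
        if objective.sense == "maximize":
            rhs = opt - (1.0 - objective_fraction) * abs(opt)
            A_ub = np.atleast_2d(-c_obj)
            b_ub = np.array([-rhs])
        else:
            rhs = opt + (1.0 - objective_fraction) * abs(opt)
            A_ub = np.atleast_2d(c_obj)
            b_ub = np.array([rhs])
    else:
        feas = _vertex(np.zeros(n), None, None, S, b_eq, bounds)
        if feas.status != 0:
            raise InfeasibleError(
                f"condition {getattr(condition, 'name', '?')!r} is "
                f"{_STATUS.get(feas.status, 'not solvable')}"
            )

    rng = np.random.default_rng(seed)

    if method == "corners":
        samples = np.empty((n_samples, n))
        for i in range(n_samples):
            c = rng.standard_normal(n)
            res = _vertex(c, A_ub, b_ub, S, b_eq, bounds)
            if res.status != 0:  # pragma: no cover - feasibility pre-checked
                raise InfeasibleError("vertex LP failed during sampling")
            samples[i] = res.x
    else:
        samples = _achr(
            rng, n_samples, rids, S, lb, ub, A_ub, b_ub, bounds, b_eq, thinning
        )

    samples = np.clip(samples, lb[None, :], ub[None, :])
    mean = samples.mean(axis=0)
    var = samples.var(axis=0, ddof=1)
    return SampleSet(
        condition=getattr(condition, "name", "") or "",
        n_samples=n_samples,
        reaction_ids=rids,
        samples=samples,
        mean=mean,
        var=var,
        seed=seed,
        method=method,
    )


def _achr(rng, n_samples, rids, S, lb, ub, A_ub, b_ub, bounds, b_eq, thinning):
    n = len(rids)
    fixed = ub - lb < 1e-12
    # equality system: mass balance + pinned fluxes
    rows = [S.toarray()] if S.shape[0] else [np.zeros((0, n))]
    rhs = [b_eq]
    if fixed.any():
        eye = np.eye(n)[fixed]
        rows.append(eye)
        rhs.append(lb[fixed])
    E = np.vstack(rows)
    N = linalg.null_space(E)
    d = N.shape[1]

    # warm-up with flux-variability vertices: maximising and minimising every
    # reaction guarantees the warm set spans the polytope, so the chain can
    # reach every face (random-objective vertices alone can miss coordinated
    # low-flux chains entirely)
    warm_list = []
    for j in range(n):
        if fixed[j]:
            continue
        c = np.zeros(n)
        for sign in (1.0, -1.0):
            c[j] = sign
            res = _vertex(c, A_ub, b_ub, S, b_eq, bounds)
            if res.status != 0:
                raise InfeasibleError("warm-up LP failed during sampling")
            warm_list.append(res.x)
        c[j] = 0.0
    if not warm_list:
        res = _vertex(np.zeros(n), A_ub, b_ub, S, b_eq, bounds)
        if res.status != 0:
            raise InfeasibleError("warm-up LP failed during sampling")
        warm_list.append(res.x)
    warm = np.array(warm_list)
    v0 = warm.mean(axis=0)

    if d == 0:  # fully determined polytope (all bounds pinned)
        return np.tile(v0, (n_samples, 1))

    alphas = (warm - v0) @ N  # coordinates of warm points in the null space
    center = alphas.mean(axis=0)
    cut = None
    if A_ub is not None:
        # single near-optimality cut: a·v <= b  ->  (a·N)·alpha <= b - a·v0
        a = A_ub[0]
        cut = (a @ N, float(b_ub[0] - a @ v0))

    steps = int(thinning) if thinning else 8 * d
    margin = 1e-12
    n_warm = len(alphas)
    out = np.empty((n_samples, n))
    for k in range(n_samples):
        # independent restart: a Dirichlet mixture of the warm vertices is a
        # feasible interior point, and using a fresh chain per sample makes
        # the emitted samples mutually independent (so the Z statistic's
        # 1/sqrt(n) null law applies)
        alpha = rng.dirichlet(np.ones(n_warm)) @ alphas
        done = 0
        attempts = 0
        while done < steps and attempts < 10 * steps:
            attempts += 1
            delta = alphas[rng.integers(n_warm)] - center
            nrm = np.linalg.norm(delta)
            if nrm < 1e-12:
                continue
            delta = delta / nrm
            dv = N @ delta
            v = v0 + N @ alpha
            # line search: lb <= v + t*dv <= ub (and the optimality cut)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_hi = np.where(dv > 1e-11, (ub - v) / dv, np.inf)
                t_lo = np.where(dv > 1e-11, (lb - v) / dv, -np.inf)
                t_hi2 = np.where(dv < -1e-11, (lb - v) / dv, np.inf)
                t_lo2 = np.where(dv < -1e-11, (ub - v) / dv, -np.inf)
            tmax = min(np.min(t_hi), np.min(t_hi2))
            tmin = max(np.max(t_lo), np.max(t_lo2))
            if cut is not None:
                a_alpha, rhs_c = cut
                slope = float(a_alpha @ delta)
                level = float(a_alpha @ alpha)
                if slope > 1e-11:
                    tmax = min(tmax, (rhs_c - level) / slope)
                elif slope < -1e-11:
                    tmin = max(tmin, (rhs_c - level) / slope)
            tmin += margin
            tmax -= margin
            if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax - tmin < 1e-10:
                continue
            t = rng.uniform(tmin, tmax)
            alpha = alpha + t * delta
            done += 1
        out[k] = v0 + N @ alpha
    return out


# ---------------------------------------------------------------------------
# Differential flux Z-score
# ---------------------------------------------------------------------------


@dataclass
class FluxZScore:
    """Per-reaction Z statistic between two sample sets, with direction calls."""

    z: Dict[str, float]
    calls: Dict[str, str]  # up | down | unchanged
    n_samples: int
    threshold: float

    def call(self, reaction_id: str) -> str:
        return self.calls[reaction_id]


def zscore_compare(
    a: SampleSet,
    b: SampleSet,
    threshold: Optional[float] = None,
) -> FluxZScore:
    """Z_i = (E_b − E_a) / sqrt(Var_b + Var_a) with direction calls.

    ``threshold`` defaults to 3/sqrt(n) (three sigma under the sampling
    null, whose sd is 1/sqrt(n)).  A zero denominator with a non-zero mean
    difference yields signed infinity and a forced call, which is logged; a
    fully degenerate reaction (zero difference, zero variance) scores 0.
    """
    if a.reaction_ids != b.reaction_ids:
        raise ValueError("sample sets index different reactions")
    n = min(a.n_samples, b.n_samples)
    thr = threshold if threshold is not None else 3.0 / np.sqrt(n)
    z: Dict[str, float] = {}
    calls: Dict[str, str] = {}
    for i, rid in enumerate(a.reaction_ids):
        num = float(b.mean[i] - a.mean[i])
        den = float(np.sqrt(b.var[i] + a.var[i]))
        if den == 0.0:
            if abs(num) < 1e-12:
                zi = 0.0
            else:
                zi = np.inf if num > 0 else -np.inf
                logger.info(
                    "reaction %s: zero variance with mean shift %.3g; "
                    "Z reported as signed infinity", rid, num,
                )
        else:
            zi = num / den
        z[rid] = zi
        if zi > thr:
            calls[rid] = "up"
        elif zi < -thr:
            calls[rid] = "down"
        else:
            calls[rid] = "unchanged"
    return FluxZScore(z=z, calls=calls, n_samples=n, threshold=thr)
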