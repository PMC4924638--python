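"""Linear programming core: growth maximization and protein-demand problems.

The ME constraint set is linear at a fixed growth rate mu, so maximal
growth is located by bisecting mu on LP feasibility over the bracket
[0, kappa/L_ribosome].  Alternate optima at the top are resolved by a
secondary objective that maximizes the un-modelled (dummy) protein, which
under the budget equality is the same as minimizing total modelled protein
mass; this yields the unique minimal proteome whose support defines the
expressed set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import (
    CatalyzedReaction,
    ConfigurationError,
    Environment,
    MEModel,
    ModelError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthSolution",
    "DemandProfile",
    "InfeasibleError",
    "assemble_lp",
    "solve_at_growth",
    "max_growth",
    "min_protein_demand",
    "overexpression_sweep",
    "EXPRESSION_THRESHOLD",
    "BISECTION_TOL",
]

#: expression threshold: protein i counts as expressed when
#: e_i * mw_i > EXPRESSION_THRESHOLD * proteome_budget
EXPRESSION_THRESHOLD = 1e-9

#: absolute bisection tolerance on the growth rate (1/h)
BISECTION_TOL = 1e-6


class InfeasibleError(ModelError):
    """The model cannot grow (or even rest) in the given environment."""


@dataclass
class GrowthSolution:
    """Outcome of a growth simulation at (or up to) a growth rate.

    ``protein_mass_fraction`` is in g/gDW and includes the dummy protein;
    the entries sum to the proteome budget in any optimal solution.
    ``expressed_set`` contains proteins with synthesis above threshold.
    """

    mu: float
    fluxes: dict[str, float]
    protein_mass_fraction: dict[str, float]
    expressed_set: frozenset[str]
    status: str = "optimal"
    protein_amount: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class DemandProfile:
    """Minimal per-protein requirements at a fixed measured growth rate.

    Obtained by maximizing dummy-protein expression at fixed mu: whatever
    budget the dummy can absorb is not needed for growth, so the remaining
    (modelled) expression is the minimal demand.  ``max_unused_fraction``
    is the dummy's share of the proteome budget at the optimum.
    """

    mu_fixed: float
    demand_mass_fraction: dict[str, float]
    max_unused_fraction: float
    status: str = "optimal"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class _LPIndex:
    """Variable layout of an assembled LP."""

    n_vars: int
    flux_fwd: dict[str, int]
    flux_bwd: dict[str, int]
    usage: dict[tuple[str, str], int]
    protein: dict[str, int]


@dataclass
class _LP:
    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    bounds: list[tuple[float, Optional[float]]]
    index: _LPIndex


def _resolve_kcat(
    rxn: CatalyzedReaction,
    prot: str,
    overrides: Optional[Mapping[tuple[str, str], float]],
) -> float:
    if overrides is not None and (rxn.id, prot) in overrides:
        kcat = overrides[(rxn.id, prot)]
        if kcat <= 0:
            raise ConfigurationError(
                f"kcat override for ({rxn.id}, {prot}) must be > 0"
            )
        return kcat
    return rxn.kcat_per_isozyme[prot]


def assemble_lp(
    model: MEModel,
    env: Environment,
    mu: float,
    *,
    kcat_overrides: Optional[Mapping[tuple[str, str], float]] = None,
    protein_caps: Optional[Mapping[str, float]] = None,
    forced_dummy_fraction: Optional[float] = None,
    isozyme_equality: bool = False,
) -> _LP:
    """Build the feasibility LP of the ME model at fixed growth rate mu.

    Variables are reaction fluxes (split forward/backward for reversible
    reactions), per-(reaction, isozyme) usage amounts, and protein amounts.
    """
    if mu < 0:
        raise ConfigurationError(f"mu must be >= 0, got {mu}")
    model.validate_environment(env)
    if kcat_overrides:
        rxn_map = model.reaction_by_id
        for rid, pid in kcat_overrides:
            if rid not in rxn_map:
                raise ConfigurationError(f"kcat override for unknown reaction {rid!r}")
            if pid not in rxn_map[rid].kcat_per_isozyme:
                raise ConfigurationError(
                    f"kcat override for unknown isozyme {pid!r} of {rid!r}"
                )
    if protein_caps:
        known = {p.id for p in model.proteins}
        unknown = set(protein_caps) - known
        if unknown:
            raise ConfigurationError(
                f"protein caps reference unknown proteins: {sorted(unknown)}"
            )
    if forced_dummy_fraction is not None and not 0 <= forced_dummy_fraction <= 1:
        raise ConfigurationError("forced dummy fraction must lie in [0, 1]")

    flux_fwd: dict[str, int] = {}
    flux_bwd: dict[str, int] = {}
    usage: dict[tuple[str, str], int] = {}
    protein: dict[str, int] = {}
    n = 0
    for rxn in model.reactions:
        flux_fwd[rxn.id] = n
        n += 1
        if rxn.reversible and not rxn.is_exchange:
            flux_bwd[rxn.id] = n
            n += 1
    for rxn in model.reactions:
        for prot in sorted(rxn.kcat_per_isozyme):
            usage[(rxn.id, prot)] = n
            n += 1
    for spec in model.proteins:
        protein[spec.id] = n
        n += 1
    index = _LPIndex(n, flux_fwd, flux_bwd, usage, protein)

    bounds: list[tuple[float, Optional[float]]] = [(0.0, None)] * n
    for rxn in model.reactions:
        j = flux_fwd[rxn.id]
        if rxn.id == model.biomass_reaction:
            bounds[j] = (mu, mu)
        elif rxn.is_exchange:
            if rxn.id in env.open_exchanges:
                ub = env.uptake_bounds.get(rxn.id)
                bounds[j] = (0.0, ub)
            else:
                bounds[j] = (0.0, 0.0)
    if protein_caps:
        for pid, cap in protein_caps.items():
            bounds[protein[pid]] = (0.0, max(cap, 0.0))

    met_index = {m: i for i, m in enumerate(model.metabolites)}
    n_eq = len(model.metabolites) + 1
    eq_extra: list[np.ndarray] = []
    A_eq = np.zeros((n_eq, n))
    b_eq = np.zeros(n_eq)
    for rxn in model.reactions:
        for met, coeff in rxn.stoichiometry.items():
            row = met_index[met]
            A_eq[row, flux_fwd[rxn.id]] += coeff
            if rxn.id in flux_bwd:
                A_eq[row, flux_bwd[rxn.id]] -= coeff
    budget_row = len(model.metabolites)
    for spec in model.proteins:
        A_eq[budget_row, protein[spec.id]] = spec.mw
    b_eq[budget_row] = model.proteome_budget
    if isozyme_equality:
        for rxn in model.reactions:
            prots = sorted(rxn.kcat_per_isozyme)
            for other in prots[1:]:
                row = np.zeros(n)
                row[usage[(rxn.id, prots[0])]] = 1.0
                row[usage[(rxn.id, other)]] = -1.0
                eq_extra.append(row)
    if eq_extra:
        A_eq = np.vstack([A_eq, np.array(eq_extra)])
        b_eq = np.concatenate([b_eq, np.zeros(len(eq_extra))])

    ub_rows: list[np.ndarray] = []
    ub_rhs: list[float] = []
    # enzyme capacity per catalysed reaction
    for rxn in model.reactions:
        if not rxn.catalyzed:
            continue
        row = np.zeros(n)
        row[flux_fwd[rxn.id]] = 1.0
        if rxn.id in flux_bwd:
            row[flux_bwd[rxn.id]] = 1.0
        for prot in rxn.kcat_per_isozyme:
            row[usage[(rxn.id, prot)]] = -_resolve_kcat(rxn, prot, kcat_overrides)
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # usage cannot exceed the protein amount
    by_protein: dict[str, list[tuple[str, str]]] = {}
    for key in usage:
        by_protein.setdefault(key[1], []).append(key)
    for pid, keys in sorted(by_protein.items()):
        row = np.zeros(n)
        for key in keys:
            row[usage[key]] = 1.0
        row[protein[pid]] = -1.0
        ub_rows.append(row)
        ub_rhs.append(0.0)
    # ribosome capacity: sum_i L_i * mu * e_i <= kappa * e_ribo
    row = np.zeros(n)
    for spec in model.proteins:
        row[protein[spec.id]] += spec.length * mu
    row[protein[model.ribosome.protein]] -= model.ribosome.kappa
    ub_rows.append(row)
    ub_rhs.append(0.0)
    # forced dummy expression: mw_u * e_u >= phi * Phi
    if forced_dummy_fraction is not None:
        dummy = model.dummy_protein
        row = np.zeros(n)
        row[protein[dummy.id]] = -dummy.mw
        ub_rows.append(row)
        ub_rhs.append(-forced_dummy_fraction * model.proteome_budget)

    return _LP(
        c=np.zeros(n),
        A_ub=np.array(ub_rows),
        b_ub=np.array(ub_rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        index=index,
    )


def _solve(lp: _LP, c: Optional[np.ndarray] = None):
    return linprog(
        c if c is not None else lp.c,
        A_ub=lp.A_ub,
        b_ub=lp.b_ub,
        A_eq=lp.A_eq,
        b_eq=lp.b_eq,
        bounds=lp.bounds,
        method="highs",
    )


def _extract(model: MEModel, lp: _LP, x: np.ndarray, mu: float) -> GrowthSolution:
    fluxes = {}
    for rid, j in lp.index.flux_fwd.items():
        v = x[j]
        if rid in lp.index.flux_bwd:
            v -= x[lp.index.flux_bwd[rid]]
        fluxes[rid] = float(v)
    mass = {}
    amount = {}
    expressed = set()
    threshold = EXPRESSION_THRESHOLD * model.proteome_budget
    for spec in model.proteins:
        e = float(x[lp.index.protein[spec.id]])
        amount[spec.id] = e
        m = e * spec.mw
        mass[spec.id] = m
        if m > threshold:
            expressed.add(spec.id)
    return GrowthSolution(
        mu=mu,
        fluxes=fluxes,
        protein_mass_fraction=mass,
        expressed_set=frozenset(expressed),
        protein_amount=amount,
    )


def solve_at_growth(
    model: MEModel,
    env: Environment,
    mu: float,
    *,
    objective: str = "max_dummy",
    **assemble_kw,
) -> Optional[GrowthSolution]:
    """Solve the fixed-mu LP; return None when infeasible.

    ``objective`` is ``"max_dummy"`` (minimal modelled proteome, the
    default witness) or ``"feasibility"``.
    """
    lp = assemble_lp(model, env, mu, **assemble_kw)
    c = None
    if objective == "max_dummy":
        c = np.zeros(lp.index.n_vars)
        c[lp.index.protein[model.dummy_protein.id]] = -1.0
    elif objective != "feasibility":
        raise ConfigurationError(f"unknown objective {objective!r}")
    res = _solve(lp, c)
    if res.status != 0:
        return None
    return _extract(model, lp, res.x, mu)


def _feasible(model: MEModel, env: Environment, mu: float, assemble_kw) -> bool:
    lp = assemble_lp(model, env, mu, **assemble_kw)
    return _solve(lp).status == 0


def max_growth(
    model: MEModel,
    env: Environment,
    *,
    kcat_overrides: Optional[Mapping[tuple[str, str], float]] = None,
    protein_caps: Optional[Mapping[str, float]] = None,
    forced_dummy_fraction: Optional[float] = None,
    isozyme_equality: bool = False,
    tol: float = BISECTION_TOL,
) -> GrowthSolution:
    """Maximal growth rate by LP-feasibility bisection.

    The bracket is [0, kappa/L_ribosome].  At the located optimum a
    secondary objective maximizes the dummy protein so the reported
    proteome (and hence the expressed set) is the unique minimal one.
    Environments with ``fixed_growth`` are solved at that rate instead.
    """
    kw = dict(
        kcat_overrides=kcat_overrides,
        protein_caps=protein_caps,
        forced_dummy_fraction=forced_dummy_fraction,
        isozyme_equality=isozyme_equality,
    )
    if env.fixed_growth is not None:
        sol = solve_at_growth(model, env, env.fixed_growth, **kw)
        if sol is None:
            raise InfeasibleError(
                f"environment {env.id!r}: fixed growth rate "
                f"{env.fixed_growth} is infeasible"
            )
        return sol
    if not _feasible(model, env, 0.0, kw):
        raise InfeasibleError(
            f"environment {env.id!r}: model infeasible even at zero growth"
        )
    lo, hi = 0.0, model.mu_upper_bound
    if _feasible(model, env, hi, kw):
        logger.warning("growth feasible at the ribosome ceiling %.6g", hi)
        lo = hi
    else:
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _feasible(model, env, mid, kw):
                lo = mid
            else:
                hi = mid
    sol = solve_at_growth(model, env, lo, **kw)
    if sol is None:  # pragma: no cover - lo was just proven feasible
        raise InfeasibleError("bisection lost feasibility at the optimum")
    return sol


def min_protein_demand(
    model: MEModel,
    env: Environment,
    mu_measured: float,
    *,
    kcat_overrides: Optional[Mapping[tuple[str, str], float]] = None,
) -> DemandProfile:
    """Minimal protein demands at a fixed measured growth rate.

    The LP maximizes expression of the un-modelled (dummy) protein; the
    optimum forces every modelled protein to its minimal level required to
    sustain ``mu_measured``.  Infeasible rates are reported as such, never
    clamped.
    """
    sol = solve_at_growth(
        model, env, mu_measured, objective="max_dummy", kcat_overrides=kcat_overrides
    )
    if sol is None:
        return DemandProfile(
            mu_fixed=mu_measured,
            demand_mass_fraction={},
            max_unused_fraction=float("nan"),
            status="infeasible",
        )
    dummy_id = model.dummy_protein.id
    demands = {
        pid: m for pid, m in sol.protein_mass_fraction.items() if pid != dummy_id
    }
    unused = sol.protein_mass_fraction[dummy_id] / model.proteome_budget
    return DemandProfile(
        mu_fixed=mu_measured,
        demand_mass_fraction=demands,
        max_unused_fraction=float(min(max(unused, 0.0), 1.0)),
    )


def overexpression_sweep(
    model: MEModel,
    env: Environment,
    phi_grid: Sequence[float],
    **kwargs,
) -> list[tuple[float, float]]:
    """Maximal growth rate as a function of forced unused-protein fraction.

    Mirrors gratuitous-protein overexpression experiments: each grid point
    forces the dummy protein to occupy at least that fraction of the
    proteome budget and re-maximizes growth.
    """
    out = []
    for phi in phi_grid:
        if not 0 <= phi <= 1:
            raise ConfigurationError(f"phi must lie in [0, 1], got {phi}")
        sol = max_growth(model, env, forced_dummy_fraction=phi, **kwargs)
        out.append((float(phi), sol.mu))
    return out
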