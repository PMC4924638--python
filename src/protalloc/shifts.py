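"""Nutrient-shift fitness simulations under pre-shift proteome constraints.

Up-shift: steady-state growth is first simulated in the pre-shift
environment (optionally with a reduced in-vivo turnover, which inflates
the proteome needed per unit flux).  The instantaneous post-shift growth
rate is then the maximal growth in the new environment subject to every
constrained protein staying at or below its pre-shift amount — no new
synthesis has happened yet.  A proteome with zero excess pins the
instantaneous rate to the pre-shift rate; an over-expressed (low-turnover)
proteome allows an immediate gain.

Supplementation: growth under an element limitation is compared with
growth after an additional source is opened in excess.  Only sources of
the *limiting* element confer a benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .model import ConfigurationError, Environment, MEModel, apply_turnover
from .solver import GrowthSolution, max_growth, solve_at_growth

logger = logging.getLogger(__name__)

__all__ = ["ShiftScenario", "ShiftResult", "simulate_upshift", "simulate_supplementation"]

#: relative slack below which a protein cap counts as binding
BINDING_TOL = 1e-6


@dataclass(frozen=True)
class ShiftScenario:
    """An instantaneous environmental up-shift.

    ``turnover_pre`` scales the pre-shift model's catalytic rates; values
    below 1 emulate an under-utilized (over-expressed) pre-shift proteome.
    ``mu_pre`` fixes the pre-shift growth rate (the minimal proteome
    sustaining it is used); when None the pre-shift optimum is used.
    ``constrained_scope`` limits which proteins are capped post-shift
    (default: every modelled protein).
    """

    env_pre: Environment
    env_post: Environment
    turnover_pre: float = 1.0
    mu_pre: Optional[float] = None
    constrained_scope: Optional[frozenset[str]] = None


@dataclass
class ShiftResult:
    mu_pre: float
    mu_instantaneous: float
    binding_constraints: list[str]
    pre_solution: GrowthSolution = field(repr=False, default=None)


def simulate_upshift(
    model: MEModel, scenario: ShiftScenario, *, tol: float = 1e-8
) -> ShiftResult:
    """Instantaneous maximal growth after a shift, capped by the old proteome.

    ``tol`` is the growth-rate bisection tolerance of the post-shift
    problem (tighter than the default so cap-pinned optima resolve
    cleanly).
    """
    if scenario.constrained_scope is not None:
        unknown = set(scenario.constrained_scope) - {p.id for p in model.proteins}
        if unknown:
            raise ConfigurationError(
                f"constrained scope references unknown proteins: {sorted(unknown)}"
            )
    pre_model = (
        apply_turnover(model, scenario.turnover_pre)
        if scenario.turnover_pre != 1.0
        else model
    )
    if scenario.mu_pre is None:
        pre = max_growth(pre_model, scenario.env_pre)
    else:
        pre = solve_at_growth(pre_model, scenario.env_pre, scenario.mu_pre)
        if pre is None:
            raise ConfigurationError(
                f"pre-shift environment {scenario.env_pre.id!r} cannot sustain "
                f"mu = {scenario.mu_pre}"
            )
    scope = (
        frozenset(model.modeled_protein_ids)
        if scenario.constrained_scope is None
        else scenario.constrained_scope
    )
    caps = {pid: pre.protein_amount[pid] for pid in scope}
    post = max_growth(model, scenario.env_post, protein_caps=caps, tol=tol)
    binding = sorted(
        pid
        for pid, cap in caps.items()
        if cap > 0 and post.protein_amount[pid] >= cap * (1 - BINDING_TOL)
    )
    return ShiftResult(
        mu_pre=pre.mu,
        mu_instantaneous=post.mu,
        binding_constraints=binding,
        pre_solution=pre,
    )


def simulate_supplementation(
    model: MEModel,
    base_env: Environment,
    limiting_bounds: dict[str, float],
    supplement_exchange: str,
) -> tuple[float, float]:
    """Growth under an uptake limitation, without and with a supplement.

    ``limiting_bounds`` caps the named uptake fluxes (mmol/gDW/h);
    ``supplement_exchange`` is then opened unbounded.  Returns
    ``(mu_limited, mu_supplemented)``.
    """
    exchange_ids = {r.id for r in model.exchanges}
    if supplement_exchange not in exchange_ids:
        raise ConfigurationError(f"unknown supplement exchange {supplement_exchange!r}")
    unknown = set(limiting_bounds) - exchange_ids
    if unknown:
        raise ConfigurationError(f"unknown limited exchanges: {sorted(unknown)}")
    env_limited = base_env.bounded(limiting_bounds)
    mu_limited = max_growth(model, env_limited).mu
    env_supp = env_limited.opened(supplement_exchange)
    mu_supp = max_growth(model, env_supp).mu
    return mu_limited, mu_supp
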