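"""Kcat sampling, utilized-set ensembles, and proteome-utilization measures.

Which proteins a growth-maximizing cell *can* use in an environment depends
on uncertain enzymatic rate parameters: alternative pathways trade off
against each other depending on their kcats.  Sampling every kcat from the
global turnover-number distribution (base-10 lognormal, log10 mean 1.11,
log10 variance 1.31) and re-maximizing growth yields an ensemble of
utilized protein sets.  Interrogating measured abundances with this
ensemble turns a single proteomics column into a *distribution* of
un-utilized proteome fractions.

The under-utilized proteome is quantified separately: the ratio of the
model's minimal protein demand (at the measured growth rate) to the
measured abundance is proportional to the in-vivo turnover of that
protein, and max-normalizing the ratio per protein across conditions gives
a relative turnover on a 0-1 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import Environment, MEModel, ModelError
from .solver import DemandProfile, InfeasibleError, max_growth

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "UtilizationDistribution",
    "TurnoverTable",
    "sample_kcats",
    "utilized_sets",
    "unutilized_distribution",
    "turnover_ratios",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the global kcat distribution and ensemble size.

    Defaults follow the global distribution of catalytic turnover numbers:
    log10(kcat) ~ Normal(mean=1.11, variance=1.31), with 100 sampled
    parameter sets per condition.
    """

    log10_mean: float = 1.11
    log10_variance: float = 1.31
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log10_variance <= 0:
            raise ModelError("log10_variance must be > 0")
        if self.n_samples < 0:
            raise ModelError("n_samples must be >= 0")


@dataclass
class UtilizationDistribution:
    """Per-condition distribution of (un-)utilized proteome fractions.

    One entry per sampled kcat set.  Fractions are relative to the total
    measured proteome mass, so for a scope (the modelled proteome)
    ``utilized + unutilized + out-of-scope == 1`` sample-wise.
    """

    condition: str
    utilized: np.ndarray
    unutilized: np.ndarray

    def __post_init__(self) -> None:
        self.utilized = np.asarray(self.utilized, dtype=float)
        self.unutilized = np.asarray(self.unutilized, dtype=float)

    @property
    def summary(self) -> dict[str, float]:
        lo, med, hi = np.percentile(self.unutilized, [2.5, 50.0, 97.5])
        return {
            "unutilized_median": float(med),
            "unutilized_p2.5": float(lo),
            "unutilized_p97.5": float(hi),
            "utilized_median": float(np.median(self.utilized)),
        }


@dataclass
class TurnoverTable:
    """Demand/measured ratios and max-normalized relative turnover.

    ``ratio`` and ``relative`` are protein x condition frames; each row of
    ``relative`` has maximum 1.  ``condition_mean`` holds the mean relative
    turnover per condition over the scoped rows with a Student-t 95%
    confidence interval of the mean.
    """

    ratio: pd.DataFrame
    relative: pd.DataFrame
    condition_mean: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def sample_kcats(
    model: MEModel, config: SamplerConfig
) -> list[dict[tuple[str, str], float]]:
    """Draw independent kcat sets for every isozyme of every reaction.

    Each draw is ``10**X`` with ``X ~ Normal(log10_mean, log10_variance)``;
    the ribosome elongation capacity is *not* resampled.  Reproducible
    under a fixed seed.
    """
    keys = [
        (rxn.id, prot)
        for rxn in model.reactions
        for prot in sorted(rxn.kcat_per_isozyme)
    ]
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(config.log10_variance))
    draws = 10.0 ** rng.normal(
        config.log10_mean, sigma, size=(config.n_samples, len(keys))
    )
    return [dict(zip(keys, row)) for row in draws]


def utilized_sets(
    model: MEModel,
    env: Environment,
    kcat_samples: Sequence[Mapping[tuple[str, str], float]],
    **solver_kw,
) -> list[frozenset[str]]:
    """One utilized (expressed) protein set per sampled kcat parameterization.

    Each set is the support of the growth-maximizing minimal proteome under
    that kcat draw, with the dummy protein excluded.  Infeasible samples
    are skipped with a warning; if every sample is infeasible the
    environment cannot support growth and an error is raised.
    """
    dummy_id = model.dummy_protein.id
    sets: list[frozenset[str]] = []
    n_bad = 0
    for i, sample in enumerate(kcat_samples):
        try:
            sol = max_growth(model, env, kcat_overrides=sample, **solver_kw)
        except InfeasibleError:
            n_bad += 1
            logger.warning("kcat sample %d infeasible in %s; skipped", i, env.id)
            continue
        sets.append(frozenset(sol.expressed_set - {dummy_id}))
    if kcat_samples and not sets:
        raise InfeasibleError(
            f"all {len(kcat_samples)} kcat samples infeasible in {env.id!r}"
        )
    if n_bad:
        logger.warning("%d/%d samples infeasible in %s", n_bad, len(kcat_samples), env.id)
    return sets


def unutilized_distribution(
    mass_fractions: pd.DataFrame,
    condition_sets: Mapping[str, Sequence[frozenset[str]]],
    scope: set[str] | frozenset[str],
) -> dict[str, UtilizationDistribution]:
    """Distributions of utilized / un-utilized proteome fraction per condition.

    ``mass_fractions`` is a protein x condition table (columns sum to 1).
    For each sampled utilized set U, the utilized fraction is the measured
    mass of U and the un-utilized fraction is the measured mass of
    ``scope \\ U``, both relative to total measured mass.  Proteins in U
    that were not measured contribute zero mass (logged).
    """
    scope = frozenset(scope)
    missing_scope = scope - set(mass_fractions.index)
    if missing_scope:
        raise ModelError(
            f"scope proteins absent from the abundance table: {sorted(missing_scope)[:5]}"
        )
    out: dict[str, UtilizationDistribution] = {}
    for cond, sets in condition_sets.items():
        col = mass_fractions[cond]
        total = float(col.sum())
        scope_mass = float(col.loc[sorted(scope)].sum())
        utilized = np.empty(len(sets))
        unutilized = np.empty(len(sets))
        warned: set[str] = set()
        for k, uset in enumerate(sets):
            present = uset & set(mass_fractions.index)
            absent = uset - present
            if absent - warned:
                logger.warning(
                    "condition %s: %d utilized proteins unmeasured (zero mass)",
                    cond,
                    len(absent - warned),
                )
                warned |= absent
            used_mass = float(col.loc[sorted(present)].sum())
            used_in_scope = float(col.loc[sorted(present & scope)].sum())
            utilized[k] = used_mass / total
            unutilized[k] = (scope_mass - used_in_scope) / total
        out[cond] = UtilizationDistribution(cond, utilized, unutilized)
    return out


def _mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    n = len(values)
    if n < 2:
        return mean, mean, mean
    sem = stats.sem(values)
    if sem == 0:
        return mean, mean, mean
    lo, hi = stats.t.interval(confidence, n - 1, loc=mean, scale=sem)
    return mean, float(lo), float(hi)


def turnover_ratios(
    demands: Mapping[str, DemandProfile],
    mass_fractions: pd.DataFrame,
    scope: Optional[set[str]] = None,
) -> TurnoverTable:
    """Demand/measured ratios and per-protein max-normalized relative turnover.

    ``demands`` maps condition -> minimal-demand profile at that
    condition's measured growth rate.  Proteins are restricted to those
    measured (> 0) in every condition and demanded (> 0) somewhere;
    excluded proteins are listed, never divided by zero.  The condition
    mean (with t-based 95% CI) is taken over ``scope`` rows (e.g. the core
    proteome) when given, otherwise over all retained rows.
    """
    conditions = list(demands)
    for cond in conditions:
        if not demands[cond].optimal:
            raise ModelError(f"demand profile for {cond!r} is not optimal")
    demand_df = pd.DataFrame(
        {c: pd.Series(demands[c].demand_mass_fraction) for c in conditions}
    ).fillna(0.0)
    common = demand_df.index.intersection(mass_fractions.index)
    demand_df = demand_df.loc[common]
    measured = mass_fractions.loc[common, conditions]

    positive = (measured > 0).all(axis=1)
    demanded = (demand_df > 0).any(axis=1)
    keep = positive & demanded
    excluded = sorted(common[~keep])
    if excluded:
        logger.info("turnover: excluded %d proteins (zero measured or never demanded)", len(excluded))
    ratio = demand_df.loc[keep] / measured.loc[keep]
    relative = ratio.div(ratio.max(axis=1), axis=0)

    rows = relative.index if scope is None else relative.index.intersection(sorted(scope))
    summary = {}
    for cond in conditions:
        mean, lo, hi = _mean_ci(relative.loc[rows, cond].to_numpy())
        summary[cond] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    condition_mean = pd.DataFrame(summary).T[["mean", "ci_low", "ci_high"]]
    return TurnoverTable(
        ratio=ratio, relative=relative, condition_mean=condition_mean, excluded=excluded
    )
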