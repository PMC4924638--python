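"""Synthetic ME models and expression datasets with planted ground truth.

The toy model has a deterministic, analysable topology: one dedicated
transporter/catabolic chain per carbon and per nitrogen source feeding a
shared biosynthetic backbone, plus a ribosome.  Backbone enzymes and the
ribosome are core by construction; each source chain belongs to its
element's segment.  Pathways for sources whose exchange is closed in a
condition are structurally unusable there, so planted "unused" mass on
them is un-utilized under *every* sampled kcat set, which makes parameter
recovery well-posed despite kcat sampling.

Proteomics generation follows the model's own logic: measured utilized
abundances are the minimal demands of the turnover-scaled model at the
generating growth rate (i.e. over-expression by 1/turnover relative to
nominal demands), the planted unused fraction u* of the proteome budget is
placed on unusable pathway proteins, and the per-condition total is the
proteome budget Phi — so converting copies back to mass fractions returns
exactly the planted fractions when noise is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CatalyzedReaction,
    Environment,
    MEModel,
    ModelError,
    ProteinSpec,
    RibosomeSpec,
    apply_turnover,
)
from .solver import max_growth, min_protein_demand

__all__ = [
    "GenerationError",
    "ToyModelConfig",
    "ConditionSpec",
    "StrainSpec",
    "SyntheticTruth",
    "make_toy_model",
    "designed_membership",
    "batch_environment",
    "make_proteomics",
    "make_trend_proteomics",
    "make_transcriptomics",
]

#: grams of protein per cell used to convert mass fractions to copies per
#: cell; an arbitrary fixed constant that cancels in every mass-fraction
#: computation.
CELL_PROTEIN_MASS = 2.0e-13
#: molecules per mmol
MOLECULES_PER_MMOL = 6.02214076e20


class GenerationError(ModelError):
    """A requested synthetic dataset is internally inconsistent."""


@dataclass(frozen=True)
class ToyModelConfig:
    """Topology and parameters of the toy ME model.

    kcats sit near the median of the global turnover-number distribution
    (10**1.11 ~ 13/h in the model's hourly units) so that sampled and
    nominal parameterizations live on the same scale.  Per-source kcat
    factors are drawn once from the seeded generator, giving sources
    distinct but reproducible qualities.
    """

    n_carbon_sources: int = 3
    n_nitrogen_sources: int = 2
    pathway_length: int = 2
    backbone_length: int = 3
    pathway_kcat: float = 80.0
    backbone_kcat: float = 8.0
    kcat_spread: float = 0.25
    enzyme_mw: float = 1.0
    enzyme_length: float = 3.0
    ribosome_kappa: float = 60.0
    ribosome_length: float = 10.0
    ribosome_mw: float = 3.0
    proteome_budget: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carbon_sources < 1 or self.n_nitrogen_sources < 1:
            raise GenerationError("need at least one source per element")
        for name in (
            "pathway_length",
            "backbone_length",
            "pathway_kcat",
            "backbone_kcat",
            "enzyme_mw",
            "enzyme_length",
            "ribosome_kappa",
            "ribosome_length",
            "ribosome_mw",
            "proteome_budget",
        ):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not 0 <= self.kcat_spread < 1:
            raise GenerationError("kcat_spread must lie in [0, 1)")


@dataclass(frozen=True)
class ConditionSpec:
    """One profiled growth condition with its planted allocation truth.

    ``unused_fraction`` (u*) is the planted un-utilized share of the
    measured proteome; ``turnover`` (tau*) the planted mean in-vivo
    turnover as a fraction of nominal capacity.  ``mu`` is required for
    chemostat conditions (the dilution rate) and computed self-consistently
    for batch/stress conditions when absent.  ``kcat_scale`` encodes
    stress conditions as a global catalytic-rate modifier.
    """

    id: str
    carbon: str = "c1"
    nitrogen: str = "n1"
    unused_fraction: float = 0.2
    turnover: float = 1.0
    mu: Optional[float] = None
    kcat_scale: float = 1.0
    kind: str = "batch"

    def __post_init__(self) -> None:
        if not 0 <= self.unused_fraction < 1:
            raise GenerationError("unused_fraction must lie in [0, 1)")
        if not 0 < self.turnover <= 1:
            raise GenerationError("turnover must lie in (0, 1]")
        if self.kcat_scale <= 0:
            raise GenerationError("kcat_scale must be positive")
        if self.kind not in ("batch", "chemostat", "stress"):
            raise GenerationError(f"unknown condition kind {self.kind!r}")
        if self.kind == "chemostat" and self.mu is None:
            raise GenerationError("chemostat conditions need a dilution rate mu")


@dataclass(frozen=True)
class StrainSpec:
    """An evolved strain for the transcriptome generator."""

    id: str
    mu: float
    delta_utilized: float = 0.0
    ribosome_factor: float = 1.0


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    conditions: dict[str, dict] = field(default_factory=dict)
    segment_label: dict[str, str] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0


def _source_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k + 1}" for k in range(n)]


def make_toy_model(config: ToyModelConfig) -> MEModel:
    """Deterministic toy ME model: source chains + shared backbone + ribosome."""
    rng = np.random.default_rng(config.seed)
    metabolites: list[str] = []
    proteins: list[ProteinSpec] = []
    reactions: list[CatalyzedReaction] = []

    def add_protein(pid: str) -> str:
        proteins.append(
            ProteinSpec(pid, mw=config.enzyme_mw, length=config.enzyme_length)
        )
        return pid

    def factor() -> float:
        return float(rng.uniform(1 - config.kcat_spread, 1 + config.kcat_spread))

    def add_chain(source: str, element: str, pool: str) -> None:
        ext = f"met_{source}"
        metabolites.append(ext)
        reactions.append(
            CatalyzedReaction(
                f"EX_{source}", {ext: 1.0}, is_exchange=True, element_tag=element
            )
        )
        f = factor()
        prev = ext
        for step in range(1, config.pathway_length + 1):
            nxt = pool if step == config.pathway_length else f"met_{source}_{step}"
            if nxt != pool:
                metabolites.append(nxt)
            enzyme = add_protein(f"E_{source}_{step}")
            reactions.append(
                CatalyzedReaction(
                    f"R_{source}_{step}",
                    {prev: -1.0, nxt: 1.0},
                    {enzyme: config.pathway_kcat * f},
                )
            )
            prev = nxt

    metabolites.extend(["pool_C", "pool_N"])
    for source in _source_names("c", config.n_carbon_sources):
        add_chain(source, "C", "pool_C")
    for source in _source_names("n", config.n_nitrogen_sources):
        add_chain(source, "N", "pool_N")

    prev = None
    for step in range(1, config.backbone_length + 1):
        nxt = "precursor" if step == config.backbone_length else f"met_bb_{step}"
        metabolites.append(nxt)
        enzyme = add_protein(f"E_bb_{step}")
        if step == 1:
            stoich = {"pool_C": -1.0, "pool_N": -1.0, nxt: 1.0}
        else:
            stoich = {prev: -1.0, nxt: 1.0}
        reactions.append(
            CatalyzedReaction(
                f"R_bb_{step}", stoich, {enzyme: config.backbone_kcat * factor()}
            )
        )
        prev = nxt
    reactions.append(CatalyzedReaction("BIOMASS", {"precursor": -1.0}))

    proteins.append(
        ProteinSpec(
            "ribosome", mw=config.ribosome_mw, length=config.ribosome_length
        )
    )
    avg_len = math.fsum(p.length for p in proteins) / len(proteins)
    proteins.append(ProteinSpec("unmodeled", mw=1.0, length=avg_len, is_dummy=True))

    model = MEModel(
        metabolites=tuple(metabolites),
        proteins=tuple(proteins),
        reactions=tuple(reactions),
        ribosome=RibosomeSpec("ribosome", config.ribosome_kappa),
        proteome_budget=config.proteome_budget,
        biomass_reaction="BIOMASS",
        id=f"toy-{config.n_carbon_sources}C-{config.n_nitrogen_sources}N",
    )
    # the base medium (first source of each element) must support growth
    base_env = batch_environment(model, "c1", "n1")
    if max_growth(model, base_env).mu <= 0:
        raise GenerationError("toy configuration yields a zero-growth base medium")
    return model


def designed_membership(config: ToyModelConfig) -> dict[str, set[str]]:
    """Segment membership implied by the toy topology (the classification oracle)."""
    core = {f"E_bb_{s}" for s in range(1, config.backbone_length + 1)} | {"ribosome"}
    c_seg = {
        f"E_{src}_{s}"
        for src in _source_names("c", config.n_carbon_sources)
        for s in range(1, config.pathway_length + 1)
    }
    n_seg = {
        f"E_{src}_{s}"
        for src in _source_names("n", config.n_nitrogen_sources)
        for s in range(1, config.pathway_length + 1)
    }
    if config.n_carbon_sources == 1:
        core |= c_seg
        c_seg = set()
    if config.n_nitrogen_sources == 1:
        core |= n_seg
        n_seg = set()
    return {"core": core, "C": c_seg, "N": n_seg}


def batch_environment(
    model: MEModel, carbon: str = "c1", nitrogen: str = "n1", **kwargs
) -> Environment:
    """Minimal-medium environment with one carbon and one nitrogen source."""
    return Environment(
        id=f"{carbon}+{nitrogen}",
        open_exchanges=frozenset({f"EX_{carbon}", f"EX_{nitrogen}"}),
        **kwargs,
    )


def _condition_model(model: MEModel, cond: ConditionSpec) -> MEModel:
    return apply_turnover(model, cond.kcat_scale) if cond.kcat_scale != 1.0 else model


def make_proteomics(
    model: MEModel,
    conditions: Sequence[ConditionSpec],
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    nonme_proteins: int = 0,
    nonme_fraction: float = 0.0,
):
    """Generate a Schmidt-style absolute proteomics table with known truth.

    Per condition: demands of the turnover-scaled model at the generating
    growth rate form the utilized abundances (uniformly rescaled to fill
    ``(1 - u* - w) * Phi``; the rescale is folded into the recorded
    effective turnover), unused mass ``u* * Phi`` is split over the
    condition's structurally unusable pathway proteins, and optional
    out-of-scope filler proteins take ``w * Phi``.  Multiplicative
    lognormal noise is applied last, then masses are converted to copies
    per cell.  Returns ``(AbundanceTable, SyntheticTruth)``; import
    :func:`protalloc.expression.to_mass_fractions` to normalize back.
    """
    from .expression import AbundanceTable  # local to avoid cycle

    if nonme_fraction and nonme_proteins <= 0:
        raise GenerationError("nonme_fraction > 0 requires nonme_proteins >= 1")
    if not 0 <= nonme_fraction < 1:
        raise GenerationError("nonme_fraction must lie in [0, 1)")
    ids = [c.id for c in conditions]
    if len(set(ids)) != len(ids):
        raise GenerationError("duplicate condition ids")

    rng = np.random.default_rng(seed)
    phi = model.proteome_budget
    dummy_id = model.dummy_protein.id
    modeled = list(model.modeled_protein_ids)
    nonme_ids = [f"nonme_{k + 1}" for k in range(nonme_proteins)]
    all_ids = modeled + nonme_ids
    mw = pd.Series(
        {**{p.id: p.mw for p in model.proteins if not p.is_dummy},
         **{pid: 2.0 for pid in nonme_ids}}
    )

    truth = SyntheticTruth(noise_sd=noise_sd, seed=seed)
    masses = pd.DataFrame(0.0, index=all_ids, columns=ids)
    growth = {}
    for cond in conditions:
        cmodel = _condition_model(model, cond)
        env = batch_environment(model, cond.carbon, cond.nitrogen)
        w = nonme_fraction
        forced = cond.unused_fraction + w
        scaled = apply_turnover(cmodel, cond.turnover)
        if cond.mu is None:
            sol = max_growth(scaled, env, forced_dummy_fraction=forced)
            mu_c = sol.mu
            demands = {
                pid: m
                for pid, m in sol.protein_mass_fraction.items()
                if pid != dummy_id and m > 0
            }
        else:
            mu_c = cond.mu
            profile = min_protein_demand(scaled, env, mu_c)
            if not profile.optimal:
                raise GenerationError(
                    f"condition {cond.id!r}: mu = {mu_c} infeasible at tau = "
                    f"{cond.turnover}"
                )
            demands = {p: m for p, m in profile.demand_mass_fraction.items() if m > 0}
        demand_mass = math.fsum(demands.values())
        target_util = (1 - forced) * phi
        # allow LP-tolerance slop at the forced optimum; the uniform
        # rescale below folds any residual into the effective turnover
        if demand_mass > target_util + 1e-6:
            raise GenerationError(
                f"condition {cond.id!r}: unused fraction {cond.unused_fraction} "
                f"leaves no room for the demanded proteome"
            )
        scale = target_util / demand_mass
        open_sources = {cond.carbon, cond.nitrogen}
        unused_proteins = [
            pid
            for pid in modeled
            if pid.startswith("E_") and not pid.startswith("E_bb_")
            and pid.split("_")[1] not in open_sources
        ]
        if cond.unused_fraction > 0 and not unused_proteins:
            raise GenerationError(
                f"condition {cond.id!r}: no unusable pathway proteins to carry "
                "the planted unused mass"
            )
        col = masses[cond.id]
        for pid, m in demands.items():
            col.loc[pid] = m * scale
        if unused_proteins:
            col.loc[unused_proteins] = cond.unused_fraction * phi / len(unused_proteins)
        if nonme_ids:
            col.loc[nonme_ids] = w * phi / len(nonme_ids)
        growth[cond.id] = mu_c
        truth.conditions[cond.id] = {
            "unused_fraction": cond.unused_fraction,
            "turnover": cond.turnover,
            "turnover_effective": cond.turnover / scale,
            "mu": mu_c,
            "kind": cond.kind,
            "kcat_scale": cond.kcat_scale,
            "utilized_proteins": sorted(demands),
            "unused_proteins": sorted(unused_proteins),
            "nonme_fraction": w,
        }

    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=masses.shape)
        masses = masses * np.exp(noise)

    copies = masses.div(mw, axis=0).mul(
        CELL_PROTEIN_MASS * MOLECULES_PER_MMOL / phi
    )
    data = pd.concat([mw.rename("mw"), copies], axis=1)
    data.index.name = "protein"
    table = AbundanceTable(
        data=data, growth_rates=pd.Series(growth, dtype=float)
    )
    for pid in modeled:
        if pid.startswith("E_bb_") or pid == "ribosome":
            truth.segment_label[pid] = "core"
        elif pid.startswith("E_c"):
            truth.segment_label[pid] = "C"
        elif pid.startswith("E_n"):
            truth.segment_label[pid] = "N"
    for pid in nonme_ids:
        truth.segment_label[pid] = "nonme"
    return table, truth


def make_trend_proteomics(
    model: MEModel,
    membership: Mapping[str, set[str]],
    mu_grid: Sequence[float],
    *,
    core_slope: float = 0.33,
    core_intercept: float = 0.26,
    c_slope: float = -0.28,
    c_intercept: float = 0.40,
    nonme_slope: float = -0.09,
    nonme_intercept: float = 0.26,
    noise_sd: float = 0.01,
    seed: int = 0,
    nonme_proteins: int = 4,
):
    """Proteomics panel with planted linear growth-rate trends.

    Core, C-segment and out-of-scope (non-ME) total mass fractions follow
    ``slope * mu + intercept`` across the growth-rate grid; whatever is
    left goes to the N segment.  Defaults plant the canonical bacterial
    allocation trends (rising core share, falling catabolic share).
    """
    from .expression import AbundanceTable

    rng = np.random.default_rng(seed)
    core = sorted(membership["core"])
    c_seg = sorted(membership.get("C", set()))
    n_seg = sorted(membership.get("N", set()))
    nonme_ids = [f"nonme_{k + 1}" for k in range(nonme_proteins)]
    mw = pd.Series(
        {**{p.id: p.mw for p in model.proteins if not p.is_dummy},
         **{pid: 2.0 for pid in nonme_ids}}
    )
    all_ids = [p for p in mw.index if p in set(core) | set(c_seg) | set(n_seg)] + nonme_ids
    cols = {}
    growth = {}
    for mu in mu_grid:
        f_core = core_slope * mu + core_intercept
        f_c = c_slope * mu + c_intercept
        f_nonme = nonme_slope * mu + nonme_intercept
        f_n = 1.0 - f_core - f_c - f_nonme
        if min(f_core, f_c, f_nonme, f_n) <= 0:
            raise GenerationError(f"trend fractions leave the simplex at mu={mu}")
        cid = f"mu_{mu:.3f}"
        col = pd.Series(0.0, index=all_ids)
        for members, total in (
            (core, f_core),
            (c_seg, f_c),
            (n_seg, f_n),
            (nonme_ids, f_nonme),
        ):
            if members:
                col.loc[members] = total / len(members)
        cols[cid] = col
        growth[cid] = float(mu)
    fractions = pd.DataFrame(cols)
    if noise_sd > 0:
        fractions = fractions * np.exp(
            rng.normal(0.0, noise_sd, size=fractions.shape)
        )
    copies = fractions.div(mw.loc[all_ids], axis=0).mul(
        CELL_PROTEIN_MASS * MOLECULES_PER_MMOL
    )
    data = pd.concat([mw.loc[all_ids].rename("mw"), copies], axis=1)
    data.index.name = "protein"
    return AbundanceTable(data=data, growth_rates=pd.Series(growth, dtype=float))


def make_transcriptomics(
    model: MEModel,
    env: Environment,
    mu_wt: float,
    strains: Sequence[StrainSpec],
    *,
    unused_fraction_wt: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
    fpkm_scale: float = 1e6,
):
    """FPKM table for a wild type plus evolved strains, with planted shifts.

    The wild type allocates ``1 - u_wt`` of its transcriptome to the genes
    demanded at ``mu_wt`` (proportional to demand) and ``u_wt`` to the
    remaining genes; an evolved strain shifts ``delta_utilized`` of
    transcriptome mass into the utilized genes and may scale its ribosome
    share (``ribosome_factor``), emulating faster translation.  Gene
    length is 3 nt per amino acid.  Returns ``(TranscriptomeTable, truth
    dict)``.
    """
    from .expression import TranscriptomeTable

    if not 0 <= unused_fraction_wt < 1:
        raise GenerationError("unused_fraction_wt must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    profile = min_protein_demand(model, env, mu_wt)
    if not profile.optimal:
        raise GenerationError(f"wild-type growth rate {mu_wt} infeasible")
    demands = {p: m for p, m in profile.demand_mass_fraction.items() if m > 0}
    genes = list(model.modeled_protein_ids)
    unused_genes = [g for g in genes if g not in demands]
    if not unused_genes:
        raise GenerationError("no un-demanded genes to carry the unused fraction")
    lengths = pd.Series({p.id: p.length * 3.0 for p in model.proteins if not p.is_dummy})

    def allocation(q_utilized: float, ribosome_factor: float) -> pd.Series:
        weights = pd.Series(demands)
        if "ribosome" in weights.index:
            weights.loc["ribosome"] *= ribosome_factor
        weights = weights / weights.sum() * q_utilized
        col = pd.Series(0.0, index=genes)
        col.loc[weights.index] = weights
        col.loc[unused_genes] = (1 - q_utilized) / len(unused_genes)
        return col

    q_wt = 1 - unused_fraction_wt
    columns = {"wt": allocation(q_wt, 1.0)}
    truth = {
        "utilized_genes": sorted(demands),
        "unused_fraction_wt": unused_fraction_wt,
        "mu_wt": mu_wt,
        "strains": {},
    }
    mus = {"wt": mu_wt}
    for strain in strains:
        q = q_wt + strain.delta_utilized
        if not 0 < q < 1:
            raise GenerationError(
                f"strain {strain.id!r}: planted delta pushes the utilized "
                "fraction outside (0, 1)"
            )
        columns[strain.id] = allocation(q, strain.ribosome_factor)
        mus[strain.id] = strain.mu
        truth["strains"][strain.id] = {
            "mu": strain.mu,
            "delta_utilized": strain.delta_utilized,
            "ribosome_factor": strain.ribosome_factor,
        }
    fractions = pd.DataFrame(columns)
    if noise_sd > 0:
        fractions = fractions * np.exp(
            rng.normal(0.0, noise_sd, size=fractions.shape)
        )
    fpkm = fractions.div(lengths, axis=0) * fpkm_scale
    data = pd.concat([lengths.rename("length"), fpkm], axis=1)
    data.index.name = "gene"
    table = TranscriptomeTable(
        data=data, growth_rates=pd.Series(mus, dtype=float)
    )
    return table, truth
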