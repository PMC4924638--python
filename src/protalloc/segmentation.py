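"""Proteome segmentation: core vs element-specific (C/N/P/S) segments.

Growth is simulated on a panel of minimal media obtained from a base
medium by swapping one element source at a time.  Proteins expressed in
*every* growth-supporting panel environment form the core proteome; the
rest is attributed to element segments.  A non-core protein belongs to
segment E when its expression depends on the E source: it is expressed in
at least one E-variant environment and absent in at least one other
(the base medium counts as the variant for its own default sources).
A protein may belong to several non-core segments.

Classification runs require isozymes of a reaction to be used in equal
amounts, so every capable isozyme of a used reaction is counted as
expressed rather than an arbitrary cheapest one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConfigurationError, Environment, MEModel, ModelError
from .solver import InfeasibleError, max_growth

logger = logging.getLogger(__name__)

__all__ = [
    "PanelVariant",
    "EnvironmentPanel",
    "ProteomeSegments",
    "SegmentMassTable",
    "EnrichmentResult",
    "TrendResult",
    "enumerate_environments",
    "classify_proteome",
    "segment_masses",
    "select_top_nonme",
    "regulon_enrichment",
    "growth_trend",
    "growth_correlation_by_group",
]

ELEMENTS = ("C", "N", "P", "S")

#: growth rates below this are treated as "no growth" when pruning the panel
GROWTH_SUPPORT_TOL = 1e-4


@dataclass(frozen=True)
class PanelVariant:
    element: str
    source: str  # exchange reaction id supplying the element
    environment: Environment


@dataclass
class EnvironmentPanel:
    """Base medium plus single-element-swap variants.

    The base environment appears as a variant once per element for its own
    default source, so counting "usable sources per element" includes the
    defaults.
    """

    base: Environment
    variants: list[PanelVariant]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def environments(self) -> dict[str, Environment]:
        envs = {self.base.id: self.base}
        for var in self.variants:
            envs.setdefault(var.environment.id, var.environment)
        return envs

    def variants_for(self, element: str) -> list[PanelVariant]:
        return [v for v in self.variants if v.element == element]


@dataclass
class ProteomeSegments:
    """Core proteome and the C/N/P/S conditional segments (disjoint from core)."""

    core: frozenset[str]
    segments: dict[str, frozenset[str]]
    expressed_by_env: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def noncore(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for seg in self.segments.values():
            out |= seg
        return out

    def labels(self) -> dict[str, list[str]]:
        """Multi-label map protein -> sorted segment labels (or ['core'])."""
        out = {p: ["core"] for p in self.core}
        for name, members in sorted(self.segments.items()):
            for p in members:
                out.setdefault(p, [])
                if name not in out[p]:
                    out[p].append(name)
        return out


@dataclass
class SegmentMassTable:
    """Measured mass per segment per condition, plus utilized non-core mass."""

    masses: pd.DataFrame  # condition x segment
    utilized_noncore: pd.Series  # condition -> median over sampled sets


@dataclass
class EnrichmentResult:
    segment: str
    regulon: str
    overlap: int
    p_value: float


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


def enumerate_environments(
    model: MEModel,
    base_sources: Mapping[str, str],
    *,
    base_id: str = "base",
    uptake_bounds: Optional[Mapping[str, float]] = None,
    solver_kw: Optional[dict] = None,
) -> EnvironmentPanel:
    """Build the element-wise environment panel from a base minimal medium.

    ``base_sources`` maps element -> exchange id of the default source.
    For every element-tagged exchange, a variant swaps it in as that
    element's sole source; variants that cannot support growth are dropped
    (logged).
    """
    solver_kw = solver_kw or {}
    exchange_ids = {r.id for r in model.exchanges}
    for element, source in base_sources.items():
        if source not in exchange_ids:
            raise ConfigurationError(
                f"base source {source!r} for element {element!r} is not an exchange"
            )
    tagged_elements = {
        r.element_tag for r in model.exchanges if r.element_tag is not None
    }
    missing = tagged_elements - set(base_sources)
    if missing:
        raise ConfigurationError(
            f"no base source configured for elements: {sorted(missing)}"
        )
    untagged_open = frozenset(
        r.id for r in model.exchanges if r.element_tag is None
    )
    bounds = dict(uptake_bounds or {})

    def build_env(sources: Mapping[str, str], env_id: str) -> Environment:
        return Environment(
            id=env_id,
            open_exchanges=frozenset(sources.values()) | untagged_open,
            uptake_bounds={
                ex: b for ex, b in bounds.items()
                if ex in sources.values() or ex in untagged_open
            },
        )

    base_env = build_env(base_sources, base_id)
    variants: list[PanelVariant] = []
    dropped: list[tuple[str, str]] = []
    supported: dict[str, bool] = {}

    def supports_growth(env: Environment) -> bool:
        if env.id in supported:
            return supported[env.id]
        try:
            mu = max_growth(model, env, **solver_kw).mu
        except InfeasibleError:
            mu = 0.0
        supported[env.id] = mu > GROWTH_SUPPORT_TOL
        return supported[env.id]

    if not supports_growth(base_env):
        raise ConfigurationError("base medium does not support growth")
    for element in sorted(tagged_elements):
        for rxn in model.exchanges_for_element(element):
            if rxn.id == base_sources[element]:
                variants.append(PanelVariant(element, rxn.id, base_env))
                continue
            sources = dict(base_sources)
            sources[element] = rxn.id
            env = build_env(sources, f"{base_id}:{element}={rxn.id}")
            if supports_growth(env):
                variants.append(PanelVariant(element, rxn.id, env))
            else:
                dropped.append((element, rxn.id))
                logger.info("dropped non-growth-supporting source %s (%s)", rxn.id, element)
    return EnvironmentPanel(base=base_env, variants=variants, dropped=dropped)


def classify_proteome(
    model: MEModel,
    panel: EnvironmentPanel,
    *,
    solver_kw: Optional[dict] = None,
) -> ProteomeSegments:
    """Classify the modelled proteome into core and element segments.

    Per panel environment, growth is maximized with isozyme-equality
    constraints and the expressed set recorded (dummy excluded).  The core
    is the intersection of expressed sets over all environments; a
    non-core protein joins segment E when it is expressed in some
    E-variant and not expressed in some other E-variant.
    """
    if not panel.variants:
        raise ModelError("empty environment panel")
    solver_kw = dict(solver_kw or {})
    solver_kw["isozyme_equality"] = True
    dummy_id = model.dummy_protein.id
    expressed: dict[str, frozenset[str]] = {}
    for env_id, env in panel.environments.items():
        try:
            sol = max_growth(model, env, **solver_kw)
        except InfeasibleError as exc:
            raise ModelError(f"classification environment {env_id!r} infeasible") from exc
        expressed[env_id] = frozenset(sol.expressed_set - {dummy_id})
    core = frozenset.intersection(*expressed.values())
    segments: dict[str, frozenset[str]] = {}
    for element in ELEMENTS:
        variants = panel.variants_for(element)
        if not variants:
            continue
        sets = [expressed[v.environment.id] for v in variants]
        union = frozenset().union(*sets)
        everywhere = frozenset.intersection(*sets)
        segments[element] = (union - everywhere) - core
    return ProteomeSegments(core=core, segments=segments, expressed_by_env=expressed)


def segment_masses(
    segments: ProteomeSegments,
    mass_fractions: pd.DataFrame,
    condition_sets: Mapping[str, Sequence[frozenset[str]]],
) -> SegmentMassTable:
    """Measured mass of each segment per condition, and utilized non-core mass.

    ``utilized_noncore`` is, per condition, the median over sampled
    utilized sets of the measured mass that is utilized but outside the
    core proteome.
    """
    rows = {}
    groups = {"core": segments.core, **segments.segments}
    index = set(mass_fractions.index)
    for cond in mass_fractions.columns:
        col = mass_fractions[cond]
        rows[cond] = {
            name: float(col.loc[sorted(members & index)].sum())
            for name, members in groups.items()
        }
    masses = pd.DataFrame(rows).T
    utilized_noncore = {}
    for cond, sets in condition_sets.items():
        if cond not in mass_fractions.columns:
            continue
        col = mass_fractions[cond]
        vals = [
            float(col.loc[sorted((uset - segments.core) & index)].sum())
            for uset in sets
        ]
        utilized_noncore[cond] = float(np.median(vals)) if vals else 0.0
    return SegmentMassTable(
        masses=masses, utilized_noncore=pd.Series(utilized_noncore, dtype=float)
    )


def select_top_nonme(
    mass_fractions: pd.DataFrame,
    me_set: set[str] | frozenset[str],
    coverage: float = 0.8,
) -> list[str]:
    """Most-abundant non-ME proteins covering >= ``coverage`` of non-ME mass.

    Per condition, proteins outside the model scope are ranked by
    abundance (ties broken by identifier) and the smallest prefix reaching
    the coverage of total non-ME mass is kept; the union over conditions
    is returned, sorted.
    """
    if not 0 < coverage <= 1:
        raise ModelError(f"coverage must lie in (0, 1], got {coverage}")
    nonme = [p for p in mass_fractions.index if p not in me_set]
    if not nonme:
        return []
    selected: set[str] = set()
    sub = mass_fractions.loc[nonme]
    for cond in mass_fractions.columns:
        col = sub[cond]
        total = float(col.sum())
        if total <= 0:
            continue
        order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
        acc = 0.0
        for pid, m in order:
            selected.add(pid)
            acc += float(m)
            if acc >= coverage * total - 1e-12:
                break
    return sorted(selected)


def regulon_enrichment(
    segment: set[str] | frozenset[str],
    regulon: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
    *,
    segment_id: str = "segment",
    regulon_id: str = "regulon",
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of a regulon in a segment.

    Population = universe, successes = regulon, draws = segment;
    p = P(X >= overlap).
    """
    universe = frozenset(universe)
    if not universe:
        raise ModelError("empty universe")
    segment = frozenset(segment) & universe
    regulon = frozenset(regulon) & universe
    overlap = len(segment & regulon)
    p = float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(regulon), len(segment))
    )
    return EnrichmentResult(
        segment=segment_id,
        regulon=regulon_id,
        overlap=overlap,
        p_value=min(max(p, 0.0), 1.0),
    )


def growth_trend(
    series: Mapping[str, float] | pd.Series,
    growth_rates: Mapping[str, float] | pd.Series,
) -> TrendResult:
    """OLS regression of a per-condition quantity against growth rate."""
    series = pd.Series(series, dtype=float)
    growth = pd.Series(growth_rates, dtype=float)
    common = series.index.intersection(growth.index)
    if len(common) < 3:
        raise ModelError(f"need >= 3 conditions, got {len(common)}")
    x = growth.loc[common].to_numpy()
    y = series.loc[common].to_numpy()
    if np.ptp(x) == 0:
        raise ModelError("zero variance in growth rates")
    if np.ptp(y) == 0:
        # a constant response carries no trend; not an error
        return TrendResult(
            slope=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            p_value=1.0,
            stderr=0.0,
        )
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


def growth_correlation_by_group(
    mass_fractions: pd.DataFrame,
    growth_rates: Mapping[str, float] | pd.Series,
    groups: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Median per-protein Pearson correlation with growth rate, per group."""
    growth = pd.Series(growth_rates, dtype=float)
    conds = [c for c in mass_fractions.columns if c in growth.index]
    if len(conds) < 3:
        raise ModelError("need >= 3 conditions with growth rates")
    x = growth.loc[conds].to_numpy()
    medians = {}
    for name, members in groups.items():
        rows = [p for p in members if p in mass_fractions.index]
        rs = []
        for pid in rows:
            y = mass_fractions.loc[pid, conds].to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            rs.append(stats.pearsonr(x, y).statistic)
        medians[name] = float(np.median(rs)) if rs else float("nan")
    return pd.Series(medians, dtype=float)
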