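"""Miniature metabolism-and-expression (ME) model formalism.

An ME model couples metabolic fluxes to the enzymes that catalyse them and
to the ribosome that synthesises those enzymes.  Because the growth rate
``mu`` multiplies protein dilution terms, the constraint set is linear only
at a *fixed* growth rate; maximal growth is found by feasibility bisection
(see :mod:`protalloc.solver`).

Constraint classes carried by the formalism:

* steady-state mass balance ``S v = 0`` with the biomass flux pinned to mu;
* enzyme capacity ``|v_j| <= sum_i kcat_{j,i} * e_i`` over the isozymes of
  each catalysed reaction;
* ribosome capacity ``sum_i L_i * mu * e_i <= kappa * e_ribo`` (the ribosome
  translates every protein, itself included);
* a fixed proteome budget ``sum_i mw_i * e_i = Phi`` shared between modelled
  proteins and a single un-modelled "dummy" protein that absorbs whatever
  budget growth does not need.

Units: fluxes mmol/gDW/h, protein amounts mmol/gDW, kcat 1/h, molecular
weight g/mmol, protein mass g/gDW, growth rate 1/h. The biomass flux equals
the growth rate by convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "ModelError",
    "ConfigurationError",
    "ProteinSpec",
    "CatalyzedReaction",
    "RibosomeSpec",
    "Environment",
    "MEModel",
    "apply_turnover",
    "load_model",
    "save_model",
]


class ModelError(ValueError):
    """A model violates a structural invariant."""


class ConfigurationError(ModelError):
    """Inputs reference unknown entities or carry out-of-range values."""


@dataclass(frozen=True)
class ProteinSpec:
    """A protein species: molecular weight (g/mmol) and length (amino acids).

    Exactly one protein per model is the *dummy* (un-modelled protein
    placeholder); its expression represents proteome mass the model does not
    account for mechanistically.
    """

    id: str
    mw: float
    length: float
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ModelError(f"protein {self.id!r}: mw must be > 0, got {self.mw}")
        if self.length <= 0:
            raise ModelError(
                f"protein {self.id!r}: length must be > 0, got {self.length}"
            )


@dataclass(frozen=True)
class CatalyzedReaction:
    """A reaction with optional isozyme catalysis.

    ``kcat_per_isozyme`` maps a catalysing protein id to its turnover number
    (1/h).  An empty map marks a spontaneous reaction; exchanges are
    spontaneous single-metabolite reactions flagged with ``is_exchange`` and
    (optionally) tagged with the element (C/N/P/S) they supply.  Exchange
    flux is uptake-positive: the exchange produces its metabolite.
    """

    id: str
    stoichiometry: Mapping[str, float]
    kcat_per_isozyme: Mapping[str, float] = field(default_factory=dict)
    reversible: bool = False
    element_tag: Optional[str] = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        object.__setattr__(self, "kcat_per_isozyme", dict(self.kcat_per_isozyme))
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        for prot, kcat in self.kcat_per_isozyme.items():
            if kcat <= 0:
                raise ModelError(
                    f"reaction {self.id!r}: kcat for {prot!r} must be > 0, got {kcat}"
                )
        if self.is_exchange:
            if self.kcat_per_isozyme:
                raise ModelError(f"exchange {self.id!r} must not be catalysed")
            if len(self.stoichiometry) != 1:
                raise ModelError(
                    f"exchange {self.id!r} must involve exactly one metabolite"
                )
        if self.element_tag is not None and self.element_tag not in "CNPS":
            raise ModelError(
                f"reaction {self.id!r}: element_tag must be one of C/N/P/S"
            )

    @property
    def catalyzed(self) -> bool:
        return bool(self.kcat_per_isozyme)


@dataclass(frozen=True)
class RibosomeSpec:
    """Ribosome identity and elongation capacity kappa (aa per h per ribosome)."""

    protein: str
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ModelError(f"ribosome kappa must be > 0, got {self.kappa}")


@dataclass(frozen=True)
class Environment:
    """A growth environment: which exchanges are open and with what bounds.

    ``uptake_bounds`` caps the uptake flux of an open exchange
    (mmol/gDW/h); absent entries mean unbounded uptake.  ``fixed_growth``
    marks chemostat-style conditions run at a dictated growth rate.
    """

    id: str
    open_exchanges: frozenset[str]
    uptake_bounds: Mapping[str, float] = field(default_factory=dict)
    fixed_growth: Optional[float] = None
    limiting_exchange: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "open_exchanges", frozenset(self.open_exchanges))
        object.__setattr__(self, "uptake_bounds", dict(self.uptake_bounds))
        for ex, bound in self.uptake_bounds.items():
            if bound < 0:
                raise ConfigurationError(
                    f"environment {self.id!r}: bound for {ex!r} must be >= 0"
                )
        if self.fixed_growth is not None and self.fixed_growth < 0:
            raise ConfigurationError(
                f"environment {self.id!r}: fixed_growth must be >= 0"
            )

    def opened(self, exchange: str, bound: Optional[float] = None) -> "Environment":
        """Return a copy with one more exchange opened (optionally bounded)."""
        bounds = dict(self.uptake_bounds)
        if bound is not None:
            bounds[exchange] = bound
        else:
            bounds.pop(exchange, None)
        return replace(
            self,
            open_exchanges=self.open_exchanges | {exchange},
            uptake_bounds=bounds,
        )

    def bounded(self, bounds: Mapping[str, float]) -> "Environment":
        merged = dict(self.uptake_bounds)
        merged.update(bounds)
        return replace(self, uptake_bounds=merged)


@dataclass(frozen=True)
class MEModel:
    """The miniature ME model: network, proteins, ribosome and budget."""

    metabolites: tuple[str, ...]
    proteins: tuple[ProteinSpec, ...]
    reactions: tuple[CatalyzedReaction, ...]
    ribosome: RibosomeSpec
    proteome_budget: float
    biomass_reaction: str
    id: str = "me-model"

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "proteins", tuple(self.proteins))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        if self.proteome_budget <= 0:
            raise ModelError("proteome_budget must be > 0")
        pids = [p.id for p in self.proteins]
        if len(set(pids)) != len(pids):
            raise ModelError("duplicate protein ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        dummies = [p for p in self.proteins if p.is_dummy]
        if len(dummies) != 1:
            raise ModelError(
                f"exactly one dummy protein required, found {len(dummies)}"
            )
        known_prot = set(pids)
        if self.ribosome.protein not in known_prot:
            raise ModelError(f"ribosome protein {self.ribosome.protein!r} unknown")
        met_set = set(self.metabolites)
        seen_mets: set[str] = set()
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    raise ModelError(
                        f"reaction {rxn.id!r} uses unknown metabolite {met!r}"
                    )
                seen_mets.add(met)
            for prot in rxn.kcat_per_isozyme:
                if prot not in known_prot:
                    raise ModelError(
                        f"reaction {rxn.id!r} maps unknown isozyme {prot!r}"
                    )
        orphan = met_set - seen_mets
        if orphan:
            raise ModelError(f"metabolites appear in no reaction: {sorted(orphan)}")
        if self.biomass_reaction not in set(rids):
            raise ModelError(f"biomass reaction {self.biomass_reaction!r} unknown")

    # -- lookups ----------------------------------------------------------

    @property
    def protein_by_id(self) -> dict[str, ProteinSpec]:
        return {p.id: p for p in self.proteins}

    @property
    def reaction_by_id(self) -> dict[str, CatalyzedReaction]:
        return {r.id: r for r in self.reactions}

    @property
    def dummy_protein(self) -> ProteinSpec:
        return next(p for p in self.proteins if p.is_dummy)

    @property
    def modeled_protein_ids(self) -> tuple[str, ...]:
        return tuple(p.id for p in self.proteins if not p.is_dummy)

    @property
    def exchanges(self) -> tuple[CatalyzedReaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def exchanges_for_element(self, element: str) -> tuple[CatalyzedReaction, ...]:
        return tuple(r for r in self.exchanges if r.element_tag == element)

    @property
    def mu_upper_bound(self) -> float:
        """Closed-form growth ceiling kappa / L_ribosome.

        At this rate the ribosome's whole capacity is consumed by its own
        dilution, leaving nothing for other proteins.
        """
        ribo = self.protein_by_id[self.ribosome.protein]
        return self.ribosome.kappa / ribo.length

    def validate_environment(self, env: Environment) -> None:
        ex_ids = {r.id for r in self.exchanges}
        unknown = set(env.open_exchanges) - ex_ids
        if unknown:
            raise ConfigurationError(
                f"environment {env.id!r} opens unknown exchanges: {sorted(unknown)}"
            )
        unknown_b = set(env.uptake_bounds) - ex_ids
        if unknown_b:
            raise ConfigurationError(
                f"environment {env.id!r} bounds unknown exchanges: {sorted(unknown_b)}"
            )

    # -- transformations --------------------------------------------------

    def scaled(self, tau: float) -> "MEModel":
        """Return a copy with all kcats and the ribosome kappa scaled by tau."""
        if tau <= 0:
            raise ConfigurationError(f"turnover multiplier must be > 0, got {tau}")
        reactions = tuple(
            replace(
                r,
                kcat_per_isozyme={p: k * tau for p, k in r.kcat_per_isozyme.items()},
            )
            for r in self.reactions
        )
        ribosome = replace(self.ribosome, kappa=self.ribosome.kappa * tau)
        return replace(self, reactions=reactions, ribosome=ribosome)

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "metabolites": list(self.metabolites),
            "proteins": [
                {
                    "id": p.id,
                    "mw": p.mw,
                    "length": p.length,
                    "is_dummy": p.is_dummy,
                }
                for p in self.proteins
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "kcat_per_isozyme": dict(r.kcat_per_isozyme),
                    "reversible": r.reversible,
                    "element_tag": r.element_tag,
                    "is_exchange": r.is_exchange,
                }
                for r in self.reactions
            ],
            "ribosome": {
                "protein": self.ribosome.protein,
                "kappa": self.ribosome.kappa,
            },
            "proteome_budget": self.proteome_budget,
            "biomass_reaction": self.biomass_reaction,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MEModel":
        try:
            proteins = tuple(
                ProteinSpec(
                    id=p["id"],
                    mw=float(p["mw"]),
                    length=float(p["length"]),
                    is_dummy=bool(p.get("is_dummy", False)),
                )
                for p in data["proteins"]
            )
            reactions = tuple(
                CatalyzedReaction(
                    id=r["id"],
                    stoichiometry={m: float(c) for m, c in r["stoichiometry"].items()},
                    kcat_per_isozyme={
                        p: float(k) for p, k in r.get("kcat_per_isozyme", {}).items()
                    },
                    reversible=bool(r.get("reversible", False)),
                    element_tag=r.get("element_tag"),
                    is_exchange=bool(r.get("is_exchange", False)),
                )
                for r in data["reactions"]
            )
            ribosome = RibosomeSpec(
                protein=data["ribosome"]["protein"],
                kappa=float(data["ribosome"]["kappa"]),
            )
            return cls(
                metabolites=tuple(data["metabolites"]),
                proteins=proteins,
                reactions=reactions,
                ribosome=ribosome,
                proteome_budget=float(data["proteome_budget"]),
                biomass_reaction=data["biomass_reaction"],
                id=data.get("id", "me-model"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"model file missing key: {exc}") from exc


def apply_turnover(model: MEModel, tau: float) -> MEModel:
    """Scale every enzymatic rate (and the ribosome kappa) by ``tau``.

    ``tau`` is the mean in-vivo turnover expressed as a fraction of the
    nominal catalytic capacity; ``tau <= 0`` is a domain error. The input
    model is unchanged.
    """
    return model.scaled(tau)


def load_model(path: str | Path) -> MEModel:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"model file {path}: invalid JSON: {exc}") from exc
    return MEModel.from_dict(data)


def save_model(model: MEModel, path: str | Path) -> None:
    text = json.dumps(model.to_dict(), indent=1, sort_keys=True)
    Path(path).write_text(text + "\n")


def average_protein_length(lengths: Iterable[float]) -> float:
    vals = list(lengths)
    if not vals:
        raise ModelError("no protein lengths supplied")
    return math.fsum(vals) / len(vals)
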