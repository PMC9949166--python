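"""Community flux balance analysis: merge species models into one LP over a
shared nutrient pool, maximize the summed growth of all members with a small
total-flux penalty as tie-breaker, and report growth rates normalized by the
community growth rate.

Merged layout
-------------
Member internals (metabolites and reactions) are copied under a
``<species>__`` prefix. Every external compound gets exactly one shared-pool
metabolite and one community-level exchange reaction whose lower bound
carries the medium availability. Each member's former exchange reaction
becomes a member ↔ pool transport that is unbounded in both directions — the
medium constrains the community, not individual members. There is no fixed
community biomass composition: each member keeps its own biomass reaction and
the objective is the unweighted sum of member growth rates, so the most
efficient converter of the medium into biomass dominates the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .fba_engine import TOL, solve_fba_pfba
from .model_core import (
    BIG,
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    supplement_medium,
)

logger = logging.getLogger(__name__)

EXTERNAL_COMPARTMENT = "e"
POOL_COMPARTMENT = "e"


@dataclass
class CommunityModel:
    members: list[str]
    model: MetabolicModel
    member_biomass_ids: dict[str, str]


@dataclass
class CommunityGrowthResult:
    community_growth: float
    member_growth: dict[str, float]
    normalized_abundance: dict[str, float] | None  # None when growth ~ 0
    status: str = "optimal"

    @property
    def defined(self) -> bool:
        return self.normalized_abundance is not None


@dataclass
class SupplementEffect:
    """Per-species effect of supplementing one compound into the community."""

    compound: str
    screenable: bool
    baseline_abundance: dict[str, float] = field(default_factory=dict)
    supplemented_abundance: dict[str, float] = field(default_factory=dict)
    abundance_delta: dict[str, float] = field(default_factory=dict)
    growth_ratio_change: dict[str, float] = field(default_factory=dict)
    selected: dict[str, bool] = field(default_factory=dict)


def merge_models(models: list[MetabolicModel], medium: Medium) -> CommunityModel:
    """Merge ≥2 species models into one community model over a shared pool."""
    if len(models) < 2:
        raise ValueError("need at least 2 models to build a community")
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids among community members")

    mets: dict[str, Metabolite] = {}
    rxns: dict[str, Reaction] = {}
    member_biomass: dict[str, str] = {}
    pool_compounds: set[str] = set()

    for model in models:
        prefix = f"{model.id}__"
        for met in model.metabolites.values():
            mets[prefix + met.id] = Metabolite(
                prefix + met.id, met.name, met.compartment, met.formula
            )
        for rxn in model.reactions.values():
            if rxn.is_exchange:
                cid = rxn.exchange_metabolite
                pool_compounds.add(cid)
                if cid not in mets:
                    mets[cid] = Metabolite(cid, model.metabolites[cid].name, POOL_COMPARTMENT)
                # member <-> pool transport, unbounded in both directions
                rxns[f"{prefix}TP_{rxn.id}"] = Reaction(
                    f"{prefix}TP_{rxn.id}",
                    {cid: -1.0, prefix + cid: 1.0},
                    -BIG,
                    BIG,
                )
            else:
                rxns[prefix + rxn.id] = Reaction(
                    prefix + rxn.id,
                    {prefix + mid: coef for mid, coef in rxn.stoichiometry.items()},
                    rxn.lower_bound,
                    rxn.upper_bound,
                    objective_coefficient=1.0 if rxn.id == model.biomass_reaction_id else 0.0,
                )
        member_biomass[model.id] = prefix + model.biomass_reaction_id

    for cid in sorted(pool_compounds):
        avail = medium.availabilities.get(cid, 0.0)
        rxns[f"EX_{cid}__community"] = Reaction(
            f"EX_{cid}__community", {cid: -1.0}, -float(avail), BIG, is_exchange=True
        )

    merged = MetabolicModel(
        id="community:" + "+".join(ids),
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=member_biomass[ids[0]],
    )
    merged.validate()
    return CommunityModel(members=ids, model=merged, member_biomass_ids=member_biomass)


def community_growth(
    cm: CommunityModel, flux_penalty: float = 1e-6, backend: str = "scipy"
) -> CommunityGrowthResult:
    """Maximize Σ member growth − flux_penalty · Σ|v|; normalize abundances.

    Normalized abundance of member i is μ_i / Σ μ. When the community does
    not grow the normalization is undefined and reported as ``None`` (never
    NaN-propagated). Exactly tied member growths are logged as degenerate:
    the LP split between symmetric members is arbitrary.
    """
    sol = solve_fba_pfba(cm.model, flux_penalty=flux_penalty, backend=backend)
    if not sol.ok:
        return CommunityGrowthResult(
            community_growth=float("nan"), member_growth={}, normalized_abundance=None,
            status=sol.status,
        )
    member = {sp: sol.fluxes[bid] for sp, bid in cm.member_biomass_ids.items()}
    total = sum(member.values())
    if total > TOL:
        norm = {sp: mu / total for sp, mu in member.items()}
        vals = sorted(member.values())
        if len(vals) > 1 and any(abs(a - b) < 1e-9 and a > TOL
                                 for a, b in zip(vals, vals[1:])):
            logger.warning(
                "community %s: tied member growth rates; the split between "
                "symmetric members is degenerate", cm.model.id,
            )
    else:
        norm = None
    return CommunityGrowthResult(
        community_growth=total, member_growth=member, normalized_abundance=norm
    )


def community_supplement_effect(
    models: list[MetabolicModel],
    medium: Medium,
    compound: str,
    dose: float = 10.0,
    flux_penalty: float = 1e-6,
    cutoff: float = 0.01,
    round_digits: int = 6,
    baseline: CommunityGrowthResult | None = None,
    backend: str = "scipy",
) -> SupplementEffect:
    """Change in normalized member abundances after supplementing one compound.

    The community is constrained with the medium extended by ``dose`` of the
    compound; baseline and supplemented abundances are rounded to
    ``round_digits`` before differencing and a member is flagged *selected*
    when its abundance change exceeds ``cutoff`` (strict). The raw
    growth-rate ratio change (μ_suppl − μ_base)/μ_base per member is reported
    alongside. A compound with no community-level exchange is marked not
    screenable.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    cm_base = merge_models(models, medium)
    if f"EX_{compound}__community" not in cm_base.model.reactions:
        return SupplementEffect(compound=compound, screenable=False)
    base = baseline or community_growth(cm_base, flux_penalty, backend=backend)
    cm_sup = merge_models(models, supplement_medium(medium, compound, dose))
    sup = community_growth(cm_sup, flux_penalty, backend=backend)
    if not (base.defined and sup.defined):
        return SupplementEffect(compound=compound, screenable=False)

    effect = SupplementEffect(compound=compound, screenable=True)
    for sp in cm_base.members:
        b = round(base.normalized_abundance[sp], round_digits)
        s = round(sup.normalized_abundance[sp], round_digits)
        delta = round(s - b, round_digits)
        effect.baseline_abundance[sp] = b
        effect.supplemented_abundance[sp] = s
        effect.abundance_delta[sp] = delta
        mu_b = round(base.member_growth[sp], round_digits)
        mu_s = round(sup.member_growth[sp], round_digits)
        effect.growth_ratio_change[sp] = (mu_s - mu_b) / mu_b if mu_b > 0 else float("nan")
        effect.selected[sp] = delta > cutoff
    return effect
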