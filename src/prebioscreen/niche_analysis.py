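"""Uptake profiles per species, unique-uptake-compound detection per
community, and the unique-fraction-vs-community-size subsampling analysis.

A compound is a *unique uptake compound* of a species within a community if
that species can take it up and no other community member can. The fraction
of species possessing at least one such compound is the quantity that drops
quickly with community size in real microbiomes, which is what makes
single-species metabolic niches a poor basis for targeted supplementation.

Uptake capability is a property of a species and its medium, independent of
which other species are present, so profiles are computed once per species
and reused across all community subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba_engine import can_take_up
from .model_core import BIG, Medium, MetabolicModel, apply_medium


@dataclass
class UptakeProfile:
    species_id: str
    uptake_compounds: set[str] = field(default_factory=set)


@dataclass
class NicheReport:
    community: list[str]
    unique_compounds: dict[str, set[str]]
    fraction_with_unique: float


def uptake_profile(
    model: MetabolicModel,
    medium: Medium,
    probe_availability: float | None = None,
    tol: float = 1e-6,
) -> UptakeProfile:
    """Compounds the species can take up under the given medium.

    Applies the medium, then asks :func:`~prebioscreen.fba_engine.can_take_up`
    for every exchange reaction. With ``probe_availability`` set, every
    exchange is instead opened at that flux (sensitivity mode probing the
    full uptake repertoire rather than the medium-restricted one; default
    off).
    """
    if probe_availability is not None:
        med = Medium(
            {rxn.exchange_metabolite: probe_availability
             for rxn in model.exchange_reactions.values()},
            name=f"probe@{probe_availability}",
        )
    else:
        med = medium
    constrained = apply_medium(model, med)
    compounds = set()
    for rid, rxn in constrained.exchange_reactions.items():
        if can_take_up(constrained, rid, tol=tol):
            compounds.add(rxn.exchange_metabolite)
    return UptakeProfile(species_id=model.id, uptake_compounds=compounds)


def unique_uptake_compounds(profiles: list[UptakeProfile]) -> NicheReport:
    """Per-species set difference against the union of all other species."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 uptake profiles")
    ids = [p.species_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids in profiles")
    unique: dict[str, set[str]] = {}
    for i, p in enumerate(profiles):
        others: set[str] = set()
        for j, q in enumerate(profiles):
            if j != i:
                others |= q.uptake_compounds
        unique[p.species_id] = p.uptake_compounds - others
    n_with = sum(1 for s in unique.values() if s)
    return NicheReport(
        community=ids,
        unique_compounds=unique,
        fraction_with_unique=n_with / len(profiles),
    )


def unique_fraction_curve(
    profiles: list[UptakeProfile],
    sizes: list[int],
    iterations: int,
    seed: int,
) -> pd.DataFrame:
    """Fraction of species with a unique compound in random subcommunities.

    For each community size, draws ``iterations`` uniform subsets without
    replacement and records the unique fraction. Deterministic given the
    seed. Returns a tidy frame (size, iteration, fraction_with_unique).
    """
    n = len(profiles)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for s in sizes:
        if not 2 <= s <= n:
            raise ValueError(f"community size {s} out of range [2, {n}]")
    rng = np.random.default_rng(seed)
    records = []
    for size in sizes:
        for it in range(iterations):
            idx = rng.choice(n, size=size, replace=False)
            report = unique_uptake_compounds([profiles[i] for i in idx])
            records.append(
                {"size": size, "iteration": it, "fraction_with_unique": report.fraction_with_unique}
            )
    return pd.DataFrame(records)


def profiles_to_frame(profiles: list[UptakeProfile]) -> pd.DataFrame:
    """Tidy (species_id, compound_id) table of uptake capabilities."""
    return pd.DataFrame(
        [
            {"species_id": p.species_id, "compound_id": c}
            for p in profiles
            for c in sorted(p.uptake_compounds)
        ]
    )


def frame_to_profiles(df: pd.DataFrame) -> list[UptakeProfile]:
    out = []
    for sid, grp in df.groupby("species_id", sort=True):
        out.append(UptakeProfile(species_id=str(sid), uptake_compounds=set(grp["compound_id"])))
    return out
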