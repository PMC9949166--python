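"""Generator of toy metabolic models, two-species benchmark communities,
media, phenotype tables, and class annotations with planted ground truth.

The toy model layout makes FBA optima analytic: each uptake compound ``c``
with biomass yield ``y`` contributes three reactions —

* exchange ``EX_c``:    c[e] ↔ environment
* transport ``TR_c``:   c[e] → c[c]
* conversion ``CV_c``:  c[c] → y · biomass_precursor[c]

plus one shared biomass reaction draining the precursor, so that the optimal
growth rate is simply Σ_c y_c · uptake_c. A yield of exactly 0 plants an
*inert but consumable* compound (the conversion becomes a dissipative sink),
and compounds with an exchange but no transport are structural dead ends the
uptake test must reject.

The default two-species benchmark emulates a host-associated pair in which
the partners share the vast majority of their uptake compounds (85%), with
10% private to the target species and 5% private to the competitor, and a
small set of planted "precision prebiotics": shared compounds on which the
target species has a configurable yield advantage. All remaining shared
compounds favor the competitor, making it the stronger generalist, so both
members grow in community simulations and only the planted compounds shift
the balance toward the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_core import (
    BIG,
    BiologTable,
    CompoundAnnotation,
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    write_biolog_tsv,
    write_annotation_tsv,
    write_medium_tsv,
    write_model,
)

BIOMASS_PRECURSOR = "biomass_pre_c"
BIOMASS_REACTION = "GROWTH"

#: Names for planted precision-prebiotic compounds (amino acids, a sugar
#: alcohol, a polyamine, etc. — the compound classes such screens surface).
DEFAULT_PREBIOTIC_NAMES = [
    "ser_L", "thr_L", "gaba", "mnl_D", "4hbz", "glyc3p", "tre", "ptrc",
]


@dataclass
class SpeciesSpec:
    """Blueprint for one toy species.

    ``uptake_compounds`` maps compound id → biomass yield (gDW produced per
    mmol consumed). Yield 0 plants a consumable but growth-inert compound.
    ``dead_end_compounds`` get an exchange reaction but no transport, so they
    can never be taken up at steady state. ``secretion_products`` maps
    product id → stoichiometric fraction emitted per unit of any uptake.
    """

    species_id: str
    uptake_compounds: dict[str, float] = field(default_factory=dict)
    unique_compounds: set[str] = field(default_factory=set)
    secretion_products: dict[str, float] = field(default_factory=dict)
    dead_end_compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(y < 0 for y in self.uptake_compounds.values()):
            raise ValueError("yields must be >= 0")
        if not self.unique_compounds <= set(self.uptake_compounds):
            raise ValueError("unique_compounds must be a subset of uptake_compounds")


@dataclass
class BenchmarkSpec:
    """Blueprint for the two-species benchmark community.

    The default split (17 shared, 2 target-private, 1 competitor-private out
    of 20 uptake compounds) reproduces an 85% / 10% / 5% niche overlap.
    """

    n_shared_compounds: int = 17
    n_unique_per_species: tuple[int, int] = (2, 1)
    n_inert_compounds: int = 2
    planted_prebiotics: dict[str, float] | None = None  # compound -> advantage factor
    n_planted: int = 8
    advantage_factor: float = 1.5
    base_yield: float = 0.5
    availability: float = 1.0  # mmol/gDW/hr per compound in the batch medium
    target_id: str = "MYb11_like"
    competitor_id: str = "MYb71_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_prebiotics is not None and any(
            f <= 1 for f in self.planted_prebiotics.values()
        ):
            raise ValueError("planted prebiotic advantage factors must be > 1")
        if self.advantage_factor <= 1:
            raise ValueError("advantage_factor must be > 1")
        if self.n_planted > self.n_shared_compounds:
            raise ValueError("cannot plant more prebiotics than shared compounds")


def generate_species_model(spec: SpeciesSpec) -> MetabolicModel:
    """Build a toy model whose uptake profile equals the spec's uptake set."""
    seen: set[str] = set()
    for cid in list(spec.uptake_compounds) + list(spec.dead_end_compounds):
        if cid in seen:
            raise ValueError(f"duplicate compound id {cid!r} in spec {spec.species_id!r}")
        seen.add(cid)

    mets: dict[str, Metabolite] = {
        BIOMASS_PRECURSOR: Metabolite(BIOMASS_PRECURSOR, "biomass precursor", "c")
    }
    rxns: dict[str, Reaction] = {}

    def ensure_external(cid: str) -> str:
        # external metabolites carry the bare compound id; the compartment
        # field distinguishes them from the "_c" internal copies, and media,
        # Biolog tables, and annotations can then share one namespace
        if cid not in mets:
            mets[cid] = Metabolite(cid, cid, "e")
        return cid

    for cid, y in spec.uptake_compounds.items():
        eid = ensure_external(cid)
        iid = f"{cid}_c"
        mets[iid] = Metabolite(iid, cid, "c")
        rxns[f"EX_{cid}"] = Reaction(f"EX_{cid}", {eid: -1.0}, 0.0, BIG, is_exchange=True)
        rxns[f"TR_{cid}"] = Reaction(f"TR_{cid}", {eid: -1.0, iid: 1.0}, 0.0, BIG)
        stoich: dict[str, float] = {iid: -1.0}
        if y > 0:
            stoich[BIOMASS_PRECURSOR] = y
        for prod, frac in spec.secretion_products.items():
            peid = ensure_external(prod)
            stoich[peid] = stoich.get(peid, 0.0) + frac
        rxns[f"CV_{cid}"] = Reaction(f"CV_{cid}", stoich, 0.0, BIG)
    for prod in spec.secretion_products:
        peid = ensure_external(prod)
        rid = f"EX_{prod}"
        if rid not in rxns:
            # secretion-only boundary: closed to uptake
            rxns[rid] = Reaction(rid, {peid: -1.0}, 0.0, BIG, is_exchange=True)
    for cid in spec.dead_end_compounds:
        eid = ensure_external(cid)
        rxns[f"EX_{cid}"] = Reaction(f"EX_{cid}", {eid: -1.0}, 0.0, BIG, is_exchange=True)
    if not any(r.is_exchange for r in rxns.values()):
        # placeholder boundary so even a no-uptake species is a valid model
        eid = ensure_external("h2o")
        rxns["EX_h2o"] = Reaction("EX_h2o", {eid: -1.0}, 0.0, BIG, is_exchange=True)
    rxns[BIOMASS_REACTION] = Reaction(
        BIOMASS_REACTION, {BIOMASS_PRECURSOR: -1.0}, 0.0, BIG, objective_coefficient=1.0
    )
    model = MetabolicModel(
        id=spec.species_id, metabolites=mets, reactions=rxns,
        biomass_reaction_id=BIOMASS_REACTION,
    )
    model.validate()
    return model


@dataclass
class BenchmarkGroundTruth:
    target: str
    competitor: str
    planted_prebiotics: set[str]
    shared_compounds: set[str]
    target_unique: set[str]
    competitor_unique: set[str]
    inert_compounds: set[str]

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "competitor": self.competitor,
            "planted_prebiotics": sorted(self.planted_prebiotics),
            "shared_compounds": sorted(self.shared_compounds),
            "target_unique": sorted(self.target_unique),
            "competitor_unique": sorted(self.competitor_unique),
            "inert_compounds": sorted(self.inert_compounds),
        }


def generate_two_species_benchmark(
    spec: BenchmarkSpec,
) -> tuple[list[MetabolicModel], Medium, BiologTable, CompoundAnnotation, BenchmarkGroundTruth]:
    """Stand-in for a target/competitor pair with planted precision prebiotics.

    Returns (models, batch medium, Biolog table, class annotation,
    ground truth). The Biolog table is positive exactly for the planted set
    (plus flat-negative rows for the inert compounds), so the screen's
    confirmed set must equal the planted set; the target's private compounds
    are deliberately *not assayed*, mirroring plates that do not carry every
    model compound.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = spec.n_shared_compounds
    n_uT, n_uC = spec.n_unique_per_species

    planted: list[str]
    if spec.planted_prebiotics is not None:
        planted = list(spec.planted_prebiotics)
        advantages = dict(spec.planted_prebiotics)
    else:
        planted = DEFAULT_PREBIOTIC_NAMES[: spec.n_planted]
        advantages = {c: spec.advantage_factor for c in planted}
    n_bg = n_shared - len(planted)
    shared = planted + [f"cpd_s{i:02d}" for i in range(n_bg)]
    target_unique = [f"cpd_t{i:02d}" for i in range(n_uT)]
    competitor_unique = [f"cpd_c{i:02d}" for i in range(n_uC)]
    inert = [f"cpd_x{i:02d}" for i in range(spec.n_inert_compounds)]

    y = spec.base_yield
    target_uptake = {c: y * advantages[c] if c in advantages else y for c in shared}
    target_uptake.update({c: y for c in target_unique})
    comp_uptake = {c: y if c in advantages else y * spec.advantage_factor for c in shared}
    comp_uptake.update({c: y for c in competitor_unique})

    target_model = generate_species_model(
        SpeciesSpec(
            species_id=spec.target_id,
            uptake_compounds=target_uptake,
            unique_compounds=set(target_unique),
            dead_end_compounds=set(inert),
        )
    )
    comp_model = generate_species_model(
        SpeciesSpec(
            species_id=spec.competitor_id,
            uptake_compounds=comp_uptake,
            unique_compounds=set(competitor_unique),
            dead_end_compounds=set(inert),
        )
    )

    all_compounds = shared + target_unique + competitor_unique + inert
    medium = Medium(
        availabilities={c: spec.availability for c in all_compounds},
        name="ngm_like_synthetic",
    )

    biolog_rows: dict[str, tuple[float, float]] = {}
    for c in planted:
        biolog_rows[c] = (0.35, 0.15)  # OD590 - OD750 = 0.20 > 0.1 -> growth
    for c in shared[len(planted):]:
        biolog_rows[c] = (0.18, 0.15)  # 0.03 -> no growth call
    for c in inert:
        biolog_rows[c] = (0.10, 0.10)
    # target-unique and competitor-unique compounds are not assayed
    biolog = BiologTable(rows=biolog_rows)

    # one class over-represented among the planted set to make enrichment
    # detectable; the rest spread over unrelated classes
    classes: dict[str, set[str]] = {}
    amino = planted[: max(1, int(round(len(planted) * 0.75)))]
    for c in amino:
        classes[c] = {"amino acid"}
    other_classes = ["carbohydrate", "fatty acid", "organic acid", "polyamine"]
    rest = [c for c in all_compounds if c not in classes]
    for i, c in enumerate(rest):
        classes[c] = {other_classes[i % len(other_classes)]}
    annotation = CompoundAnnotation(classes=classes)

    truth = BenchmarkGroundTruth(
        target=spec.target_id,
        competitor=spec.competitor_id,
        planted_prebiotics=set(planted),
        shared_compounds=set(shared),
        target_unique=set(target_unique),
        competitor_unique=set(competitor_unique),
        inert_compounds=set(inert),
    )
    # benchmark construction is deterministic; rng kept for future noise hooks
    del rng
    return [target_model, comp_model], medium, biolog, annotation, truth


def generate_community_pool(
    n_species: int,
    overlap: float,
    n_compounds: int,
    seed: int,
    base_yield: float = 0.5,
) -> list[MetabolicModel]:
    """Species drawing uptake sets from a common pool with tunable overlap.

    Each species samples ``k = round(overlap * n_compounds)`` compounds
    uniformly without replacement from a shared pool of ``n_compounds``, so
    the expected fraction of one species' compounds found in another's set is
    exactly ``overlap``. ``overlap = 1`` yields identical profiles (the full
    pool; no species can have a unique compound); ``overlap = 0`` yields
    pairwise-disjoint private sets (every species has only unique compounds).
    Intermediate values leave uniqueness to sampling chance, which is what
    makes the unique fraction fall as communities grow.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    if n_species < 1 or n_compounds < 1:
        raise ValueError("n_species and n_compounds must be positive")
    rng = np.random.default_rng(seed)
    pool = [f"pool{i:03d}" for i in range(n_compounds)]
    models = []
    private_counter = 0
    for s in range(n_species):
        if overlap == 0.0:
            chosen = []
            for _ in range(max(2, n_compounds // 4)):
                chosen.append(f"priv{private_counter:04d}")
                private_counter += 1
        else:
            k = max(1, int(round(overlap * n_compounds)))
            chosen = list(rng.choice(pool, size=k, replace=False))
        spec = SpeciesSpec(
            species_id=f"sp{s:03d}",
            uptake_compounds={c: base_yield for c in chosen},
        )
        models.append(generate_species_model(spec))
    return models


def write_benchmark(
    out_dir: str | Path, spec: BenchmarkSpec | None = None, sbml: bool = True
) -> None:
    """Write the benchmark as files (JSON + SBML models, TSV tables, JSON truth)."""
    spec = spec or BenchmarkSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models, medium, biolog, annotation, truth = generate_two_species_benchmark(spec)
    for m in models:
        write_model(m, out / f"{m.id}.json")
        if sbml:
            write_model(m, out / f"{m.id}.xml")
    write_medium_tsv(medium, out / "medium.tsv")
    write_biolog_tsv(biolog, out / "biolog.tsv")
    write_annotation_tsv(annotation, out / "annotation.tsv")
    (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
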