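"""Minimal individual-based spatial community simulator.

Bacterial individuals live on a rectangular grid whose cells hold discrete
substrate amounts (mmol, converted from concentrations via a configured cell
volume). Each timestep, every individual — in seeded-random order — solves an
FBA with a secondary total-flux minimization against its local cell: the
uptake bound of compound ``c`` is ``local_amount(c) / (biomass · Δt)`` (the
maximum-available-amount rule applied locally). Biomass then grows linearly
within the step, local substrate is debited/credited by the realized exchange
fluxes, individuals divide into two halves once they reach twice the initial
biomass (daughter placed in a random neighboring cell), perform a random walk
over the 8-neighborhood with reflecting boundaries, and finally substrate
diffuses by one conservative discrete-Laplacian pass.

This is an independent minimal simulator in the style of individual-based
FBA arenas; numeric agreement with any particular arena package is not a
goal. All stochastic entry points take explicit seeds; replicate runs for a
supplementation are paired with matched control replicates sharing the same
per-replicate seed to reduce between-replicate variance in relative changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba_engine import GlpkProblem
from .model_core import BIG, Medium, MetabolicModel


@dataclass
class Individual:
    species_id: str
    biomass: float  # gDW
    position: tuple[int, int]

    def __post_init__(self) -> None:
        if self.biomass <= 0:
            raise ValueError("biomass must be > 0")


@dataclass
class ArenaConfig:
    grid_shape: tuple[int, int] = (30, 30)
    n_individuals_per_species: int = 20
    dilution: float = 1000.0
    cell_volume_ul: float = 1.0  # µL per grid cell; converts mM -> mmol
    timestep_hours: float = 1.0
    initial_biomass: float = 5e-7  # gDW per inoculated individual
    flux_penalty: float = 1e-6
    diffusion_rate: float = 0.2  # fraction exchanged per neighbor pair and pass


@dataclass
class Arena:
    config: ArenaConfig
    substrate: dict[str, np.ndarray]  # compound -> (rows, cols) mmol per cell
    individuals: list[Individual]
    rng: np.random.Generator
    models: dict[str, MetabolicModel]
    solvers: dict[str, GlpkProblem] = field(default_factory=dict)
    exchange_map: dict[str, dict[str, str]] = field(default_factory=dict)
    t: int = 0
    infeasible_events: int = 0

    def total_biomass(self) -> dict[str, float]:
        out = {sp: 0.0 for sp in self.models}
        for ind in self.individuals:
            out[ind.species_id] += ind.biomass
        return out


def _mm_to_mmol_per_cell(conc_mM: float, config: ArenaConfig) -> float:
    # mM = mmol/L; cell volume in liters = µL * 1e-6
    return (conc_mM / config.dilution) * config.cell_volume_ul * 1e-6


def init_arena(
    models: list[MetabolicModel],
    medium_mM: Medium,
    seed: int,
    config: ArenaConfig | None = None,
) -> Arena:
    """Inoculate a fresh arena: n individuals per species at seeded-random
    cells, medium (mM) diluted by the configured factor and spread uniformly
    across cells."""
    config = config or ArenaConfig()
    if config.n_individuals_per_species < 1:
        raise ValueError("need at least one individual per species")
    rows, cols = config.grid_shape
    if rows < 1 or cols < 1:
        raise ValueError("grid_shape must be positive")
    rng = np.random.default_rng(seed)
    substrate = {
        cid: np.full((rows, cols), _mm_to_mmol_per_cell(conc, config))
        for cid, conc in medium_mM.availabilities.items()
    }
    individuals = []
    for model in models:
        for _ in range(config.n_individuals_per_species):
            pos = (int(rng.integers(rows)), int(rng.integers(cols)))
            individuals.append(Individual(model.id, config.initial_biomass, pos))
    arena = Arena(
        config=config,
        substrate=substrate,
        individuals=individuals,
        rng=rng,
        models={m.id: m for m in models},
    )
    _prepare_solvers(arena)
    return arena


def _prepare_solvers(arena: Arena) -> None:
    for sp, model in arena.models.items():
        arena.solvers[sp] = GlpkProblem(model, flux_penalty=arena.config.flux_penalty)
        arena.exchange_map[sp] = {
            rxn.exchange_metabolite: rid
            for rid, rxn in model.exchange_reactions.items()
        }


def _diffuse(grid: np.ndarray, rate: float) -> None:
    """One conservative 4-neighbor diffusion pass (in place).

    Implemented in flux form — every pair of adjacent cells exchanges
    ``rate * (difference)/2`` — so each compound's grid total is conserved
    exactly and reflecting boundaries need no special casing.
    """
    for axis in (0, 1):
        # flux[i] = amount flowing from cell i+1 into cell i (negative: i -> i+1)
        flux = 0.5 * rate * np.diff(grid, axis=axis)
        pad_hi = [(0, 0), (0, 0)]
        pad_hi[axis] = (0, 1)
        pad_lo = [(0, 0), (0, 0)]
        pad_lo[axis] = (1, 0)
        # cell i gains flux[i] from above and loses flux[i-1] to below
        grid += np.pad(flux, pad_hi) - np.pad(flux, pad_lo)


def _neighbors(pos: tuple[int, int], shape: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = pos
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                out.append((rr, cc))
    return out


def step(arena: Arena) -> Arena:
    """Advance the arena by one timestep (in place; returns the arena)."""
    cfg = arena.config
    dt = cfg.timestep_hours
    rng = arena.rng
    order = rng.permutation(len(arena.individuals))
    newborn: list[Individual] = []
    for idx in order:
        ind = arena.individuals[idx]
        sp = ind.species_id
        solver = arena.solvers[sp]
        exch = arena.exchange_map[sp]
        model = arena.models[sp]
        r, c = ind.position
        # uptake bounds from the local cell
        for cid, rid in exch.items():
            amount = arena.substrate.get(cid)
            local = float(amount[r, c]) if amount is not None else 0.0
            ub = model.reactions[rid].upper_bound
            lb = -min(local / (ind.biomass * dt), BIG) if local > 0 else 0.0
            solver.set_bounds(rid, lb, ub)
        sol = solver.solve(flux_ids=list(exch.values()))
        if not sol.ok:
            arena.infeasible_events += 1
            continue  # individual idles this step
        mu = sol.objective_value
        for cid, rid in exch.items():
            v = sol.fluxes[rid]
            if v == 0.0:
                continue
            grid = arena.substrate.get(cid)
            if grid is None:
                if v < 0:
                    continue
                # first secretion of a compound absent from the medium
                grid = arena.substrate[cid] = np.zeros(cfg.grid_shape)
            grid[r, c] += v * ind.biomass * dt  # v<0 uptake, v>0 secretion
            if grid[r, c] < 0.0:
                assert grid[r, c] > -1e-6, f"substrate {cid} deficit {grid[r, c]}"
                grid[r, c] = 0.0
        ind.biomass *= 1.0 + mu * dt
        # division at twice the inoculation biomass
        if ind.biomass >= 2.0 * cfg.initial_biomass:
            half = ind.biomass / 2.0
            ind.biomass = half
            nbrs = _neighbors(ind.position, cfg.grid_shape)
            daughter_pos = nbrs[rng.integers(len(nbrs))] if nbrs else ind.position
            newborn.append(Individual(sp, half, daughter_pos))
        # random move to one of the 8 neighbors, or stay
        nbrs = _neighbors(ind.position, cfg.grid_shape) + [ind.position]
        ind.position = nbrs[rng.integers(len(nbrs))]
    arena.individuals.extend(newborn)
    for grid in arena.substrate.values():
        _diffuse(grid, cfg.diffusion_rate)
    arena.t += 1
    return arena


@dataclass
class AbmRunResult:
    """Replicate biomass trajectories and supplementation relative changes.

    ``trajectory`` is tidy: (replicate, timestep, species_id, total_biomass)
    with 1-based timesteps; timestep 1 is the initial state, so an n-step run
    carries timesteps 1..n+1. ``relative_change`` (replicate, species_id,
    relative_change) is only present when a matched control is available;
    changes compare final-timestep total biomass to the matched control
    replicate and are rounded to six digits.
    """

    compound: str | None
    trajectory: pd.DataFrame
    relative_change: pd.DataFrame | None = None

    def final_biomass(self) -> pd.DataFrame:
        t_final = int(self.trajectory["timestep"].max())
        return self.trajectory[self.trajectory["timestep"] == t_final]


def _run_one(
    models: list[MetabolicModel],
    medium_mM: Medium,
    compound: str | None,
    dose_mM: float,
    n_steps: int,
    seed: int,
    config: ArenaConfig,
) -> pd.DataFrame:
    med = medium_mM.copy()
    arena = init_arena(models, med, seed=seed, config=config)
    if compound is not None and dose_mM > 0:
        # supplement once at t=0, after dilution, uniformly across cells
        extra = dose_mM * config.cell_volume_ul * 1e-6
        grid = arena.substrate.setdefault(
            compound, np.zeros(config.grid_shape)
        )
        grid += extra
    rows = []
    totals = arena.total_biomass()
    for sp, b in totals.items():
        rows.append({"timestep": 1, "species_id": sp, "total_biomass": b})
    for k in range(n_steps):
        step(arena)
        for sp, b in arena.total_biomass().items():
            rows.append({"timestep": k + 2, "species_id": sp, "total_biomass": b})
    return pd.DataFrame(rows)


def run_supplement_replicates(
    models: list[MetabolicModel],
    medium_mM: Medium,
    compound: str | None,
    dose_mM: float = 0.01,
    n_steps: int = 12,
    n_replicates: int = 15,
    seed: int = 0,
    config: ArenaConfig | None = None,
    control: AbmRunResult | None = None,
    round_digits: int = 6,
) -> AbmRunResult:
    """Run supplementation replicates with matched-seed controls.

    Each replicate i uses a seed derived from the master seed; the control
    replicate i shares that seed, so initial placement and random streams are
    paired. With ``compound=None`` only control trajectories are produced
    (reusable across compounds via the ``control`` argument).
    """
    if n_steps < 1 or n_replicates < 1:
        raise ValueError("n_steps and n_replicates must be >= 1")
    config = config or ArenaConfig()
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    frames = []
    for i, s in enumerate(rep_seeds):
        df = _run_one(models, medium_mM, compound, dose_mM, n_steps, s, config)
        df.insert(0, "replicate", i)
        frames.append(df)
    traj = pd.concat(frames, ignore_index=True)
    result = AbmRunResult(compound=compound, trajectory=traj)
    if compound is None:
        return result
    if control is None:
        control = run_supplement_replicates(
            models, medium_mM, None, 0.0, n_steps, n_replicates, seed, config
        )
    result.relative_change = _relative_change(result, control, round_digits)
    return result


def _relative_change(
    suppl: AbmRunResult, control: AbmRunResult, round_digits: int = 6
) -> pd.DataFrame:
    fs = suppl.final_biomass().set_index(["replicate", "species_id"])["total_biomass"]
    fc = control.final_biomass().set_index(["replicate", "species_id"])["total_biomass"]
    rel = ((fs - fc) / fc).round(round_digits)
    out = rel.reset_index()
    out.columns = ["replicate", "species_id", "relative_change"]
    return out
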