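"""Decision layer of the supplementation screen: the three screen arms
(single-species FBA, community FBA, individual-based simulation), the
rounding/cutoff/test rules, the cross-method intersection with phenotype
(Biolog) confirmation, compound-class enrichment, and the host
colonization-proportion analysis.

Selection rules
---------------
* single-species FBA: relative growth-rate increase
  (μ_suppl − μ_base)/μ_base, both rounded to six digits first; selected when
  the change exceeds 0.01 (strict).
* community FBA: change of the target's growth-normalized abundance, same
  rounding and cutoff.
* individual-based arm: per-compound two-sided Wilcoxon rank-sum test between
  the two species' replicate relative-change vectors; p-values
  Benjamini–Hochberg-adjusted across compounds; selected when the target's
  median relative change exceeds the competitor's AND the adjusted p-value is
  below α (default 0.05).

A compound passes the screen when selected by every arm run; it is
*confirmed* when additionally the Biolog growth call for the target is
positive. Compounds absent from the plate are reported as not assayed, never
silently treated as negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .agent_sim import AbmRunResult, ArenaConfig, run_supplement_replicates
from .community_fba import SupplementEffect, community_growth, community_supplement_effect, merge_models
from .fba_engine import solve_fba
from .model_core import (
    BiologTable,
    CompoundAnnotation,
    Medium,
    MetabolicModel,
    apply_medium,
    biolog_growth_call,
    supplement_medium,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Statistics primitives
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact distribution for small untied samples (n_x + n_y ≤ 20), normal
    approximation with tie correction otherwise; identical inputs (all tied)
    give p = 1 rather than NaN. Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum needs non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size + y.size <= 20) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Screen arms
# ---------------------------------------------------------------------------


@dataclass
class SingleFbaRecord:
    compound: str
    mu_base: float
    mu_suppl: float
    relative_change: float | None  # None when baseline growth is zero
    selected: bool


def screen_single_fba(
    model: MetabolicModel,
    medium: Medium,
    compounds: list[str],
    dose: float = 10.0,
    cutoff: float = 0.01,
    round_digits: int = 6,
    backend: str = "scipy",
) -> tuple[set[str], list[SingleFbaRecord]]:
    """Relative growth increase of one species under each supplementation."""
    base_sol = solve_fba(apply_medium(model, medium), backend=backend)
    if not base_sol.ok:
        raise RuntimeError(f"baseline FBA {base_sol.status} for model {model.id!r}")
    mu_base = round(base_sol.objective_value, round_digits)
    records = []
    selected: set[str] = set()
    for compound in compounds:
        med = supplement_medium(medium, compound, dose)
        sol = solve_fba(apply_medium(model, med), backend=backend)
        mu_s = round(sol.objective_value, round_digits) if sol.ok else float("nan")
        if mu_base <= 0:
            logger.info("compound %s: undefined baseline (mu_base=0), excluded", compound)
            records.append(SingleFbaRecord(compound, mu_base, mu_s, None, False))
            continue
        rel = round((mu_s - mu_base) / mu_base, round_digits)
        sel = rel > cutoff
        if sel:
            selected.add(compound)
        records.append(SingleFbaRecord(compound, mu_base, mu_s, rel, sel))
    return selected, records


def screen_community_fba(
    models: list[MetabolicModel],
    medium: Medium,
    target: str,
    compounds: list[str],
    dose: float = 10.0,
    cutoff: float = 0.01,
    round_digits: int = 6,
    flux_penalty: float = 1e-6,
    backend: str = "scipy",
) -> tuple[set[str], list[SupplementEffect]]:
    """Compounds whose supplementation raises the target's normalized abundance."""
    baseline = community_growth(merge_models(models, medium), flux_penalty, backend=backend)
    records = []
    selected: set[str] = set()
    for compound in compounds:
        eff = community_supplement_effect(
            models, medium, compound, dose=dose, flux_penalty=flux_penalty,
            cutoff=cutoff, round_digits=round_digits, baseline=baseline,
            backend=backend,
        )
        records.append(eff)
        if eff.screenable and eff.selected.get(target, False):
            selected.add(compound)
    return selected, records


def screen_abm_stats(
    results: dict[str, AbmRunResult],
    target: str,
    other: str,
    alpha: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Wilcoxon + BH selection over the individual-based arm's results.

    For each compound, the target's and competitor's per-replicate relative
    biomass changes are compared with a two-sided rank-sum test; p-values are
    FDR-adjusted across compounds; a compound is selected iff the target's
    median change exceeds the competitor's and adjusted p < alpha.
    """
    rows = []
    for compound, res in results.items():
        if res.relative_change is None:
            raise ValueError(f"ABM result for {compound!r} lacks relative changes")
        rc = res.relative_change
        xt = rc.loc[rc["species_id"] == target, "relative_change"].to_numpy()
        xo = rc.loc[rc["species_id"] == other, "relative_change"].to_numpy()
        if xt.size < 2 or xo.size < 2:
            raise ValueError("need >= 2 replicates per species")
        rows.append(
            {
                "compound": compound,
                "median_target": float(np.median(xt)),
                "median_other": float(np.median(xo)),
                "p": wilcoxon_rank_sum(xt, xo),
            }
        )
    stats = pd.DataFrame(rows)
    stats["p_adj"] = bh_fdr(stats["p"].to_numpy())
    stats["selected"] = (stats["median_target"] > stats["median_other"]) & (
        stats["p_adj"] < alpha
    )
    return set(stats.loc[stats["selected"], "compound"]), stats


def run_abm_arm(
    models: list[MetabolicModel],
    medium_mM: Medium,
    compounds: list[str],
    dose_mM: float = 0.01,
    n_steps: int = 12,
    n_replicates: int = 15,
    seed: int = 0,
    config: ArenaConfig | None = None,
) -> dict[str, AbmRunResult]:
    """Run control once and each supplementation against it (matched seeds)."""
    control = run_supplement_replicates(
        models, medium_mM, None, 0.0, n_steps, n_replicates, seed, config
    )
    out: dict[str, AbmRunResult] = {}
    for compound in compounds:
        out[compound] = run_supplement_replicates(
            models, medium_mM, compound, dose_mM, n_steps, n_replicates, seed,
            config, control=control,
        )
    return out


# ---------------------------------------------------------------------------
# Intersection, confirmation, enrichment
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    per_method: dict[str, set[str]]
    intersection: set[str]
    biolog_confirmed: set[str]
    not_assayed: set[str]
    evidence: dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_method": {k: sorted(v) for k, v in self.per_method.items()},
            "intersection": sorted(self.intersection),
            "biolog_confirmed": sorted(self.biolog_confirmed),
            "not_assayed": sorted(self.not_assayed),
        }


def intersect_and_confirm(
    per_method_sets: dict[str, set[str]], biolog: BiologTable | None
) -> ScreenResult:
    """Intersect the arms' selections and confirm against the Biolog calls."""
    if not per_method_sets:
        raise ValueError("need at least one method's selection set")
    sets = list(per_method_sets.values())
    intersection = set(sets[0])
    for s in sets[1:]:
        intersection &= s
    confirmed: set[str] = set()
    not_assayed: set[str] = set()
    if biolog is not None:
        for c in intersection:
            call = biolog_growth_call(biolog, c)
            if call is None:
                not_assayed.add(c)
            elif call:
                confirmed.add(c)
    return ScreenResult(
        per_method={k: set(v) for k, v in per_method_sets.items()},
        intersection=intersection,
        biolog_confirmed=confirmed,
        not_assayed=not_assayed,
    )


def class_enrichment(
    candidates: set[str],
    annotation: CompoundAnnotation,
    background: set[str],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher-exact enrichment of compound classes among the candidates.

    The 2×2 table per class counts membership in/out of the candidate set ×
    in/out of the class, over the background (the compounds of the target's
    model). One-sided ("greater", i.e. enrichment) by default. Classes with
    no background member are skipped with a log entry. Returns a frame with
    the counts, odds ratio, p, and BH-adjusted p, sorted by p.
    """
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    rows = []
    for cls in sorted(annotation.all_classes()):
        in_class = {c for c in background if cls in annotation.classes.get(c, set())}
        if not in_class:
            logger.info("class %r has no background member; skipped", cls)
            continue
        a = len(candidates & in_class)
        b = len(candidates - in_class)
        c = len(in_class - candidates)
        d = len(background - candidates - in_class)
        odds, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {"class": cls, "cand_in_class": a, "cand_out_class": b,
             "bg_in_class": c, "bg_out_class": d, "odds_ratio": odds, "p": p}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Host colonization analysis
# ---------------------------------------------------------------------------


@dataclass
class HostColonizationData:
    """Proportions of the target species on lawns and inside hosts."""

    prop_lawn_base: float
    prop_lawn_suppl: float
    prop_worm_base: float
    prop_worm_suppl: float | None = None  # observed, used for the chi-square

    def __post_init__(self) -> None:
        for name in ("prop_lawn_base", "prop_lawn_suppl", "prop_worm_base"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def expected_worm_proportion(d: HostColonizationData) -> float:
    """Expected in-host target proportion under supplementation.

    The product of the supplemented lawn proportion and the host-filtering
    shift observed without supplementation (in-host / on-lawn ratio):

        E = prop_lawn_suppl × (prop_worm_base / prop_lawn_base)

    If observed in-host proportions exceed this expectation, the host
    environment amplifies the supplement's effect beyond the change in diet.
    """
    if d.prop_lawn_base == 0:
        raise ValueError("expectation undefined: baseline lawn proportion is 0")
    expected = d.prop_lawn_suppl * (d.prop_worm_base / d.prop_lawn_base)
    if expected > 1:
        logger.warning("expected proportion %.4f > 1; clipped", expected)
        expected = 1.0
    return expected


def chisq_observed_vs_expected(observed_counts, expected_props) -> tuple[float, int, float]:
    """Pearson chi-square of observed counts against expected proportions."""
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed counts must be positive")
    if not math.isclose(props.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be positive")
    exp = obs.sum() * props
    chi2, p = scipy.stats.chisquare(obs, f_exp=exp)
    return float(chi2), len(obs) - 1, float(p)


# ---------------------------------------------------------------------------
# Three-arm orchestration
# ---------------------------------------------------------------------------


def run_three_arm_screen(
    models: list[MetabolicModel],
    medium: Medium,
    medium_mM: Medium,
    target: str,
    compounds: list[str],
    biolog: BiologTable | None = None,
    dose: float = 10.0,
    dose_mM: float = 0.01,
    cutoff: float = 0.01,
    round_digits: int = 6,
    alpha: float = 0.05,
    n_steps: int = 12,
    n_replicates: int = 15,
    seed: int = 0,
    arena_config: ArenaConfig | None = None,
    methods: tuple[str, ...] = ("fba_single", "community_fba", "abm"),
) -> ScreenResult:
    """Run the requested arms, intersect, and Biolog-confirm.

    ``medium`` is the batch medium (fluxes, mmol/gDW/hr) for the FBA arms;
    ``medium_mM`` the concentration medium for the spatial arm. The target
    species must be one of the two community members.
    """
    others = [m.id for m in models if m.id != target]
    if len(models) != 2 or len(others) != 1:
        raise ValueError("the three-arm screen is defined for two-species communities")
    other = others[0]
    target_model = next(m for m in models if m.id == target)

    per_method: dict[str, set[str]] = {}
    evidence: dict[str, object] = {}
    if "fba_single" in methods:
        sel, recs = screen_single_fba(
            target_model, medium, compounds, dose, cutoff, round_digits
        )
        per_method["fba_single"] = sel
        evidence["fba_single"] = recs
    if "community_fba" in methods:
        sel, effs = screen_community_fba(
            models, medium, target, compounds, dose, cutoff, round_digits
        )
        per_method["community_fba"] = sel
        evidence["community_fba"] = effs
    if "abm" in methods:
        results = run_abm_arm(
            models, medium_mM, compounds, dose_mM, n_steps, n_replicates, seed,
            arena_config,
        )
        sel, stats = screen_abm_stats(results, target, other, alpha)
        per_method["abm"] = sel
        evidence["abm"] = stats
    result = intersect_and_confirm(per_method, biolog)
    result.evidence = evidence
    return result
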