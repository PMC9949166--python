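"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the package
implementation it checks: FBA objectives through cobrapy (different code
path and a different LP solver), rank-sum p-values by exhaustive enumeration
over rank assignments, Fisher p-values by hypergeometric enumeration, the
BH step-up by its textbook definition, and unique-fraction means by
exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from prebioscreen.model_core import MetabolicModel
from prebioscreen.niche_analysis import UptakeProfile, unique_uptake_compounds


def cobra_fba_objective(model: MetabolicModel) -> tuple[str, float]:
    """Solve the same toy model with cobrapy/optlang-GLPK."""
    import cobra

    cmodel = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites.values()
    }
    rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.add_metabolites({mets[mid]: c for mid, c in r.stoichiometry.items()})
        rxns.append(cr)
    cmodel.add_reactions(rxns)
    cmodel.objective = {
        cmodel.reactions.get_by_id(r.id): r.objective_coefficient
        for r in model.reactions.values()
        if r.objective_coefficient != 0
    }
    sol = cmodel.optimize()
    return sol.status, float(sol.objective_value) if sol.status == "optimal" else float("nan")


def ranksum_p_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n, n_x) assignments.

    Assumes no ties. p = 2 * min tail probability of the Mann-Whitney U
    statistic (inclusive), capped at 1 — the standard exact two-sided rule.
    """
    nx, ny = len(x), len(y)
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == nx + ny, "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    obs_u = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    us = []
    all_ranks = list(range(1, nx + ny + 1))
    for combo in itertools.combinations(all_ranks, nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    total = len(us)
    lo = sum(1 for u in us if u <= obs_u) / total
    hi = sum(1 for u in us if u >= obs_u) / total
    return min(1.0, 2 * min(lo, hi))


def fisher_p_hypergeom(a: int, b: int, c: int, d: int, alternative: str = "greater") -> float:
    """Fisher exact p for [[a, b], [c, d]] by hypergeometric enumeration."""
    N = a + b + c + d
    K = a + c  # column margin (e.g. in-class)
    n = a + b  # row margin (candidates)

    def pmf(k: int) -> Fraction:
        return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))

    support = range(max(0, n - (N - K)), min(n, K) + 1)
    if alternative == "greater":
        p = sum(pmf(k) for k in support if k >= a)
    elif alternative == "less":
        p = sum(pmf(k) for k in support if k <= a)
    else:  # two-sided: sum of outcomes no more probable than observed
        pa = pmf(a)
        p = sum(pmf(k) for k in support if pmf(k) <= pa)
    return float(p)


def bh_stepup(pvalues) -> list[float]:
    """Textbook BH step-up: adj_i = min over j>=i of p_(j) * m / j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


def mean_unique_fraction_exhaustive(profiles: list[UptakeProfile], size: int) -> float:
    """Mean fraction-with-unique over ALL subsets of the given size."""
    fractions = [
        unique_uptake_compounds(list(combo)).fraction_with_unique
        for combo in itertools.combinations(profiles, size)
    ]
    return sum(fractions) / len(fractions)
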