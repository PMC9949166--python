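"""Linear-programming core: flux balance analysis (FBA), FBA with a secondary
total-flux minimization (parsimonious tie-breaking), and per-exchange flux
minimization for uptake testing.

Two interchangeable LP backends are provided behind one interface:

* ``"scipy"`` — ``scipy.optimize.linprog`` (HiGHS), the default for one-off
  solves;
* ``"glpk"`` — GLPK via ``swiglpk`` with a persistent problem object whose
  bounds can be mutated between solves (microsecond warm re-solves, used by
  the spatial simulator).

Results must agree between backends to within the global 1e-6 tolerance; the
test suite checks this. The uptake test (:func:`min_exchange_flux` /
:func:`can_take_up`) minimizes the flux through one exchange reaction subject
only to steady state and bounds — minimizing an exchange flux is maximizing
uptake of that compound under the sign convention — and imposes no growth
requirement by default. An optional ``min_growth`` argument forces a minimum
biomass flux for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_core import MetabolicModel

#: Numerical zero threshold used throughout (matches sixth-digit rounding).
TOL = 1e-6

DEFAULT_BACKEND = "scipy"


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``objective_value`` is the primary (growth) objective evaluated on the
    flux vector; for penalized solves the combined value including the
    total-flux penalty is kept in ``penalized_objective``.
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    penalized_objective: float | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _matrices(model: MetabolicModel):
    """Stoichiometric matrix S (metabolites x reactions), bounds, objective."""
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rxn_ids = list(model.reactions)
    rows, cols, vals = [], [], []
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    obj = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        obj[j] = rxn.objective_coefficient
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(coef)
    S = sp.coo_matrix((vals, (rows, cols)), shape=(len(met_index), len(rxn_ids))).tocsr()
    return S, lb, ub, obj, rxn_ids


_STATUS = {0: "optimal", 1: "infeasible", 2: "infeasible", 3: "unbounded", 4: "infeasible"}


def _linprog_status(res) -> str:
    if res.status == 0:
        return "optimal"
    if res.status == 3:
        return "unbounded"
    return "infeasible"


def _solve_scipy(S, lb, ub, c_min, n_aux_rows=None, A_ub=None, b_ub=None):
    m = S.shape[0]
    res = linprog(
        c=c_min,
        A_eq=S,
        b_eq=np.zeros(m),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res


def solve_fba(model: MetabolicModel, backend: str = DEFAULT_BACKEND) -> FluxSolution:
    """Maximize the objective (biomass) subject to S·v = 0 and flux bounds."""
    S, lb, ub, obj, rxn_ids = _matrices(model)
    if backend == "scipy":
        res = _solve_scipy(S, lb, ub, -obj)
        status = _linprog_status(res)
        if status != "optimal":
            return FluxSolution(status=status, objective_value=float("nan"))
        v = res.x
    elif backend == "glpk":
        prob = GlpkProblem(model, flux_penalty=0.0)
        sol = prob.solve()
        return sol
    else:
        raise ValueError(f"unknown LP backend {backend!r}")
    return FluxSolution(
        status="optimal",
        objective_value=float(obj @ v),
        fluxes=dict(zip(rxn_ids, map(float, v))),
    )


def solve_fba_pfba(
    model: MetabolicModel,
    flux_penalty: float = 1e-6,
    backend: str = DEFAULT_BACKEND,
) -> FluxSolution:
    """Maximize objective − flux_penalty · Σ|v| in a single LP.

    Absolute values are linearized with auxiliary variables t_j ≥ |v_j|
    (t_j ≥ v_j and t_j ≥ −v_j). With ``flux_penalty = 0`` this reduces to
    :func:`solve_fba`.
    """
    if flux_penalty < 0:
        raise ValueError("flux_penalty must be >= 0")
    if flux_penalty == 0:
        return solve_fba(model, backend=backend)
    if backend == "glpk":
        return GlpkProblem(model, flux_penalty=flux_penalty).solve()
    if backend != "scipy":
        raise ValueError(f"unknown LP backend {backend!r}")

    S, lb, ub, obj, rxn_ids = _matrices(model)
    n = len(rxn_ids)
    m = S.shape[0]
    # variables x = [v, t]; equalities [S 0] x = 0;
    # inequalities v - t <= 0 and -v - t <= 0.
    S_full = sp.hstack([S, sp.csr_matrix((m, n))]).tocsr()
    I = sp.identity(n)
    A_ub = sp.vstack([sp.hstack([I, -I]), sp.hstack([-I, -I])]).tocsr()
    b_ub = np.zeros(2 * n)
    t_ub = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n), t_ub))
    c = np.concatenate([-obj, np.full(n, flux_penalty)])
    res = linprog(c=c, A_eq=S_full, b_eq=np.zeros(m), A_ub=A_ub, b_ub=b_ub,
                  bounds=bounds, method="highs")
    status = _linprog_status(res)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x[:n]
    growth = float(obj @ v)
    return FluxSolution(
        status="optimal",
        objective_value=growth,
        fluxes=dict(zip(rxn_ids, map(float, v))),
        penalized_objective=growth - flux_penalty * float(np.abs(v).sum()),
    )


def min_exchange_flux(
    model: MetabolicModel,
    exchange_id: str,
    min_growth: float | None = None,
    backend: str = DEFAULT_BACKEND,
) -> float:
    """Minimum feasible flux through one exchange reaction.

    Under the sign convention (negative = uptake) this maximizes uptake of
    the exchanged compound. No growth requirement is imposed unless
    ``min_growth`` is given, in which case biomass flux ≥ min_growth is added
    as a constraint.
    """
    rxn = model.reactions.get(exchange_id)
    if rxn is None or not rxn.is_exchange:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction of model {model.id!r}")
    S, lb, ub, obj, rxn_ids = _matrices(model)
    j = rxn_ids.index(exchange_id)
    c = np.zeros(len(rxn_ids))
    c[j] = 1.0
    if min_growth is not None:
        k = rxn_ids.index(model.biomass_reaction_id)
        lb = lb.copy()
        lb[k] = max(lb[k], min_growth)
    if backend == "glpk":
        prob = GlpkProblem(model, flux_penalty=0.0, objective_override={exchange_id: -1.0})
        if min_growth is not None:
            k = rxn_ids.index(model.biomass_reaction_id)
            prob.set_bounds(model.biomass_reaction_id, lb[k], ub[k])
        sol = prob.solve()
        if not sol.ok:
            raise RuntimeError(f"uptake LP {sol.status} for {exchange_id!r}")
        return sol.fluxes[exchange_id]
    if backend != "scipy":
        raise ValueError(f"unknown LP backend {backend!r}")
    res = _solve_scipy(S, lb, ub, c)
    status = _linprog_status(res)
    if status != "optimal":
        raise RuntimeError(f"uptake LP {status} for {exchange_id!r} in model {model.id!r}")
    return float(res.x[j])


def can_take_up(
    model: MetabolicModel,
    exchange_id: str,
    tol: float = TOL,
    min_growth: float | None = None,
    backend: str = DEFAULT_BACKEND,
) -> bool:
    """True iff the compound's exchange flux can be made strictly negative.

    A minimal flux below ``-tol`` means the network can absorb the compound
    at steady state, i.e. the species can take it up.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    return min_exchange_flux(model, exchange_id, min_growth=min_growth, backend=backend) < -tol


# ---------------------------------------------------------------------------
# GLPK backend with persistent, bound-mutable problems
# ---------------------------------------------------------------------------


class GlpkProblem:
    """A GLPK LP built once from a model, supporting fast bound mutation.

    Always formulated with flux-splitting auxiliaries (t ≥ |v|) so the same
    problem serves plain FBA (``flux_penalty=0``) and penalized FBA. The
    objective maximizes Σ obj_j·v_j − flux_penalty·Σ t_j, or an arbitrary
    linear objective via ``objective_override`` (reaction id → coefficient,
    maximized).
    """

    def __init__(
        self,
        model: MetabolicModel,
        flux_penalty: float = 1e-6,
        objective_override: dict[str, float] | None = None,
    ):
        import swiglpk as glp

        self._glp = glp
        self.rxn_ids = list(model.reactions)
        self._col = {rid: j + 1 for j, rid in enumerate(self.rxn_ids)}
        self.flux_penalty = flux_penalty
        n = len(self.rxn_ids)
        met_index = {mid: i + 1 for i, mid in enumerate(model.metabolites)}
        m = len(met_index)
        self._obj = {
            rid: r.objective_coefficient
            for rid, r in model.reactions.items()
            if r.objective_coefficient != 0
        }

        lp = glp.glp_create_prob()
        self.lp = lp
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        use_aux = flux_penalty > 0
        ncols = 2 * n if use_aux else n
        nrows = m + (2 * n if use_aux else 0)
        glp.glp_add_rows(lp, nrows)
        glp.glp_add_cols(lp, ncols)
        for i in range(1, m + 1):
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)

        entries: list[tuple[int, int, float]] = []
        for j, rid in enumerate(self.rxn_ids, start=1):
            rxn = model.reactions[rid]
            self._set_col(j, rxn.lower_bound, rxn.upper_bound)
            for mid, coef in rxn.stoichiometry.items():
                entries.append((met_index[mid], j, coef))
            coeff = objective_override.get(rid, 0.0) if objective_override is not None \
                else rxn.objective_coefficient
            glp.glp_set_obj_coef(lp, j, coeff)
        if use_aux:
            for j, rid in enumerate(self.rxn_ids, start=1):
                rxn = model.reactions[rid]
                t_ub = max(abs(rxn.lower_bound), abs(rxn.upper_bound))
                tj = n + j
                self._set_col(tj, 0.0, t_ub)
                glp.glp_set_obj_coef(lp, tj, -flux_penalty)
                # rows: v - t <= 0 ; -v - t <= 0
                r1, r2 = m + 2 * j - 1, m + 2 * j
                glp.glp_set_row_bnds(lp, r1, glp.GLP_UP, 0.0, 0.0)
                glp.glp_set_row_bnds(lp, r2, glp.GLP_UP, 0.0, 0.0)
                entries.append((r1, j, 1.0))
                entries.append((r1, tj, -1.0))
                entries.append((r2, j, -1.0))
                entries.append((r2, tj, -1.0))

        ia = glp.intArray(len(entries) + 1)
        ja = glp.intArray(len(entries) + 1)
        ar = glp.doubleArray(len(entries) + 1)
        for k, (ri, cj, val) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = ri, cj, val
        glp.glp_load_matrix(lp, len(entries), ia, ja, ar)
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF

    def __del__(self):
        try:
            self._glp.glp_delete_prob(self.lp)
        except Exception:
            pass

    def _set_col(self, j: int, lb: float, ub: float) -> None:
        glp = self._glp
        if lb == ub:
            glp.glp_set_col_bnds(self.lp, j, glp.GLP_FX, lb, ub)
        else:
            glp.glp_set_col_bnds(self.lp, j, glp.GLP_DB, lb, ub)

    def set_bounds(self, reaction_id: str, lb: float, ub: float) -> None:
        self._set_col(self._col[reaction_id], lb, ub)

    def solve(self, flux_ids: list[str] | None = None) -> FluxSolution:
        """Solve (warm-started after the first call); returns a FluxSolution.

        ``flux_ids`` restricts which reaction fluxes are extracted (cheaper
        in tight loops); None extracts all.
        """
        glp = self._glp
        ret = glp.glp_simplex(self.lp, self._parm)
        status = glp.glp_get_status(self.lp)
        if ret != 0 or status not in (glp.GLP_OPT, glp.GLP_FEAS):
            if status == glp.GLP_UNBND:
                return FluxSolution(status="unbounded", objective_value=float("nan"))
            return FluxSolution(status="infeasible", objective_value=float("nan"))
        ids = self.rxn_ids if flux_ids is None else flux_ids
        fluxes = {rid: glp.glp_get_col_prim(self.lp, self._col[rid]) for rid in ids}
        growth = sum(
            coef * glp.glp_get_col_prim(self.lp, self._col[rid])
            for rid, coef in self._obj.items()
        )
        pen = glp.glp_get_obj_val(self.lp) if self.flux_penalty > 0 else None
        return FluxSolution(status="optimal", objective_value=growth, fluxes=fluxes,
                            penalized_objective=pen)
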