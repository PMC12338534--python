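"""Abundance-coupled community flux balance analysis and net exchange fluxes.

Member models are merged into one LP with namespaced compartments.  Each
member's boundary (exchange) reactions are rerouted through a shared
environment compartment; only community-level boundary reactions touch the
outside (the gut lumen).  Coupling is realized as

* fixed biomass proportions  v_bio,i = a_i * mu_C  (a_i = relative abundance,
  mu_C = community growth rate), and
* flux-biomass coupling  |v_ij| <= c * v_bio,i  for every non-biomass reaction
  of member i, with coupling constant c (400 by default),

and the LP maximizes mu_C.  From a solved instance we report, per environment
metabolite, each member's net transfer into the environment; cross-feeding is
summarized as internal_transfer = min(total production, total consumption)
and the community-lumen boundary flux as lumen_net = production - consumption
(positive = export to the lumen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .metmodel import MetabolicModel

__all__ = [
    "CommunityModel",
    "CommunitySolution",
    "ExchangeNetFluxTable",
    "build_community_model",
    "solve_community_fba",
    "net_exchange_fluxes",
    "filter_exchange_variance",
]

_LUMEN_EXPORT_CAP = 1000.0


@dataclass
class CommunityModel:
    members: list[tuple[MetabolicModel, float]]  # (model, relative abundance)
    coupling: float
    # assembled LP pieces
    var_names: list[str]
    A_eq: sparse.csr_matrix
    b_eq: np.ndarray
    A_ub: sparse.csr_matrix
    b_ub: np.ndarray
    bounds: list[tuple[float, float]]
    mu_index: int
    member_biomass_index: dict[str, int]
    # (member_id, metabolite) -> list of (var index, env coefficient)
    transfer_terms: dict[tuple[str, str], list[tuple[int, float]]]
    lumen_index: dict[str, int]  # env metabolite -> boundary-flux var index

    @property
    def abundances(self) -> dict[str, float]:
        return {m.model_id: a for m, a in self.members}


def build_community_model(
    members: list[MetabolicModel],
    abundances: list[float] | dict[str, float],
    coupling: float = 400.0,
    lumen_bounds: dict[str, tuple[float, float]] | None = None,
) -> CommunityModel:
    """Merge member models into an abundance-coupled community LP.

    Members with zero abundance are dropped; abundances are renormalized to
    sum to one.  Exchange reactions of each member are rewritten as transfers
    between the member compartment and the shared environment; community-level
    exchanges are added for every environment metabolite, with lumen uptake
    capacity equal to the largest uptake capacity any member's own exchange
    granted for that metabolite (and a permissive export bound).
    ``lumen_bounds`` overrides the community boundary flux bounds per
    metabolite (positive = export to lumen), e.g. ``{"vit": (0, 0)}`` closes
    the lumen for ``vit`` entirely.
    """
    if isinstance(abundances, dict):
        abundances = [abundances[m.model_id] for m in members]
    if len(abundances) != len(members):
        raise ValueError("one abundance per member required")
    if any(a < 0 for a in abundances):
        raise ValueError("abundances must be non-negative")
    kept = [(m, a) for m, a in zip(members, abundances) if a > 0]
    if not kept:
        raise ValueError("at least one member must have positive abundance")
    total = sum(a for _, a in kept)
    kept = [(m, a / total) for m, a in kept]
    ids = [m.model_id for m, _ in kept]
    if len(set(ids)) != len(ids):
        raise ValueError(f"member model ids collide: {ids}")
    for m, _ in kept:
        if m.model_id == "ENV" or "::" in m.model_id:
            raise ValueError(f"member id {m.model_id!r} collides with the namespace scheme")
        bad = [met for met in m.metabolites if "::" in met]
        if bad:
            raise ValueError(f"metabolite ids {bad} collide with the namespace scheme")

    var_names: list[str] = []
    bounds: list[tuple[float, float]] = []
    eq_rows: dict[str, dict[int, float]] = {}   # balance row per namespaced metabolite
    ub_rows: list[tuple[dict[int, float], float]] = []
    member_biomass_index: dict[str, int] = {}
    transfer_terms: dict[tuple[str, str], list[tuple[int, float]]] = {}
    lumen_uptake_cap: dict[str, float] = {}
    lumen_export_cap: dict[str, float] = {}

    def new_var(name: str, lb: float, ub: float) -> int:
        var_names.append(name)
        bounds.append((lb, ub))
        return len(var_names) - 1

    def add_eq(met: str, idx: int, coef: float) -> None:
        eq_rows.setdefault(met, {})[idx] = eq_rows.setdefault(met, {}).get(idx, 0.0) + coef

    for model, _a in kept:
        mid = model.model_id
        for rxn in model.reactions:
            j = new_var(f"{mid}::{rxn.id}", rxn.lower_bound, rxn.upper_bound)
            if rxn.id == model.objective_reaction:
                member_biomass_index[mid] = j
            if rxn.is_exchange:
                # reroute: member-side coefficients stay, mirrored into env
                for met, coef in rxn.stoichiometry.items():
                    add_eq(f"{mid}::{met}", j, coef)
                    add_eq(f"ENV::{met}", j, -coef)
                    transfer_terms.setdefault((mid, met), []).append((j, -coef))
                    # capacity bookkeeping: production rate into env is -coef*v
                    rates = sorted((-coef * rxn.lower_bound, -coef * rxn.upper_bound))
                    lumen_export_cap[met] = max(lumen_export_cap.get(met, 0.0), rates[1])
                    lumen_uptake_cap[met] = max(lumen_uptake_cap.get(met, 0.0), -rates[0])
            else:
                for met, coef in rxn.stoichiometry.items():
                    add_eq(f"{mid}::{met}", j, coef)

    mu_index = new_var("mu_C", 0.0, np.inf)

    # community boundary (lumen) exchanges: positive flux = export to lumen
    lumen_index: dict[str, int] = {}
    env_metabolites = sorted(
        met.split("::", 1)[1] for met in eq_rows if met.startswith("ENV::")
    )
    for met in env_metabolites:
        if lumen_bounds is not None and met in lumen_bounds:
            lb, ub = lumen_bounds[met]
        else:
            lb, ub = -lumen_uptake_cap.get(met, 0.0), _LUMEN_EXPORT_CAP
        j = new_var(f"EX_lumen::{met}", lb, ub)
        add_eq(f"ENV::{met}", j, -1.0)
        lumen_index[met] = j

    # fixed biomass proportions: v_bio,i - a_i * mu_C = 0
    for model, a in kept:
        row_name = f"PROP::{model.model_id}"
        add_eq(row_name, member_biomass_index[model.model_id], 1.0)
        add_eq(row_name, mu_index, -a)

    # flux-biomass coupling for every non-biomass member reaction
    var_index = {name: j for j, name in enumerate(var_names)}
    for model, _a in kept:
        mid = model.model_id
        bio_j = member_biomass_index[mid]
        for rxn in model.reactions:
            if rxn.id == model.objective_reaction:
                continue
            j = var_index[f"{mid}::{rxn.id}"]
            ub_rows.append(({j: 1.0, bio_j: -coupling}, 0.0))
            ub_rows.append(({j: -1.0, bio_j: -coupling}, 0.0))

    n = len(var_names)
    row_order = sorted(eq_rows)
    A_eq = sparse.lil_matrix((len(row_order), n))
    for i, rname in enumerate(row_order):
        for j, coef in eq_rows[rname].items():
            A_eq[i, j] = coef
    A_ub = sparse.lil_matrix((len(ub_rows), n))
    b_ub = np.zeros(len(ub_rows))
    for i, (row, rhs) in enumerate(ub_rows):
        for j, coef in row.items():
            A_ub[i, j] = coef
        b_ub[i] = rhs

    return CommunityModel(
        members=kept,
        coupling=coupling,
        var_names=var_names,
        A_eq=A_eq.tocsr(),
        b_eq=np.zeros(len(row_order)),
        A_ub=A_ub.tocsr(),
        b_ub=b_ub,
        bounds=bounds,
        mu_index=mu_index,
        member_biomass_index=member_biomass_index,
        transfer_terms=transfer_terms,
        lumen_index=lumen_index,
    )


@dataclass
class CommunitySolution:
    status: str  # solved | infeasible | unbounded
    community_growth: float | None = None
    member_biomass: dict[str, float] = field(default_factory=dict)
    # (member, metabolite) -> net transfer into environment (+ = secretion)
    transfers: pd.DataFrame = field(default_factory=pd.DataFrame)  # member x metabolite
    lumen: pd.Series = field(default_factory=pd.Series)  # + = export to lumen
    fluxes: pd.Series = field(default_factory=pd.Series)


def solve_community_fba(cm: CommunityModel) -> CommunitySolution:
    """Maximize community growth; infeasibility is a status, not an exception."""
    c = np.zeros(len(cm.var_names))
    c[cm.mu_index] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=cm.A_eq,
        b_eq=cm.b_eq,
        A_ub=cm.A_ub,
        b_ub=cm.b_ub,
        bounds=cm.bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return CommunitySolution(status="infeasible")
    if res.status == 3:
        return CommunitySolution(status="unbounded")
    if res.status != 0:
        return CommunitySolution(status="failed")

    v = res.x
    members = [m.model_id for m, _ in cm.members]
    metabolites = sorted(cm.lumen_index)
    transfers = pd.DataFrame(0.0, index=members, columns=metabolites)
    for (mid, met), terms in cm.transfer_terms.items():
        transfers.loc[mid, met] = sum(coef * v[j] for j, coef in terms)
    lumen = pd.Series({met: v[j] for met, j in cm.lumen_index.items()}).reindex(metabolites)
    return CommunitySolution(
        status="solved",
        community_growth=float(v[cm.mu_index]),
        member_biomass={mid: float(v[j]) for mid, j in cm.member_biomass_index.items()},
        transfers=transfers,
        lumen=lumen,
        fluxes=pd.Series(v, index=cm.var_names),
    )


@dataclass
class ExchangeNetFluxTable:
    """Metabolite x sample summaries of community exchange fluxes."""

    internal_transfer: pd.DataFrame  # min(production, consumption) among members
    lumen_net: pd.DataFrame          # boundary flux, + = export to lumen
    infeasible_samples: list[str] = field(default_factory=list)


def net_exchange_fluxes(solutions: dict[str, CommunitySolution]) -> ExchangeNetFluxTable:
    """Summarize per-sample community solutions into net exchange tables.

    Per metabolite and sample: production P = sum_i max(0, transfer_i),
    consumption C = sum_i max(0, -transfer_i); internal_transfer = min(P, C);
    lumen_net = P - C.  Infeasible samples are recorded and omitted from the
    columns.
    """
    solved = {s: sol for s, sol in solutions.items() if sol.status == "solved"}
    infeasible = [s for s, sol in solutions.items() if sol.status != "solved"]
    metabolites = sorted({m for sol in solved.values() for m in sol.transfers.columns})
    internal = pd.DataFrame(0.0, index=metabolites, columns=sorted(solved))
    lumen = pd.DataFrame(0.0, index=metabolites, columns=sorted(solved))
    for s, sol in solved.items():
        tr = sol.transfers.reindex(columns=metabolites, fill_value=0.0)
        production = tr.clip(lower=0).sum(axis=0)
        consumption = (-tr).clip(lower=0).sum(axis=0)
        internal[s] = np.minimum(production, consumption)
        lumen[s] = production - consumption
    return ExchangeNetFluxTable(internal, lumen, infeasible)


def filter_exchange_variance(
    table: ExchangeNetFluxTable, params=None
) -> ExchangeNetFluxTable:
    """Apply the near-zero-variance rule to each value plane independently."""
    from .preprocess import NZVParams, near_zero_var_filter

    params = params or NZVParams()
    if table.internal_transfer.empty and table.lumen_net.empty:
        raise ValueError("empty exchange table")
    internal, _ = near_zero_var_filter(table.internal_transfer, params)
    lumen, _ = near_zero_var_filter(table.lumen_net, params)
    return ExchangeNetFluxTable(internal, lumen, list(table.infeasible_samples))
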