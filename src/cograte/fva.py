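"""Single-organism FBA/FVA and the FVA-derived reaction-abundance matrix.

Flux balance analysis maximizes biomass flux subject to steady-state mass
balance (S v = 0) and flux bounds.  Flux variability analysis then computes,
per reaction, the attainable flux range while growth is held at or above a
fraction of the optimum (0.99 by default).  A reaction is called *active* for
an organism when its FVA range reaches a magnitude above 1e-6 in either
direction; the per-organism activity vectors, normalized by each organism's
active-reaction count and weighted by its relative abundance per sample, give
a reaction x sample relative functional-abundance matrix whose columns sum
to one.

All LPs are solved with HiGHS through :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .metmodel import MetabolicModel

__all__ = [
    "FVAResult",
    "fba_max_growth",
    "fva_at_fraction",
    "reaction_incidence",
    "build_reaction_abundance_matrix",
    "normalize_abundance",
]

logger = logging.getLogger(__name__)

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(model: MetabolicModel, c: np.ndarray, sense: str,
           bounds: list[tuple[float, float]]):
    S = model.stoichiometric_matrix()
    res = linprog(
        c if sense == "min" else -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    status = _STATUS.get(res.status, "failed")
    value = None
    if status == "optimal":
        value = res.fun if sense == "min" else -res.fun
    return value, status, res


def fba_max_growth(model: MetabolicModel) -> tuple[float | None, str]:
    """Maximize the objective (biomass) flux; returns (optimum, status)."""
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(model.objective_reaction)] = 1.0
    value, status, _ = _solve(model, c, "max", model.bounds())
    return value, status


@dataclass
class FVAResult:
    """Per-reaction flux ranges at growth >= fraction * max_growth."""

    model_id: str
    fraction: float
    max_growth: float | None
    status: str
    ranges: pd.DataFrame = field(default_factory=pd.DataFrame)  # columns: min, max

    def range(self, rid: str) -> tuple[float, float]:
        row = self.ranges.loc[rid]
        return float(row["min"]), float(row["max"])


def fva_at_fraction(model: MetabolicModel, fraction: float = 0.99) -> FVAResult:
    """Flux variability analysis at ``fraction`` of the maximal growth rate.

    The growth requirement is installed as a raised lower bound on the
    objective reaction.  Infeasible base problems yield ``status='infeasible'``
    with empty ranges.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    max_growth, status = fba_max_growth(model)
    if status != "optimal":
        return FVAResult(model.model_id, fraction, None, status)

    obj_idx = model.reaction_ids.index(model.objective_reaction)
    bounds = model.bounds()
    lb, ub = bounds[obj_idx]
    bounds[obj_idx] = (max(lb, fraction * max_growth), ub)

    n = len(model.reactions)
    mins = np.empty(n)
    maxs = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo, st_lo, _ = _solve(model, c, "min", bounds)
        hi, st_hi, _ = _solve(model, c, "max", bounds)
        if st_lo != "optimal" or st_hi != "optimal":
            return FVAResult(model.model_id, fraction, max_growth, "infeasible")
        mins[j], maxs[j] = lo, hi
    # FP guard: a range can invert by solver tolerance only
    swap = mins > maxs
    mins[swap], maxs[swap] = maxs[swap], mins[swap]
    ranges = pd.DataFrame({"min": mins, "max": maxs}, index=model.reaction_ids)
    return FVAResult(model.model_id, fraction, max_growth, "solved", ranges)


def reaction_incidence(fva: FVAResult, tol: float = 1e-6) -> pd.Series:
    """Binary activity per reaction: 1 iff max(|min|, |max|) > tol."""
    if fva.status != "solved":
        raise ValueError(f"model {fva.model_id!r}: FVA status is {fva.status!r}")
    magnitude = np.maximum(fva.ranges["min"].abs(), fva.ranges["max"].abs())
    return (magnitude > tol).astype(int)


def normalize_abundance(abundance: pd.DataFrame) -> pd.DataFrame:
    """Renormalize a taxon x sample table so each column sums to one."""
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    colsum = abundance.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum.index[colsum <= 0].tolist()
        raise ValueError(f"samples with zero total abundance: {bad}")
    return abundance.div(colsum, axis=1)


def build_reaction_abundance_matrix(
    incidences: dict[str, pd.Series], abundance: pd.DataFrame
) -> pd.DataFrame:
    """Reaction x sample relative functional-abundance scores.

    score(r, s) = sum_m [active_m(r) / n_active(m)] * abundance(m, s),
    followed by per-sample (column) normalization to unit sum.  Models with no
    active reaction are excluded with a warning.
    """
    missing = set(abundance.index) - set(incidences)
    if missing:
        raise ValueError(f"no incidence vector for model(s): {sorted(missing)}")
    abundance = normalize_abundance(abundance)

    all_reactions = sorted({r for inc in incidences.values() for r in inc.index})
    scores = pd.DataFrame(0.0, index=all_reactions, columns=abundance.columns)
    for model_id in abundance.index:
        inc = incidences[model_id]
        n_active = int(inc.sum())
        if n_active == 0:
            logger.warning("model %s has zero active reactions; excluded", model_id)
            continue
        weight = inc.reindex(all_reactions, fill_value=0).astype(float) / n_active
        scores += np.outer(weight.values, abundance.loc[model_id].values)
    colsum = scores.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum.index[colsum <= 0].tolist()
        raise ValueError(f"samples with zero total reaction score: {bad}")
    return scores.div(colsum, axis=1)
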