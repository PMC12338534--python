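"""Downstream characterization of selected features.

Spearman associations between feature values and the composite cognitive
rank; hypergeometric over-representation analysis of selected genes against
GMT gene sets with a layer-specific universe (set sizes restricted to
10-500 within the universe, BH correction, reported sets need nominal
p <= 0.05 and an overlap of at least three genes); and per-model functional
category scores (fraction of a category's reactions present in a metabolic
model, with categories represented identically in every model dropped).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metmodel import MetabolicModel

__all__ = [
    "spearman_association",
    "read_gmt",
    "overrepresentation_test",
    "functional_category_score",
    "drop_uniform_categories",
]


def spearman_association(values, rank) -> tuple[float, float]:
    """Spearman rho (average-tie ranks) and two-sided p; NaN for constants."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(rank, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: set id, description, then member genes (deduplicated)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs id, description, genes")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def overrepresentation_test(
    selected,
    gene_sets: dict[str, set[str]],
    universe,
    min_size: int = 10,
    max_size: int = 500,
    p_max: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    Gene sets are first restricted to the universe and kept only if their
    within-universe size lies in [min_size, max_size].  p = P(X >= k) for
    overlap k, set size K, selection size n, universe size N; BH across the
    tested family.  The returned frame is sorted by (q, set size ascending)
    and carries a ``reported`` flag for sets with nominal p <= p_max and
    overlap >= min_overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    n = len(selected)
    N = len(universe)

    rows = []
    for set_id, genes in gene_sets.items():
        members = genes & universe
        K = len(members)
        if not min_size <= K <= max_size:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, k, K, n, N, p))
    result = pd.DataFrame(
        rows, columns=["set_id", "k", "K", "n", "N", "p"]
    ).set_index("set_id")
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["reported"] = pd.Series(dtype=bool)
        return result
    result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    result["reported"] = (result["p"] <= p_max) & (result["k"] >= min_overlap)
    return result.sort_values(["q", "K"], ascending=[True, True])


def functional_category_score(
    model: MetabolicModel | set[str], categories: dict[str, set[str]]
) -> pd.Series:
    """Per category: |model reactions in category| / |category|."""
    reactions = (
        set(model.reaction_ids) if isinstance(model, MetabolicModel) else set(model)
    )
    scores = {}
    for name, members in categories.items():
        members = set(members)
        if not members:
            raise ValueError(f"category {name!r} is empty")
        scores[name] = len(reactions & members) / len(members)
    return pd.Series(scores)


def drop_uniform_categories(scores: pd.DataFrame) -> pd.DataFrame:
    """Drop categories (rows) scored identically in every model (zero variance)."""
    keep = scores.nunique(axis=1) > 1
    return scores.loc[keep]
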