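"""All-relevant feature selection: Boruta with shadow features, wrapped in a
repeated-run stability scheme and a two-stage single-layer -> integrated
selection.

One Boruta run: each iteration permutes every (still active) feature to form
shadow copies, fits a random-forest regressor on [X | shadows], and scores a
*hit* for a real feature whose importance strictly exceeds the best shadow
importance.  After every iteration a two-sided binomial test (success
probability 0.5, Bonferroni-adjusted over the currently undecided features)
confirms features with significantly many hits and rejects features with
significantly few; rejected features and their shadows leave the matrix.
Features still undecided after ``max_iterations`` are tentative and count as
not confirmed.

The shadow pool never shrinks below ``shadow_floor_factor`` times the
original feature count: when rejections thin the active set, additional
independent permutations of the remaining features are appended.  This keeps
the best-shadow threshold calibrated to the original dimensionality — the
feature with the largest *chance* association in a p-dimensional null matrix
is the maximum of p draws, and must be compared against a maximum over a
pool of comparable size, or late iterations would confirm it spuriously.

Stability stage: the run is repeated ``n_runs`` times (seeds seed+1 ..
seed+n_runs); features confirmed in >= ``robust_min`` runs are *robust*,
features confirmed at least once are *candidates*.  The integrated stage
pools the candidates of all layers (layer-qualified ids) and repeats the
stability stage on the combined matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "BorutaConfig",
    "BorutaDecision",
    "StabilityResult",
    "boruta_run",
    "stability_select",
    "integrate_layers",
]


@dataclass
class BorutaConfig:
    max_iterations: int = 100
    alpha: float = 0.01
    adjust: bool = True          # Bonferroni over currently undecided features
    n_trees: int = 500
    importance: str = "impurity"  # or "permutation"
    max_features: str | float = "sqrt"
    shadow_floor_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iterations < 10:
            raise ValueError("max_iterations must be >= 10")
        if self.importance not in {"impurity", "permutation"}:
            raise ValueError(f"unknown importance {self.importance!r}")


@dataclass
class BorutaDecision:
    status: pd.Series      # per feature: confirmed | rejected | tentative
    hits: pd.Series        # per feature: number of shadow-beating iterations
    iterations: int

    @property
    def confirmed(self) -> list[str]:
        return self.status.index[self.status == "confirmed"].tolist()


def _importances(X: np.ndarray, y: np.ndarray, cfg: BorutaConfig,
                 rng: np.random.Generator) -> np.ndarray:
    rf = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        max_features=cfg.max_features,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    rf.fit(X, y)
    if cfg.importance == "impurity":
        return rf.feature_importances_
    from sklearn.inspection import permutation_importance

    pi = permutation_importance(
        rf, X, y, n_repeats=5,
        random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
    )
    return pi.importances_mean


def boruta_run(X: pd.DataFrame, y: pd.Series, cfg: BorutaConfig | None = None) -> BorutaDecision:
    """One Boruta run on a feature x sample matrix against a numeric response."""
    cfg = cfg or BorutaConfig()
    if X.isna().any().any() or pd.Series(y).isna().any():
        raise ValueError("missing values are not allowed")
    samples = list(X.columns)
    y = pd.Series(y).loc[samples].to_numpy(dtype=float)
    if len(samples) < 5:
        raise ValueError("need at least 5 samples")
    features = list(X.index)
    data = X.to_numpy(dtype=float).T  # samples x features

    rng = np.random.default_rng(cfg.seed)
    status = pd.Series("tentative", index=features, dtype=object)
    hits = pd.Series(0, index=features, dtype=int)
    active = list(range(len(features)))      # undecided + confirmed stay in the forest
    undecided = set(range(len(features)))
    n_samples = data.shape[0]

    n_original = len(features)
    shadow_floor = int(np.ceil(cfg.shadow_floor_factor * n_original))
    iteration = 0
    while undecided and iteration < cfg.max_iterations:
        iteration += 1
        Xa = data[:, active]
        replicates = max(1, int(np.ceil(shadow_floor / Xa.shape[1])))
        shadows = rng.permuted(
            np.tile(Xa, (1, replicates)), axis=0
        )[:, : max(shadow_floor, Xa.shape[1])]
        imp = _importances(np.hstack([Xa, shadows]), y, cfg, rng)
        real_imp = imp[: Xa.shape[1]]
        shadow_max = imp[Xa.shape[1]:].max()
        for pos, j in enumerate(active):
            if j in undecided and real_imp[pos] > shadow_max:
                hits.iloc[j] += 1

        m = len(undecided)
        idx = np.fromiter(undecided, dtype=int)
        ks = hits.to_numpy()[idx]
        # two-sided exact binomial p at success prob 0.5 (symmetric case)
        pvals = np.minimum(
            1.0,
            2.0 * np.minimum(
                stats.binom.cdf(ks, iteration, 0.5),
                stats.binom.sf(ks - 1, iteration, 0.5),
            ),
        )
        if cfg.adjust:
            pvals = np.minimum(1.0, pvals * m)
        for j, k_hits, p in zip(idx, ks, pvals):
            if p <= cfg.alpha:
                status.iloc[j] = "confirmed" if k_hits > iteration / 2 else "rejected"
                undecided.discard(int(j))
        active = [j for j in active if status.iloc[j] != "rejected"]

    return BorutaDecision(status=status, hits=hits, iterations=iteration)


@dataclass
class StabilityResult:
    stage: str                    # "single_layer" | "integrated"
    n_runs: int
    robust_min: int
    n_confirmed: pd.Series        # per feature, confirmations out of n_runs
    layer: pd.Series = field(default_factory=pd.Series)  # feature -> layer id

    @property
    def robust(self) -> pd.Series:
        return self.n_confirmed >= self.robust_min

    @property
    def candidate(self) -> pd.Series:
        return self.n_confirmed >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": self.layer.reindex(self.n_confirmed.index)
                if len(self.layer) else "",
                "n_confirmed": self.n_confirmed,
                "robust": self.robust,
                "candidate": self.candidate,
            }
        )


def stability_select(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: BorutaConfig | None = None,
    n_runs: int = 50,
    robust_min: int = 10,
    stage: str = "single_layer",
    layer_id: str = "",
) -> StabilityResult:
    """Repeat Boruta ``n_runs`` times with seeds seed+1 .. seed+n_runs."""
    cfg = cfg or BorutaConfig()
    counts = pd.Series(0, index=X.index, dtype=int)
    for k in range(1, n_runs + 1):
        decision = boruta_run(X, y, replace(cfg, seed=cfg.seed + k))
        counts[decision.status == "confirmed"] += 1
    layer = pd.Series(layer_id, index=X.index) if layer_id else pd.Series(dtype=object)
    return StabilityResult(stage, n_runs, robust_min, counts, layer)


def integrate_layers(
    stage1: dict[str, StabilityResult],
    layers: dict[str, pd.DataFrame],
    y: pd.Series,
    cfg: BorutaConfig | None = None,
    n_runs: int = 50,
    robust_min: int = 10,
) -> StabilityResult:
    """Pool stage-1 candidates across layers and rerun the stability stage.

    Features enter under layer-qualified ids ``layer::feature``; the final
    cross-layer predictor set is the robust features of the returned result.
    """
    blocks = []
    layer_of = {}
    for name, res in stage1.items():
        cand = res.candidate
        cand_ids = cand.index[cand].tolist()
        if not cand_ids:
            continue
        block = layers[name].loc[cand_ids].copy()
        block.index = [f"{name}::{fid}" for fid in cand_ids]
        for qid in block.index:
            layer_of[qid] = name
        blocks.append(block)
    if not blocks:
        raise ValueError("empty candidate pool: no feature was confirmed in any run")
    common = set.intersection(*(set(b.columns) for b in blocks))
    if not common:
        raise ValueError("layers share no samples")
    order = sorted(common)
    pooled = pd.concat([b[order] for b in blocks], axis=0)
    result = stability_select(
        pooled, y.loc[order], cfg, n_runs=n_runs, robust_min=robust_min,
        stage="integrated",
    )
    result.layer = pd.Series(layer_of).reindex(pooled.index)
    return result
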