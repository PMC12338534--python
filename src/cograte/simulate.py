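"""Synthetic cohort, omics, metabolic-model and methylation generators.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes, so all stages run without any download.

Behavioral model: mouse i carries a latent intercept b0_i and learning slope
b1_i (drawn per age group); trial-level latent performance on training day d
is y = b0_i + b1_i * d + e with e ~ N(0, noise_sd) on the -log(latency s)
scale.  Latency = clamp(exp(-y), 1, 240); a trial is censored exactly when
the 240 s cap binds.  Discrete cognitive scores are thresholded from the
same latent y (monotone in ability by construction).  Defaults reproduce the
study design: 83 mice in age groups 3/9/15/24/28 months (16/16/16/17/18),
240 s cap, and roughly 30% censored training trials.

Omics layers: planted features follow a Gaussian-copula association with the
cognitive rank whose Spearman correlation targets ``effect_size`` (random
sign); everything else is independent noise.  Methylation-type layers are
mapped through a logistic into [0, 1], expression/metabolome layers through
an exponential into positive values.  A configured fraction of samples is
withheld from one layer to exercise the complete-case intersection.

Metabolic models: small chain / branch / cross-feeding motifs (<= ~30
reactions) with ground-truth FVA ranges attached, computed by an independent
oracle (cobra's GLPK-backed FVA) rather than the package's own LP code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metmodel import MetabolicModel, Reaction

__all__ = [
    "SimCohortConfig",
    "SimOmicsConfig",
    "simulate_barnes_maze",
    "simulate_omics_layers",
    "simulate_metabolic_models",
    "simulate_taxon_abundance",
    "simulate_cpg_table",
    "simulate_gene_sets",
    "write_trials_csv",
    "write_layer_tsv",
    "write_abundance_tsv",
    "write_cpg_tsv",
    "write_tss_bed",
    "write_gmt",
]

DEFAULT_AGE_GROUPS = ((3, 16), (9, 16), (15, 16), (24, 17), (28, 18))
#: latent -log(latency) intercepts and per-day learning slopes by age (months)
DEFAULT_BASELINE = {3: -5.5, 9: -5.6, 15: -5.7, 24: -6.0, 28: -6.1}
DEFAULT_LEARNING = {3: 0.50, 9: 0.45, 15: 0.35, 24: 0.20, 28: 0.14}

TRAINING_SCORE_EDGES = (-5.6, -4.8, -4.0, -3.0)
TRAINING_SCORE_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)
PROBE_SCORE_EDGES = (-5.2, -4.2, -3.0)
PROBE_SCORE_VALUES = (0.0, 0.167, 0.5, 1.0)


@dataclass
class SimCohortConfig:
    n_mice: int = 83
    age_groups: tuple[tuple[int, int], ...] = DEFAULT_AGE_GROUPS
    seed: int = 0
    censor_limit: float = 240.0
    noise_sd: float = 0.8
    learning_rate_by_age: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LEARNING)
    )
    baseline_by_age: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    intercept_sd: float = 0.3
    slope_sd: float = 0.08

    def __post_init__(self) -> None:
        if sum(n for _, n in self.age_groups) != self.n_mice:
            raise ValueError(
                f"group sizes sum to {sum(n for _, n in self.age_groups)}, "
                f"but n_mice = {self.n_mice}"
            )
        if self.censor_limit <= 0 or self.noise_sd <= 0:
            raise ValueError("censor_limit and noise_sd must be positive")
        for age, _n in self.age_groups:
            if age not in self.baseline_by_age or age not in self.learning_rate_by_age:
                raise ValueError(f"no latent parameters for age {age}")


def _score_from_latent(y: float, edges, values) -> float:
    return values[int(np.searchsorted(edges, y, side="right"))]


def simulate_barnes_maze(cfg: SimCohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial records plus the latent truth table.

    Returns (trials, truth): trials holds 18 training trials (6 days x 3),
    a probe (day 7) and retention trials (days 11, 12) per mouse; truth holds
    each mouse's latent intercept/slope and summary ability for recovery
    tests.
    """
    rng = np.random.default_rng(cfg.seed)
    trial_rows = []
    truth_rows = []
    mouse_no = 0
    for age, group_n in cfg.age_groups:
        for _ in range(group_n):
            mouse_no += 1
            mid = f"m{mouse_no:03d}"
            b0 = cfg.baseline_by_age[age] + rng.normal(0, cfg.intercept_sd)
            b1 = cfg.learning_rate_by_age[age] + rng.normal(0, cfg.slope_sd)
            truth_rows.append(
                {
                    "mouse_id": mid,
                    "age_months": age,
                    "intercept": b0,
                    "slope": b1,
                    "ability": b0 + 3.5 * b1,
                }
            )

            def emit(phase: str, day: int, trial_index: int) -> None:
                y = b0 + b1 * day + rng.normal(0, cfg.noise_sd)
                latency = float(np.clip(np.exp(-y), 1.0, cfg.censor_limit))
                censored = latency >= cfg.censor_limit
                if phase == "probe":
                    score = (
                        0.0
                        if censored
                        else _score_from_latent(y, PROBE_SCORE_EDGES, PROBE_SCORE_VALUES)
                    )
                else:
                    score = _score_from_latent(
                        y, TRAINING_SCORE_EDGES, TRAINING_SCORE_VALUES
                    )
                trial_rows.append(
                    {
                        "mouse_id": mid,
                        "phase": phase,
                        "day": day,
                        "trial_index": trial_index,
                        "latency": latency,
                        "censored": censored,
                        "cognitive_score": score,
                    }
                )

            for day in range(1, 7):
                for t in range(1, 4):
                    emit("training", day, t)
            emit("probe", 7, 1)
            emit("retention11", 11, 1)
            emit("retention12", 12, 1)
    return pd.DataFrame(trial_rows), pd.DataFrame(truth_rows)


DEFAULT_LAYER_SIZES = {
    "hippocampus_expr": 300,
    "colon_expr": 300,
    "liver_expr": 300,
    "hippocampus_meth": 200,
    "colon_meth": 200,
    "metabolome": 150,
}


@dataclass
class SimOmicsConfig:
    n_features_per_layer: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_SIZES)
    )
    n_planted: int = 10
    effect_size: float = 0.6
    missing_sample_fraction: float = 9.0 / 83.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.n_planted > min(self.n_features_per_layer.values()):
            raise ValueError("n_planted exceeds the smallest layer")
        if not 0.0 <= self.missing_sample_fraction < 1.0:
            raise ValueError("missing_sample_fraction must lie in [0, 1)")


def _is_methylation(layer: str) -> bool:
    return layer.endswith("meth")


def simulate_omics_layers(
    cfg: SimOmicsConfig, cognitive_rank: pd.Series
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Feature x sample matrices per layer plus the planted-feature registry.

    Planted features are monotone in the cognitive rank with Spearman
    correlation targeting ``effect_size`` (the latent Pearson coefficient is
    2 sin(pi * effect_size / 6), the Gaussian-copula inverse); the planted
    budget is spread round-robin over the layers.
    """
    rank = pd.Series(cognitive_rank).astype(float)
    if not np.isfinite(rank).all():
        raise ValueError("cognitive rank vector must be finite")
    samples = list(rank.index)
    n = len(samples)
    rng = np.random.default_rng(cfg.seed)

    # normal scores of the rank: the latent Gaussian the copula couples to
    z = stats.norm.ppf(stats.rankdata(rank.to_numpy()) / (n + 1))
    z = (z - z.mean()) / z.std()
    rho_latent = 2.0 * np.sin(np.pi * cfg.effect_size / 6.0)

    layer_names = list(cfg.n_features_per_layer)
    planted_layers = [layer_names[i % len(layer_names)] for i in range(cfg.n_planted)]
    registry_rows = []
    layers: dict[str, pd.DataFrame] = {}
    for layer in layer_names:
        p = cfg.n_features_per_layer[layer]
        n_pl = planted_layers.count(layer)
        latent = rng.normal(size=(p, n))
        signs = np.empty(p)
        for j in range(n_pl):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            latent[j] = sign * (
                rho_latent * z + np.sqrt(1.0 - rho_latent**2) * rng.normal(size=n)
            )
            signs[j] = sign
        feature_ids = [f"{layer}_f{j + 1:04d}" for j in range(p)]
        for j in range(n_pl):
            registry_rows.append(
                {
                    "feature_id": feature_ids[j],
                    "layer": layer,
                    "sign": signs[j],
                    "target_effect": cfg.effect_size,
                }
            )
        if _is_methylation(layer):
            values = 1.0 / (1.0 + np.exp(-latent))  # bounded in (0, 1)
        else:
            values = np.exp(2.0 + 0.8 * latent)  # positive, right-skewed
        layers[layer] = pd.DataFrame(values, index=feature_ids, columns=samples)

    n_withheld = int(round(cfg.missing_sample_fraction * n))
    if n_withheld and layer_names:
        withheld = rng.choice(samples, size=n_withheld, replace=False)
        for s in withheld:
            layer = layer_names[int(rng.integers(len(layer_names)))]
            layers[layer] = layers[layer].drop(columns=s)
    registry = pd.DataFrame(
        registry_rows, columns=["feature_id", "layer", "sign", "target_effect"]
    )
    return layers, registry


# ---------------------------------------------------------------------------
# metabolic-model fixtures


def _chain_model(model_id: str, n_steps: int, cap: float) -> MetabolicModel:
    mets = [f"M{k}" for k in range(n_steps + 1)]
    reactions = [Reaction("EX_M0", {"M0": 1.0}, 0.0, cap, True)]
    for k in range(n_steps):
        reactions.append(
            Reaction(f"r{k + 1}", {mets[k]: -1.0, mets[k + 1]: 1.0}, 0.0, cap, False)
        )
    reactions.append(Reaction("bio", {mets[-1]: -1.0}, 0.0, 1000.0, False))
    return MetabolicModel(model_id, mets, reactions, "bio")


def _branch_model(model_id: str, cap_a: float, cap_b: float) -> MetabolicModel:
    mets = ["A", "B", "C", "P"]
    cap = cap_a + cap_b
    reactions = [
        Reaction("EX_A", {"A": 1.0}, 0.0, cap, True),
        Reaction("branch1", {"A": -1.0, "B": 1.0}, 0.0, cap_a, False),
        Reaction("branch2", {"A": -1.0, "C": 1.0}, 0.0, cap_b, False),
        Reaction("join1", {"B": -1.0, "P": 1.0}, 0.0, cap, False),
        Reaction("join2", {"C": -1.0, "P": 1.0}, 0.0, cap, False),
        Reaction("bio", {"P": -1.0}, 0.0, 1000.0, False),
    ]
    return MetabolicModel(model_id, mets, reactions, "bio")


def _producer_model(model_id: str, cap: float) -> MetabolicModel:
    mets = ["glc", "ac", "X"]
    reactions = [
        Reaction("EX_glc", {"glc": 1.0}, 0.0, cap, True),
        Reaction("ferment", {"glc": -1.0, "X": 1.0, "ac": 1.0}, 0.0, cap, False),
        Reaction("EX_ac", {"ac": -1.0}, 0.0, 1000.0, True),
        Reaction("bio", {"X": -1.0}, 0.0, 1000.0, False),
    ]
    return MetabolicModel(model_id, mets, reactions, "bio")


def _consumer_model(model_id: str, cap: float) -> MetabolicModel:
    mets = ["ac", "X"]
    reactions = [
        Reaction("EX_ac", {"ac": 1.0}, 0.0, cap, True),
        Reaction("assim", {"ac": -1.0, "X": 1.0}, 0.0, cap, False),
        Reaction("bio", {"X": -1.0}, 0.0, 1000.0, False),
    ]
    return MetabolicModel(model_id, mets, reactions, "bio")


def oracle_fva(model: MetabolicModel, fraction: float = 0.99) -> pd.DataFrame:
    """Independent per-reaction flux ranges via cobra's GLPK-backed FVA."""
    from cobra.flux_analysis import flux_variability_analysis

    from .metmodel import to_cobra

    cm = to_cobra(model)
    sol = cm.slim_optimize()
    ranges = flux_variability_analysis(cm, fraction_of_optimum=fraction)
    ranges = ranges.rename(columns={"minimum": "min", "maximum": "max"})
    ranges.attrs["max_growth"] = float(sol)
    return ranges.loc[model.reaction_ids]


def simulate_metabolic_models(
    n_taxa: int, seed: int, fraction: float = 0.99
) -> tuple[list[MetabolicModel], dict[str, pd.DataFrame]]:
    """Generate small fixture models (chain/branch/cross-feeding motifs).

    Ground-truth flux ranges at ``fraction`` of maximal growth are attached
    for every model, computed by the independent oracle.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    models: list[MetabolicModel] = []
    for i in range(n_taxa):
        mid = f"taxon{i + 1:02d}"
        motif = i % 4
        if motif == 0:
            models.append(_chain_model(mid, int(rng.integers(2, 6)), float(rng.integers(5, 15))))
        elif motif == 1:
            cap_a = float(rng.integers(4, 8))
            cap_b = float(rng.integers(2, 5))
            models.append(_branch_model(mid, cap_a, cap_b))
        elif motif == 2:
            models.append(_producer_model(mid, float(rng.integers(5, 12))))
        else:
            models.append(_consumer_model(mid, float(rng.integers(3, 8))))
    truth = {m.model_id: oracle_fva(m, fraction) for m in models}
    return models, truth


def simulate_taxon_abundance(
    model_ids: list[str], samples: list[str], seed: int, concentration: float = 2.0
) -> pd.DataFrame:
    """Dirichlet relative abundances, taxa x samples, columns summing to one."""
    rng = np.random.default_rng(seed)
    values = rng.dirichlet([concentration] * len(model_ids), size=len(samples)).T
    return pd.DataFrame(values, index=model_ids, columns=samples)


# ---------------------------------------------------------------------------
# methylation fixtures


def simulate_cpg_table(
    n_genes: int,
    seed: int,
    n_samples: int = 6,
    window: int = 1000,
    cpg_per_gene: int = 4,
    n_background: int = 20,
    missing_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG-level methylation table plus a TSS BED table.

    CpGs are scattered inside and outside the +-window around each TSS on
    alternating strands; per-sample ratios are Beta(2, 2) draws in [0, 1].
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    tss_rows = []
    cpg_rows = []
    for g in range(n_genes):
        tss_pos = 5000 + 10000 * g
        strand = "+" if g % 2 == 0 else "-"
        tss_rows.append(("chr1", tss_pos, tss_pos + 1, f"gene{g + 1:03d}", 0, strand))
        offsets = rng.integers(-window, window, size=cpg_per_gene)
        for off in offsets:
            cpg_rows.append(("chr1", int(tss_pos + off), strand))
    span = 5000 + 10000 * n_genes
    for _ in range(n_background):
        # far outside every promoter window
        cpg_rows.append(("chr1", int(span + 50000 + rng.integers(0, 100000)), "+"))
    cpg_rows.sort(key=lambda r: r[1])
    ratios = rng.beta(2.0, 2.0, size=(len(cpg_rows), n_samples))
    if missing_fraction > 0:
        mask = rng.random(size=ratios.shape) < missing_fraction
        ratios[mask] = np.nan
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "strand"])
    for j, s in enumerate(samples):
        cpg[s] = ratios[:, j]
    tss = pd.DataFrame(
        tss_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return cpg, tss[["chrom", "start", "end", "name", "strand"]]


def simulate_gene_sets(
    features: list[str], seed: int, n_sets: int = 15, set_size: tuple[int, int] = (10, 40)
) -> dict[str, set[str]]:
    """Random gene sets over a feature universe (for enrichment plumbing)."""
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        size = min(size, len(features))
        members = rng.choice(features, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = set(members.tolist())
    return sets


# ---------------------------------------------------------------------------
# writers (plain-text formats only)


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def write_layer_tsv(layer: pd.DataFrame, path: str | Path) -> None:
    layer.to_csv(path, sep="\t", index_label="feature_id")


def write_abundance_tsv(abundance: pd.DataFrame, path: str | Path) -> None:
    abundance.to_csv(path, sep="\t", index_label="taxon_id")


def write_cpg_tsv(cpg: pd.DataFrame, path: str | Path) -> None:
    cpg.to_csv(path, sep="\t", index=False)


def write_tss_bed(tss: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in tss.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t0\t{row.strand}\n"
            )


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            genes = "\t".join(sorted(sets[set_id]))
            fh.write(f"{set_id}\tsynthetic\t{genes}\n")
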