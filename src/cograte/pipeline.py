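"""End-to-end orchestration of the synthetic-to-selection pipeline.

``run_all`` executes simulate -> cognitive scoring -> FVA reaction
abundances -> community FBA -> preprocessing -> two-stage stability
selection -> enrichment on a fully synthetic cohort, writes every stage
output as plain text and records a manifest (seeds, per-stage shapes, file
digests) so that two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import annotate, behavior, community, fva, preprocess, simulate
from .boruta import BorutaConfig, integrate_layers, stability_select
from .preprocess import NZVParams
from .simulate import SimCohortConfig, SimOmicsConfig

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 1
    cohort: SimCohortConfig = field(default_factory=SimCohortConfig)
    omics: SimOmicsConfig = field(default_factory=SimOmicsConfig)
    nzv: NZVParams = field(default_factory=NZVParams)
    boruta: BorutaConfig = field(default_factory=BorutaConfig)
    fva_fraction: float = 0.99
    activity_tol: float = 1e-6
    coupling: float = 400.0
    n_runs: int = 50
    robust_min: int = 10
    n_taxa: int = 6
    n_cpg_genes: int = 30

    def __post_init__(self) -> None:
        # one master seed fans out to every stage deterministically
        self.cohort = replace(self.cohort, seed=self.seed)
        self.omics = replace(self.omics, seed=self.seed + 1)
        self.boruta = replace(self.boruta, seed=self.seed + 2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub_cls in (
            ("cohort", SimCohortConfig),
            ("omics", SimOmicsConfig),
            ("nzv", NZVParams),
            ("boruta", BorutaConfig),
        ):
            if key in raw:
                sub = raw.pop(key)
                if "age_groups" in sub:
                    sub["age_groups"] = tuple(tuple(g) for g in sub["age_groups"])
                kwargs[key] = sub_cls(**sub)
        kwargs.update(raw)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on synthetic data; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        logger.info("[%s] %s", stage, info)

    def write(name: str, writer, obj) -> Path:
        path = out / name
        writer(obj, path)
        manifest["files"][name] = _sha256(path)
        return path

    # -- simulate + behavior ------------------------------------------------
    try:
        trials, truth = simulate.simulate_barnes_maze(cfg.cohort)
        write("trials.csv", simulate.write_trials_csv, trials)
        truth.to_csv(out / "latent_truth.csv", index=False)
        manifest["files"]["latent_truth.csv"] = _sha256(out / "latent_truth.csv")
        record("simulate", n_mice=cfg.cohort.n_mice, n_trials=len(trials))
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        rank_result = behavior.cognitive_rank_pipeline(trials, cfg.cohort.censor_limit)
        ranks = rank_result.ranks.copy()
        ranks["composite"] = rank_result.composite
        write("cognitive_rank.tsv", lambda df, p: df.to_csv(p, sep="\t"), ranks)
        record("score-behavior", n_mice=rank_result.n_cohort)
    except Exception as err:
        raise RuntimeError(f"stage 'score-behavior' failed: {err}") from err

    samples = list(rank_result.composite.index)

    # -- FVA reaction abundances -------------------------------------------
    try:
        models, truth_fva = simulate.simulate_metabolic_models(
            cfg.n_taxa, cfg.seed + 10, cfg.fva_fraction
        )
        abundance = simulate.simulate_taxon_abundance(
            [m.model_id for m in models], samples, cfg.seed + 11
        )
        write("taxon_abundance.tsv", simulate.write_abundance_tsv, abundance)
        incidences = {}
        for model in models:
            res = fva.fva_at_fraction(model, cfg.fva_fraction)
            incidences[model.model_id] = fva.reaction_incidence(res, cfg.activity_tol)
        matrix = fva.build_reaction_abundance_matrix(incidences, abundance)
        write("reaction_abundance.tsv", simulate.write_layer_tsv, matrix)
        record(
            "fva-abundance",
            n_models=len(models),
            n_reactions=matrix.shape[0],
            n_samples=matrix.shape[1],
        )
    except Exception as err:
        raise RuntimeError(f"stage 'fva-abundance' failed: {err}") from err

    # -- community simulations ---------------------------------------------
    try:
        solutions = {}
        for s in samples:
            cm = community.build_community_model(
                models, abundance[s].to_dict(), cfg.coupling
            )
            solutions[s] = community.solve_community_fba(cm)
        net = community.net_exchange_fluxes(solutions)
        filtered = community.filter_exchange_variance(net, cfg.nzv)
        write("exchange_internal.tsv", simulate.write_layer_tsv, filtered.internal_transfer)
        write("exchange_lumen.tsv", simulate.write_layer_tsv, filtered.lumen_net)
        record(
            "community",
            n_solved=len(samples) - len(net.infeasible_samples),
            n_infeasible=len(net.infeasible_samples),
            n_internal=filtered.internal_transfer.shape[0],
            n_lumen=filtered.lumen_net.shape[0],
        )
    except Exception as err:
        raise RuntimeError(f"stage 'community' failed: {err}") from err

    # -- preprocess ---------------------------------------------------------
    try:
        layers, registry = simulate.simulate_omics_layers(
            cfg.omics, rank_result.composite
        )
        registry.to_csv(out / "planted_registry.tsv", sep="\t", index=False)
        manifest["files"]["planted_registry.tsv"] = _sha256(out / "planted_registry.tsv")

        cpg, tss = simulate.simulate_cpg_table(
            cfg.n_cpg_genes, cfg.seed + 12, n_samples=len(samples)
        )
        cpg.columns = list(cpg.columns[:3]) + samples
        promoter = preprocess.aggregate_promoter_methylation(cpg, tss)
        if not promoter.empty:
            layers["promoter_meth"] = promoter
        layers["mag_abundance"] = abundance
        layers["reaction_abundance"] = matrix
        if not filtered.internal_transfer.empty:
            layers["community_exchange"] = filtered.internal_transfer

        filtered_layers = {}
        removal = {}
        for name, layer in layers.items():
            kept, report = preprocess.near_zero_var_filter(layer, cfg.nzv)
            filtered_layers[name] = kept
            removal[name] = int(report["removed"].sum())
        aligned, aligned_rank = preprocess.intersect_complete_samples(
            filtered_layers, rank_result.composite
        )
        for name, layer in aligned.items():
            write(f"layer_{name}.tsv", simulate.write_layer_tsv, layer)
        record(
            "preprocess",
            n_layers=len(aligned),
            n_samples=len(aligned_rank),
            removed_features=removal,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'preprocess' failed: {err}") from err

    # -- selection ----------------------------------------------------------
    try:
        stage1 = {}
        for name, layer in aligned.items():
            if layer.empty:
                continue
            stage1[name] = stability_select(
                layer,
                aligned_rank,
                cfg.boruta,
                n_runs=cfg.n_runs,
                robust_min=cfg.robust_min,
                layer_id=name,
            )
        stage1_frame = pd.concat(
            [res.to_frame() for res in stage1.values()], axis=0
        )
        write(
            "selection_single_layer.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index_label="feature_id"),
            stage1_frame,
        )
        integrated = integrate_layers(
            stage1, aligned, aligned_rank, cfg.boruta,
            n_runs=cfg.n_runs, robust_min=cfg.robust_min,
        )
        write(
            "selection_integrated.tsv",
            lambda df, p: df.to_csv(p, sep="\t", index_label="feature_id"),
            integrated.to_frame(),
        )
        record(
            "select",
            single_layer_robust=int(sum(res.robust.sum() for res in stage1.values())),
            candidates=int(sum(res.candidate.sum() for res in stage1.values())),
            integrated_robust=int(integrated.robust.sum()),
        )
    except Exception as err:
        raise RuntimeError(f"stage 'select' failed: {err}") from err

    # -- enrichment ---------------------------------------------------------
    try:
        universe_layer = next(
            (n for n in aligned if n.endswith("expr")), list(aligned)[0]
        )
        universe = list(aligned[universe_layer].index)
        gene_sets = simulate.simulate_gene_sets(universe, cfg.seed + 13)
        simulate.write_gmt(gene_sets, out / "gene_sets.gmt")
        manifest["files"]["gene_sets.gmt"] = _sha256(out / "gene_sets.gmt")
        res = stage1[universe_layer]
        selected = res.robust.index[res.robust].tolist()
        enrichment = annotate.overrepresentation_test(selected, gene_sets, universe)
        write(
            "enrichment.tsv",
            lambda df, p: df.to_csv(p, sep="\t"),
            enrichment,
        )
        record(
            "enrich",
            universe_layer=universe_layer,
            n_selected=len(selected),
            n_sets_tested=len(enrichment),
            n_reported=int(enrichment["reported"].sum()) if len(enrichment) else 0,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'enrich' failed: {err}") from err

    manifest["config"] = json.loads(json.dumps(asdict(cfg), default=str))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
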