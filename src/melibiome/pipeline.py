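"""End-to-end orchestration of the gut-microbiome analysis graph.

``run_pipeline`` reproduces the study's full statistical workflow on real
or simulated inputs:

stage 1 (all samples)
    host-DNA filter (chloroplast / mitochondria / unassigned) -> rarefy to
    1311 sequences -> chord-PCA, Bray-Curtis PCoA, Hill ^2D -> Bayesian
    unequal-variance group model per metric across sample types (leaf
    epiphytes and endophytes pooled as "plant") -> random-forest
    sample-type classification;

stage 2 (frass and whole-caterpillar samples)
    drop plant samples, Wolbachia and rare OTUs (<1% everywhere), re-rarefy
    the unrarefied table to 500 -> UPGMA dendrogram, ordination and
    diversity -> Bayesian linear models for PC/PCO/^2D on type, plant,
    population and age -> multinomial-Dirichlet differential abundance on
    the frass 15-20 day subset with the posterior-predictive RMSE model
    comparison -> random-forest tasks (type, plant, population, age);

performance
    Bernoulli-logit survival model on the caterpillar-level rearing data
    and a DIC-ranked ladder of weight models with microbiome covariates
    and microbiome x plant interactions.

Every stochastic step is seeded deterministically from the global seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import dirichlet_da, ordination
from .bayes import (
    GroupModelFit,
    McmcSettings,
    PosteriorSummary,
    PriorSpec,
    RegressionFit,
    fit_group_model,
    fit_linear_model,
    fit_logistic_model,
)
from .otu_table import (
    CHLOROPLAST_RULES,
    MITOCHONDRIA_RULES,
    UNASSIGNED,
    WOLBACHIA_RULES,
    OtuTable,
    SampleMetadata,
    SampleType,
    rarefy,
    relative_abundance,
    filter_rare_otus,
    filter_taxa,
)
from .synthetic import SimulatedStudy, SimulationConfig, simulate_study

__all__ = [
    "PipelineConfig",
    "ClassificationResult",
    "WeightModelLadder",
    "PipelineReport",
    "run_pipeline",
    "rf_classify",
    "weight_model_ladder",
]


@dataclass
class PipelineConfig:
    """Knobs for the full analysis graph; defaults are the study settings."""

    simulation: SimulationConfig | None = None
    otu_table: OtuTable | None = None
    metadata: list[SampleMetadata] | None = None
    caterpillars: pd.DataFrame | None = None  # cat_id, population, plant, survived_15d
    depth_stage1: int = 1311
    depth_stage2: int = 500
    rare_otu_threshold: float = 0.01
    n_axes: int = 2
    diversity_q: float = 2.0
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    prior: PriorSpec = field(default_factory=PriorSpec)
    da_ages: tuple[int, ...] = (15, 20)
    da_min_group_n: int = 2
    da_n_draws: int = 10_000
    rf_n_trees: int = 50_000
    weight_ages: tuple[int, ...] = (15, 20)
    seed: int = 0
    outdir: str | Path | None = None


@dataclass
class ClassificationResult:
    task: str
    classes: list[str]
    confusion: np.ndarray  # rows true, cols predicted (out-of-bag)
    oob_accuracy: float
    importance: pd.DataFrame  # otu_id, gini ranking


@dataclass
class WeightModelLadder:
    models: list[tuple[str, RegressionFit]]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(name, fit.dic, fit.pd_eff) for name, fit in self.models],
            columns=["model", "dic", "pd"],
        ).sort_values("dic", ignore_index=True)

    @property
    def best(self) -> str:
        return min(self.models, key=lambda nf: nf[1].dic)[0]


@dataclass
class PipelineReport:
    config: PipelineConfig
    truth: dict | None
    sample_accounting: dict
    stage1: dict
    stage2: dict
    performance: dict
    manifest: dict

    def to_json(self) -> str:
        return json.dumps(self.manifest, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, PosteriorSummary):
        return {"pm": obj.pm, "etpi_95": list(obj.etpi_95),
                "pp_gt0": obj.pp_gt0, "pp_lt0": obj.pp_lt0}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _summ_dict(s: PosteriorSummary) -> dict:
    return _jsonify(s)


def rf_classify(
    features: np.ndarray,
    labels: Sequence[str],
    n_trees: int = 50_000,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    task: str = "classification",
) -> ClassificationResult:
    """Random-forest classification with out-of-bag evaluation.

    GINI split criterion, sqrt(K) candidate features per split, and
    mean-decrease-in-GINI importances (normalized to sum to 1).  The
    confusion matrix and accuracy are computed from out-of-bag votes, so no
    separate test split is needed even when OTUs outnumber samples.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("classification needs >= 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs >= 2 members")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        oob_score=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(x, y)
    votes = rf.oob_decision_function_
    have_votes = ~np.isnan(votes).any(axis=1) & (votes.sum(axis=1) > 0)
    pred = np.array(classes)[np.argmax(np.nan_to_num(votes), axis=1)]
    cls_index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y[have_votes], pred[have_votes]):
        confusion[cls_index[t], cls_index[p]] += 1
    oob_acc = float(np.mean(pred[have_votes] == y[have_votes]))
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(x.shape[1])]
    importance = (
        pd.DataFrame({"otu_id": list(feature_names), "gini": rf.feature_importances_})
        .sort_values("gini", ascending=False, ignore_index=True)
    )
    return ClassificationResult(
        task=task,
        classes=list(classes),
        confusion=confusion,
        oob_accuracy=oob_acc,
        importance=importance,
    )


def weight_model_ladder(
    weights: np.ndarray,
    base_design: pd.DataFrame,
    microbiome: pd.DataFrame,
    prior: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    plant_column: str = "plant_Me",
) -> WeightModelLadder:
    """DIC-ranked ladder of weight models.

    The base model regresses weight on plant, population and age; each
    microbiome column (PC1/PC2/PCO1/PCO2/^2D) is added alone and with a
    microbiome x plant interaction.  The base model is always present.
    """
    models: list[tuple[str, RegressionFit]] = []
    seeds = np.random.SeedSequence(settings.seed).generate_state(
        2 * len(microbiome.columns) + 1
    ) % (2**31)

    def fit(name: str, design: pd.DataFrame, seed: int) -> None:
        s = dataclasses.replace(settings, seed=int(seed))
        models.append((name, fit_linear_model(weights, design, prior, s)))

    fit("base", base_design, seeds[0])
    for k, col in enumerate(microbiome.columns):
        d1 = base_design.copy()
        d1[col] = microbiome[col].to_numpy()
        fit(f"base+{col}", d1, seeds[2 * k + 1])
        d2 = d1.copy()
        d2[f"{col}:plant"] = microbiome[col].to_numpy() * base_design[plant_column].to_numpy()
        fit(f"base+{col}+{col}:plant", d2, seeds[2 * k + 2])
    return WeightModelLadder(models=models)


# ---------------------------------------------------------------------------
# helpers

def _derive_seeds(seed: int, labels: Sequence[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(labels)) % (2**31)
    return {lab: int(s) for lab, s in zip(labels, state)}


def _metric_frame(table: OtuTable, n_axes: int, q: float) -> tuple[pd.DataFrame, dict]:
    """Chord-PCA, Bray-Curtis PCoA and Hill diversity for a rarefied table."""
    rel = relative_abundance(table)
    chord = ordination.chord_transform(rel)
    pca_res = ordination.pca(chord, n_axes, sample_ids=table.sample_ids)
    bc = ordination.bray_curtis(rel, labels=table.sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcoa_res = ordination.pcoa(bc, n_axes)
    div = ordination.hill_diversity(rel, q, sample_ids=table.sample_ids)
    data = {"sample_id": table.sample_ids}
    for k in range(pca_res.scores.shape[1]):
        data[f"PC{k + 1}"] = pca_res.scores[:, k]
    for k in range(pcoa_res.scores.shape[1]):
        data[f"PCO{k + 1}"] = pcoa_res.scores[:, k]
    data["D2"] = div.values
    extras = {
        "pca_explained": pca_res.explained,
        "pca_loadings": pca_res.loadings,
        "pcoa_explained": pcoa_res.explained,
        "pcoa_eigenvalues": pcoa_res.eigenvalues,
        "bray_curtis": bc,
        "pca_otu_ids": table.otu_ids,
    }
    return pd.DataFrame(data).set_index("sample_id"), extras


def _type_group(meta: SampleMetadata) -> str:
    return "plant" if meta.sample_type.is_plant else meta.sample_type.value


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis graph; see the module docstring for stages."""
    seeds = _derive_seeds(
        config.seed,
        ["rarefy1", "rarefy2", "rf1", "rf2_type", "rf2_plant", "rf2_pop", "rf2_age",
         "da", "rmse", "mcmc_base", "survival", "ladder"],
    )
    truth = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        study = simulate_study(sim_cfg)
        table, metadata, truth = study.otu_table, study.metadata, study.truth
        caterpillars = pd.DataFrame(truth["caterpillars"])
    else:
        if config.otu_table is None or config.metadata is None:
            raise ValueError("provide either a simulation config or table + metadata")
        table, metadata = config.otu_table, config.metadata
        caterpillars = config.caterpillars
    meta_by_id = {m.sample_id: m for m in metadata}
    accounting: dict = {"input_samples": table.n_samples, "input_otus": table.n_otus}

    mcmc = config.mcmc
    mcmc_seeds = np.random.SeedSequence(seeds["mcmc_base"]).generate_state(64) % (2**31)
    seed_iter = iter(int(s) for s in mcmc_seeds)

    def settings() -> McmcSettings:
        return dataclasses.replace(mcmc, seed=next(seed_iter))

    # ---------------- stage 1 -----------------
    stage1_filtered = filter_taxa(
        table, [*CHLOROPLAST_RULES, *MITOCHONDRIA_RULES, UNASSIGNED]
    )
    accounting["stage1_otus_after_filter"] = stage1_filtered.n_otus
    r1 = rarefy(stage1_filtered, config.depth_stage1, seeds["rarefy1"])
    t1 = r1.table
    accounting["stage1_samples_retained"] = t1.n_samples
    accounting["stage1_samples_dropped"] = len(r1.dropped_sample_ids)

    metrics1, extras1 = _metric_frame(t1, config.n_axes, config.diversity_q)
    type_groups = [_type_group(meta_by_id[s]) for s in t1.sample_ids]
    group_models: dict[str, GroupModelFit] = {}
    for metric in metrics1.columns:
        group_models[metric] = fit_group_model(
            metrics1[metric].to_numpy(), type_groups, config.prior, settings()
        )
    rel1 = relative_abundance(t1)
    rf1 = rf_classify(
        rel1, type_groups, config.rf_n_trees, seeds["rf1"],
        feature_names=t1.otu_ids, task="sample_type_all",
    )
    stage1 = {
        "metrics": metrics1,
        "pca_explained": extras1["pca_explained"],
        "pcoa_explained": extras1["pcoa_explained"],
        "group_models": group_models,
        "rf_sample_type": rf1,
    }

    # ---------------- stage 2 -----------------
    keep_ids = [
        s for s in table.sample_ids if not meta_by_id[s].sample_type.is_plant
    ]
    t2_unrarefied = table.select_samples(keep_ids)
    t2_unrarefied = filter_taxa(
        t2_unrarefied,
        [*CHLOROPLAST_RULES, *MITOCHONDRIA_RULES, *WOLBACHIA_RULES, UNASSIGNED],
    )
    t2_unrarefied = filter_rare_otus(t2_unrarefied, config.rare_otu_threshold)
    accounting["stage2_otus_after_filter"] = t2_unrarefied.n_otus
    r2 = rarefy(t2_unrarefied, config.depth_stage2, seeds["rarefy2"])
    t2 = r2.table
    accounting["stage2_samples_retained"] = t2.n_samples
    accounting["stage2_samples_dropped"] = len(r2.dropped_sample_ids)

    metrics2, extras2 = _metric_frame(t2, config.n_axes, config.diversity_q)
    dendro = ordination.upgma(extras2["bray_curtis"])

    design2 = pd.DataFrame(
        {
            "intercept": 1.0,
            "type_larva": [
                float(meta_by_id[s].sample_type == SampleType.LARVA)
                for s in t2.sample_ids
            ],
            "plant_Me": [float(meta_by_id[s].plant.value == "Me") for s in t2.sample_ids],
            "pop_BST": [
                float(meta_by_id[s].population.value == "BST") for s in t2.sample_ids
            ],
            "age": [float(meta_by_id[s].age_days) for s in t2.sample_ids],
        },
        index=t2.sample_ids,
    )
    linear_models: dict[str, RegressionFit] = {}
    for metric in metrics2.columns:
        linear_models[metric] = fit_linear_model(
            metrics2[metric].to_numpy(), design2, config.prior, settings()
        )

    # differential abundance on the homogeneous frass subset
    da_ids = [
        s for s in t2.sample_ids
        if meta_by_id[s].sample_type == SampleType.FRASS
        and meta_by_id[s].age_days in config.da_ages
    ]
    da_labels = {
        s: f"{meta_by_id[s].plant.value[0]}-{meta_by_id[s].population.value}"
        for s in da_ids
    }
    label_counts = pd.Series(list(da_labels.values())).value_counts()
    da_keep = [s for s in da_ids if label_counts[da_labels[s]] >= config.da_min_group_n]
    dropped_groups = [g for g, n in label_counts.items() if n < config.da_min_group_n]
    da_section: dict = {"dropped_groups": dropped_groups, "n_samples": len(da_keep)}
    if len({da_labels[s] for s in da_keep}) >= 2:
        da_table = t2.select_samples(da_keep)
        da_fit = dirichlet_da.fit_dm(
            da_table, [da_labels[s] for s in da_keep],
            n_draws=config.da_n_draws, seed=seeds["da"],
        )
        da_probs = dirichlet_da.otu_difference_probs(da_fit)
        da_rmse = dirichlet_da.pp_rmse_compare(
            da_table, [da_labels[s] for s in da_keep],
            n_draws=config.da_n_draws, seed=seeds["rmse"],
        )
        da_section.update(
            fit=da_fit,
            difference_probs=da_probs,
            flagged_otus=sorted(da_probs.loc[da_probs["flagged"], "otu_id"].unique()),
            pp_rmse=da_rmse,
        )
    else:
        da_section["note"] = "fewer than two groups meet the minimum sample size"

    rel2 = relative_abundance(t2)
    rf2: dict[str, ClassificationResult | dict] = {}
    rf_tasks = {
        "type": [meta_by_id[s].sample_type.value for s in t2.sample_ids],
        "plant": [meta_by_id[s].plant.value for s in t2.sample_ids],
        "population": [meta_by_id[s].population.value for s in t2.sample_ids],
        "age": [str(meta_by_id[s].age_days) for s in t2.sample_ids],
    }
    for task, labels in rf_tasks.items():
        try:
            rf2[task] = rf_classify(
                rel2, labels, config.rf_n_trees, seeds[f"rf2_{task if task != 'population' else 'pop'}"],
                feature_names=t2.otu_ids, task=task,
            )
        except ValueError as exc:
            rf2[task] = {"error": str(exc)}

    stage2 = {
        "metrics": metrics2,
        "pca_explained": extras2["pca_explained"],
        "pcoa_explained": extras2["pcoa_explained"],
        "upgma_newick": dendro.newick,
        "upgma": dendro,
        "linear_models": linear_models,
        "da": da_section,
        "rf": rf2,
    }

    # ---------------- performance -----------------
    performance: dict = {}
    if caterpillars is not None and len(caterpillars) > 0:
        surv_design = pd.DataFrame(
            {
                "intercept": 1.0,
                "pop_BST": (caterpillars["population"] == "BST").astype(float),
                "plant_Lu": (caterpillars["plant"] == "Lu").astype(float),
            }
        )
        y_surv = caterpillars["survived_15d"].astype(float).to_numpy()
        cells = {
            "HWR-Me": np.array([1.0, 0.0, 0.0]),
            "HWR-Lu": np.array([1.0, 0.0, 1.0]),
            "BST-Me": np.array([1.0, 1.0, 0.0]),
            "BST-Lu": np.array([1.0, 1.0, 1.0]),
        }
        performance["survival"] = fit_logistic_model(
            y_surv, surv_design, config.prior,
            dataclasses.replace(mcmc, seed=seeds["survival"]), cells=cells,
        )
        performance["survival_fraction"] = float(np.mean(y_surv))
    weight_ids = [
        s for s in t2.sample_ids
        if meta_by_id[s].sample_type == SampleType.FRASS
        and meta_by_id[s].age_days in config.weight_ages
        and meta_by_id[s].weight_mg is not None
    ]
    if len(weight_ids) >= 8:
        base = pd.DataFrame(
            {
                "intercept": 1.0,
                "plant_Me": [float(meta_by_id[s].plant.value == "Me") for s in weight_ids],
                "pop_BST": [float(meta_by_id[s].population.value == "BST") for s in weight_ids],
                "age": [float(meta_by_id[s].age_days) for s in weight_ids],
            },
            index=weight_ids,
        )
        micro = metrics2.loc[weight_ids, ["PC1", "PC2", "PCO1", "PCO2", "D2"]]
        wvec = np.array([meta_by_id[s].weight_mg for s in weight_ids])
        ladder = weight_model_ladder(
            wvec, base, micro, config.prior,
            dataclasses.replace(mcmc, seed=seeds["ladder"]),
        )
        performance["weight_ladder"] = ladder
        performance["weight_n"] = len(weight_ids)

    manifest = _build_manifest(accounting, stage1, stage2, performance, truth)
    report = PipelineReport(
        config=config,
        truth=truth,
        sample_accounting=accounting,
        stage1=stage1,
        stage2=stage2,
        performance=performance,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_outputs(report, Path(config.outdir))
    return report


def _build_manifest(accounting, stage1, stage2, performance, truth) -> dict:
    man: dict = {"sample_accounting": accounting}
    man["stage1"] = {
        "pca_explained": stage1["pca_explained"],
        "pcoa_explained": stage1["pcoa_explained"],
        "group_models": {
            metric: {
                "mu": {g: fit.mu[g] for g in fit.groups},
                "sigma": {g: fit.sigma[g] for g in fit.groups},
            }
            for metric, fit in stage1["group_models"].items()
        },
        "rf_sample_type": {
            "oob_accuracy": stage1["rf_sample_type"].oob_accuracy,
            "classes": stage1["rf_sample_type"].classes,
            "confusion": stage1["rf_sample_type"].confusion,
            "top_otus": stage1["rf_sample_type"].importance.head(5).to_dict("records"),
        },
    }
    man["stage2"] = {
        "pca_explained": stage2["pca_explained"],
        "linear_models": {
            metric: {
                "coefficients": fit.coefficients,
                "sigma": fit.sigma,
                "dic": fit.dic,
            }
            for metric, fit in stage2["linear_models"].items()
        },
        "upgma_newick": stage2["upgma_newick"],
        "rf": {
            task: (
                {"oob_accuracy": res.oob_accuracy, "classes": res.classes,
                 "confusion": res.confusion}
                if not isinstance(res, dict) else res
            )
            for task, res in stage2["rf"].items()
        },
    }
    da = stage2["da"]
    man["stage2"]["da"] = {
        "n_samples": da.get("n_samples"),
        "dropped_groups": da.get("dropped_groups"),
        "flagged_otus": da.get("flagged_otus", []),
    }
    if "pp_rmse" in da:
        man["stage2"]["da"]["pp_rmse_full_better"] = da["pp_rmse"].pp_full_better
        man["stage2"]["da"]["rmse_full_mean"] = float(np.mean(da["pp_rmse"].rmse_draws_full))
        man["stage2"]["da"]["rmse_null_mean"] = float(np.mean(da["pp_rmse"].rmse_draws_null))
    man["performance"] = {}
    if "survival" in performance:
        surv: RegressionFit = performance["survival"]
        man["performance"]["survival"] = {
            "coefficients": surv.coefficients,
            "fitted_probabilities": surv.fitted_probabilities,
            "observed_fraction": performance["survival_fraction"],
        }
    if "weight_ladder" in performance:
        ladder: WeightModelLadder = performance["weight_ladder"]
        man["performance"]["weight"] = {
            "n": performance["weight_n"],
            "dic_table": ladder.table.to_dict("records"),
            "best_model": ladder.best,
            "base_coefficients": dict(ladder.models[0][1].coefficients),
        }
    if truth is not None:
        man["truth_summary"] = {
            "n_caterpillars": truth["n_caterpillars"],
            "n_survived_15d": truth["n_survived_15d"],
            "weight_model": truth["weight_model"],
            "survival_model": truth["survival_model"],
            "age_diversity_slope": truth["age_diversity_slope"],
        }
    return man


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    report.stage1["metrics"].to_csv(outdir / "stage1_metrics.tsv", sep="\t")
    report.stage2["metrics"].to_csv(outdir / "stage2_metrics.tsv", sep="\t")
    (outdir / "upgma.nwk").write_text(report.stage2["upgma_newick"] + "\n")
    da = report.stage2["da"]
    if "fit" in da:
        da["fit"].summary.to_csv(outdir / "da_summary.tsv", sep="\t", index=False)
        da["difference_probs"].to_csv(outdir / "da_difference_probs.tsv", sep="\t", index=False)
    rf1 = report.stage1["rf_sample_type"]
    rf1.importance.to_csv(outdir / "rf_sample_type_importance.tsv", sep="\t", index=False)
    if report.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(report.truth, indent=2, default=_jsonify))
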