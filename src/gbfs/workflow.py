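"""End-to-end GBFS and GBFS-Mol2Vec pipeline orchestration.

One :class:`WorkflowConfig` drives every stage: dataset I/O and split,
descriptor generation and cleaning, dual relevance ranking, brute-force
engineering, two-step multicollinearity reduction, permutation/RFE
refinement, optional Mol2Vec concatenation, hyperparameter optimization,
and the single final test-set evaluation. Paper-stated defaults are kept
where they exist: correlation threshold 0.8, Ward linkage cut 0.5,
10-repeat permutation analysis, 10-fold RFE on negative RMSE.

A single master seed deterministically derives per-stage seeds, so two
runs from the same config are identical end to end; the run manifest
(config hash, per-stage feature counts, selection-artifact hash, test
access count) suffices to check that.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .data import (
    CLASSIFICATION,
    REGRESSION,
    MoleculeTable,
    SplitIndex,
    random_split,
    read_molecule_table,
    scaffold_split,
)
from .engineer import (
    FULL_OP_SET,
    brute_force_engineer,
    correlation_filter,
    spearman_ward_cluster,
)
from .featurize import DEFAULT_BLOCKS, FeatureCleaner, featurize_table
from .mol2vec import Mol2VecVectorizer
from .optimize import (
    DEFAULT_SPACE,
    FittedModel,
    HyperparameterSpace,
    Param,
    attach_embeddings,
    bayesian_optimize,
    coarse_grid_search,
    train_final_model,
)
from .refine import permutation_importance, recursive_feature_elimination
from .relevance import compute_feature_scores, select_relevant

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class WorkflowConfig:
    """All thresholds, fold counts, seeds and stage toggles in one place."""

    # dataset
    dataset_path: str | None = None
    smiles_column: str = "smiles"
    target_column: str = "y"
    task_type: str = REGRESSION
    # split
    split_kind: str = "random"  # random | scaffold
    test_fraction: float = 0.2
    validation_fraction: float = 0.1
    # featurization
    blocks: tuple = DEFAULT_BLOCKS
    max_missing_fraction: float = 0.2
    # relevance policy
    n_gain: int = 150
    n_stat: int = 50
    min_normalized: float = 0.9
    mi_k: int = 3
    # engineering
    op_set: tuple = FULL_OP_SET
    engineer_top_k: int = 4
    ratio_epsilon: float = 1e-9
    # multicollinearity reduction
    correlation_threshold: float = 0.8
    correlation_mode: str = "ranked"
    linkage_threshold: float = 0.5
    # refinement
    permutation_repeats: int = 10
    rfe_folds: int = 10
    rfe_metric: str = "neg_rmse"
    rfe_step: int | None = None  # auto: 1 below 200 features, 5 above
    rfe_min_size: int = 1
    rfe_within_se: float = 1.0
    # optimization: "two_step" | "bayes" | "none"
    optimization: str = "two_step"
    grid: dict | None = None
    search_space: object | None = None  # HyperparameterSpace; None -> default
    n_calls: int = 25
    opt_cv_folds: int = 5
    # mol2vec
    mol2vec: bool = False
    mol2vec_dimension: int = 300
    mol2vec_window: int = 10
    mol2vec_min_count: int = 3
    mol2vec_epochs: int = 5
    mol2vec_max_radius: int = 1
    # selection-stage GBDT parameters
    gbdt_params: dict | None = None
    master_seed: int = 0

    def __post_init__(self):
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if self.linkage_threshold <= 0:
            raise ValueError("linkage_threshold must be positive")
        if self.rfe_folds < 2 or self.permutation_repeats < 1:
            raise ValueError("invalid fold/repeat counts")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["blocks"] = [
            {"block_name": b.block_name, "params": b.params} for b in self.blocks
        ]
        d["op_set"] = list(self.op_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        from .featurize import DescriptorBlockSpec

        d = dict(d)
        if "blocks" in d and d["blocks"] is not None:
            d["blocks"] = tuple(
                DescriptorBlockSpec(b["block_name"], b.get("params", {}))
                for b in d["blocks"]
            )
        if "op_set" in d:
            d["op_set"] = tuple(d["op_set"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """Everything a run produced, plus the provenance manifest."""

    config: WorkflowConfig
    split: SplitIndex
    feature_scores: pd.DataFrame
    selected_relevant: list[str]
    engineered_names: list[str]
    correlation_retained: list[str]
    cluster_retained: list[str]
    permutation_report: pd.DataFrame
    rfe_report: object
    final_features: list[str]
    optimization_trace: object | None
    model: FittedModel
    validation_metrics: dict
    test_metrics: dict
    manifest: dict
    mol2vec_model: object | None = None
    cleaner: object | None = None
    engineer_parents: list[str] = field(default_factory=list)


def _selection_hash(
    selected, engineered, corr_retained, cluster_retained, rfe_selected
) -> str:
    payload = json.dumps(
        {
            "selected": selected,
            "engineered": engineered,
            "correlation_retained": corr_retained,
            "cluster_retained": cluster_retained,
            "rfe_selected": rfe_selected,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _evaluate(model: FittedModel, X, y, task_type: str) -> dict:
    if task_type == CLASSIFICATION:
        proba = model.predict_proba(X)[:, 1]
        labels = (proba >= 0.5).astype(int)
        counts = M.ConfusionCounts.from_labels(y, labels)
        out = M.classification_metrics(counts)
        out["auc_roc"] = M.auc_roc(y, proba)
        out["n"] = len(y)
        return out
    return M.regression_report(y, model.predict(X))


def run_workflow(
    config: WorkflowConfig,
    table: MoleculeTable | None = None,
    X_base: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> RunResult:
    """Execute the full pipeline (GBFS, or GBFS-Mol2Vec if enabled).

    ``table`` (or ``config.dataset_path``) supplies the molecules;
    ``X_base`` optionally injects a precomputed base feature matrix to
    skip descriptor generation (it must align with the table rows).
    """
    cfg = config
    if table is None:
        if cfg.dataset_path is None:
            raise ValueError("either a table or config.dataset_path is required")
        table = read_molecule_table(
            cfg.dataset_path,
            smiles_column=cfg.smiles_column,
            target_columns=[cfg.target_column],
            task_type=cfg.task_type,
        )
    y_all = table.targets[cfg.target_column].to_numpy(dtype=float)

    # --- split -----------------------------------------------------------
    if cfg.split_kind == "scaffold":
        frac = (
            1.0 - cfg.test_fraction - cfg.validation_fraction,
            cfg.validation_fraction,
            cfg.test_fraction,
        )
        split = scaffold_split(table, frac)
    else:
        split = random_split(
            len(table),
            cfg.test_fraction,
            cfg.validation_fraction,
            seed=stage_seed(cfg.master_seed, "split"),
        )
    tr, va = split.train, split.validation

    # --- featurize + clean ----------------------------------------------
    if X_base is None:
        X_base = featurize_table(table, cfg.blocks)
    cleaner = FeatureCleaner(cfg.max_missing_fraction)
    cleaner.fit(X_base.iloc[tr])
    X = cleaner.transform(X_base)
    counts = {"base": X_base.shape[1], "cleaned": X.shape[1]}

    # --- relevance -------------------------------------------------------
    scores = compute_feature_scores(
        X.iloc[tr],
        y_all[tr],
        task_type=cfg.task_type,
        gbdt_params=cfg.gbdt_params,
        mi_k=cfg.mi_k,
        seed=stage_seed(cfg.master_seed, "relevance"),
    )
    selected = select_relevant(scores, cfg.n_gain, cfg.n_stat, cfg.min_normalized)
    counts["relevance_selected"] = len(selected)

    sel_scores = scores[scores["feature"].isin(set(selected))]
    gain_order = list(sel_scores.sort_values("gain_rank")["feature"])
    # F-statistic order settles pairwise collinearity: an imperfect copy
    # of a feature always has strictly lower univariate association with
    # the target than the feature itself, so the correlation filter
    # keeps original coordinates and discards their fingerprint twins.
    # Ensemble gain (multivariate) settles everything else: engineering
    # parents, cluster representatives and RFE elimination.
    f_order = list(sel_scores.sort_values("f_stat", ascending=False)["feature"])

    # --- engineering -----------------------------------------------------
    engineered = brute_force_engineer(
        X[selected],
        cfg.op_set,
        min(cfg.engineer_top_k, len(gain_order)),
        cfg.ratio_epsilon,
        parent_order=gain_order,
    )
    X_eng = pd.concat([X[selected], engineered], axis=1)
    counts["after_engineering"] = X_eng.shape[1]

    # --- multicollinearity reduction ------------------------------------
    # Engineered columns rank after all base features, so a derived
    # column collinear with its parent never displaces the parent;
    # engineered features survive only where they add signal beyond
    # their parents.
    seed_mc = stage_seed(cfg.master_seed, "decorrelate")
    corr_priority = f_order + list(engineered.columns)
    corr_retained = correlation_filter(
        X_eng.iloc[tr],
        cfg.correlation_threshold,
        corr_priority,
        cfg.correlation_mode,
        seed=seed_mc,
    )
    # An engineered column is a deterministic function of its two
    # parents; when both parents survive the filter it carries no
    # information a tree ensemble cannot build itself, so it is
    # redundant (pairwise correlation cannot see this two-variable
    # dependence). It is kept only when it preserves signal from an
    # eliminated parent.
    parent_map = engineered.attrs.get("parents", {})
    retained_set = set(corr_retained)
    corr_retained = [
        c
        for c in corr_retained
        if c not in parent_map
        or not (parent_map[c][0] in retained_set and parent_map[c][1] in retained_set)
    ]
    counts["after_correlation_filter"] = len(corr_retained)
    cluster_priority = gain_order + list(engineered.columns)
    if len(corr_retained) >= 2:
        assignment = spearman_ward_cluster(
            X_eng.iloc[tr][corr_retained],
            cfg.linkage_threshold,
            priority=[p for p in cluster_priority if p in set(corr_retained)],
        )
        cluster_retained = [c for c in corr_retained if c in set(assignment.retained)]
    else:
        assignment = None
        cluster_retained = list(corr_retained)
    counts["after_clustering"] = len(cluster_retained)
    X_red = X_eng[cluster_retained]

    # --- refinement ------------------------------------------------------
    seed_refine = stage_seed(cfg.master_seed, "refine")
    probe_model = train_final_model(
        X_red.iloc[tr], y_all[tr], cfg.task_type, cfg.gbdt_params, seed_refine
    )
    perm_idx = va if len(va) else tr
    perm_report = permutation_importance(
        probe_model._model,
        X_red.iloc[perm_idx],
        y_all[perm_idx],
        metric="auc" if cfg.task_type == CLASSIFICATION else "neg_rmse",
        n_repeats=cfg.permutation_repeats,
        seed=seed_refine,
    )
    step = cfg.rfe_step
    if step is None:
        step = 1 if X_red.shape[1] < 200 else 5
    rfe = recursive_feature_elimination(
        X_red.iloc[tr],
        y_all[tr],
        task_type=cfg.task_type,
        estimator_params=cfg.gbdt_params,
        cv_folds=cfg.rfe_folds,
        metric="auc" if cfg.task_type == CLASSIFICATION else cfg.rfe_metric,
        step=step,
        seed=seed_refine,
        min_size=cfg.rfe_min_size,
        within_se=cfg.rfe_within_se,
    )
    final_features = rfe.selected_features
    counts["after_rfe"] = len(final_features)
    selection_hash = _selection_hash(
        selected,
        list(engineered.columns),
        corr_retained,
        cluster_retained,
        final_features,
    )

    # --- mol2vec (GBFS-Mol2Vec divergence point) -------------------------
    X_final = X_eng[final_features]
    m2v = None
    if cfg.mol2vec:
        m2v = Mol2VecVectorizer(
            dimension=cfg.mol2vec_dimension,
            window=cfg.mol2vec_window,
            min_count=cfg.mol2vec_min_count,
            epochs=cfg.mol2vec_epochs,
            max_radius=cfg.mol2vec_max_radius,
            seed=stage_seed(cfg.master_seed, "mol2vec"),
        )
        m2v.fit([table.smiles[i] for i in tr])
        E = m2v.transform(table.smiles)
        X_final = attach_embeddings(X_final, E)
    counts["final_model_inputs"] = X_final.shape[1]

    # --- optimization ----------------------------------------------------
    seed_opt = stage_seed(cfg.master_seed, "optimize")
    trace = None
    best_point: dict | None = None
    Xtr, ytr = X_final.iloc[tr], y_all[tr]
    if cfg.optimization in ("two_step", "grid"):
        grid = cfg.grid or {
            "learning_rate": [0.01, 0.05, 0.1],
            "num_leaves": [15, 31, 63],
        }
        best_point, region, _ = coarse_grid_search(
            Xtr, ytr, grid, cfg.task_type, cfg.opt_cv_folds, seed_opt
        )
        if cfg.optimization == "two_step":
            space = HyperparameterSpace(
                [
                    Param(
                        name,
                        "log-real" if name == "learning_rate" else "real"
                        if isinstance(vals[0], float)
                        else "integer",
                        (min(vals), max(vals)),
                    )
                    for name, vals in region.items()
                    if min(vals) < max(vals)
                ]
            )
            if space.params:
                trace = bayesian_optimize(
                    Xtr,
                    ytr,
                    space,
                    n_calls=cfg.n_calls,
                    cv_folds=cfg.opt_cv_folds,
                    seed=seed_opt,
                    task_type=cfg.task_type,
                )
                point = dict(trace.best_point)
                for k in ("num_leaves", "n_estimators", "min_child_samples"):
                    if k in point:
                        point[k] = int(round(point[k]))
                best_point = {**best_point, **point}
    elif cfg.optimization == "bayes":
        trace = bayesian_optimize(
            Xtr,
            ytr,
            cfg.search_space or DEFAULT_SPACE,
            n_calls=cfg.n_calls,
            cv_folds=cfg.opt_cv_folds,
            seed=seed_opt,
            task_type=cfg.task_type,
        )
        best_point = {
            k: (int(round(v)) if k in ("num_leaves", "n_estimators", "min_child_samples") else v)
            for k, v in trace.best_point.items()
        }
    elif cfg.optimization != "none":
        raise ValueError(f"unknown optimization mode: {cfg.optimization!r}")

    # --- final model and single test evaluation -------------------------
    model = train_final_model(
        Xtr, ytr, cfg.task_type, {**(cfg.gbdt_params or {}), **(best_point or {})},
        stage_seed(cfg.master_seed, "final_model"),
    )
    validation_metrics = (
        _evaluate(model, X_final.iloc[va], y_all[va], cfg.task_type)
        if len(va)
        else {}
    )
    te = split.test  # sole test access
    test_metrics = _evaluate(model, X_final.iloc[te], y_all[te], cfg.task_type)

    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "mol2vec": cfg.mol2vec,
        "stage_feature_counts": counts,
        "selection_hash": selection_hash,
        "best_hyperparameters": best_point,
        "validation_metrics": validation_metrics,
        "test_metrics": test_metrics,
        "test_access_count": split.test_access_count,
    }
    result = RunResult(
        config=cfg,
        split=split,
        feature_scores=scores,
        selected_relevant=selected,
        engineered_names=list(engineered.columns),
        correlation_retained=corr_retained,
        cluster_retained=cluster_retained,
        permutation_report=perm_report,
        rfe_report=rfe,
        final_features=final_features,
        optimization_trace=trace,
        model=model,
        validation_metrics=validation_metrics,
        test_metrics=test_metrics,
        manifest=manifest,
        mol2vec_model=m2v,
        cleaner=cleaner,
        engineer_parents=gain_order[: min(cfg.engineer_top_k, len(gain_order))],
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def run_gbfs(config: WorkflowConfig, **kwargs) -> RunResult:
    """Plain GBFS run (Mol2Vec disabled regardless of config)."""
    cfg = dataclasses.replace(config, mol2vec=False)
    return run_workflow(cfg, **kwargs)


def run_gbfs_mol2vec(config: WorkflowConfig, **kwargs) -> RunResult:
    """GBFS-Mol2Vec run: identical to GBFS through refinement, then
    embeddings are concatenated before optimization."""
    cfg = dataclasses.replace(config, mol2vec=True)
    return run_workflow(cfg, **kwargs)


def _write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.split.to_json(outdir / "split.json")
    result.feature_scores.to_csv(outdir / "feature_scores.csv", index=False)
    result.permutation_report.to_csv(outdir / "permutation.csv", index=False)
    (outdir / "rfe.json").write_text(json.dumps(result.rfe_report.to_json()))
    (outdir / "selection.json").write_text(
        json.dumps(
            {
                "relevance_selected": result.selected_relevant,
                "engineered": result.engineered_names,
                "correlation_retained": result.correlation_retained,
                "cluster_retained": result.cluster_retained,
                "final_features": result.final_features,
            }
        )
    )
    if result.optimization_trace is not None:
        (outdir / "optimization_trace.json").write_text(
            json.dumps(result.optimization_trace.to_json())
        )
    result.model.save(outdir / "model")
    if result.mol2vec_model is not None:
        result.mol2vec_model.model_.save(outdir / "mol2vec")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


class GBFSWorkflow:
    """Meta-estimator: fit the whole workflow on a molecule table.

    ``fit`` runs every stage on the table's training partition and keeps
    the fitted model; ``predict`` featurizes new SMILES and applies the
    feature-name contract of the final model.
    """

    def __init__(self, config: WorkflowConfig | None = None, **overrides):
        base = config or WorkflowConfig()
        self.config = dataclasses.replace(base, **overrides) if overrides else base

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        if "config" in params:
            self.config = params["config"]
        return self

    def fit(self, table: MoleculeTable, X_base: pd.DataFrame | None = None):
        self.result_ = run_workflow(self.config, table=table, X_base=X_base)
        return self

    def predict(self, smiles: list[str]) -> np.ndarray:
        res = self.result_
        X = res.cleaner.transform(featurize_table(smiles, self.config.blocks))
        X_sel = X[res.selected_relevant]
        eng = brute_force_engineer(
            X_sel,
            self.config.op_set,
            len(res.engineer_parents),
            self.config.ratio_epsilon,
            parent_order=res.engineer_parents,
        )
        X_final = pd.concat([X_sel, eng], axis=1)[res.final_features]
        if self.config.mol2vec:
            E = res.mol2vec_model.transform(smiles)
            X_final = attach_embeddings(X_final, E)
        return res.model.predict(X_final)
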