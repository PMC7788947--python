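"""End-to-end experiment orchestration.

One :func:`run` call chains the full study on one dataset: simulate (or
load) a signature screen, associate it with viability records, subset by
perturbation time and concentration mode, select genes with WRFEN, tune
the boosted-tree hyperparameters with FEBPSO, fit the final model and
evaluate on a held-out test split.  Every stochastic stage draws its seed
from the experiment seed, so a run is reproducible end to end, and all
intermediate artifacts can be written to a run directory for stage-wise
inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import association, boosting, febpso, sensitivity, simulate, wrfen
from .association import MatchedDataset

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    synthetic: simulate.SyntheticSpec = field(default_factory=simulate.SyntheticSpec)
    time_h: float | None = 24.0
    use_concentration: bool = False  # S2 variant
    n_trees: int = wrfen.DEFAULT_N_TREES
    n_genes_selected: object = "auto"
    swarm: febpso.SwarmConfig = field(default_factory=lambda: febpso.SwarmConfig(T=20))
    # boosting-round bounds trimmed for the synthetic benchmark scale
    space_bounds: dict = field(default_factory=lambda: {"iteration_times": (50, 400)})
    train_fraction: float = 0.6
    val_fraction: float = 0.2
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            for key in ("dose_grid", "times"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = simulate.SyntheticSpec(**syn)
        if "swarm" in d:
            d["swarm"] = febpso.SwarmConfig(**d["swarm"])
        if "space_bounds" in d:
            d["space_bounds"] = {k: tuple(v) for k, v in d["space_bounds"].items()}
        return cls(**d)


@dataclass
class RunReport:
    selected_genes: list
    tuned_params: dict
    fitness_history: np.ndarray
    tuned_val_pearson: float
    default_val_pearson: float
    test_report: sensitivity.EvaluationReport
    model: boosting.TrainedModel
    dataset: MatchedDataset
    splits: dict
    provenance: dict

    def summary(self) -> dict:
        return {
            "n_selected_genes": len(self.selected_genes),
            "selected_genes": self.selected_genes,
            "tuned_params": self.tuned_params,
            "tuned_val_pearson": self.tuned_val_pearson,
            "default_val_pearson": self.default_val_pearson,
            "test": self.test_report.to_dict(),
            "provenance": self.provenance,
        }


def take(ds: MatchedDataset, idx) -> MatchedDataset:
    """Row-subset a matched dataset by positional indices."""
    idx = np.asarray(idx)
    return MatchedDataset(
        X=ds.X.iloc[idx].reset_index(drop=True),
        y=ds.y.iloc[idx].reset_index(drop=True),
        meta=ds.meta.iloc[idx].reset_index(drop=True),
        s2=ds.s2,
        time_h=ds.time_h,
        extra_cols=ds.extra_cols,
        provenance=ds.provenance,
    )


def split_indices(n: int, train_fraction: float, val_fraction: float, seed: int):
    """Seeded shuffled train/validation/test row split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_val = int(round(val_fraction * n))
    return perm[:n_train], perm[n_train: n_train + n_val], perm[n_train + n_val:]


def build_dataset(config: ExperimentConfig):
    """Simulate a screen and run the association stage; returns the
    matched (and optionally time-subset, S2-extended) dataset plus the
    simulation artifacts."""
    sig, truth = simulate.generate_signatures(config.synthetic)
    vt = simulate.viability_table(sig, truth)
    by_dose = config.synthetic.pert_type == "compound"
    ds = association.match_viability(sig, vt, by_dose=by_dose)
    if config.time_h is not None:
        ds = association.subset_by_time(ds, config.time_h)
    if config.use_concentration:
        ds = association.with_concentration_feature(ds)
    return ds, sig, truth


def run(config: ExperimentConfig) -> RunReport:
    """Execute the full pipeline and return its report."""
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    split_seed, wrfen_seed, swarm_seed, fit_seed = (int(s) for s in seeds)

    ds, sig, truth = build_dataset(config)
    if len(ds) < 10:
        raise ValueError(f"matched dataset too small ({len(ds)} rows) — stage: association")
    tr, va, te = split_indices(len(ds), config.train_fraction, config.val_fraction, split_seed)
    train, val, test = take(ds, tr), take(ds, va), take(ds, te)

    rf = wrfen.rf_rank(train, n_trees=config.n_trees, seed=wrfen_seed)
    en = fused = None
    try:
        en = wrfen.en_rank(train, seed=wrfen_seed)
    except ValueError as err:
        # a signal-free target can shrink every coefficient to zero at all
        # grid points; fall back to the forest ranking alone
        logger.warning("elastic-net ranking unavailable (%s): using RF ranking only", err)
    if en is not None:
        fused = wrfen.fuse_rankings(rf, en)
        genes = wrfen.select_genes(fused, config.n_genes_selected)
    else:
        k = rf.retained_count if config.n_genes_selected == "auto" else int(config.n_genes_selected)
        genes = rf.genes[: min(k, rf.retained_count)]
    features = genes + list(ds.extra_cols)

    space = febpso.HyperparamSpace().with_bounds(**config.space_bounds)
    swarm_cfg = febpso.SwarmConfig(**{**asdict(config.swarm), "seed": swarm_seed})
    Xtr, ytr = train.X, train.y.to_numpy(float)
    Xva, yva = val.X, val.y.to_numpy(float)

    def fitness(position):
        return boosting.fitness_of(position, space, (Xtr, ytr), (Xva, yva), features, seed=fit_seed)

    result = febpso.optimize(fitness, swarm_cfg, space=space)

    default_model = boosting.fit(Xtr, ytr, features, boosting.DEFAULT_PARAMS, seed=fit_seed)
    default_val = sensitivity.regression_metrics(yva, boosting.predict(default_model, Xva))[0]

    best_params = result.best_params
    if not np.isfinite(result.best_fitness) or result.best_fitness <= -1.0:
        # every particle hit a degenerate region (possible when the target
        # carries no signal): the tuned model is no better than the baseline
        logger.warning(
            "swarm found no non-degenerate parameter combination; "
            "falling back to default hyperparameters"
        )
        best_params = dict(boosting.DEFAULT_PARAMS)

    # hyperparameters frozen: refit the final model on train + validation
    Xfit = pd.concat([Xtr, Xva], ignore_index=True)
    yfit = np.concatenate([ytr, yva])
    model = boosting.fit(Xfit, yfit, features, best_params, seed=fit_seed)
    test_pred = boosting.predict(model, test.X)
    test_report = sensitivity.evaluate(test.y.to_numpy(float), test_pred)

    report = RunReport(
        selected_genes=genes,
        tuned_params=best_params,
        fitness_history=result.history,
        tuned_val_pearson=float(result.best_fitness),
        default_val_pearson=float(default_val),
        test_report=test_report,
        model=model,
        dataset=ds,
        splits={"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()},
        provenance={
            "seed": config.seed,
            "stage_seeds": {"split": split_seed, "wrfen": wrfen_seed,
                            "swarm": swarm_seed, "fit": fit_seed},
            "time_h": config.time_h,
            "s2": config.use_concentration,
            "rf_pearson": rf.validation_pearson,
            "en_pearson": en.validation_pearson if en is not None else None,
        },
    )
    if config.outdir:
        _write_artifacts(config, report, rf, en, fused)
    return report


def cross_validate(model: boosting.TrainedModel, other: MatchedDataset) -> sensitivity.EvaluationReport:
    """Apply a trained model to a foreign matched dataset and report
    regression metrics (the independent-dataset validation step)."""
    missing = [f for f in model.features if f not in other.X.columns]
    if missing:
        raise ValueError(f"foreign dataset lacks model features: {missing}")
    pred = boosting.predict(model, other.X)
    return sensitivity.evaluate(other.y.to_numpy(float), pred)


def sensitivity_validation(
    model: boosting.TrainedModel,
    signatures: pd.DataFrame,
    sens_table: pd.DataFrame,
    use_concentration: bool = False,
) -> sensitivity.EvaluationReport:
    """Score a model against a drug-sensitivity table.

    Predicts viability per signature instance, keeps the lowest prediction
    per (drug, cell line), joins the sensitivity table, labels each pair by
    the GI50 rule and reports ROC/PR and Mann-Whitney statistics.
    """
    X = signatures.copy()
    if use_concentration and association.DOSE_FEATURE not in X.columns:
        X[association.DOSE_FEATURE] = np.log10(X["dose_um"].astype(float))
    records = pd.DataFrame(
        {
            "pert_id": X["pert_id"],
            "cell_line": X["cell_line"],
            "predicted_viability": boosting.predict(model, X),
        }
    )
    collapsed = sensitivity.min_viability_collapse(records)
    joined = collapsed.merge(sens_table, on=["pert_id", "cell_line"], how="inner")
    labels = [sensitivity.gi50_label(s, m) for s, m in zip(joined["drug_sens"], joined["test_max_conc"])]
    obs = joined["true_viability"].to_numpy(float) if "true_viability" in joined else joined["predicted_viability"].to_numpy(float)
    return sensitivity.evaluate(obs, joined["predicted_viability"].to_numpy(float), labels=labels)


def _write_artifacts(config: ExperimentConfig, report: RunReport,
                     rf: wrfen.GeneRanking, en, fused) -> None:
    from pathlib import Path

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rf.to_frame().to_csv(out / "ranking_rf.csv", index=False)
    if en is not None:
        en.to_frame().to_csv(out / "ranking_en.csv", index=False)
    if fused is not None:
        fused.to_frame().to_csv(out / "ranking_fused.csv", index=False)
    pd.DataFrame(
        {"iteration": np.arange(len(report.fitness_history)), "best_fitness": report.fitness_history}
    ).to_csv(out / "fitness_history.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=float)
    with open(out / "splits.json", "w") as fh:
        json.dump(report.splits, fh)
    report.dataset.write(out / "matched_matrix.csv", out / "matched_target.csv")
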