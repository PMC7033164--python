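"""End-to-end model construction, evaluation and method comparison.

The reference flow mirrors how hybrid PSO-BP photosynthesis models are built
in practice:

1. obtain a dataset (generated or read from CSV);
2. split 80/20 into training and validation (seeded, random);
3. fit the [-1, 1] normalization on the *training split only* and apply it
   to inputs (Tem, CO2, Par) and target;
4. search the flattened weight vector of the 3-5-1 network with the particle
   swarm, minimizing training MSE;
5. fine-tune from the swarm's global best with damped least squares
   (Levenberg-Marquardt) — or plain gradient descent if configured;
6. denormalize predictions and report MSE, MAE, MRE and R^2 on both splits,
   plus RMSE in raw and in normalized units.

``compare_methods`` runs the plain-BP arm (random initial weights) against
the PSO-BP arm with the swarm's fitness evaluations charged to the BP arm's
epoch budget, so the two arms spend comparable numbers of full-batch
evaluations.  ``fit_fluorescence_models`` builds the auxiliary models that
predict the electron transport rate (ETR) and non-photochemical quenching
(NPQ) from the same environmental drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bpnet, preprocess, pso
from .errors import ConfigurationError, SchemaError
from .synthetic import Dataset, GeneratorConfig, generate_dataset, read_dataset

DEFAULT_INPUTS = ("tem", "co2", "par")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_metrics(y_true, y_pred) -> dict:
    """MSE, MAE, mean relative error and R^2 of predictions.

    MRE averages |residual| / |truth| over entries with |truth| >= 1e-9;
    the number of excluded near-zero entries is reported alongside.
    R^2 = 1 - SS_res / SS_tot with SS_tot about the mean of ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ConfigurationError("cannot evaluate metrics on empty input")
    if y_true.shape != y_pred.shape:
        raise ConfigurationError("y_true and y_pred must be aligned")
    resid = y_pred - y_true
    mse_v = float(np.mean(resid ** 2))
    mae_v = float(np.mean(np.abs(resid)))
    include = np.abs(y_true) >= 1e-9
    mre_v = (float(np.mean(np.abs(resid[include]) / np.abs(y_true[include])))
             if include.any() else float("nan"))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ConfigurationError("R^2 undefined: y_true is constant")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return {"mse": mse_v, "mae": mae_v, "mre": mre_v, "r2": r2,
            "rmse": math.sqrt(mse_v), "n": int(y_true.size),
            "mre_excluded": int((~include).sum())}


# ---------------------------------------------------------------------------
# configuration and report containers
# ---------------------------------------------------------------------------

def default_train_config() -> bpnet.TrainConfig:
    # pipeline default: LM to (near) convergence; the bare TrainConfig default
    # keeps the literal gradient rule for standalone use
    return bpnet.TrainConfig(optimizer="lm", goal=1e-6, max_epochs=200)


@dataclass
class PipelineConfig:
    """Everything one model run needs; seeds are explicit for reproducibility."""

    dataset: object = None                 # None | GeneratorConfig | Dataset | path
    target: str = "pn"                     # 'pn', 'etr' or 'npq'
    inputs: tuple[str, ...] = DEFAULT_INPUTS
    method: str = "psobp"                  # 'bp' or 'psobp'
    split_seed: int = 0
    split_fraction: float = 0.8
    hidden_constant: int = 3               # c in L = (m+n)/2 + c
    train: bpnet.TrainConfig = field(default_factory=default_train_config)
    pso: pso.PSOConfig = field(default_factory=pso.PSOConfig)
    init_seed: int = 0                     # random init for the plain-BP arm
    outdir: str | None = None

    def __post_init__(self):
        self.inputs = tuple(self.inputs)
        if self.target in self.inputs:
            raise ConfigurationError(
                f"target '{self.target}' cannot also be an input")
        if self.method not in ("bp", "psobp"):
            raise ConfigurationError("method must be 'bp' or 'psobp'")


@dataclass
class ModelReport:
    method: str
    target: str
    train_metrics: dict
    validation_metrics: dict
    rmse_normalized_train: float
    rmse_normalized_validation: float
    epochs_used: int
    epochs_to_goal: int
    converged: bool
    pso_evaluations: int
    seeds: dict

    def to_dict(self) -> dict:
        return {
            "method": self.method, "target": self.target,
            "train": self.train_metrics, "validation": self.validation_metrics,
            "rmse_normalized": {"train": self.rmse_normalized_train,
                                "validation": self.rmse_normalized_validation},
            "epochs_used": self.epochs_used,
            "epochs_to_goal": self.epochs_to_goal,
            "converged": self.converged,
            "pso_evaluations": self.pso_evaluations,
            "seeds": self.seeds,
        }


@dataclass
class ModelBundle:
    """Fitted artefacts of one run (weights, normalization, split, traces)."""

    weights: bpnet.NetworkWeights
    norm: preprocess.NormalizationParams
    split: preprocess.SplitIndices
    trace: bpnet.TrainTrace
    pso_history: list[float]
    dataset: Dataset


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def resolve_dataset(source) -> Dataset:
    """Accept a Dataset, a GeneratorConfig, a CSV path, or None (defaults)."""
    if source is None:
        return generate_dataset(GeneratorConfig())
    if isinstance(source, Dataset):
        return source
    if isinstance(source, GeneratorConfig):
        return generate_dataset(source)
    return read_dataset(Path(source))


def _model_table(dataset: Dataset, inputs, target: str) -> pd.DataFrame:
    frame = dataset.frame
    fluor = set(preprocess.FLUOR_FACTORS)
    needed = [c for c in (*inputs, target) if c in fluor]
    if needed and "valid_fluor" in frame.columns:
        frame = frame[frame["valid_fluor"].astype(bool)]
    cols = list(inputs) + [target]
    for col in cols:
        if col not in frame.columns:
            raise SchemaError(f"column '{col}' missing from dataset")
    frame = frame[cols].dropna()
    if frame.empty:
        raise SchemaError(
            f"no valid records for target column '{target}'")
    return frame.reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> tuple[ModelReport, ModelBundle]:
    """Build, train and evaluate one model according to ``config``."""
    dataset = resolve_dataset(config.dataset)
    table = _model_table(dataset, config.inputs, config.target)
    split = preprocess.train_val_split(len(table), config.split_fraction,
                                       config.split_seed)

    # normalization fitted on the training split only (no leakage)
    cols = list(config.inputs) + [config.target]
    norm = preprocess.fit_normalization(table.iloc[split.train], cols)
    X = np.column_stack([
        preprocess.normalize(table[c].to_numpy(float), norm, c)
        for c in config.inputs])
    y = preprocess.normalize(table[config.target].to_numpy(float), norm,
                             config.target).reshape(-1, 1)
    X_tr, y_tr = X[split.train], y[split.train]
    X_va, y_va = X[split.validation], y[split.validation]

    m = len(config.inputs)
    L = bpnet.hidden_node_count(m, 1, config.hidden_constant)
    arch = bpnet.NetworkArchitecture(m=m, L=L, n_out=1)

    pso_history: list[float] = []
    pso_evals = 0
    if config.method == "psobp":
        fitness = pso.make_mse_fitness(arch, X_tr, y_tr)
        gbest, _, pso_history = pso.optimize(arch.n_params, config.pso, fitness)
        pso_evals = config.pso.population * len(pso_history)
        w0 = bpnet.unflatten(gbest, arch)
    else:
        w0 = bpnet.init_weights(arch, seed=config.init_seed)

    w, trace = bpnet.train(w0, X_tr, y_tr, config.train)

    def split_report(Xs, ys):
        pred_n = bpnet.forward(w, Xs).ravel()
        truth = preprocess.denormalize(ys.ravel(), norm, config.target)
        pred = preprocess.denormalize(pred_n, norm, config.target)
        metrics = evaluate_metrics(truth, pred)
        rmse_norm = float(np.sqrt(np.mean((pred_n - ys.ravel()) ** 2)))
        return metrics, rmse_norm

    tr_metrics, tr_rmse_n = split_report(X_tr, y_tr)
    va_metrics, va_rmse_n = split_report(X_va, y_va)

    report = ModelReport(
        method=config.method, target=config.target,
        train_metrics=tr_metrics, validation_metrics=va_metrics,
        rmse_normalized_train=tr_rmse_n, rmse_normalized_validation=va_rmse_n,
        epochs_used=trace.epochs_used,
        epochs_to_goal=trace.epochs_to_goal(config.train.goal),
        converged=trace.converged,
        pso_evaluations=pso_evals,
        seeds={"data": dataset.meta.get("seed"), "split": config.split_seed,
               "pso": config.pso.seed, "init": config.init_seed},
    )
    bundle = ModelBundle(weights=w, norm=norm, split=split, trace=trace,
                         pso_history=pso_history, dataset=dataset)
    return report, bundle


def run_psobp(config: PipelineConfig | None = None) -> tuple[ModelReport, ModelBundle]:
    """The reference PSO-BP run (swarm-initialized weights, LM fine-tune)."""
    if config is None:
        config = PipelineConfig()
    if config.method != "psobp":
        config = replace(config, method="psobp")
    return run_pipeline(config)


def _with_seed(config: PipelineConfig, seed: int) -> PipelineConfig:
    """Derive one coherent seed bundle (< 2^31) from a single run seed."""
    return replace(
        config,
        split_seed=(seed * 7 + 1) % (2 ** 31),
        init_seed=(seed * 7 + 2) % (2 ** 31),
        pso=replace(config.pso, seed=(seed * 7 + 3) % (2 ** 31)),
    )


def default_compare_train_config() -> bpnet.TrainConfig:
    # the comparison races both arms under the literal fixed-step
    # gradient-descent trainer, where initialization quality matters
    return bpnet.TrainConfig(optimizer="gd", eta=0.05, max_epochs=500,
                             goal=1e-3)


def compare_methods(config: PipelineConfig | None = None,
                    seeds: Sequence[int] = (0, 1, 2, 3, 4),
                    train_config: bpnet.TrainConfig | None = None,
                    charge_pso_evals: bool = False,
                    methods: tuple[str, str] = ("bp", "psobp")) -> dict:
    """Plain BP (random init) versus PSO-BP (swarm init) over several seeds.

    Both arms share one trainer configuration — by default the fixed-step
    gradient rule, the regime whose slow convergence swarm initialization is
    meant to cure — and matched per-seed epoch budgets, mirroring how
    training-iteration counts are conventionally compared; the swarm's own
    fitness-evaluation cost is reported per seed so the reader can judge the
    total expense.  With ``charge_pso_evals=True`` the BP arm's epoch budget
    is instead enlarged by that evaluation count (one full-batch evaluation
    ~ one epoch), equalizing total function evaluations.

    Returns per-seed rows, per-metric medians, and a verdict flag per metric
    naming the method with the better median (epochs-to-goal and errors
    lower-is-better, R^2 higher).  Epochs-to-goal is censored at the trace
    length when the goal MSE is never reached.
    """
    if config is None:
        config = PipelineConfig()
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ConfigurationError("compare_methods needs at least 3 seeds")
    train_cfg = default_compare_train_config() if train_config is None \
        else train_config
    if any(m not in ("bp", "psobp") for m in methods) or len(methods) != 2:
        raise ConfigurationError("methods must be two of 'bp'/'psobp'")
    labels = methods if methods[0] != methods[1] \
        else (methods[0] + "_a", methods[1] + "_b")

    rows = []
    for seed in seeds:
        run_cfg = replace(_with_seed(config, seed), train=train_cfg)
        # the swarm's cost (second arm) may be charged to the first arm
        second_report, _ = run_pipeline(replace(run_cfg, method=methods[1]))
        first_train = train_cfg
        if charge_pso_evals:
            extra = int(math.ceil(second_report.pso_evaluations))
            first_train = replace(train_cfg,
                                  max_epochs=train_cfg.max_epochs + extra)
        first_report, _ = run_pipeline(replace(run_cfg, method=methods[0],
                                               train=first_train))
        for label, rep in zip(labels, (first_report, second_report)):
            rows.append({
                "seed": seed, "arm": label, "method": rep.method,
                "pso_evaluations": rep.pso_evaluations,
                "epochs_to_goal": rep.epochs_to_goal,
                "final_train_mse_norm": rep.rmse_normalized_train ** 2,
                "train_mse": rep.train_metrics["mse"],
                "validation_mse": rep.validation_metrics["mse"],
                "validation_r2": rep.validation_metrics["r2"],
                "validation_mae": rep.validation_metrics["mae"],
            })
    table = pd.DataFrame(rows)
    med = table.groupby("arm").median(numeric_only=True).drop(columns="seed")
    a, b = labels
    verdicts = {}
    for metric in ("epochs_to_goal", "final_train_mse_norm", "train_mse",
                   "validation_mse", "validation_mae"):
        verdicts[metric] = b if med.loc[b, metric] <= med.loc[a, metric] else a
    verdicts["validation_r2"] = (b if med.loc[b, "validation_r2"]
                                 >= med.loc[a, "validation_r2"] else a)
    return {"per_seed": table, "medians": med, "verdicts": verdicts,
            "goal": train_cfg.goal, "seeds": seeds, "arms": labels}


FLUOR_MODEL_LABELS = {"pn": "Model1", "etr": "Model2", "npq": "Model3"}


def fit_fluorescence_models(config: PipelineConfig | None = None,
                            targets: Sequence[str] = ("etr", "npq")) -> dict:
    """PSO-BP models for Pn plus each fluorescence target, same inputs.

    Returns the three reports plus a summary table of per-target train and
    validation R^2 and RMSE (raw and normalized units).
    """
    if config is None:
        config = PipelineConfig()
    dataset = resolve_dataset(config.dataset)
    reports = {}
    rows = []
    for target in ("pn", *targets):
        run_cfg = replace(config, dataset=dataset, target=target,
                          method="psobp")
        report, _ = run_pipeline(run_cfg)
        reports[target] = report
        rows.append({
            "model": FLUOR_MODEL_LABELS.get(target, target),
            "target": target,
            "train_r2": report.train_metrics["r2"],
            "train_rmse": report.train_metrics["rmse"],
            "train_rmse_normalized": report.rmse_normalized_train,
            "validation_r2": report.validation_metrics["r2"],
            "validation_rmse": report.validation_metrics["rmse"],
            "validation_rmse_normalized": report.rmse_normalized_validation,
        })
    return {"reports": reports, "table": pd.DataFrame(rows)}
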