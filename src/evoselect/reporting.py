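"""Held-out validation, default-settings baseline, and run reports.

After evolution, the archived best models are refit on the full
train/test partition and scored once on the untouched validation
partition (native data — never resampled); the single best model is
selected by accuracy (classification) or R^2 (regression), ties broken
by fitness.  The baseline repeats the experiment without optimization:
the inner learner with its library-default hyperparameters on the full
feature set, under the same cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evolution import RunResult
from .exceptions import ConfigurationError
from .fitness import (
    EvaluatedModel,
    _classification_metrics,
    _regression_metrics,
    bic_classification,
    bic_regression,
    evaluate,
)
from .inner_models import CLASSIFICATION, make_inner_model
from .search_space import Chromosome, get_profile

__all__ = [
    "RunConfig",
    "ValidationReport",
    "validate_final",
    "run_default_baseline",
    "emit_report",
]


@dataclass
class RunConfig:
    """Round-trippable record of every setting of a run."""

    task: str = "regression"
    inner: str = "linear"
    target: str = "y"
    n_population: int = 100
    subset_min: int = 1
    subset_max: int = 50
    max_generations: int = 500
    plateau_window: int = 20
    plateau_tol: float = 1e-4
    warm_start: bool = True
    k_cap: int | None = None
    cutoff: float | None = None
    split_fraction: float = 0.7
    archive_size: int = 100
    fixed_settings: dict = field(default_factory=dict)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ValidationReport:
    """Per-archived-model held-out metrics plus the selected winner."""

    rows: pd.DataFrame  # one row per archived model
    selected_index: int
    selected_metrics: dict[str, float]
    selection_metric: str
    baseline_metrics: dict[str, float] | None = None

    @property
    def deltas(self) -> dict[str, float] | None:
        if self.baseline_metrics is None:
            return None
        return {
            k: self.selected_metrics[k] - self.baseline_metrics[k]
            for k in self.selected_metrics
            if k in self.baseline_metrics
        }


def _score_on(model, features, X, y, task) -> dict[str, float]:
    values = X[features].to_numpy(dtype=float)
    y = np.asarray(y)
    p = len(features) + 1
    if task == CLASSIFICATION:
        probs = model.predict_proba(values)
        classes = np.unique(y)
        order = np.searchsorted(classes, model.classes_)
        aligned = np.empty_like(probs)
        aligned[:, order] = probs
        metrics = _classification_metrics(y, aligned)
        metrics["bic"] = bic_classification(y, aligned, p)
    else:
        y_hat = model.predict(values)
        metrics = _regression_metrics(y, y_hat)
        metrics["bic"] = bic_regression(y, y_hat, p)
    return metrics


def validate_final(
    archive: list[EvaluatedModel],
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    task: str,
    inner_kind: str,
    fixed_settings: dict | None = None,
    rng: np.random.Generator | None = None,
    baseline_metrics: dict[str, float] | None = None,
) -> ValidationReport:
    """Refit every archived model on the train/test partition and score
    it once on the held-out validation partition.

    Selection: best accuracy (classification) or R^2 (regression), ties
    broken by the validation BIC.
    """
    if not archive:
        raise ConfigurationError("empty archive")
    rng = rng or np.random.default_rng()
    select_by = "accuracy" if task == CLASSIFICATION else "r2"
    records = []
    for i, model in enumerate(archive):
        features = sorted(model.chromosome.features)
        seed = int(rng.integers(2**31))
        fitted = make_inner_model(
            inner_kind,
            task,
            model.chromosome.hyperparameter_values,
            fixed_settings,
            random_state=seed,
        ).fit(X_train[features].to_numpy(dtype=float), np.asarray(y_train))
        metrics = _score_on(fitted, features, X_val, y_val, task)
        records.append(
            {"model": i, "n_features": len(features), "train_bic": model.bic, **metrics}
        )
    rows = pd.DataFrame(records)
    order = rows.sort_values([select_by, "bic"], ascending=[False, True])
    selected = int(order.index[0])
    selected_metrics = {
        k: float(rows.loc[selected, k]) for k in rows.columns if k != "model"
    }
    return ValidationReport(
        rows=rows,
        selected_index=selected,
        selected_metrics=selected_metrics,
        selection_metric=select_by,
        baseline_metrics=baseline_metrics,
    )


def run_default_baseline(
    X: pd.DataFrame,
    y,
    inner_kind: str,
    task: str,
    rng: np.random.Generator,
    fixed_settings: dict | None = None,
    k_cap: int | None = None,
    X_val: pd.DataFrame | None = None,
    y_val=None,
) -> dict[str, float]:
    """No-optimization comparison: library-default hyperparameters on the
    full feature set under the same cross-validation.

    When a validation partition is supplied, refits on the full
    train/test data and adds ``val_*`` metrics for it.
    """
    defaults = {h.name: h.default for h in get_profile(inner_kind)}
    chromosome = Chromosome(defaults, frozenset(X.columns), provenance="random")
    result = evaluate(
        chromosome,
        X,
        y,
        task,
        inner_kind,
        rng,
        fixed_settings=fixed_settings,
        k_cap=k_cap,
        compute_importances=False,
    )
    metrics = {"bic": result.bic, **result.metrics}
    if X_val is not None:
        features = sorted(chromosome.features)
        fitted = make_inner_model(
            inner_kind,
            task,
            defaults,
            fixed_settings,
            random_state=int(rng.integers(2**31)),
        ).fit(X[features].to_numpy(dtype=float), np.asarray(y))
        for k, v in _score_on(fitted, features, X_val, y_val, task).items():
            metrics[f"val_{k}"] = v
    metrics["hyperparameters"] = defaults  # type: ignore[assignment]
    return metrics


def emit_report(
    run_result: RunResult,
    validation: ValidationReport | None,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> list[Path]:
    """Write the run's tables as delimited text plus a JSON run record.

    Files: fitness trace (generation -> best fitness), importance
    ranking of the best model, metrics summary (evolved vs default when
    a baseline is present), tuned-vs-default hyperparameters, and the
    serialized run record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    trace = pd.DataFrame(
        {
            "generation": np.arange(1, run_result.n_generations + 1),
            "best_bic": run_result.best_history,
        }
    )
    written.append(out / "fitness_trace.tsv")
    trace.to_csv(written[-1], sep="\t", index=False)

    best = run_result.best
    imp = pd.DataFrame(
        sorted(best.importances.items(), key=lambda kv: (-abs(kv[1]), kv[0])),
        columns=["feature", "importance"],
    )
    written.append(out / "importance_ranking.tsv")
    imp.to_csv(written[-1], sep="\t", index=False)

    summary_rows = [{"model": "evolved", "bic": best.bic, **best.metrics}]
    if validation is not None:
        summary_rows.append(
            {"model": "evolved_validation", **validation.selected_metrics}
        )
        if validation.baseline_metrics is not None:
            base = {
                k: v
                for k, v in validation.baseline_metrics.items()
                if k != "hyperparameters"
            }
            summary_rows.append({"model": "default_baseline", **base})
    written.append(out / "metrics_summary.tsv")
    pd.DataFrame(summary_rows).to_csv(written[-1], sep="\t", index=False)

    profile = get_profile(config.inner) if config else None
    hp_rows = []
    for name, value in sorted(best.chromosome.hyperparameter_values.items()):
        default = None
        if profile:
            default = next((h.default for h in profile if h.name == name), None)
        hp_rows.append({"hyperparameter": name, "tuned": value, "default": default})
    written.append(out / "hyperparameters.tsv")
    pd.DataFrame(hp_rows).to_csv(written[-1], sep="\t", index=False)

    record = {"run": run_result.to_dict()}
    if config is not None:
        record["config"] = asdict(config)
    if validation is not None:
        record["validation"] = {
            "selected_index": validation.selected_index,
            "selected_metrics": validation.selected_metrics,
            "selection_metric": validation.selection_metric,
            "baseline_metrics": validation.baseline_metrics,
        }
    written.append(out / "run_record.json")
    written[-1].write_text(json.dumps(record, indent=2, sort_keys=True, default=float))
    return written
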