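"""Nested, repeated cross-validation wrapping GA selection and
classification, plus selection-frequency aggregation.

The outer loop is a stratified 5-fold CV repeated (default 100 times) with
fresh fold assignments per repeat; inside every outer training fold the GA
selects a chromosome and the classifier is fitted on those features only
(SVMs additionally tune hyperparameters by a stratified 5-fold *inner* CV
on the training fold). Out-of-fold predictions estimate generalization; no
statistic of any kind is computed from test rows before prediction.

Feature importance/stability is the *selection frequency*: the number of
fold-fits (out of repeats x k, i.e. 500 at full-scale defaults) whose
selected chromosome contains the feature.

All randomness descends from one master seed via ``numpy.random
.SeedSequence`` spawning, so reports are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .classifiers import (
    FittedClassifier,
    SvmSpec,
    decision_values,
    fit_lsld,
    tune_svm,
)
from .ga import Chromosome, GaConfig, run_ga
from .schema import FeatureSchema, FeatureTable, OutcomeLabels

CLASSIFIER_KINDS = ("lsld", "svm-linear", "svm-rbf")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier the pipeline fits on the selected chromosome."""

    kind: str = "lsld"
    svm: SvmSpec | None = None
    inner_k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind.startswith("svm") and self.svm is None:
            kernel = self.kind.split("-", 1)[1]
            object.__setattr__(self, "svm", SvmSpec(kernel=kernel))


@dataclass
class FoldResult:
    """Everything one outer fold produced."""

    repeat: int
    fold: int
    chromosome: Chromosome
    classifier_kind: str
    hyperparameters: dict
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray


@dataclass
class FeatureFrequency:
    """Per-feature count of appearances in selected chromosomes across all
    fold-fits; ``denominator`` = repeats x k."""

    counts: np.ndarray
    denominator: int
    schema: FeatureSchema

    @property
    def percentage(self) -> np.ndarray:
        return 100.0 * self.counts / self.denominator

    def ranking(self) -> pd.DataFrame:
        """Features ranked by count descending, ties by schema order."""
        order = np.lexsort((np.arange(len(self.counts)), -self.counts))
        return pd.DataFrame({
            "feature": [self.schema.feature_names[i] for i in order],
            "feature_index": order,
            "group_tag": [self.schema.group_tags[i] for i in order],
            "count": self.counts[order].astype(int),
            "percentage": self.percentage[order],
        })


@dataclass
class CVReport:
    """Aggregate of a full nested-CV run; the raw results container that
    :class:`fatiguecast.model.NestedCVResults` wraps."""

    fold_results: list[FoldResult]
    per_repeat: list[metrics.PerformanceSummary]
    roc: metrics.RocSummary | None
    frequency: FeatureFrequency
    classifier_kind: str
    repeats: int
    k_outer: int
    seed: int
    ga_config: GaConfig = field(repr=False)

    @property
    def overall(self) -> dict[str, float]:
        """Mean over repeats of each per-repeat metric (NaN-aware for
        PPV/NPV, which can be undefined in a repeat)."""
        keys = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")
        return {key: float(np.nanmean([getattr(s, key)
                                       for s in self.per_repeat]))
                for key in keys}

    def ci95(self) -> dict[str, tuple[float, float]]:
        """95% normal-approximation CI across repeats per metric."""
        out = {}
        for key in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = np.array([getattr(s, key) for s in self.per_repeat])
            m = float(np.nanmean(vals))
            se = float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals))) \
                if len(vals) > 1 else 0.0
            out[key] = (m - 1.96 * se, m + 1.96 * se)
        return out

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for fr in self.fold_results:
            for sid, yt, yp, sc in zip(fr.test_ids, fr.y_true, fr.y_pred,
                                       fr.scores):
                rows.append({
                    "repeat": fr.repeat, "fold": fr.fold,
                    "subject_id": sid, "y_true": int(yt),
                    "y_pred": int(yp), "score": float(sc),
                    "genes": " ".join(map(str, fr.chromosome.genes)),
                })
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        ci = self.ci95()
        rows = []
        for key, val in self.overall.items():
            row = {"metric": key, "mean": val}
            if key in ci:
                row["ci95_low"], row["ci95_high"] = ci[key]
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Write fold-level, frequency and summary tables plus a run
        manifest under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fold_table().to_csv(outdir / "folds.csv", index=False)
        self.frequency.ranking().to_csv(outdir / "frequency.csv",
                                        index=False)
        self.summary_table().to_csv(outdir / "summary.csv", index=False)
        manifest = {
            "classifier": self.classifier_kind,
            "repeats": self.repeats,
            "k_outer": self.k_outer,
            "seed": self.seed,
            "ga": {
                "chromosome_length": self.ga_config.chromosome_length,
                "population_size": self.ga_config.population_size,
                "parent_fraction": self.ga_config.parent_fraction,
                "mutation_rate": self.ga_config.mutation_rate,
                "generations": self.ga_config.generations,
                "elitism": self.ga_config.elitism,
            },
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_folds(
    labels: OutcomeLabels | np.ndarray,
    k: int = 5,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Stratified outer-fold assignment (0..k-1) per subject.

    Fold sizes differ by at most one, overall and within each class.
    """
    y = labels.improver if isinstance(labels, OutcomeLabels) \
        else np.asarray(labels)
    if min(np.sum(y == y[0]), np.sum(y != y[0])) < k:
        raise ValueError(f"each class needs >= {k} members for {k} folds")
    rs = _seed_int(seed) if isinstance(seed, np.random.SeedSequence) \
        else int(seed) % (2 ** 31)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test] = fold
    return assignment


def _fit_on_chromosome(
    X_train: np.ndarray,
    y_train: np.ndarray,
    chromosome: Chromosome,
    spec: ClassifierSpec,
    inner_seed: int,
) -> FittedClassifier:
    cols = list(chromosome.genes)
    Xc = X_train[:, cols]
    if spec.kind == "lsld":
        return fit_lsld(Xc, y_train, feature_indices=cols)
    return tune_svm(Xc, y_train, spec.svm, inner_k=spec.inner_k,
                    seed=inner_seed, feature_indices=cols)


def run_fold(
    table: FeatureTable,
    labels: OutcomeLabels,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    classifier_spec: ClassifierSpec,
    ga_config: GaConfig,
    seed: int | np.random.SeedSequence = 0,
    repeat: int = 0,
    fold: int = 0,
) -> FoldResult:
    """GA selection + classifier fit on the training rows only, then
    predictions for the test rows."""
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")
    y = labels.y_signed()
    X_train, y_train = table.values[train_idx], y[train_idx]
    if np.unique(y_train).size < 2:
        raise ValueError("training fold contains a single class")

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ga_ss, inner_ss = ss.spawn(2)
    rng = np.random.default_rng(ga_ss)
    chromosome, _ = run_ga(X_train, y_train, ga_config, rng=rng)
    model = _fit_on_chromosome(X_train, y_train, chromosome,
                               classifier_spec, _seed_int(inner_ss))

    X_test = table.values[test_idx][:, list(chromosome.genes)]
    scores = decision_values(model, X_test)
    preds = np.where(scores > 0, 1, -1)
    return FoldResult(
        repeat=repeat, fold=fold, chromosome=chromosome,
        classifier_kind=classifier_spec.kind,
        hyperparameters=dict(model.hyperparameters),
        test_ids=[labels.subject_ids[i] for i in test_idx],
        y_true=y[test_idx], y_pred=preds, scores=scores,
    )


def aggregate_frequency(
    fold_results: Sequence[FoldResult], schema: FeatureSchema
) -> FeatureFrequency:
    """Count, per feature, the fold-fits whose selected chromosome contains
    it."""
    if not fold_results:
        raise ValueError("no fold results to aggregate")
    counts = np.zeros(len(schema), dtype=int)
    for fr in fold_results:
        counts[list(fr.chromosome.genes)] += 1
    return FeatureFrequency(counts, len(fold_results), schema)


def run_nested_cv(
    table: FeatureTable,
    labels: OutcomeLabels,
    classifier_spec: ClassifierSpec | str = "lsld",
    ga_config: GaConfig | None = None,
    repeats: int = 100,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified nested CV; the pipeline's main entry point.

    Per-repeat performance is computed from that repeat's pooled
    out-of-fold predictions (every subject is tested exactly once per
    repeat); the overall summary averages over repeats.
    """
    if isinstance(classifier_spec, str):
        classifier_spec = ClassifierSpec(kind=classifier_spec)
    if ga_config is None:
        ga_config = GaConfig()
    y = labels.y_signed()
    n = table.n_subjects
    master = np.random.SeedSequence(seed)
    repeat_streams = master.spawn(repeats)

    fold_results: list[FoldResult] = []
    per_repeat: list[metrics.PerformanceSummary] = []
    curves = []
    for r, r_ss in enumerate(repeat_streams):
        fold_ss, *fit_ss = r_ss.spawn(k + 1)
        assignment = make_folds(labels, k=k, seed=fold_ss)
        pooled_true = np.empty(n, dtype=int)
        pooled_pred = np.empty(n, dtype=int)
        pooled_score = np.empty(n, dtype=float)
        for fold in range(k):
            test_idx = np.where(assignment == fold)[0]
            train_idx = np.where(assignment != fold)[0]
            fr = run_fold(table, labels, train_idx, test_idx,
                          classifier_spec, ga_config, seed=fit_ss[fold],
                          repeat=r, fold=fold)
            fold_results.append(fr)
            pooled_true[test_idx] = fr.y_true
            pooled_pred[test_idx] = fr.y_pred
            pooled_score[test_idx] = fr.scores
        summary = metrics.summarize_performance(pooled_true, pooled_pred)
        fpr, tpr, auc_val = metrics.roc_points(pooled_true, pooled_score)
        summary.auc = auc_val
        curves.append((fpr, tpr, auc_val))
        per_repeat.append(summary)

    roc = metrics.mean_roc(curves) if len(curves) >= 2 else None
    frequency = aggregate_frequency(fold_results, table.schema)
    return CVReport(
        fold_results=fold_results, per_repeat=per_repeat, roc=roc,
        frequency=frequency, classifier_kind=classifier_spec.kind,
        repeats=repeats, k_outer=k, seed=seed, ga_config=ga_config,
    )


def chromosome_sweep(
    table: FeatureTable,
    labels: OutcomeLabels,
    classifier_spec: ClassifierSpec | str = "lsld",
    ga_config: GaConfig | None = None,
    lengths: Sequence[int] = tuple(range(1, 21)),
    repeats: int = 100,
    k: int = 5,
    seed: int = 0,
) -> "SweepReport":
    """Re-run the nested CV for each chromosome length; used to study how
    the size of the selected feature set affects performance and which
    features stay at the top of the selection-frequency ranking."""
    if ga_config is None:
        ga_config = GaConfig()
    if max(lengths) > len(table.schema):
        raise ValueError("chromosome length exceeds the feature count")
    reports = {}
    for L in lengths:
        cfg = replace(ga_config, chromosome_length=int(L),
                      population_size=None)
        reports[int(L)] = run_nested_cv(
            table, labels, classifier_spec, cfg,
            repeats=repeats, k=k, seed=seed,
        )
    return SweepReport(reports)


@dataclass
class SweepReport:
    """Per-chromosome-length CV reports with tabular views."""

    reports: dict[int, CVReport]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for L, rep in sorted(self.reports.items()):
            ci = rep.ci95()["accuracy"]
            row = {"chromosome_length": L, **rep.overall,
                   "accuracy_ci95_low": ci[0], "accuracy_ci95_high": ci[1]}
            rows.append(row)
        return pd.DataFrame(rows)

    def frequency(self, length: int) -> FeatureFrequency:
        return self.reports[length].frequency
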