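"""Model / Results façade over the nested-CV pipeline.

:class:`FatigueOutcomeModel` binds one modality's feature table and the
fatigue outcome labels to a classifier and GA configuration;
:meth:`FatigueOutcomeModel.fit` runs the repeated nested cross-validation
and returns :class:`NestedCVResults`, which carries the performance
estimates with their across-repeat uncertainty, the feature
selection-frequency ranking, diagnostics and a ``summary()`` table, in the
spirit of statsmodels model/results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics
from .classifiers import SvmSpec
from .crossval import (
    ClassifierSpec,
    CVReport,
    SweepReport,
    chromosome_sweep,
    run_nested_cv,
)
from .ga import GaConfig
from .schema import (
    FeatureSchema,
    FeatureTable,
    OutcomeLabels,
    SUBJECT_ID_COLUMN,
    label_improvement,
)


class FatigueOutcomeModel:
    """Predicts fatigue improvement (improver vs non-improver) from one
    modality's feature table via GA-selected features.

    Parameters
    ----------
    table
        Subjects x features table for one modality.
    labels
        Outcome labels aligned with the table's subjects.
    classifier
        ``"lsld"`` (least-squares linear discriminant, default),
        ``"svm-linear"`` or ``"svm-rbf"``.
    ga
        GA feature-selection settings (default: chromosome length 8,
        population 80, 100 generations).
    svm
        Hyperparameter grids when an SVM classifier is used.
    """

    def __init__(
        self,
        table: FeatureTable,
        labels: OutcomeLabels,
        classifier: str = "lsld",
        ga: GaConfig | None = None,
        svm: SvmSpec | None = None,
        inner_k: int = 5,
    ) -> None:
        if table.subject_ids != labels.subject_ids:
            raise ValueError("table and labels subjects differ or are "
                             "ordered differently")
        self.table = table
        self.labels = labels
        self.ga = ga if ga is not None else GaConfig()
        self.spec = ClassifierSpec(kind=classifier, svm=svm, inner_k=inner_k)

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        scores: pd.DataFrame,
        schema: FeatureSchema,
        threshold: int = 2,
        **kwargs,
    ) -> "FatigueOutcomeModel":
        """Build from raw dataframes: ``features`` holds ``subject_id`` +
        schema columns; ``scores`` holds ``subject_id``, ``cfs_baseline``,
        ``cfs_followup``."""
        ids = features[SUBJECT_ID_COLUMN].astype(str).tolist()
        table = FeatureTable(schema, ids,
                             features[list(schema.feature_names)]
                             .to_numpy(dtype=float))
        scores = scores.set_index(SUBJECT_ID_COLUMN).loc[ids]
        labels = label_improvement(
            scores["cfs_baseline"].to_numpy(),
            scores["cfs_followup"].to_numpy(),
            threshold=threshold, subject_ids=ids,
        )
        return cls(table, labels, **kwargs)

    def fit(self, repeats: int = 100, k: int = 5,
            seed: int = 0) -> "NestedCVResults":
        """Run the repeated nested CV and return the results object."""
        report = run_nested_cv(self.table, self.labels, self.spec, self.ga,
                               repeats=repeats, k=k, seed=seed)
        return NestedCVResults(self, report)

    def sweep_chromosome_length(
        self,
        lengths: Sequence[int] = tuple(range(1, 21)),
        repeats: int = 100,
        k: int = 5,
        seed: int = 0,
    ) -> SweepReport:
        """Nested CV per chromosome length (performance vs subset size)."""
        return chromosome_sweep(self.table, self.labels, self.spec, self.ga,
                                lengths=lengths, repeats=repeats, k=k,
                                seed=seed)


@dataclass
class NestedCVResults:
    """Results of :meth:`FatigueOutcomeModel.fit`.

    ``overall`` averages each metric across repeats; ``ci95`` gives the
    across-repeat 95% confidence interval; ``feature_frequency`` ranks
    features by how often the GA selected them across all fold-fits.
    """

    model: FatigueOutcomeModel
    report: CVReport
    _trends: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def overall(self) -> dict[str, float]:
        return self.report.overall

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        return self.report.ci95()

    @property
    def feature_frequency(self) -> pd.DataFrame:
        return self.report.frequency.ranking()

    @property
    def roc(self) -> metrics.RocSummary | None:
        return self.report.roc

    def top_features(self, n: int = 10) -> pd.DataFrame:
        """The n most frequently selected features, annotated with the
        direction and significance of their group difference
        (two-sample t-test, '+' = higher in non-improvers)."""
        top = self.feature_frequency.head(n)
        trends = metrics.trend_ttest(self.model.table, self.model.labels,
                                     top["feature_index"].tolist())
        return top.merge(trends[["feature_index", "sign", "t", "p"]],
                         on="feature_index")

    def summary(self) -> str:
        """Plain-text summary table in the house style of statsmodels."""
        o, ci = self.overall, self.ci95
        rep = self.report
        fmt = metrics.format_percent
        lines = [
            "Fatigue outcome nested-CV results",
            "=" * 58,
            f"classifier:        {rep.classifier_kind}",
            f"subjects:          {self.model.table.n_subjects} "
            f"({self.model.labels.n_improvers} improvers / "
            f"{self.model.labels.n_nonimprovers} non-improvers)",
            f"features:          {len(self.model.table.schema)} "
            f"({self.model.table.schema.modality})",
            f"chromosome length: {rep.ga_config.chromosome_length}",
            f"outer CV:          {rep.k_outer}-fold x {rep.repeats} repeats "
            f"({len(rep.fold_results)} fold-fits), seed {rep.seed}",
            "-" * 58,
            f"{'metric':<14}{'mean':>10}{'95% CI':>24}",
        ]
        for key in ("accuracy", "sensitivity", "specificity", "auc"):
            lo, hi = ci[key]
            lines.append(f"{key:<14}{fmt(o[key]):>10}"
                         f"{'[' + fmt(lo) + ', ' + fmt(hi) + ']':>24}")
        for key in ("ppv", "npv"):
            val = o[key]
            shown = fmt(val) if np.isfinite(val) else "undefined"
            lines.append(f"{key:<14}{shown:>10}")
        lines.append("-" * 58)
        lines.append("top selected features (count / "
                     f"{rep.frequency.denominator} fold-fits):")
        for _, row in self.feature_frequency.head(5).iterrows():
            lines.append(f"  {row['feature']:<38}{row['count']:>4}  "
                         f"({row['percentage']:.1f}%)")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        self.report.write(outdir)

    def plot_roc(self, ax=None):
        """Mean ROC with its 95% band (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if self.roc is None:
            raise ValueError("ROC summary needs >= 2 repeats")
        if ax is None:
            _, ax = plt.subplots()
        r = self.roc
        ax.plot(r.fpr_grid, r.mean_tpr,
                label=f"{self.report.classifier_kind} "
                      f"(AUC {r.mean_auc:.2f})")
        ax.fill_between(r.fpr_grid, r.lower, r.upper, alpha=0.25)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
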