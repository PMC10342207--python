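"""Statistics and machine learning on per-cell FLIM feature tables.

Implements the comparison framework for the two quantification routes:
group-wise Welch t-tests on single features, UMAP embedding for cluster
visualization, pairwise random-forest classifiers on three feature sets
(the 8 curve-fit features, the 4 phasor features, and their union) under
stratified 5-fold cross-validation, and paired fold-wise t-tests between
feature sets on accuracy or ROC AUC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .features import DECAY_FEATURES, FEATURE_COLUMNS, PHASOR_FEATURES

__all__ = [
    "FeatureSetSpec",
    "FEATURE_SETS",
    "ClassifierReport",
    "ComparisonResult",
    "group_ttests",
    "embed_2d",
    "make_folds",
    "train_rft_pairwise",
    "compare_feature_sets",
    "run_comparison_suite",
    "SuiteResult",
]

N_FOLDS = 5


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    columns: tuple


FEATURE_SETS = {
    "decay8": FeatureSetSpec("decay8", tuple(DECAY_FEATURES)),
    "phasor4": FeatureSetSpec("phasor4", tuple(PHASOR_FEATURES)),
    "combined12": FeatureSetSpec("combined12", tuple(FEATURE_COLUMNS)),
}


@dataclass
class ClassifierReport:
    """Cross-validated random-forest results for one pairwise comparison."""

    class_a: str
    class_b: str
    feature_set: str
    fold_accuracies: np.ndarray
    fold_aucs: np.ndarray
    importances: dict
    roc_points: dict
    seed: int
    fold_assignment: np.ndarray
    cell_ids: list

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def to_dict(self) -> dict:
        return {
            "class_a": self.class_a,
            "class_b": self.class_b,
            "feature_set": self.feature_set,
            "fold_accuracies": [float(v) for v in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "fold_aucs": [float(v) for v in self.fold_aucs],
            "mean_auc": self.mean_auc,
            "importances": {k: float(v) for k, v in self.importances.items()},
            "roc_points": {k: [float(v) for v in vals] for k, vals in self.roc_points.items()},
            "seed": int(self.seed),
            "fold_assignment": [int(v) for v in self.fold_assignment],
            "cell_ids": [list(map(int, pair)) for pair in self.cell_ids],
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Paired fold-wise t-test between two feature sets on one metric."""

    metric: str
    feature_set_a: str
    feature_set_b: str
    values_a: tuple
    values_b: tuple
    t_statistic: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "feature_set_a": self.feature_set_a,
            "feature_set_b": self.feature_set_b,
            "values_a": list(self.values_a),
            "values_b": list(self.values_b),
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def group_ttests(table: pd.DataFrame, feature: str, groups=None, alpha: float = 0.05
                 ) -> pd.DataFrame:
    """Pairwise two-sided Welch t-tests on one feature across groups.

    Returns one row per unordered group pair with t, p and a significance flag
    at the 0.05 threshold (unadjusted, matching the convention of reporting
    each pairwise contrast on its own).
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    if groups is None:
        groups = sorted(table["group"].unique())
    samples = {}
    for g in groups:
        x = table.loc[table["group"] == g, feature].dropna().to_numpy()
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations for {feature!r}")
        if np.var(x) == 0:
            raise ValueError(f"group {g!r} has zero variance for {feature!r}")
        samples[g] = x
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if samples[a].size == samples[b].size and np.array_equal(samples[a], samples[b]):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(samples[a], samples[b], equal_var=False)
        rows.append(
            {
                "feature": feature,
                "group_a": a,
                "group_b": b,
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def embed_2d(table: pd.DataFrame, feature_set="combined12", seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of z-scored features, for cluster visualization."""
    import umap  # deferred: numba JIT import is slow

    spec = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else feature_set
    if len(table) < 10:
        raise ValueError(f"need at least 10 rows to embed, got {len(table)}")
    x = StandardScaler().fit_transform(table[list(spec.columns)].to_numpy())
    reducer = umap.UMAP(n_components=2, random_state=int(seed),
                        n_neighbors=min(15, len(table) - 1))
    coords = reducer.fit_transform(x)
    return pd.DataFrame(
        {"umap1": coords[:, 0], "umap2": coords[:, 1], "group": table["group"].to_numpy()}
    )


def make_folds(y: np.ndarray, seed: int, n_folds: int = N_FOLDS,
               blocks: np.ndarray | None = None) -> np.ndarray:
    """Stratified fold assignment (test-fold index per row), seeded.

    When ``blocks`` is given (e.g. source field ids), all cells of a block are
    kept in the same fold — cells from one image are correlated, and letting
    them straddle the train/test split inflates accuracy estimates.
    """
    if blocks is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
        splits = skf.split(np.zeros((len(y), 1)), y)
    else:
        skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
        splits = skf.split(np.zeros((len(y), 1)), y, groups=np.asarray(blocks))
    assignment = np.full(len(y), -1, dtype=int)
    for k, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = k
    return assignment


def train_rft_pairwise(
    table: pd.DataFrame,
    class_a: str,
    class_b: str,
    feature_set="combined12",
    seed: int = 0,
    n_estimators: int = 500,
    fold_assignment: np.ndarray | None = None,
    min_cells: int = 25,
) -> ClassifierReport:
    """Stratified 5-fold cross-validated random forest for one class pair.

    Each fold trains on 80% of the cells and evaluates accuracy and ROC AUC on
    the held-out 20%; gini importances are averaged over folds.  Passing a
    precomputed ``fold_assignment`` lets several feature sets share identical
    folds, which the paired feature-set comparison requires.
    """
    spec = FEATURE_SETS[feature_set] if isinstance(feature_set, str) else feature_set
    sub = table[table["group"].isin([class_a, class_b])].reset_index(drop=True)
    for cls in (class_a, class_b):
        n = int((sub["group"] == cls).sum())
        if n < min_cells:
            raise ValueError(f"class {cls!r} has {n} cells; need at least {min_cells}")
    y = (sub["group"] == class_b).to_numpy().astype(int)
    x = sub[list(spec.columns)].to_numpy()
    if fold_assignment is None:
        fold_assignment = make_folds(y, seed)
    fold_assignment = np.asarray(fold_assignment)
    if fold_assignment.shape != y.shape:
        raise ValueError("fold_assignment length does not match the class pair's cells")

    accs, aucs, imps = [], [], []
    pooled_scores = np.zeros(len(y))
    for k in range(int(fold_assignment.max()) + 1):
        test = fold_assignment == k
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(seed) + k, n_jobs=1
        )
        clf.fit(x[~test], y[~test])
        scores = clf.predict_proba(x[test])[:, 1]
        pooled_scores[test] = scores
        accs.append(float(np.mean((scores >= 0.5).astype(int) == y[test])))
        aucs.append(float(roc_auc_score(y[test], scores)))
        imps.append(clf.feature_importances_)
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    return ClassifierReport(
        class_a=class_a,
        class_b=class_b,
        feature_set=spec.name,
        fold_accuracies=np.asarray(accs),
        fold_aucs=np.asarray(aucs),
        importances=dict(zip(spec.columns, np.mean(imps, axis=0))),
        roc_points={"fpr": fpr, "tpr": tpr},
        seed=int(seed),
        fold_assignment=fold_assignment.copy(),
        cell_ids=list(map(tuple, sub[["field_id", "cell_id"]].to_numpy())),
    )


def compare_feature_sets(
    report_a: ClassifierReport, report_b: ClassifierReport, metric: str = "accuracy",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Paired two-sided t-test across matched folds on accuracy or AUC.

    Requires both reports to have been produced on the same cells with the
    same fold assignment (otherwise a paired test is undefined).
    """
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    if report_a.cell_ids != report_b.cell_ids or not np.array_equal(
        report_a.fold_assignment, report_b.fold_assignment
    ):
        raise ValueError("reports have mismatched fold assignments; paired test undefined")
    a = report_a.fold_accuracies if metric == "accuracy" else report_a.fold_aucs
    b = report_b.fold_accuracies if metric == "accuracy" else report_b.fold_aucs
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    elif np.std(diffs, ddof=1) == 0:
        t, p = float(np.sign(diffs[0]) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    return ComparisonResult(
        metric=metric,
        feature_set_a=report_a.feature_set,
        feature_set_b=report_b.feature_set,
        values_a=tuple(float(v) for v in a),
        values_b=tuple(float(v) for v in b),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
    )


@dataclass
class SuiteResult:
    """All pairwise reports and feature-set comparisons for one dataset."""

    reports: dict  # (class_a, class_b) -> {feature_set: ClassifierReport}
    comparisons: list  # ((class_a, class_b), ComparisonResult)
    groups: list
    seed: int

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "seed": int(self.seed),
            "reports": {
                f"{a}__vs__{b}": {name: rep.to_dict() for name, rep in pair.items()}
                for (a, b), pair in self.reports.items()
            },
            "comparisons": [
                {"pair": [a, b], **res.to_dict()} for (a, b), res in self.comparisons
            ],
        }

    def summary_frame(self) -> pd.DataFrame:
        """One row per (pair, feature set) with mean accuracy and AUC."""
        rows = []
        for (a, b), pair in self.reports.items():
            for name, rep in pair.items():
                rows.append(
                    {
                        "class_a": a,
                        "class_b": b,
                        "feature_set": name,
                        "mean_accuracy": rep.mean_accuracy,
                        "mean_auc": rep.mean_auc,
                    }
                )
        return pd.DataFrame(rows)


def run_comparison_suite(table: pd.DataFrame, groups=None, seed: int = 0,
                         n_estimators: int = 500, group_by_field: bool = False) -> SuiteResult:
    """All pairwise classifiers x three feature sets, plus feature-set comparisons.

    For every unordered group pair the three feature sets share one fold
    assignment; decay8-vs-phasor4 and combined12-vs-each are compared by paired
    fold-wise t-tests on both accuracy and AUC.  ``group_by_field`` blocks CV
    folds by source field (off by default, matching cell-level analysis).
    """
    if groups is None:
        groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    reports = {}
    comparisons = []
    for a, b in itertools.combinations(groups, 2):
        sub = table[table["group"].isin([a, b])].reset_index(drop=True)
        y = (sub["group"] == b).to_numpy().astype(int)
        blocks = sub["field_id"].to_numpy() if group_by_field else None
        folds = make_folds(y, seed, blocks=blocks)
        pair_reports = {
            name: train_rft_pairwise(
                table, a, b, name, seed=seed, n_estimators=n_estimators,
                fold_assignment=folds,
            )
            for name in FEATURE_SETS
        }
        reports[(a, b)] = pair_reports
        for metric in ("accuracy", "auc"):
            for fs_a, fs_b in (
                ("decay8", "phasor4"),
                ("combined12", "decay8"),
                ("combined12", "phasor4"),
            ):
                comparisons.append(
                    ((a, b), compare_feature_sets(pair_reports[fs_a], pair_reports[fs_b], metric))
                )
    return SuiteResult(reports=reports, comparisons=comparisons, groups=list(groups),
                       seed=int(seed))
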