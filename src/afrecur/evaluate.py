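"""Evaluation protocol: fixed test set, bootstrap repetitions, metrics.

The protocol mirrors the study design:

1. a stratified test set (8 recurrence + 8 no-recurrence by default, ~22% of
   a 74-patient cohort) is drawn once and never touches feature selection,
   imputation, standardization or weight fitting;
2. the remaining patients are re-split per bootstrap repetition into 2/3
   training and 1/3 validation, stratified per class;
3. SFFS picks one feature subset per method (five single classifiers and
   three ensembles) from aggregated validation accuracy;
4. per repetition, models are refit on the training part, ensemble weights
   derived from validation votes, and the test set scored;
5. accuracy/sensitivity/specificity are averaged (mean +/- SD) over
   repetitions, the F1-score is computed from the element-wise averaged
   confusion matrix, ROC/AUC from pooled test scores, and feature-group
   usage summarises each method's chosen subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .data import AnalysisConfig, Cohort
from .ensembles import (awv_weights, ensemble_classify, grid_search_weights,
                        mean_voting_weights)
from .hrv import FEATURE_GROUPS, FEATURE_NAMES, GROUP_ORDER, extract_features
from .selection import SelectionTrace, sffs, single_classifier_objective
from .single import CLASSIFIER_KINDS, make_single_classifier

logger = logging.getLogger("afrecur")

ENSEMBLE_METHODS = ("mv", "awv", "owv")
ALL_METHODS = CLASSIFIER_KINDS + ENSEMBLE_METHODS


# ---------------------------------------------------------------------------
# split protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Fixed test ids plus per-repetition train/validation id lists."""

    test_ids: tuple[str, ...]
    repetitions: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int


def make_split(ids, labels, config: AnalysisConfig | None = None,
               seed: int | None = None) -> SplitPlan:
    """Draw the fixed stratified test set and the bootstrap repetitions.

    Per repetition and per class, ``round(n_class * validation_fraction)``
    of the non-test patients go to validation, the rest to training.
    Deterministic given the seed. With ``redraw_test_per_repetition`` the
    test set is redrawn each repetition (sensitivity analysis only).
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    ids = np.asarray(ids, dtype=object)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    n_test = {0: config.test_per_class[0], 1: config.test_per_class[1]}
    for cls in (0, 1):
        avail = int(np.count_nonzero(labels == cls))
        if avail < n_test[cls] + 3:
            raise ValueError(
                f"class {cls} too small: {avail} patients cannot supply "
                f"{n_test[cls]} test patients plus train/validation rows")

    def draw_test(r: np.random.Generator) -> np.ndarray:
        test = []
        for cls in (0, 1):
            members = np.flatnonzero(labels == cls)
            test.extend(r.choice(members, size=n_test[cls], replace=False))
        return np.sort(np.array(test))

    test_idx = draw_test(rng)
    reps = []
    for _ in range(config.n_repetitions):
        if config.redraw_test_per_repetition:
            test_idx = draw_test(rng)
        rest = np.setdiff1d(np.arange(ids.size), test_idx)
        train, val = [], []
        for cls in (0, 1):
            members = rest[labels[rest] == cls]
            n_val = int(round(members.size * config.validation_fraction))
            n_val = min(max(n_val, 1), members.size - 1)
            perm = rng.permutation(members)
            val.extend(perm[:n_val])
            train.extend(perm[n_val:])
        reps.append((tuple(ids[np.sort(np.array(train))]),
                     tuple(ids[np.sort(np.array(val))])))
    plan = SplitPlan(test_ids=tuple(ids[test_idx]), repetitions=tuple(reps),
                     seed=seed)
    logger.info("split plan: %d test patients, %d repetitions, seed=%d",
                len(plan.test_ids), len(plan.repetitions), seed)
    return plan


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix entries must be >= 0")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=float(np.count_nonzero((y_true == 1) & (y_pred == 1))),
            tn=float(np.count_nonzero((y_true == 0) & (y_pred == 0))),
            fp=float(np.count_nonzero((y_true == 0) & (y_pred == 1))),
            fn=float(np.count_nonzero((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV and F1 from a confusion
    matrix (recurrence = positive class); 0/0 ratios are NaN (logged)."""

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.info("metric %s undefined (zero denominator)", name)
            return float("nan")
        return num / den

    total = cm.tp + cm.tn + cm.fp + cm.fn
    return {
        "accuracy": ratio(cm.tp + cm.tn, total, "accuracy"),
        "sensitivity": ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "ppv": ratio(cm.tp, cm.tp + cm.fp, "ppv"),
        "f1": ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1"),
    }


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores) and trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}), auc


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """Everything the evaluation produces, ready for CSV export."""

    per_repetition: pd.DataFrame
    summary: pd.DataFrame
    averaged_confusion: pd.DataFrame
    roc_points: dict[str, pd.DataFrame]
    auc: dict[str, float]
    auc_per_repetition: dict[str, float]
    traces: dict[str, SelectionTrace]
    selected_features: dict[str, tuple[str, ...]]
    group_usage: pd.DataFrame
    weights: pd.DataFrame
    test_ids: tuple[str, ...]

    def to_dir(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.per_repetition.to_csv(path / "per_repetition.csv", index=False)
        self.summary.to_csv(path / "summary.csv")
        self.averaged_confusion.to_csv(path / "averaged_confusion.csv")
        self.group_usage.to_csv(path / "group_usage.csv")
        self.weights.to_csv(path / "weights.csv", index=False)
        for method, pts in self.roc_points.items():
            pts.to_csv(path / f"roc_{method}.csv", index=False)
        sizes = {m: pd.Series(t.accuracies, index=t.sizes)
                 for m, t in self.traces.items()}
        pd.DataFrame(sizes).rename_axis("subset_size").to_csv(
            path / "selection_accuracy_by_size.csv")
        sel = pd.DataFrame(
            [(m, ", ".join(f)) for m, f in self.selected_features.items()],
            columns=["method", "selected_features"])
        sel.to_csv(path / "selected_features.csv", index=False)
        with open(path / "summary.txt", "w") as fh:
            fh.write(self.format_summary())

    def format_summary(self) -> str:
        lines = ["Test-set performance (mean +/- SD over repetitions):", ""]
        for method in self.summary.index:
            row = self.summary.loc[method]
            lines.append(
                f"  {method:12s} accuracy {row['accuracy_mean']:.2f} +/- "
                f"{row['accuracy_sd']:.2f}  sensitivity "
                f"{row['sensitivity_mean']:.2f}  specificity "
                f"{row['specificity_mean']:.2f}  F1 {row['f1']:.2f}  "
                f"AUC {self.auc[method]:.2f}")
        lines += ["", "Selected features:"]
        for method, feats in self.selected_features.items():
            lines.append(f"  {method:12s} ({len(feats)}): {', '.join(feats)}")
        return "\n".join(lines) + "\n"


def _ensemble_objective(method: str, X: np.ndarray, y: np.ndarray, splits,
                        config: AnalysisConfig, seed: int,
                        vote_cache: dict | None = None):
    """Validation accuracy of one voting ensemble for a feature subset.

    ``vote_cache`` maps (subset, split index) to the five classifiers'
    validation votes so the three ensemble searches share fitted votes for
    subsets they all visit.
    """
    cache = {} if vote_cache is None else vote_cache

    def objective(subset: tuple[int, ...]) -> float:
        cols = list(subset)
        accs = []
        for s, (train_idx, val_idx) in enumerate(splits):
            key = (tuple(sorted(subset)), s)
            votes = cache.get(key)
            if votes is None:
                votes = np.empty((val_idx.size, len(CLASSIFIER_KINDS)))
                for j, kind in enumerate(CLASSIFIER_KINDS):
                    model = make_single_classifier(kind, config, seed)
                    model.fit(X[np.ix_(train_idx, cols)], y[train_idx])
                    votes[:, j] = model.predict(X[np.ix_(val_idx, cols)])
                cache[key] = votes
            y_val = y[val_idx]
            if method == "mv":
                pred, _ = ensemble_classify(mean_voting_weights(), votes)
                acc = float(np.mean(pred == y_val))
            elif method == "awv":
                single_acc = (votes == y_val[:, None]).mean(axis=0)
                pred, _ = ensemble_classify(awv_weights(single_acc), votes)
                acc = float(np.mean(pred == y_val))
            else:  # owv: best achievable grid accuracy on validation
                _, acc = grid_search_weights(votes, y_val, config.owv_step)
            accs.append(acc)
        return float(np.mean(accs))

    return objective


def run_experiment(cohort: Cohort | None = None,
                   config: AnalysisConfig | None = None,
                   features: pd.DataFrame | None = None,
                   seed: int | None = None) -> PerformanceReport:
    """Run the full selection + classification + evaluation pipeline.

    Either a cohort (features are extracted first) or a precomputed feature
    matrix (58 columns + ``recurrence``, from :func:`extract_features`) must
    be supplied.
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    if features is None:
        if cohort is None:
            raise ValueError("provide a cohort or a feature matrix")
        features = extract_features(cohort, config)
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing or "recurrence" not in features.columns:
        raise ValueError("feature matrix must contain the 58 canonical "
                         "features plus 'recurrence'")

    ids = np.asarray(features.index, dtype=object)
    y_all = features["recurrence"].to_numpy(dtype=int)
    X_all = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    pos = {pid: i for i, pid in enumerate(ids)}

    plan = make_split(ids, y_all, config, seed)
    test_rows = np.array([pos[p] for p in plan.test_ids])
    rep_rows = [
        (np.array([pos[p] for p in train]), np.array([pos[p] for p in val]))
        for train, val in plan.repetitions
    ]

    # --- feature selection: one SFFS per method on aggregated validation
    # accuracy over the first n_selection_repetitions splits (test rows are
    # structurally excluded: objectives only ever index train/val rows)
    sel_splits = rep_rows[: config.n_selection_repetitions]
    traces: dict[str, SelectionTrace] = {}
    for kind in CLASSIFIER_KINDS:
        obj = single_classifier_objective(kind, X_all, y_all, sel_splits,
                                          config, seed)
        traces[kind] = sffs(obj, X_all.shape[1], config.sffs_max_size,
                            feature_names=FEATURE_NAMES)
        logger.info("SFFS[%s]: %d features, validation accuracy %.3f", kind,
                    traces[kind].chosen_size, traces[kind].chosen_accuracy)
    vote_cache: dict = {}
    for method in ENSEMBLE_METHODS:
        obj = _ensemble_objective(method, X_all, y_all, sel_splits, config,
                                  seed, vote_cache)
        traces[method] = sffs(obj, X_all.shape[1], config.sffs_max_size,
                              feature_names=FEATURE_NAMES)
        logger.info("SFFS[%s]: %d features, validation accuracy %.3f", method,
                    traces[method].chosen_size, traces[method].chosen_accuracy)

    subsets = {m: list(traces[m].chosen_subset) for m in ALL_METHODS}
    y_test = y_all[test_rows]

    rows = []
    weight_rows = []
    pooled_scores: dict[str, list[np.ndarray]] = {m: [] for m in ALL_METHODS}
    owv_cached: np.ndarray | None = None
    for rep, (train_idx, val_idx) in enumerate(rep_rows):
        y_train, y_val = y_all[train_idx], y_all[val_idx]

        # single classifiers on their own subsets
        for kind in CLASSIFIER_KINDS:
            cols = subsets[kind]
            model = make_single_classifier(kind, config, seed).fit(
                X_all[np.ix_(train_idx, cols)], y_train)
            val_acc = float(np.mean(
                model.predict(X_all[np.ix_(val_idx, cols)]) == y_val))
            pred = model.predict(X_all[np.ix_(test_rows, cols)])
            score = model.decision_score(X_all[np.ix_(test_rows, cols)])
            cm = ConfusionMatrix.from_predictions(y_test, pred)
            rows.append({"method": kind, "repetition": rep,
                         "validation_accuracy": val_acc,
                         "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
                         **compute_metrics(cm)})
            pooled_scores[kind].append(score)

        # ensembles, each on its own SFFS subset
        for method in ENSEMBLE_METHODS:
            cols = subsets[method]
            models = [make_single_classifier(k, config, seed).fit(
                X_all[np.ix_(train_idx, cols)], y_train)
                for k in CLASSIFIER_KINDS]
            val_votes = np.column_stack(
                [m.predict(X_all[np.ix_(val_idx, cols)]) for m in models])
            if method == "mv":
                w = mean_voting_weights()
            elif method == "awv":
                w = awv_weights((val_votes == y_val[:, None]).mean(axis=0))
            else:
                if config.owv_per_repetition or owv_cached is None:
                    w, _ = grid_search_weights(val_votes, y_val, config.owv_step)
                    owv_cached = w
                else:
                    w = owv_cached
            val_pred, _ = ensemble_classify(w, val_votes)
            val_acc = float(np.mean(val_pred == y_val))
            test_votes = np.column_stack(
                [m.predict(X_all[np.ix_(test_rows, cols)]) for m in models])
            pred, score = ensemble_classify(w, test_votes)
            cm = ConfusionMatrix.from_predictions(y_test, pred)
            rows.append({"method": method, "repetition": rep,
                         "validation_accuracy": val_acc,
                         "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
                         **compute_metrics(cm)})
            pooled_scores[method].append(score)
            weight_rows.extend(
                {"method": method, "repetition": rep, "classifier": k,
                 "weight": float(wi)}
                for k, wi in zip(CLASSIFIER_KINDS, w))

    per_rep = pd.DataFrame(rows)

    # --- aggregation
    summary_rows = {}
    avg_cms = {}
    roc_points = {}
    auc_pooled = {}
    auc_mean = {}
    for method in ALL_METHODS:
        sub = per_rep[per_rep["method"] == method]
        avg_cm = ConfusionMatrix(tp=sub["tp"].mean(), tn=sub["tn"].mean(),
                                 fp=sub["fp"].mean(), fn=sub["fn"].mean())
        avg_cms[method] = avg_cm
        f1_avg = compute_metrics(avg_cm)["f1"]
        summary_rows[method] = {
            "accuracy_mean": sub["accuracy"].mean(),
            "accuracy_sd": sub["accuracy"].std(ddof=1),
            "sensitivity_mean": sub["sensitivity"].mean(),
            "sensitivity_sd": sub["sensitivity"].std(ddof=1),
            "specificity_mean": sub["specificity"].mean(),
            "specificity_sd": sub["specificity"].std(ddof=1),
            "validation_accuracy_mean": sub["validation_accuracy"].mean(),
            "f1": f1_avg,
        }
        scores = np.concatenate(pooled_scores[method])
        labels = np.tile(y_test, len(rep_rows))
        pts, auc = roc_auc(scores, labels)
        roc_points[method] = pts
        auc_pooled[method] = auc
        rep_aucs = [roc_auc(s, y_test)[1] for s in pooled_scores[method]
                    if np.unique(y_test).size == 2]
        auc_mean[method] = float(np.mean(rep_aucs))

    summary = pd.DataFrame(summary_rows).T
    summary.index.name = "method"
    avg_cm_frame = pd.DataFrame(
        {m: {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
         for m, c in avg_cms.items()}).T
    avg_cm_frame.index.name = "method"

    usage_rows = {}
    for method in ALL_METHODS:
        names = traces[method].subset_names()
        groups = [FEATURE_GROUPS[n] for n in names]
        usage_rows[method] = {
            g: 100.0 * groups.count(g) / len(groups) for g in GROUP_ORDER}
    group_usage = pd.DataFrame(usage_rows).T[list(GROUP_ORDER)]
    group_usage.index.name = "method"

    return PerformanceReport(
        per_repetition=per_rep,
        summary=summary,
        averaged_confusion=avg_cm_frame,
        roc_points=roc_points,
        auc=auc_pooled,
        auc_per_repetition=auc_mean,
        traces=traces,
        selected_features={m: traces[m].subset_names() for m in ALL_METHODS},
        group_usage=group_usage,
        weights=pd.DataFrame(weight_rows),
        test_ids=plan.test_ids,
    )


# ---------------------------------------------------------------------------
# group-comparison statistics
# ---------------------------------------------------------------------------

def compare_groups(features: pd.DataFrame, labels=None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-group comparison table.

    Continuous features: Shapiro-Wilk normality gate at ``alpha`` on each
    class; both normal -> unpaired t-test and mean +/- SD summaries,
    otherwise Mann-Whitney U and median (IQR). Binary features: Pearson
    chi-square on the 2x2 table. Constant features are skipped with a note.
    """
    if labels is None:
        if "recurrence" not in features.columns:
            raise ValueError("labels required (or a 'recurrence' column)")
        labels = features["recurrence"]
        features = features.drop(columns=["recurrence"])
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")

    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        g0, g1 = x[ok & (y == 0)], x[ok & (y == 1)]
        entry = {"feature": name, "n0": g0.size, "n1": g1.size}
        values = np.unique(x[ok])
        if values.size < 2:
            entry.update(test="skipped", statistic=np.nan, p_value=np.nan,
                         significant=False, note="constant feature")
            rows.append(entry)
            continue
        if set(values) <= {0.0, 1.0}:
            table = np.array([
                [np.count_nonzero(g0 == 1), np.count_nonzero(g0 == 0)],
                [np.count_nonzero(g1 == 1), np.count_nonzero(g1 == 0)],
            ])
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            entry.update(
                test="chi-square", statistic=float(chi2), p_value=float(p),
                summary0=f"{int(table[0, 0])} ({100 * table[0, 0] / g0.size:.1f}%)",
                summary1=f"{int(table[1, 0])} ({100 * table[1, 0] / g1.size:.1f}%)",
            )
        else:
            normal = all(
                g.size >= 3 and np.ptp(g) > 0 and stats.shapiro(g).pvalue > alpha
                for g in (g0, g1))
            if normal:
                stat, p = stats.ttest_ind(g0, g1, equal_var=True)
                entry.update(
                    test="t-test", statistic=float(stat), p_value=float(p),
                    summary0=f"{g0.mean():.2f} +/- {g0.std(ddof=1):.2f}",
                    summary1=f"{g1.mean():.2f} +/- {g1.std(ddof=1):.2f}",
                )
            else:
                stat, p = stats.mannwhitneyu(g0, g1, alternative="two-sided")
                iqr0 = np.percentile(g0, 75) - np.percentile(g0, 25)
                iqr1 = np.percentile(g1, 75) - np.percentile(g1, 25)
                entry.update(
                    test="mann-whitney", statistic=float(stat),
                    p_value=float(p),
                    summary0=f"{np.median(g0):.2f} ({iqr0:.2f})",
                    summary1=f"{np.median(g1):.2f} ({iqr1:.2f})",
                )
        entry["significant"] = bool(entry["p_value"] < alpha)
        rows.append(entry)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (accuracy-vs-subset-size and ROC)
# ---------------------------------------------------------------------------

def plot_report(report: PerformanceReport, out_dir) -> list[str]:
    """Render the accuracy-vs-feature-count and ROC figures as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for method, trace in report.traces.items():
        ax.plot(trace.sizes, trace.accuracies, marker="o", ms=3, label=method)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("validation accuracy")
    ax.set_title("SFFS validation accuracy by subset size")
    ax.legend(fontsize=8)
    path = out_dir / "accuracy_by_subset_size.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5.5, 5))
    for method, pts in report.roc_points.items():
        ax.plot(pts["fpr"], pts["tpr"],
                label=f"{method} (AUC {report.auc[method]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title("ROC, pooled test scores")
    ax.legend(fontsize=8)
    path = out_dir / "roc.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))
    return written
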