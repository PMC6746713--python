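"""Leave-one-subject-out screening pipeline.

Each LOSO iteration holds one subject out, balances the remaining subjects'
session feature vectors by random under-sampling, runs a nested 5-fold
cross-validation (folds grouped by subject) in which each fold performs
select-k-best ANOVA-F feature selection and grid-search hyperparameter
tuning, adopts the (features, hyperparameters) pair of the fold with the
highest held-out AUC of subject-mean probabilities, refits on the full
balanced training pool, and finally scores every session of the held-out
subject.  The subject's screening score is the arithmetic mean of their
session probabilities.

The public surface follows the estimator/results idiom:

>>> model = ScreeningModel(feature_table, labels, PipelineConfig(seed=7))
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluate import RocSummary, auc_mann_whitney, bootstrap_roc, youden_operating_point
from .evaluate import _labels_to_series

__all__ = [
    "PipelineConfig",
    "IterationRecord",
    "ScreeningModel",
    "ScreeningResults",
    "balance_training_sessions",
    "nested_select_and_tune",
    "fit_final_model",
    "predict_subject",
    "run_loso",
    "selection_frequency_report",
    "DEFAULT_GRIDS",
]

_META_COLUMNS = ("subject_id", "session_id", "day_index")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    "gradient_boosting": {"learning_rate": [0.05, 0.1], "n_estimators": [100, 300]},
    "svm": {"C": [0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the LOSO pipeline.

    ``subject_folds`` keeps inner folds grouped by subject (no subject
    straddles a fold boundary); ``winner_fold_rule`` adopts the single best
    fold's selection literally, while ``False`` tunes on the mean AUC across
    folds.  ``grid=None`` uses the classifier's default grid.
    """

    classifier: str = "random_forest"
    k_best: int = 5
    n_folds: int = 5
    grid: Mapping[str, list] | None = None
    seed: int = 0
    balance: bool = True
    subject_folds: bool = True
    winner_fold_rule: bool = True
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k_best < 1:
            raise ValueError("k_best must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.classifier not in DEFAULT_GRIDS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; "
                f"choose from {sorted(DEFAULT_GRIDS)}"
            )

    @property
    def effective_grid(self) -> dict[str, list]:
        return dict(self.grid) if self.grid is not None else DEFAULT_GRIDS[self.classifier]


def _make_classifier(name: str, params: Mapping, seed: int):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.svm import SVC

    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", probability=True,
                   random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


def balance_training_sessions(
    rows: pd.DataFrame, labels01: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Under-sample the majority class to the minority session count (seeded).

    Row order of the output is a seeded shuffle; the original index is kept so
    row identity is traceable.
    """
    y = rows["subject_id"].map(labels01)
    pos = rows[y == 1]
    neg = rows[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present in the training sessions")
    m = min(len(pos), len(neg))
    take_pos = _undersample(pos, m, rng)
    take_neg = _undersample(neg, m, rng)
    out = pd.concat([take_pos, take_neg])
    return out.iloc[rng.permutation(len(out))]


def _undersample(rows: pd.DataFrame, m: int, rng: np.random.Generator) -> pd.DataFrame:
    """Random subsample of size m, allocated proportionally per subject so
    the under-sampling never silently drops a training subject."""
    if m >= len(rows):
        return rows
    sizes = rows.groupby("subject_id").size()
    # largest-remainder proportional quotas, at least one row per subject
    exact = sizes * m / len(rows)
    quotas = np.maximum(np.floor(exact).astype(int), 1)
    remainders = (exact - np.floor(exact)).sort_values(ascending=False)
    for s in remainders.index:
        if quotas.sum() >= m:
            break
        quotas[s] += 1
    while quotas.sum() > m:  # trim overshoot from the largest contributors
        s = quotas.idxmax()
        quotas[s] -= 1
    parts = []
    for s, q in quotas.items():
        g = rows[rows["subject_id"] == s]
        parts.append(g.iloc[rng.choice(len(g), size=min(q, len(g)), replace=False)])
    return pd.concat(parts)


def _subject_fold_assignments(
    rows: pd.DataFrame, labels01: pd.Series, cfg: PipelineConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Positional row indices of each inner fold's held-out portion.

    Folds are subject-grouped by default.  A permutation is retried (up to 10
    times) until every fold's held-out and training portions contain both
    classes.
    """
    n_folds = cfg.n_folds
    y_rows = rows["subject_id"].map(labels01).to_numpy()

    for _ in range(10):
        if cfg.subject_folds:
            subjects = np.array(sorted(rows["subject_id"].unique()))
            if len(subjects) < n_folds:
                raise ValueError(
                    f"need at least {n_folds} training subjects for "
                    f"{n_folds}-fold inner cross-validation, got {len(subjects)}"
                )
            # stratified deal: shuffle each class's subjects, then assign
            # round-robin so every fold mixes classes whenever possible
            groups: list[list] = [[] for _ in range(n_folds)]
            slot = 0
            for cls in (1, 0):
                cls_subjects = np.array(
                    [s for s in subjects if labels01[s] == cls]
                )
                for s in cls_subjects[rng.permutation(len(cls_subjects))]:
                    groups[slot % n_folds].append(s)
                    slot += 1
            folds = [
                np.flatnonzero(rows["subject_id"].isin(g).to_numpy()) for g in groups
            ]
        else:
            perm = rng.permutation(len(rows))
            folds = [np.asarray(f) for f in np.array_split(perm, n_folds)]
        ok = True
        for f in folds:
            test_y = y_rows[f]
            train_mask = np.ones(len(rows), dtype=bool)
            train_mask[f] = False
            train_y = y_rows[train_mask]
            if len(np.unique(test_y)) < 2 or len(np.unique(train_y)) < 2:
                ok = False
                break
        if ok:
            return folds
    raise ValueError(
        "could not build inner folds with both classes in every fold "
        "after 10 seeded permutations"
    )


def _fit_and_score_fold(
    rows, y_rows, fold_test_idx, feature_names, cfg, rng_seed
):
    """One inner fold: selection on the fold-train portion, grid search scored
    by held-out subject-mean AUC.  Returns (selected, best_params, best_auc)."""
    from sklearn.feature_selection import SelectKBest, f_classif
    from sklearn.preprocessing import StandardScaler

    train_mask = np.ones(len(rows), dtype=bool)
    train_mask[fold_test_idx] = False
    tr = rows.iloc[train_mask.nonzero()[0]]
    te = rows.iloc[fold_test_idx]
    y_tr = y_rows[train_mask]

    k = min(cfg.k_best, len(feature_names))
    scaler = StandardScaler().fit(tr[feature_names])
    X_tr = scaler.transform(tr[feature_names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield harmless F warnings
        selector = SelectKBest(f_classif, k=k).fit(X_tr, y_tr)
    selected = [feature_names[i] for i in selector.get_support(indices=True)]

    sel_scaler = StandardScaler().fit(tr[selected])
    X_sel_tr = sel_scaler.transform(tr[selected])
    X_sel_te = sel_scaler.transform(te[selected])

    te_subjects = te["subject_id"].to_numpy()
    y_te = y_rows[fold_test_idx]
    subj_order = pd.unique(te_subjects)
    subj_labels = pd.Series(y_te, index=te_subjects).groupby(level=0).first()

    best = None
    for combo in _grid_combinations(cfg.effective_grid):
        clf = _make_classifier(cfg.classifier, combo, rng_seed)
        clf.fit(X_sel_tr, y_tr)
        probs = clf.predict_proba(X_sel_te)[:, 1]
        means = pd.Series(probs, index=te_subjects).groupby(level=0).mean()
        auc = auc_mann_whitney(
            means.loc[subj_order].to_numpy(),
            subj_labels.loc[subj_order].to_numpy(),
        )
        if best is None or auc > best[0]:
            best = (auc, combo)
    return selected, best[1], best[0]


def _grid_combinations(grid: Mapping[str, list]):
    keys = sorted(grid)
    for values in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, values))


def nested_select_and_tune(
    train_rows: pd.DataFrame,
    labels01: pd.Series,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[list[str], dict, float]:
    """Nested k-fold feature selection and hyperparameter tuning.

    Returns (selected feature names, hyperparameters, winning fold AUC).
    Under the winner-fold rule the pair from the fold with the highest
    held-out AUC is adopted (ties: lowest fold index); otherwise the
    hyperparameters maximising the mean AUC across folds are adopted together
    with the most frequently selected features.
    """
    feature_names = _feature_columns(train_rows)
    y_rows = train_rows["subject_id"].map(labels01).to_numpy()
    folds = _subject_fold_assignments(train_rows, labels01, cfg, rng)
    clf_seed = int(rng.integers(0, 2**31 - 1))

    records = [
        _fit_and_score_fold(train_rows, y_rows, f, feature_names, cfg, clf_seed)
        for f in folds
    ]
    if cfg.winner_fold_rule:
        aucs = [r[2] for r in records]
        winner = int(np.argmax(aucs))  # argmax takes the lowest index on ties
        selected, params, auc = records[winner]
        return selected, params, auc

    # mean-across-folds mode: modal features, then best mean-AUC hyperparameters
    from collections import Counter

    counts = Counter()
    for sel, _, _ in records:
        counts.update(sel)
    k = min(cfg.k_best, len(feature_names))
    selected = [name for name, _ in counts.most_common(k)]
    mean_scores = []
    for combo in _grid_combinations(cfg.effective_grid):
        scores = []
        for f in folds:
            scores.append(
                _score_combo_on_fold(
                    train_rows, y_rows, f, selected, combo, cfg, clf_seed
                )
            )
        mean_scores.append((float(np.mean(scores)), combo))
    best_auc, best_params = max(mean_scores, key=lambda t: t[0])
    return selected, best_params, best_auc


def _score_combo_on_fold(rows, y_rows, fold_test_idx, selected, combo, cfg, seed):
    from sklearn.preprocessing import StandardScaler

    train_mask = np.ones(len(rows), dtype=bool)
    train_mask[fold_test_idx] = False
    tr, te = rows.iloc[train_mask.nonzero()[0]], rows.iloc[fold_test_idx]
    scaler = StandardScaler().fit(tr[selected])
    clf = _make_classifier(cfg.classifier, combo, seed)
    clf.fit(scaler.transform(tr[selected]), y_rows[train_mask])
    probs = clf.predict_proba(scaler.transform(te[selected]))[:, 1]
    te_subjects = te["subject_id"].to_numpy()
    means = pd.Series(probs, index=te_subjects).groupby(level=0).mean()
    labs = pd.Series(y_rows[fold_test_idx], index=te_subjects).groupby(level=0).first()
    return auc_mann_whitney(means.to_numpy(), labs.loc[means.index].to_numpy())


@dataclass
class FittedModel:
    """A trained per-iteration model: standardizer + classifier + features."""

    classifier: object
    scaler: object
    selected: list[str]
    params: dict

    @property
    def importances(self) -> dict[str, float] | None:
        imp = getattr(self.classifier, "feature_importances_", None)
        if imp is None:
            return None
        return dict(zip(self.selected, map(float, imp)))

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(rows[self.selected])
        return self.classifier.predict_proba(X)[:, 1]


def fit_final_model(
    train_rows: pd.DataFrame,
    labels01: pd.Series,
    selected: list[str],
    params: dict,
    cfg: PipelineConfig,
    seed: int,
) -> FittedModel:
    """Fit the final iteration model on all balanced training rows.

    Standardization parameters are fit on the training rows only and stored
    with the model; features that are constant in training are dropped with a
    warning (their z-scores are undefined).
    """
    from sklearn.preprocessing import StandardScaler

    usable = []
    for f in selected:
        if train_rows[f].nunique() <= 1:
            warnings.warn(f"dropping constant training feature {f!r}")
        else:
            usable.append(f)
    if not usable:
        raise ValueError("no non-degenerate features left to fit")
    y = train_rows["subject_id"].map(labels01).to_numpy()
    scaler = StandardScaler().fit(train_rows[usable])
    clf = _make_classifier(cfg.classifier, params, seed)
    clf.fit(scaler.transform(train_rows[usable]), y)
    return FittedModel(classifier=clf, scaler=scaler, selected=usable, params=dict(params))


def predict_subject(model: FittedModel, subject_rows: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Session probabilities (chronological row order) and their mean."""
    if len(subject_rows) == 0:
        raise ValueError("no valid sessions to predict for this subject")
    probs = model.predict_proba(subject_rows)
    return probs, float(probs.mean())


@dataclass
class IterationRecord:
    test_subject: str
    selected: list[str]
    params: dict
    inner_auc: float
    importances: dict[str, float] | None
    train_row_ids: np.ndarray = field(repr=False)


def run_loso(
    feature_table: pd.DataFrame,
    labels,
    cfg: PipelineConfig | None = None,
) -> "ScreeningResults":
    """Run the full LOSO pipeline; one iteration per subject.

    ``feature_table`` holds one session per row (``subject_id``,
    ``session_id``, ``day_index`` plus feature columns); ``labels`` maps
    subjects to DT/HC (or 1/0).  Every random draw derives from ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    labels01 = _labels_to_series(labels)
    table = feature_table.reset_index(drop=True)
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    missing = [s for s in subjects if s not in labels01.index]
    if missing:
        raise ValueError(f"subjects without labels: {missing}")
    y_subj = labels01.loc[subjects]
    if y_subj.nunique() < 2:
        raise ValueError("cohort has a single class; screening is undefined")

    seed_seqs = np.random.SeedSequence(cfg.seed).spawn(len(subjects))
    iterations: list[IterationRecord] = []
    session_rows = []
    for subject, sseq in zip(subjects, seed_seqs):
        rng = np.random.default_rng(sseq)
        test_rows = table[table["subject_id"] == subject]
        train_pool = table[table["subject_id"] != subject]
        if cfg.balance:
            train_rows = balance_training_sessions(train_pool, labels01, rng)
        else:
            train_rows = train_pool
        # leakage guard: held-out rows must not appear in the training pool
        overlap = np.intersect1d(train_rows.index.to_numpy(), test_rows.index.to_numpy())
        if len(overlap):
            raise AssertionError(
                f"leakage: test subject rows {overlap[:5]} present in training pool"
            )
        selected, params, inner_auc = nested_select_and_tune(
            train_rows, labels01, cfg, rng
        )
        model = fit_final_model(
            train_rows, labels01, selected, params, cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        probs, _mean = predict_subject(model, test_rows)
        iterations.append(
            IterationRecord(
                test_subject=subject,
                selected=list(model.selected),
                params=dict(params),
                inner_auc=float(inner_auc),
                importances=model.importances,
                train_row_ids=train_rows.index.to_numpy(),
            )
        )
        for (_, row), p in zip(test_rows.iterrows(), probs):
            session_rows.append(
                {"subject_id": subject, "session_id": row["session_id"],
                 "day_index": int(row["day_index"]), "prob": float(p)}
            )

    session_table = pd.DataFrame(
        session_rows, columns=["subject_id", "session_id", "day_index", "prob"]
    )
    return ScreeningResults(
        session_table=session_table,
        labels01=y_subj,
        iterations=iterations,
        config=cfg,
        feature_names=_feature_columns(table),
    )


def selection_frequency_report(
    iterations: list[IterationRecord],
    feature_names: list[str],
    consistency_threshold: float = 90.0,
) -> pd.DataFrame:
    """Per-feature selection frequency and impurity importance over iterations.

    Importance statistics are averaged only over the iterations in which the
    feature was selected; never-selected features report NaN importances.
    Features selected in at least ``consistency_threshold`` percent of
    iterations are flagged as consistently selected.
    """
    if not iterations:
        raise ValueError("no LOSO iterations to report on")
    n = len(iterations)
    rows = []
    for f in feature_names:
        hits = [it for it in iterations if f in it.selected]
        freq = 100.0 * len(hits) / n
        imps = [it.importances[f] for it in hits
                if it.importances is not None and f in it.importances]
        rows.append(
            {"feature": f,
             "times_selected_pct": freq,
             "importance_mean": float(np.mean(imps)) if imps else np.nan,
             "importance_std": float(np.std(imps)) if imps else np.nan,
             "consistent": freq >= consistency_threshold}
        )
    return pd.DataFrame(rows)


@dataclass
class ScreeningResults:
    """LOSO results: per-session probabilities, subject means and diagnostics."""

    session_table: pd.DataFrame
    labels01: pd.Series
    iterations: list[IterationRecord]
    config: PipelineConfig
    feature_names: list[str] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.labels01.index)

    @property
    def subject_means(self) -> pd.Series:
        return (
            self.session_table.groupby("subject_id")["prob"].mean()
            .reindex(self.subject_ids)
        )

    @property
    def y_true(self) -> np.ndarray:
        return self.labels01.to_numpy()

    def session_probs(self, subject_id: str) -> np.ndarray:
        t = self.session_table
        return t.loc[t["subject_id"] == subject_id, "prob"].to_numpy()

    @property
    def auc(self) -> float:
        return auc_mann_whitney(self.subject_means.to_numpy(), self.y_true)

    def decisions(self, threshold: float | None = None) -> pd.Series:
        thr = self.config.decision_threshold if threshold is None else threshold
        return (self.subject_means >= thr).map({True: "DT", False: "HC"})

    def bootstrap_roc(self, n_boot: int = 1000, seed: int | None = None) -> RocSummary:
        if seed is None:
            seed = self.config.seed
        return bootstrap_roc(
            self.subject_means.to_numpy(), self.y_true, n_boot=n_boot, seed=seed
        )

    def youden(self) -> tuple[float, float, float]:
        return youden_operating_point(self.subject_means.to_numpy(), self.y_true)

    def selection_frequency(self, consistency_threshold: float = 90.0) -> pd.DataFrame:
        names = self.feature_names or sorted(
            {f for it in self.iterations for f in it.selected}
        )
        return selection_frequency_report(
            self.iterations, names, consistency_threshold
        )

    def summary(self, n_boot: int = 1000) -> str:
        """Human-readable results table (AUC with bootstrap CI, per-subject scores)."""
        roc = self.bootstrap_roc(n_boot=n_boot)
        thr, sens, spec = self.youden()
        lines = [
            "LOSO depressive-tendency screening results",
            "=" * 58,
            f"classifier: {self.config.classifier}   k_best: {self.config.k_best}"
            f"   folds: {self.config.n_folds}   seed: {self.config.seed}",
            f"subjects: {len(self.subject_ids)} "
            f"(DT {int(self.y_true.sum())} / HC {int((1 - self.y_true).sum())})"
            f"   sessions: {len(self.session_table)}",
            f"point AUC: {self.auc:.3f}",
            f"bootstrap AUC: {roc.mean_auc:.3f} "
            f"[{roc.ci_low:.3f}-{roc.ci_high:.3f}; 95% CI, {n_boot} bootstraps]",
            f"Youden threshold: {thr:.3f}  sensitivity: {sens:.2f}  "
            f"specificity: {spec:.2f}",
            "-" * 58,
            f"{'subject':<12}{'label':>6}{'mean prob':>12}{'decision':>10}",
        ]
        dec = self.decisions(thr)
        for s in self.subject_ids:
            lab = "DT" if self.labels01[s] == 1 else "HC"
            lines.append(f"{s:<12}{lab:>6}{self.subject_means[s]:>12.3f}{dec[s]:>10}")
        sel = self.selection_frequency()
        consistent = sel[sel["consistent"]]["feature"].tolist()
        lines.append("-" * 58)
        lines.append(f"consistently selected features (>=90%): {', '.join(consistent) or '-'}")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": {
                "classifier": self.config.classifier,
                "k_best": self.config.k_best,
                "n_folds": self.config.n_folds,
                "seed": self.config.seed,
                "balance": self.config.balance,
            },
            "labels": {s: int(v) for s, v in self.labels01.items()},
            "sessions": self.session_table.to_dict(orient="records"),
            "iterations": [
                {"test_subject": it.test_subject, "selected": it.selected,
                 "params": {k: v for k, v in it.params.items()},
                 "inner_auc": it.inner_auc, "importances": it.importances}
                for it in self.iterations
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "ScreeningResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        c = payload["config"]
        cfg = PipelineConfig(
            classifier=c["classifier"], k_best=c["k_best"], n_folds=c["n_folds"],
            seed=c["seed"], balance=c["balance"],
        )
        iterations = [
            IterationRecord(
                test_subject=it["test_subject"], selected=it["selected"],
                params=it["params"], inner_auc=it["inner_auc"],
                importances=it["importances"], train_row_ids=np.array([]),
            )
            for it in payload["iterations"]
        ]
        return cls(
            session_table=pd.DataFrame(payload["sessions"]),
            labels01=pd.Series(payload["labels"]).astype(int),
            iterations=iterations,
            config=cfg,
        )


class ScreeningModel:
    """Subject screening model over a session feature table.

    Parameters
    ----------
    feature_table : DataFrame
        One session per row; ``subject_id``, ``session_id``, ``day_index``
        plus feature columns (canonically the 20 session features).
    labels : DataFrame, Series or mapping
        Subject group labels (DT/HC strings or 1/0).
    config : PipelineConfig, optional
    """

    def __init__(self, feature_table: pd.DataFrame, labels, config: PipelineConfig | None = None):
        self.feature_table = feature_table.reset_index(drop=True)
        self.labels = _labels_to_series(labels)
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(cls, features_path, labels_path, config: PipelineConfig | None = None):
        features = pd.read_csv(features_path)
        labels = pd.read_csv(labels_path)
        return cls(features, labels, config)

    def fit(self) -> ScreeningResults:
        """Run the LOSO pipeline and return the results object."""
        return run_loso(self.feature_table, self.labels, self.config)
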