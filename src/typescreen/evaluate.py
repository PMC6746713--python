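"""Performance evaluation: bootstrap ROC, Youden operating point, group tests.

The decision unit throughout is the *subject*: each subject carries one score
(the mean of their per-session probabilities) and one binary label (DT = 1,
HC = 0).  AUC is computed by the rank (Mann-Whitney) formulation, confidence
intervals by resampling subjects with replacement, and operating points by
maximising the Youden index J = sensitivity + specificity - 1 under equal
misclassification cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocSummary",
    "auc_mann_whitney",
    "bootstrap_roc",
    "youden_operating_point",
    "groupwise_feature_tests",
    "correlation_with_phq9",
    "covariate_logistic_test",
]


def auc_mann_whitney(scores, labels) -> float:
    """AUC by the rank formulation (ties counted half).

    Equals the probability that a random positive outscores a random
    negative, with ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximising J = sens + spec - 1.

    The decision rule is ``score >= threshold -> positive``; the sweep runs
    over all distinct observed scores.  Ties in J are broken by higher
    sensitivity, then by lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    best = None
    for thr in np.unique(scores):
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        key = (j, sens, -thr)
        if best is None or key > best[0]:
            best = (key, (float(thr), sens, spec))
    return best[1]


@dataclass
class RocSummary:
    """Bootstrap ROC summary at the subject level."""

    mean_auc: float
    ci_low: float
    ci_high: float
    threshold: float
    sensitivity: float
    specificity: float
    n_bootstraps: int
    point_auc: float
    fpr_grid: np.ndarray = field(repr=False)
    mean_tpr: np.ndarray = field(repr=False)
    auc_samples: np.ndarray = field(repr=False)

    @property
    def mean_curve(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr_grid.tolist(), self.mean_tpr.tolist()))


def _roc_tpr_on_grid(scores, labels, grid):
    """TPR at fixed FPR values (vertical averaging support)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    tpr_interp = np.interp(grid, fpr, tpr)
    tpr_interp[0] = 0.0
    return tpr_interp


def bootstrap_roc(
    subject_scores,
    labels,
    n_boot: int = 1000,
    seed: int | None = None,
    resample: bool = True,
    grid_size: int = 101,
) -> RocSummary:
    """Bootstrap the subject-level ROC curve.

    Subjects are resampled with replacement per replicate; single-class
    replicates are redrawn.  The mean curve is obtained by vertical averaging
    of per-replicate TPR on a fixed FPR grid, the CI is the 2.5/97.5
    percentile of the AUC samples, and the operating point is the Youden
    maximiser on the original (unresampled) sample.  ``resample=False`` makes
    every replicate the identity sample (diagnostic use).
    """
    scores = np.asarray(subject_scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(scores)
    if np.sum(labels == 1) < 2 or np.sum(labels == 0) < 2:
        raise ValueError("need at least two subjects per class for the bootstrap")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_size)
    aucs = np.empty(n_boot)
    tprs = np.empty((n_boot, grid_size))
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n) if resample else np.arange(n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        sc = scores[idx]
        aucs[b] = auc_mann_whitney(sc, lab)
        tprs[b] = _roc_tpr_on_grid(sc, lab, grid)
    thr, sens, spec = youden_operating_point(scores, labels)
    return RocSummary(
        mean_auc=float(aucs.mean()),
        ci_low=float(np.percentile(aucs, 2.5)),
        ci_high=float(np.percentile(aucs, 97.5)),
        threshold=thr,
        sensitivity=sens,
        specificity=spec,
        n_bootstraps=n_boot,
        point_auc=auc_mann_whitney(scores, labels),
        fpr_grid=grid,
        mean_tpr=tprs.mean(axis=0),
        auc_samples=aucs,
    )


def groupwise_feature_tests(
    feature_table: pd.DataFrame,
    labels: pd.DataFrame | dict,
    feature_names: list[str] | None = None,
    exact_max_n: int = 12,
    correct: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U tests on per-subject feature means.

    Sessions are first averaged within subject, so each subject contributes
    one observation per feature.  The exact null distribution is used when
    both groups have at most ``exact_max_n`` subjects and the data are
    tie-free; otherwise the normal approximation with tie correction.
    Raw p-values are reported; ``correct=True`` adds a Benjamini-Hochberg
    column.
    """
    lab = _labels_to_series(labels)
    if feature_names is None:
        feature_names = [
            c for c in feature_table.columns
            if c not in ("subject_id", "session_id", "day_index")
        ]
    means = feature_table.groupby("subject_id")[feature_names].mean()
    lab = lab.reindex(means.index)
    g1 = means[lab == 1]
    g0 = means[lab == 0]
    rows = []
    for f in feature_names:
        x, y = g1[f].to_numpy(), g0[f].to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append({"feature": f, "u": np.nan, "p": np.nan, "skipped": True})
            continue
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= exact_max_n and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {"feature": f, "u": float(res.statistic), "p": float(res.pvalue),
             "skipped": False}
        )
    out = pd.DataFrame(rows)
    if correct:
        from statsmodels.stats.multitest import multipletests

        ok = ~out["p"].isna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adj_bh"] = adj
    return out


def correlation_with_phq9(subject_values, phq9_scores) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p) across subjects.

    Returns (nan, nan) with a warning when either vector is constant.
    """
    x = np.asarray(subject_values, dtype=float)
    y = np.asarray(phq9_scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def covariate_logistic_test(table: pd.DataFrame, outcome: str = "group") -> pd.DataFrame:
    """Logistic regression of group status on prediction and demographics.

    ``table`` holds one row per subject with the binary outcome column and
    the covariates (typically: prediction probability, age, education, gender,
    convergence session count, sessions per day).  Categorical covariates
    must already be numerically coded.  Returns a coefficient table (constant
    first) with Wald z statistics and two-sided p-values; non-convergence
    (e.g. perfect separation) is flagged via the ``converged`` attribute in
    ``DataFrame.attrs`` and a warning.
    """
    import statsmodels.api as sm

    y = table[outcome].astype(int)
    X = table.drop(columns=[outcome]).astype(float)
    X = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in statsmodels
            warnings.warn(f"logistic fit did not converge cleanly: {exc}")
            fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
            converged = False
    out = pd.DataFrame(
        {"estimate": fit.params, "std_error": fit.bse,
         "z": fit.tvalues, "p": fit.pvalues}
    )
    if not converged:
        warnings.warn("logistic regression flagged as non-converged "
                      "(possible perfect separation); interpret with care")
    out.attrs["converged"] = converged
    return out


def _labels_to_series(labels) -> pd.Series:
    """Normalise label input to a subject-indexed 0/1 series (DT = 1)."""
    if isinstance(labels, pd.DataFrame):
        s = labels.set_index("subject_id")["label"]
    elif isinstance(labels, pd.Series):
        s = labels
    else:
        s = pd.Series(dict(labels))
    if s.dtype == object:
        s = s.map({"DT": 1, "HC": 0})
    return s.astype(int)
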