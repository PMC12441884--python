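"""Cohort-level statistics: group comparisons, logistic classifiers and ROC.

Reproduces the statistical layer of an MR-cytometry subtyping study: rank-sum
and Kruskal-Wallis comparisons of each imaging metric, single- and
multi-variable logistic regression classifiers for IHC factor status (ER, PR,
HER2, Ki67) and one-vs-rest molecular subtype, with apparent (in-sample) AUC
and stratified percentile-bootstrap 95% confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import DataError

__all__ = [
    "MannWhitneyResult",
    "KruskalResult",
    "ClassifierReport",
    "SubtypeReport",
    "FEATURE_SETS",
    "mann_whitney",
    "kruskal_wallis",
    "auc_midrank",
    "roc_points",
    "logistic_roc",
    "ihc_report",
    "subtype_report",
]

IHC_TARGETS = ("ER", "PR", "HER2", "Ki67")
SUBTYPE_TARGETS = ("TNBC", "HER2", "LuminalA", "LuminalB")

#: Classifier feature sets: all ADC metrics for the time-dependent-dMRI
#: classifier, and all fitted parameters (plus cellularity) per model.
FEATURE_SETS: dict[str, list[str]] = {
    "td-dMRI": ["adc_pgse", "adc_25hz", "adc_50hz", "delta_adc"],
    "IMPULSED": ["impulsed_d", "impulsed_v_in", "impulsed_d_ex",
                 "impulsed_d_in", "impulsed_cellularity"],
    "JOINT": ["joint_d", "joint_v_in", "joint_k_in", "joint_d_ex",
              "joint_cellularity"],
    "EXCHANGE": ["exchange_d", "exchange_v_in", "exchange_k_in",
                 "exchange_d_ex", "exchange_cellularity"],
}


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first sample
    p_value: float
    all_tied: bool = False


@dataclass(frozen=True)
class KruskalResult:
    statistic: float  # tie-corrected H
    p_value: float
    all_tied: bool = False


@dataclass
class ClassifierReport:
    """One logistic-regression classifier: apparent AUC with bootstrap CI."""

    target: str
    features: tuple[str, ...]
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    p_wald: float
    p_lr: float
    coefficients: np.ndarray
    separation: bool = False
    n_boot: int = 0


@dataclass
class SubtypeReport:
    auc_table: pd.DataFrame
    kruskal_table: pd.DataFrame


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (both n <= 8), otherwise the
    tie-corrected normal approximation.  All-tied data return p = 1 flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(a.size * b.size / 2.0, 1.0, all_tied=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups: Sequence) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, all_tied=True)
    h, p = sps.kruskal(*groups)
    return KruskalResult(float(h), float(p))


def auc_midrank(scores, y) -> float:
    """AUC as the normalized Mann-Whitney statistic P(s+ > s-) + P(=)/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs both classes present")
    ranks = sps.rankdata(scores)
    return float((np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_points(scores, y) -> pd.DataFrame:
    """ROC curve (fpr, tpr, threshold) over all score thresholds."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    order = np.argsort(-scores, kind="stable")
    s, lab = scores[order], (y[order] == 1)
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    tps = np.cumsum(lab)
    fps = np.cumsum(~lab)
    # keep the last point of each tied-score block
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    thr = np.r_[np.inf, s[keep]]
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

_BETA_CAP = 30.0


def _newton_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 40,
                     tol: float = 1e-10) -> np.ndarray:
    """Unregularized ML logistic fit (IRLS); X already carries the intercept.

    Coefficients are capped at +/-30 on the standardized-internal scale used
    by the caller, which is where quasi-separated bootstrap resamples end up.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        H.flat[:: H.shape[0] + 1] += 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = np.clip(beta + step, -_BETA_CAP, _BETA_CAP)
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def logistic_roc(
    features,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    stratified: bool = True,
    target: str = "",
    feature_names: Sequence[str] | None = None,
) -> ClassifierReport:
    """Unregularized logistic classifier with apparent ROC/AUC and bootstrap CI.

    The AUC is the rank statistic of the fitted probabilities (apparent,
    in-sample).  The CI is a stratified percentile bootstrap (``n_boot``
    resamples, seeded).  The reported p-value is the Wald test of the slope
    for single-feature models and the likelihood-ratio test against the
    intercept-only model for combined models.  Perfect separation is flagged
    and returns AUC 1.0 with unreliable coefficients.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("features and labels disagree in length")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    if n <= k + 1:
        raise ValueError(f"need n > n_features + 1 (n={n}, k={k})")

    Xs = _standardize(X)
    Xd = sm.add_constant(Xs, has_constant="add")
    separation = False
    p_wald = p_lr = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            beta = np.asarray(fit.params)
            if not np.all(np.isfinite(fit.bse)) or np.max(np.abs(beta)) > _BETA_CAP:
                raise RuntimeError("unstable maximum-likelihood fit")
            p_wald = float(fit.pvalues[1]) if k == 1 else float(np.min(fit.pvalues[1:]))
            llf, llnull = float(fit.llf), float(fit.llnull)
            p_lr = float(sps.chi2.sf(max(0.0, 2.0 * (llf - llnull)), df=k))
        except Exception:
            beta = _newton_logistic(Xd, y)
            separation = True
    probs = 1.0 / (1.0 + np.exp(-np.clip(Xd @ beta, -35, 35)))
    auc = auc_midrank(probs, y)
    if separation and auc >= 1.0 - 1e-12:
        auc = 1.0

    ci_low = ci_high = auc
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for i in range(n_boot):
            if stratified:
                idx = np.concatenate([
                    rng.choice(pos, size=pos.size, replace=True),
                    rng.choice(neg, size=neg.size, replace=True),
                ])
            else:
                idx = rng.choice(n, size=n, replace=True)
                if np.unique(y[idx]).size < 2:  # resample lost a class
                    aucs[i] = np.nan
                    continue
            bb = _newton_logistic(Xd[idx], y[idx])
            pb = Xd[idx] @ bb
            aucs[i] = auc_midrank(pb, y[idx])
        aucs = aucs[np.isfinite(aucs)]
        ci_low, ci_high = (float(v) for v in np.percentile(aucs, [2.5, 97.5]))
        ci_low = min(ci_low, auc)
        ci_high = max(ci_high, auc)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(k)
    )
    return ClassifierReport(
        target=target, features=names, auc=auc, ci_low=ci_low, ci_high=ci_high,
        p_value=(p_wald if k == 1 else p_lr), p_wald=p_wald, p_lr=p_lr,
        coefficients=beta, separation=separation, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Table-shaped reports
# ---------------------------------------------------------------------------


def _short_param(model: str, column: str) -> str:
    prefix = {"td-dMRI": "", "IMPULSED": "impulsed_", "JOINT": "joint_",
              "EXCHANGE": "exchange_"}[model]
    return column[len(prefix):] if prefix and column.startswith(prefix) else column


def _validate_table(table: pd.DataFrame, needed: Sequence[str]) -> None:
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise DataError(f"metric table is missing columns: {missing}")
    vals = table[list(needed)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("metric table contains non-finite metric values")


def _report_rows(
    table: pd.DataFrame,
    y: np.ndarray,
    target: str,
    models: Sequence[str],
    n_boot: int,
    seed: int,
) -> list[dict]:
    rows = []
    for m in models:
        feats = FEATURE_SETS[m]
        for col in feats:
            rep = logistic_roc(table[col].to_numpy(), y, n_boot=n_boot,
                               seed=seed, target=target, feature_names=[col])
            rows.append({
                "model": m, "parameter": _short_param(m, col), "target": target,
                "auc": rep.auc, "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                "p": rep.p_value,
            })
        rep = logistic_roc(table[feats].to_numpy(), y, n_boot=n_boot,
                           seed=seed, target=target, feature_names=feats)
        rows.append({
            "model": m, "parameter": "combined", "target": target,
            "auc": rep.auc, "ci_low": rep.ci_low, "ci_high": rep.ci_high,
            "p": rep.p_value,
        })
    return rows


def ihc_report(
    table: pd.DataFrame,
    models: Sequence[str] = ("td-dMRI", "IMPULSED", "JOINT", "EXCHANGE"),
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Classifier table for the four IHC factor targets.

    One row per (model, parameter, target): every single-metric classifier
    plus one combined classifier per model, for ER, PR, HER2 and Ki67.
    """
    needed = [c for m in models for c in FEATURE_SETS[m]]
    _validate_table(table, needed)
    rows: list[dict] = []
    for target in IHC_TARGETS:
        if target not in table.columns or table[target].isna().any():
            raise DataError(f"missing IHC label column {target!r}")
        y = table[target].to_numpy().astype(int)
        rows += _report_rows(table, y, target, models, n_boot, seed)
    return pd.DataFrame(rows)


def subtype_report(
    table: pd.DataFrame,
    models: Sequence[str] = ("td-dMRI", "IMPULSED", "JOINT", "EXCHANGE"),
    n_boot: int = 2000,
    seed: int = 0,
) -> SubtypeReport:
    """One-vs-rest classifier table over the four molecular subtypes, plus
    Kruskal-Wallis comparisons of each metric across subtypes.

    Subtypes with fewer than 2 lesions are excluded with a warning.
    """
    needed = [c for m in models for c in FEATURE_SETS[m]]
    _validate_table(table, needed)
    if "subtype" not in table.columns:
        raise DataError("metric table needs a 'subtype' column")
    subtype = table["subtype"].astype(str).to_numpy()
    rows: list[dict] = []
    for target in SUBTYPE_TARGETS:
        y = (subtype == target).astype(int)
        if y.sum() < 2:
            warnings.warn(f"subtype {target!r} has n < 2; excluded from report")
            continue
        rows += _report_rows(table, y, target, models, n_boot, seed)
    kw_rows = []
    present = [s for s in SUBTYPE_TARGETS if np.sum(subtype == s) >= 2]
    for m in models:
        for col in FEATURE_SETS[m]:
            groups = [table.loc[subtype == s, col].to_numpy() for s in present]
            res = kruskal_wallis(groups)
            kw_rows.append({
                "model": m, "parameter": _short_param(m, col),
                "kw_h": res.statistic, "kw_p": res.p_value,
            })
    return SubtypeReport(
        auc_table=pd.DataFrame(rows), kruskal_table=pd.DataFrame(kw_rows)
    )
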