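"""Fitting scores to ISUP grade and CsPCa, with resampled ROC evaluation.

Linear fits report the Pearson correlation R against ISUP grade (overall
and within scanner / histopathology-technique subgroups).  The binary
endpoint is clinically significant prostate cancer (CsPCa, ISUP >= 2);
univariate or multivariable logistic fits are evaluated through the ROC
AUC on repeated random 70/30 train/test splits, summarised by the mean and
the 2.5/97.5 percentile interval of the AUC distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CSPCA_THRESHOLD = 2


@dataclass
class EvalResult:
    """Per-variant evaluation summary."""

    variant: str
    pearson_r: float
    slope: float
    intercept: float
    mean_auc: float
    auc_ci: tuple[float, float]
    n_iterations: int
    seed: int
    subgroup_r: dict = field(default_factory=dict)
    n_redraws: int = 0

    def as_dict(self) -> dict:
        return {
            "variant": self.variant,
            "pearson_r": self.pearson_r,
            "slope": self.slope,
            "intercept": self.intercept,
            "mean_auc": self.mean_auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "subgroup_r": self.subgroup_r,
            "n_redraws": self.n_redraws,
        }


def classify_cspca(isup: int) -> bool:
    """True for clinically significant disease (ISUP grade >= 2)."""
    isup = int(isup)
    if not 0 <= isup <= 5:
        raise ValueError(f"ISUP grade must be in 0..5, got {isup}")
    return isup >= CSPCA_THRESHOLD


def pearson_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line and Pearson R.  Returns ``(r, slope, intercept)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        raise ValueError("correlation undefined for constant input")
    r, _ = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(slope), float(intercept)


def fit_logistic(
    X, labels, max_iter: int = 50, tol: float = 1e-10, ridge: float = 0.0
) -> np.ndarray:
    """Maximum-likelihood logistic coefficients by IRLS.

    ``X`` is ``(n,)`` for a univariate fit or ``(n, p)``; an intercept
    column is added internally.  Returns ``[intercept, slopes...]``.  On
    perfectly separable data the iteration caps at ``max_iter``; the score
    map is then still monotone, which is all ROC ranking needs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, p = X.shape
    if n < p + 2:
        raise ValueError("too few observations for logistic fit")
    # standardise internally for numerical stability, un-scale at the end
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Z = np.column_stack([np.ones(n), (X - mu) / sd])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = np.clip(Z @ beta, -30, 30)
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(pr * (1 - pr), 1e-10, None)
        grad = Z.T @ (y - pr) - ridge * beta
        H = (Z * w[:, None]).T @ Z + (ridge + 1e-12) * np.eye(p + 1)
        step = np.linalg.solve(H, grad)
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    slopes = beta[1:] / sd
    intercept = beta[0] - float(slopes @ mu)
    return np.concatenate([[intercept], slopes])


def predict_logistic(coef: np.ndarray, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = np.clip(coef[0] + X @ coef[1:], -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative).

    Ties count one half, via midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def resampled_auc_ci(
    X,
    labels,
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
    max_redraws: int = 200,
) -> dict:
    """Mean AUC and 2.5/97.5 percentile CI over random 70/30 splits.

    Each iteration draws an unstratified split, fits a logistic model on
    the training fold and scores the held-out fold.  A split whose folds
    do not both contain both classes is redrawn (and counted); AUC would
    be undefined otherwise.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("too few patients for resampled evaluation")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("split leaves too few patients in a fold")
    aucs = np.empty(n_iter)
    redraws = 0
    for it in range(n_iter):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                break
            redraws += 1
        else:
            raise ValueError("could not draw a two-class split")
        coef = fit_logistic(X[tr], y[tr])
        pr = predict_logistic(coef, X[te])
        aucs[it] = roc_auc(pr, y[te])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return {
        "mean_auc": float(aucs.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "aucs": aucs,
        "n_redraws": redraws,
    }


def subgroup_fits(
    scores_by_variant: dict[str, np.ndarray],
    cohort: pd.DataFrame,
    grouping: str,
    min_size: int = 3,
) -> pd.DataFrame:
    """Pearson R per subgroup (scanner or technique) and the ΔR summary.

    Returns a tidy frame with one row per (variant, group) plus, for each
    group, ΔR = mean over variants of ``R_group - R_all`` with a normal
    95% interval from the spread over variants.  Groups smaller than
    ``min_size`` (or with constant scores) are skipped with a warning row
    omitted.
    """
    if grouping not in ("scanner", "technique"):
        raise ValueError("grouping must be 'scanner' or 'technique'")
    y = cohort["isup"].to_numpy(dtype=float)
    rows = []
    groups = list(dict.fromkeys(cohort[grouping]))
    any_group = False
    for variant, x in scores_by_variant.items():
        x = np.asarray(x, dtype=float)
        r_all, _, _ = pearson_fit(x, y)
        rows.append({"variant": variant, "group": "ALL", "r": r_all, "n": len(y)})
        for g in groups:
            sel = (cohort[grouping] == g).to_numpy()
            if sel.sum() < min_size:
                continue
            if np.ptp(x[sel]) < 1e-12 or np.ptp(y[sel]) < 1e-12:
                continue
            r_g, _, _ = pearson_fit(x[sel], y[sel])
            rows.append({"variant": variant, "group": g, "r": r_g, "n": int(sel.sum())})
            any_group = True
    if not any_group:
        raise ValueError(f"no {grouping} group reaches the minimum size {min_size}")
    df = pd.DataFrame(rows)
    # ΔR per group: mean over variants of (R_group - R_all), normal 95% CI
    summary = []
    r_all_by_variant = df[df.group == "ALL"].set_index("variant")["r"]
    for g in df[df.group != "ALL"]["group"].unique():
        sub = df[df.group == g]
        deltas = sub["r"].to_numpy() - r_all_by_variant[sub["variant"]].to_numpy()
        se = deltas.std(ddof=1) / np.sqrt(len(deltas)) if len(deltas) > 1 else 0.0
        summary.append(
            {
                "variant": "DELTA_R",
                "group": g,
                "r": float(deltas.mean()),
                "n": int(sub["n"].iloc[0]),
                "ci95": 1.96 * float(se),
            }
        )
    return pd.concat([df, pd.DataFrame(summary)], ignore_index=True)


def evaluate_variant(
    variant: str,
    scores: np.ndarray,
    cohort: pd.DataFrame,
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
) -> EvalResult:
    """Linear fit to ISUP grade plus resampled logistic AUC for CsPCa."""
    y = cohort["isup"].to_numpy(dtype=float)
    labels = np.array([classify_cspca(g) for g in cohort["isup"]])
    r, slope, intercept = pearson_fit(scores, y)
    res = resampled_auc_ci(scores, labels, n_iter=n_iter, train_frac=train_frac, seed=seed)
    return EvalResult(
        variant=variant,
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        mean_auc=res["mean_auc"],
        auc_ci=(res["ci_low"], res["ci_high"]),
        n_iterations=n_iter,
        seed=seed,
        n_redraws=res["n_redraws"],
    )
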