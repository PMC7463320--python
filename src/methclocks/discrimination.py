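"""ROC curves, AUC and confidence intervals for tumor/normal and
case/control discrimination by a clock score.

The AUC is the Mann-Whitney rank statistic (ties count one half), which
equals the trapezoidal integral of the ROC curve swept over all distinct
score thresholds.  The reported AUC is "derived from logistic regression"
in the sense that a univariate logistic fit (Newton iterations, in-module)
is run alongside and its predicted-probability AUC is asserted to coincide
with the score AUC — predicted probabilities are a monotone transform of
the score, so the two are identical by construction and the fit serves as
an internal consistency check.

Confidence intervals: DeLong's variance estimator by default, or a Wald
interval on the logit scale.  The paired origin of tumor/normal samples is
ignored in the CI, matching the unpaired ROC treatment of the underlying
analyses; see the methods note for the caveat.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import ROCResult, SampleSheet, scores_as_series

log = logging.getLogger(__name__)

CI_METHODS = ("delong", "logit_wald")


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong's AUC variance from midrank placements."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # placement of each positive among negatives and vice versa
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def fit_logistic(x: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-10):
    """Univariate logistic regression by Newton-Raphson.

    Returns (intercept, slope).  Iterations are capped rather than checked
    for convergence: under complete separation the likelihood has no
    maximum, but predicted probabilities remain a monotone map of ``x``,
    which is all the AUC equivalence check needs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        wdiag = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * wdiag[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), float(beta[1])


def _curve_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC points from a sweep over all distinct thresholds, (0,0) to (1,1)."""
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return pts


def _resolve_labels(sheet: SampleSheet, positive: str) -> tuple[pd.Series, str]:
    """Map the positive-class label onto tissue roles or case/control groups.

    Returns a boolean Series indexed by sample_id over the samples that
    participate (the positive class and its natural complement), plus a
    human-readable definition of the positive class.
    """
    data = sheet.data
    if positive in ("tumor", "normal"):
        sub = data[data["tissue_role"].isin(["tumor", "normal"])]
        labels = sub.set_index("sample_id")["tissue_role"] == positive
        definition = f"{positive} tissue"
    elif positive in ("case", "control"):
        sub = data[data["group"].isin(["case", "control"])]
        labels = sub.set_index("sample_id")["group"] == positive
        definition = f"{positive} blood sample"
    else:
        raise ValueError(
            f"positive must be a tissue role (tumor/normal) or group (case/control), "
            f"got {positive!r}"
        )
    return labels, definition


def roc_from_values(
    values: pd.Series,
    labels: pd.Series,
    clock: str = "score",
    ci_method: str = "delong",
    positive_definition: str = "positive",
) -> ROCResult:
    """ROC/AUC/CI from per-sample values and boolean labels."""
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {CI_METHODS}")
    common = labels.index.intersection(values.index)
    values = values.reindex(common)
    ok = values.notna()
    values, labels = values[ok], labels.reindex(common)[ok]
    pos = values[labels].to_numpy()
    neg = values[~labels].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("one class is empty; cannot compute ROC")

    score_arr = values.to_numpy()
    label_arr = labels.to_numpy().astype(int)
    auc = rank_auc(pos, neg)
    points = _curve_points(score_arr, label_arr)

    constant = np.all(score_arr == score_arr[0])
    if constant:
        warnings.warn("constant scores: AUC degenerates to 0.5", stacklevel=2)
        ci_low = ci_high = auc
    else:
        var = delong_variance(pos, neg)
        se = np.sqrt(var)
        z = norm.ppf(0.975)
        if ci_method == "delong":
            ci_low = max(0.0, auc - z * se)
            ci_high = min(1.0, auc + z * se)
        else:  # logit_wald
            if auc in (0.0, 1.0) or se == 0.0:
                ci_low = ci_high = auc
            else:
                lo = np.log(auc / (1 - auc))
                se_l = se / (auc * (1 - auc))
                ci_low = float(expit(lo - z * se_l))
                ci_high = float(expit(lo + z * se_l))
        # logistic-regression equivalence: predicted probabilities are a
        # monotone transform of the score, so their AUC must match
        icpt, slope = fit_logistic(score_arr, label_arr)
        if slope != 0.0:
            # rank on the linear predictor: expit is strictly increasing, so
            # the predicted-probability AUC is identical, without the
            # float saturation expit suffers under complete separation
            eta = icpt + slope * score_arr
            auc_lr = rank_auc(eta[label_arr == 1], eta[label_arr == 0])
            expected = auc if slope > 0 else 1.0 - auc
            if abs(auc_lr - expected) > 1e-9:
                raise RuntimeError(
                    f"logistic-fit AUC {auc_lr} disagrees with score AUC {auc}"
                )

    return ROCResult(
        clock=clock,
        n_pos=pos.size,
        n_neg=neg.size,
        points=points,
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_method=ci_method,
        positive_definition=positive_definition,
    )


def roc_auc(
    scores: pd.DataFrame,
    sheet: SampleSheet,
    positive: str,
    ci_method: str = "delong",
    clock: str | None = None,
) -> ROCResult:
    """ROC analysis of one clock's scores against a sample-sheet label."""
    values = scores_as_series(scores, clock)
    clock_name = clock or str(scores["clock"].iloc[0])
    labels, definition = _resolve_labels(sheet, positive)
    return roc_from_values(
        values, labels, clock=clock_name, ci_method=ci_method, positive_definition=definition
    )


def flip_orientation(r: ROCResult) -> ROCResult:
    """Reflect a ROC result so the score discriminates in the other direction.

    AUC maps to 1 - AUC, the curve reflects through the diagonal's
    antisymmetry, and the flipped flag toggles; applying it twice restores
    the original result.
    """
    pts = r.points[::-1].copy()
    pts = np.column_stack([1.0 - pts[:, 0], 1.0 - pts[:, 1]])
    return ROCResult(
        clock=r.clock,
        n_pos=r.n_pos,
        n_neg=r.n_neg,
        points=pts,
        auc=1.0 - r.auc,
        ci_low=1.0 - r.ci_high,
        ci_high=1.0 - r.ci_low,
        ci_method=r.ci_method,
        positive_definition=r.positive_definition,
        flipped=not r.flipped,
    )


def oriented(r: ROCResult) -> ROCResult:
    """Return ``r`` flipped if necessary so the reported AUC is >= 0.5."""
    return flip_orientation(r) if r.auc < 0.5 else r


def roc_to_dict(r: ROCResult) -> dict:
    """JSON-friendly view of a ROC result (curve points omitted)."""
    return {
        "clock": r.clock,
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
        "auc": r.auc,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "ci_method": r.ci_method,
        "positive_definition": r.positive_definition,
        "flipped": r.flipped,
    }
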