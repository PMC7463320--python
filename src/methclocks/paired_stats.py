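"""Paired tumor-vs-normal comparison via the Wilcoxon signed-rank test.

The test is implemented in-module.  Zero within-pair differences are
dropped (the classic Wilcoxon convention; Pratt's zero-rank alternative is
available as ``zero_method="pratt"``), absolute differences are ranked with
midranks for ties, and W is the sum of ranks of positive differences.

The exact null distribution of W is obtained by the standard generating-
function recursion over all 2^n equally likely sign assignments (guarded at
n = 25); midranks are doubled so every achievable statistic is an integer
and tail counts are exact.  Above the guard, a continuity-corrected normal
approximation with the usual tie correction is used.  Two-sided p-values
double the smaller tail, capped at 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .containers import BetaMatrix, PairedTestResult, SampleSheet, scores_as_series

log = logging.getLogger(__name__)

EXACT_N_GUARD = 25


@dataclass
class PairedValues:
    """Tumor/normal value pairs, one row per subject with both values."""

    frame: pd.DataFrame  # columns: subject_id, tumor, normal
    n_excluded: int

    @property
    def diffs(self) -> np.ndarray:
        return (self.frame["tumor"] - self.frame["normal"]).to_numpy()


@dataclass
class WilcoxonResult:
    statistic_w: float
    p_value: float
    n: int  # informative (non-zero) pairs
    n_zero: int
    method: str  # exact | normal


def pair_samples(values, sheet: SampleSheet, clock: str | None = None) -> PairedValues:
    """Join per-sample values into (subject, tumor value, normal value) rows.

    ``values`` may be a Series indexed by sample_id, a score table (pass
    ``clock`` when it holds several clocks), or a single-probe view of a
    :class:`BetaMatrix` obtained as ``m.values.loc[probe]``.  Subjects
    missing either tissue role, or whose value is missing, are excluded and
    counted.
    """
    if isinstance(values, pd.DataFrame):
        values = scores_as_series(values, clock)
    elif isinstance(values, BetaMatrix):
        raise TypeError("pass a single probe row, e.g. m.values.loc[probe]")
    values = pd.Series(values)
    pairs, excluded = sheet.complete_pairs()
    tumor = values.reindex(pairs["tumor_sample"]).to_numpy()
    normal = values.reindex(pairs["normal_sample"]).to_numpy()
    ok = ~(np.isnan(tumor) | np.isnan(normal))
    n_excluded = len(excluded) + int((~ok).sum())
    frame = pd.DataFrame(
        {
            "subject_id": pairs["subject_id"].to_numpy()[ok],
            "tumor": tumor[ok],
            "normal": normal[ok],
        }
    )
    if frame.empty:
        raise ValueError("no complete tumor/normal pairs with observed values")
    if n_excluded:
        log.info("excluded %d subject(s) lacking a complete observed pair", n_excluded)
    return PairedValues(frame=frame, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# the signed-rank test
# ---------------------------------------------------------------------------

def _exact_two_sided_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for doubled midranks ``ranks2`` and statistic ``w2``.

    Counts sign assignments by the generating-function recursion, which
    enumerates the same 2^n equally likely outcomes as brute force.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    denom = float(2 ** len(ranks2))
    p_ge = float(counts[w2:].sum()) / denom
    p_le = float(counts[: w2 + 1].sum()) / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    diffs, mode: str = "auto", zero_method: str = "drop"
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    ``mode="exact"`` requires at most 25 informative pairs; ``"auto"`` uses
    the exact distribution when n <= 25 and the absolute differences are
    tie-free, else the tie-corrected normal approximation with continuity
    correction.
    """
    if mode not in ("auto", "exact", "normal"):
        raise ValueError("mode must be 'auto', 'exact' or 'normal'")
    if zero_method not in ("drop", "pratt"):
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    d = np.asarray(diffs, dtype=float)
    if d.size == 0 or not np.all(np.isfinite(d)):
        raise ValueError("differences must be a non-empty finite vector")
    n_zero = int((d == 0).sum())
    if zero_method == "drop":
        d = d[d != 0]
    if d.size == 0 or (zero_method == "pratt" and n_zero == d.size):
        raise ValueError("all differences are zero; test undefined")

    absd = np.abs(d)
    ranks = rankdata(absd)  # midranks
    if zero_method == "pratt":
        nonzero = d != 0
        w = float(ranks[nonzero & (d > 0)].sum())
        n = int(nonzero.sum())
        ranks_used = ranks[nonzero]
        has_ties = len(np.unique(absd)) < len(absd)
    else:
        w = float(ranks[d > 0].sum())
        n = d.size
        ranks_used = ranks
        has_ties = len(np.unique(absd)) < n

    if mode == "exact" and n > EXACT_N_GUARD:
        raise ValueError(f"exact mode limited to n <= {EXACT_N_GUARD} (got n = {n})")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_GUARD and not has_ties)

    if use_exact:
        ranks2 = np.round(2.0 * ranks_used).astype(np.int64)
        w2 = int(round(2.0 * w))
        p = _exact_two_sided_p(ranks2, w2)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks_used, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            p = 1.0
        else:
            z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal"
    p = max(p, np.finfo(float).tiny)  # p-values live in (0, 1]
    return WilcoxonResult(statistic_w=w, p_value=p, n=n, n_zero=n_zero, method=method)


# ---------------------------------------------------------------------------
# stratified comparisons
# ---------------------------------------------------------------------------

def _one_comparison(pv: PairedValues, clock: str, stratum: str, mode: str) -> PairedTestResult:
    diffs = pv.diffs
    res = wilcoxon_signed_rank(diffs, mode=mode)
    med = float(np.median(diffs))
    direction = "tumor_higher" if med > 0 else "normal_higher" if med < 0 else "none"
    return PairedTestResult(
        clock=clock,
        stratum=stratum,
        n_pairs=res.n,
        n_zero_diffs=res.n_zero,
        statistic_w=res.statistic_w,
        p_value=res.p_value,
        median_diff=med,
        direction=direction,
    )


def compare_by_stratum(
    scores: pd.DataFrame,
    sheet: SampleSheet,
    strata: str = "overall",
    mode: str = "auto",
) -> list[PairedTestResult]:
    """Paired comparison per clock, overall or within each tumor stage.

    Strata with fewer than 2 informative pairs are skipped (logged, not an
    error).
    """
    if strata not in ("overall", "stage"):
        raise ValueError("strata must be 'overall' or 'stage'")
    results: list[PairedTestResult] = []
    for clock in scores["clock"].unique():
        values = scores_as_series(scores, clock)
        pv = pair_samples(values, sheet)
        if strata == "overall":
            groups = {"overall": pv.frame}
        else:
            stage = sheet.subject_stage().reindex(pv.frame["subject_id"]).to_numpy()
            groups = {
                str(s): pv.frame[stage == s] for s in pd.unique(stage)
            }
        for label, frame in groups.items():
            sub = PairedValues(frame=frame.reset_index(drop=True), n_excluded=pv.n_excluded)
            diffs = sub.diffs
            if (diffs != 0).sum() < 2:
                log.info(
                    "skipping stratum %r for clock %r: fewer than 2 informative pairs",
                    label,
                    clock,
                )
                continue
            results.append(_one_comparison(sub, clock, label, mode))
    return results


def results_to_frame(results: list[PairedTestResult]) -> pd.DataFrame:
    """Tabulate comparison results for TSV output."""
    return pd.DataFrame(
        [
            {
                "clock": r.clock,
                "stratum": r.stratum,
                "n_pairs": r.n_pairs,
                "n_zero_diffs": r.n_zero_diffs,
                "W": r.statistic_w,
                "p_value": r.p_value,
                "median_diff": r.median_diff,
                "direction": r.direction,
            }
            for r in results
        ]
    )
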