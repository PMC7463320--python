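"""Quality filtering and probe-category-stratified quantile normalization.

Filtering follows the CPACOR-style two-step rule: entries whose detection
p-value exceeds the threshold are masked as missing, then probes whose
missing fraction exceeds the missingness threshold are removed (both
inequalities strict).  An alternative "any_sample" mode removes a probe
outright if any sample fails detection or the probe exceeds the missingness
threshold, for pipelines that prefer hard probe-level exclusion.

Normalization is classic quantile normalization applied independently
within probe categories (the 450K convention splits probes into six
categories by design type and color channel).  The implementation works on
beta values: ranks are computed on observed entries only, the reference
distribution is the across-sample mean of per-sample quantile functions
evaluated on a common grid, and tied values receive the mean of the
reference values their rank positions span.  Missing entries stay missing.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BetaMatrix

log = logging.getLogger(__name__)

FILTER_MODES = ("mask_then_remove", "any_sample")


@dataclass
class FilterReport:
    """Bookkeeping of the probe-filtering step."""

    n_probes_in: int
    n_entries_masked: int
    n_probes_removed: int
    n_probes_out: int
    detection_step_applied: bool
    per_probe_missing_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_probes_out != self.n_probes_in - self.n_probes_removed:
            raise ValueError("inconsistent probe counts in filter report")
        fracs = np.array(list(self.per_probe_missing_fraction.values()), dtype=float)
        if fracs.size and (fracs.min() < 0 or fracs.max() > 1):
            raise ValueError("missing fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def hash_categories(probe_ids, k: int = 6, prefix: str = "cat") -> dict[str, str]:
    """Assign probes to ``k`` pseudo-categories by a stable hash of the id.

    Stands in for the Illumina design-type/color-channel manifest when
    normalizing synthetic data: it exercises the stratified code path with a
    deterministic, order-independent assignment.
    """
    if k < 1:
        raise ValueError("k must be positive")
    out = {}
    for probe in probe_ids:
        digest = hashlib.md5(str(probe).encode()).hexdigest()
        out[str(probe)] = f"{prefix}{int(digest, 16) % k}"
    return out


class ProbeFilter(BaseEstimator, TransformerMixin):
    """Detection-p masking and missingness-based probe removal.

    Parameters
    ----------
    p_threshold
        Entries with detection p-value strictly above this are masked.
    missing_threshold
        Probes with missing fraction strictly above this (after masking)
        are removed.
    mode
        "mask_then_remove" (default) or "any_sample" (remove a probe if any
        entry fails detection, no per-entry masking).
    """

    def __init__(
        self,
        p_threshold: float = 0.01,
        missing_threshold: float = 0.05,
        mode: str = "mask_then_remove",
    ):
        self.p_threshold = p_threshold
        self.missing_threshold = missing_threshold
        self.mode = mode

    def _validate(self) -> None:
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in [0, 1]")
        if not 0.0 <= self.missing_threshold <= 1.0:
            raise ValueError("missing_threshold must be in [0, 1]")
        if self.mode not in FILTER_MODES:
            raise ValueError(f"mode must be one of {FILTER_MODES}")

    def fit(self, X: BetaMatrix, y=None) -> "ProbeFilter":
        self._validate()
        masked = self._mask(X)
        frac = masked.values.isna().mean(axis=1)
        if self.mode == "mask_then_remove":
            remove = frac > self.missing_threshold
        else:
            any_fail = (
                (X.detection_p > self.p_threshold).any(axis=1)
                if X.detection_p is not None
                else pd.Series(False, index=X.values.index)
            )
            remove = any_fail | (X.values.isna().mean(axis=1) > self.missing_threshold)
        self.kept_probes_ = list(frac.index[~remove])
        self.report_ = FilterReport(
            n_probes_in=X.n_probes,
            n_entries_masked=self._n_masked(X),
            n_probes_removed=int(remove.sum()),
            n_probes_out=len(self.kept_probes_),
            detection_step_applied=X.detection_p is not None,
            per_probe_missing_fraction={str(p): float(frac[p]) for p in frac.index},
        )
        if X.detection_p is None:
            log.info("no detection p-values present; detection filtering skipped")
        return self

    def _mask(self, X: BetaMatrix) -> BetaMatrix:
        if X.detection_p is None or self.mode == "any_sample":
            return X
        masked = X.values.mask(X.detection_p > self.p_threshold)
        return BetaMatrix(masked, X.detection_p)

    def _n_masked(self, X: BetaMatrix) -> int:
        if X.detection_p is None or self.mode == "any_sample":
            return 0
        newly = (X.detection_p > self.p_threshold) & X.values.notna()
        return int(newly.to_numpy().sum())

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "kept_probes_"):
            raise RuntimeError("ProbeFilter must be fitted before transform")
        masked = self._mask(X)
        return masked.select_probes([p for p in self.kept_probes_ if p in masked.values.index])


def filter_probes(
    m: BetaMatrix,
    p_threshold: float = 0.01,
    missing_threshold: float = 0.05,
    mode: str = "mask_then_remove",
) -> tuple[BetaMatrix, FilterReport]:
    """Functional wrapper around :class:`ProbeFilter` (fit and apply on ``m``)."""
    f = ProbeFilter(p_threshold=p_threshold, missing_threshold=missing_threshold, mode=mode)
    out = f.fit(m).transform(m)
    return out, f.report_


class StratifiedQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization within probe categories.

    ``fit`` learns, per category, a reference quantile function (the mean
    across samples of each sample's observed quantile function on a common
    grid); ``transform`` replaces each sample's observed values by reference
    values at their rank positions, preserving within-sample order.  With
    complete data, ``fit_transform`` is classic quantile normalization: the
    sorted values of every sample become the mean order statistics.

    Parameters
    ----------
    categories
        Mapping probe id -> category label covering every probe of the
        matrix, or None to hash probes into ``n_categories`` pseudo-categories.
    n_categories
        Number of hash categories when ``categories`` is None (default 6,
        mirroring the 450K design-type x color-channel split).
    """

    def __init__(self, categories: dict[str, str] | None = None, n_categories: int = 6):
        self.categories = categories
        self.n_categories = n_categories

    def _resolve_categories(self, X: BetaMatrix) -> dict[str, str]:
        cats = self.categories
        if cats is None:
            cats = hash_categories(X.probe_ids, k=self.n_categories)
        missing = [p for p in X.probe_ids if p not in cats]
        if missing:
            raise ValueError(f"probe {missing[0]!r} has no category assignment")
        return cats

    def fit(self, X: BetaMatrix, y=None) -> "StratifiedQuantileNormalizer":
        if X.n_samples < 2:
            raise ValueError("quantile normalization needs at least 2 samples")
        cats = self._resolve_categories(X)
        self.categories_ = {p: cats[p] for p in X.probe_ids}
        self.reference_: dict[str, np.ndarray] = {}
        by_cat: dict[str, list] = {}
        for probe, cat in self.categories_.items():
            by_cat.setdefault(cat, []).append(probe)
        for cat, probes in by_cat.items():
            block = X.values.loc[probes].to_numpy()
            size = len(probes)
            grid = np.linspace(0.0, 1.0, size) if size > 1 else np.array([0.5])
            curves = []
            for j in range(block.shape[1]):
                col = block[:, j]
                obs = np.sort(col[~np.isnan(col)])
                if obs.size == 0:
                    continue
                pos = np.linspace(0.0, 1.0, obs.size) if obs.size > 1 else np.array([0.5])
                curves.append(np.interp(grid, pos, obs))
            if not curves:
                raise ValueError(f"category {cat!r} has no observed values")
            self.reference_[cat] = np.mean(curves, axis=0)
        self._grid_ = {
            cat: (np.linspace(0.0, 1.0, ref.size) if ref.size > 1 else np.array([0.5]))
            for cat, ref in self.reference_.items()
        }
        return self

    def transform(self, X: BetaMatrix) -> BetaMatrix:
        if not hasattr(self, "reference_"):
            raise RuntimeError("normalizer must be fitted before transform")
        cats = self._resolve_categories(X)
        unknown = sorted({c for c in (cats[p] for p in X.probe_ids)} - set(self.reference_))
        if unknown:
            raise ValueError(f"no reference distribution for category {unknown[0]!r}")
        out = X.values.copy()
        probe_cat = np.array([cats[p] for p in X.probe_ids])
        for cat, ref in self.reference_.items():
            sel = probe_cat == cat
            if not sel.any():
                continue
            block = out.loc[sel].to_numpy()
            for j in range(block.shape[1]):
                block[:, j] = self._normalize_column(block[:, j], ref, self._grid_[cat])
            out.loc[sel] = block
        return X.with_values(out)

    @staticmethod
    def _normalize_column(col: np.ndarray, ref: np.ndarray, grid: np.ndarray) -> np.ndarray:
        obs_idx = np.flatnonzero(~np.isnan(col))
        n_obs = obs_idx.size
        if n_obs == 0:
            return col
        vals = col[obs_idx]
        order = np.argsort(vals, kind="mergesort")
        sorted_vals = vals[order]
        pos = np.linspace(0.0, 1.0, n_obs) if n_obs > 1 else np.array([0.5])
        candidate = np.interp(pos, grid, ref)
        # tied input values share the mean of the reference values their
        # rank positions span
        assigned = np.empty(n_obs)
        i = 0
        while i < n_obs:
            j = i
            while j + 1 < n_obs and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            assigned[i : j + 1] = candidate[i : j + 1].mean()
            i = j + 1
        new = np.full(col.shape, np.nan)
        new[obs_idx[order]] = assigned
        return new


def quantile_normalize_stratified(
    m: BetaMatrix, cats: dict[str, str] | None = None, n_categories: int = 6
) -> BetaMatrix:
    """Functional wrapper: fit the normalizer on ``m`` and normalize ``m``."""
    qn = StratifiedQuantileNormalizer(categories=cats, n_categories=n_categories)
    return qn.fit(m).transform(m)
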