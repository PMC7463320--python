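"""Linear methylation clocks, output transformations and age acceleration.

A clock is a linear predictor over CpG beta values, ``intercept + sum_j
w_j * beta_j``, optionally passed through a nonlinear output map.  The
10-CpG blood-derived mortality risk score (MRscore) ships with the package;
phenotypic-age style clocks (a mortality-scale linear predictor mapped to
years through a Gompertz cumulative distribution) and the multitissue
epigenetic-clock age calibration are supported as parameterized
transformations whose constants arrive with the user-supplied coefficient
file — the published 513- and 353-CpG weight sets are deliberately not
bundled.

Age acceleration is the residual of a methylation-age estimate regressed on
chronological age by ordinary least squares; positive residuals mean
epigenetically older than expected for one's age.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import io as mio
from .containers import BetaMatrix, CoefficientSet, SampleSheet, make_score_table

log = logging.getLogger(__name__)

MISSING_POLICIES = ("error", "mean_impute", "skip_renormalize")


# ---------------------------------------------------------------------------
# output transformations
# ---------------------------------------------------------------------------

@dataclass
class PhenoAgeTransformParams:
    """Constants of the two-step mortality-to-age transformation.

    Step 1 converts the linear predictor ``lp`` to a mortality probability
    through a Gompertz CDF over a fixed horizon::

        risk = 1 - exp(-exp(lp) * C),   C = (exp(gamma * horizon) - 1) / gamma

    (``C = horizon`` in the ``gamma -> 0`` limit).  Step 2 maps the risk to
    an age in years::

        age = age_offset + log(-gomp_coeff * log(1 - risk)) / slope

    Composing the two steps analytically gives the numerically stable form
    used here, ``age = age_offset + (log(gomp_coeff) + log(C) + lp) / slope``,
    which avoids the catastrophic underflow of ``log(1 - risk)`` for large
    predictors.  The defaults are the identity parameterization (slope 1,
    offset 0, ``gomp_coeff * C = 1``); real constants come from the
    coefficient file's ``#transform.*`` headers.
    """

    age_offset: float = 0.0
    slope: float = 1.0
    gomp_coeff: float = 1.0
    gamma: float = 0.0
    horizon: float = 1.0

    @classmethod
    def from_dict(cls, params: dict[str, float]) -> "PhenoAgeTransformParams":
        known = {"age_offset", "slope", "gomp_coeff", "gamma", "horizon"}
        unknown = set(params) - known
        if unknown:
            raise ValueError(f"unknown phenoage transform parameter(s): {sorted(unknown)}")
        return cls(**params)

    @property
    def gompertz_scale(self) -> float:
        if self.gamma == 0.0:
            return self.horizon
        return math.expm1(self.gamma * self.horizon) / self.gamma

    def validate(self) -> None:
        for name in ("age_offset", "slope", "gomp_coeff", "gamma", "horizon"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"phenoage transform constant {name} is not finite")
        if self.gomp_coeff <= 0:
            raise ValueError(
                "phenoage transform undefined: log of non-positive value "
                f"(gomp_coeff = {self.gomp_coeff})"
            )
        if self.gompertz_scale <= 0:
            raise ValueError(
                "phenoage transform undefined: log of non-positive value "
                f"(Gompertz scale from gamma = {self.gamma}, horizon = {self.horizon})"
            )
        if self.slope == 0:
            raise ValueError("phenoage transform slope must be non-zero")
        # declared monotone-increasing: verified on a grid at load time
        grid = np.linspace(-50.0, 50.0, 11)
        vals = phenoage_transform(grid, self)
        if not np.all(np.diff(vals) > 0):
            raise ValueError(
                "phenoage transform is not monotone increasing "
                f"(slope = {self.slope})"
            )


def phenoage_transform(linear_predictor, p: PhenoAgeTransformParams):
    """Map a mortality-scale linear predictor to an age in years."""
    if p.gomp_coeff <= 0 or p.gompertz_scale <= 0:
        p.validate()  # raises with the offending constant combination
    lp = np.asarray(linear_predictor, dtype=float)
    out = p.age_offset + (math.log(p.gomp_coeff) + math.log(p.gompertz_scale) + lp) / p.slope
    return float(out) if np.isscalar(linear_predictor) else out


def phenoage_inverse(age, p: PhenoAgeTransformParams):
    """Inverse of :func:`phenoage_transform` (age in years back to predictor)."""
    a = np.asarray(age, dtype=float)
    lp = (a - p.age_offset) * p.slope - math.log(p.gomp_coeff) - math.log(p.gompertz_scale)
    return float(lp) if np.isscalar(age) else lp


def horvath_age_transform(x, adult_age: float = 20.0):
    """Anti-transform of the multitissue clock's age calibration.

    Log-linear below the adult threshold, linear above it; continuous and
    strictly increasing.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, (1.0 + adult_age) * np.exp(x) - 1.0, (1.0 + adult_age) * x + adult_age)
    return float(out) if out.ndim == 0 else out


def _apply_transform(scores: np.ndarray, c: CoefficientSet) -> np.ndarray:
    if c.transform == "identity":
        return scores
    if c.transform == "phenoage":
        params = PhenoAgeTransformParams.from_dict(c.transform_params)
        params.validate()
        return phenoage_transform(scores, params)
    if c.transform == "horvath":
        adult = c.transform_params.get("adult_age", 20.0)
        return horvath_age_transform(scores, adult_age=adult)
    raise ValueError(f"unknown transform {c.transform!r}")


# ---------------------------------------------------------------------------
# clock scoring
# ---------------------------------------------------------------------------

def _resolve_coefficients(coefficients) -> CoefficientSet:
    if isinstance(coefficients, CoefficientSet):
        return coefficients
    if isinstance(coefficients, str):
        if coefficients.lower() == "mrscore":
            return mio.load_bundled_coefficients("mrscore")
        return mio.read_coefficients(coefficients)
    raise TypeError("coefficients must be a CoefficientSet, 'mrscore', or a file path")


class ClockScorer(BaseEstimator, TransformerMixin):
    """Score samples with a linear methylation clock.

    Parameters
    ----------
    coefficients
        A :class:`CoefficientSet`, the string ``"mrscore"`` for the bundled
        mortality risk score, or a coefficient-file path.
    missing_policy
        How to handle clock CpGs that are missing in a sample:
        ``"error"`` aborts; ``"mean_impute"`` (default) substitutes the
        probe's mean over non-missing samples (learned in ``fit``);
        ``"skip_renormalize"`` drops the term and rescales the remaining
        weights so the total absolute weight is preserved.
    """

    def __init__(self, coefficients="mrscore", missing_policy: str = "mean_impute"):
        self.coefficients = coefficients
        self.missing_policy = missing_policy

    def fit(self, X: BetaMatrix, y=None) -> "ClockScorer":
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        c = _resolve_coefficients(self.coefficients)
        present = [p for p in c.probes if p in X.values.index]
        if not present:
            raise ValueError(
                f"matrix contains none of clock {c.name!r}'s probes; "
                f"missing: {c.probes}"
            )
        self.coefficients_ = c
        self.means_ = X.values.loc[present].mean(axis=1, skipna=True)
        return self

    def transform(self, X: BetaMatrix) -> pd.DataFrame:
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("ClockScorer must be fitted before transform")
        c = self.coefficients_
        probes = c.probes
        weights = np.array([c.terms[p] for p in probes], dtype=float)
        block = X.values.reindex(probes)  # absent probes become all-NaN rows
        B = block.to_numpy()
        missing = np.isnan(B)
        n_samples = X.n_samples

        if self.missing_policy == "error":
            if missing.any():
                i, j = np.argwhere(missing)[0]
                raise ValueError(
                    f"missing beta value for clock probe {probes[i]!r} in "
                    f"sample {X.sample_ids[j]!r} under missing_policy='error'"
                )
            scores = c.intercept + weights @ B
            used = np.full(n_samples, len(probes))
            imputed = np.zeros(n_samples, dtype=int)
        elif self.missing_policy == "mean_impute":
            fill = self.means_.reindex(probes).to_numpy()
            unfixable = np.isnan(fill) & missing.any(axis=1)
            if unfixable.any():
                bad = [probes[i] for i in np.flatnonzero(unfixable)]
                raise ValueError(
                    f"cannot mean-impute clock probe(s) {bad}: no observed "
                    "values in the fitted matrix"
                )
            if missing.any():
                warnings.warn(
                    f"mean-imputing {int(missing.sum())} missing beta value(s) "
                    f"for clock {c.name!r}",
                    stacklevel=2,
                )
            Bf = np.where(missing, fill[:, None], B)
            scores = c.intercept + weights @ Bf
            used = (~missing).sum(axis=0)
            imputed = missing.sum(axis=0)
        else:  # skip_renormalize
            total_abs = np.abs(weights).sum()
            W = np.where(missing, 0.0, weights[:, None])
            used_abs = np.abs(W).sum(axis=0)
            if np.any(used_abs == 0):
                j = int(np.flatnonzero(used_abs == 0)[0])
                raise ValueError(
                    f"sample {X.sample_ids[j]!r} has no observed clock probes"
                )
            factor = total_abs / used_abs
            raw = np.nansum(W * B, axis=0)
            scores = c.intercept + factor * raw
            used = (~missing).sum(axis=0)
            imputed = missing.sum(axis=0)

        scores = _apply_transform(np.asarray(scores, dtype=float), c)
        return make_score_table(X.sample_ids, c.name, scores, used, imputed)


def compute_linear_score(
    m: BetaMatrix, c: CoefficientSet | str, missing_policy: str = "mean_impute"
) -> pd.DataFrame:
    """Score every sample of ``m`` with clock ``c`` (thin wrapper)."""
    scorer = ClockScorer(coefficients=c, missing_policy=missing_policy)
    return scorer.fit(m).transform(m)


def mrscore(m: BetaMatrix, missing_policy: str = "mean_impute") -> pd.DataFrame:
    """Convenience: score samples with the bundled 10-CpG mortality score."""
    return compute_linear_score(m, "mrscore", missing_policy=missing_policy)


# ---------------------------------------------------------------------------
# age acceleration
# ---------------------------------------------------------------------------

class AgeAccelerationRegressor(BaseEstimator, RegressorMixin):
    """OLS of methylation age on chronological age, closed form.

    ``fit`` computes slope ``b = cov(age, DNAmAge) / var(age)`` and
    intercept ``a = mean(DNAmAge) - b * mean(age)``; residuals are the age
    acceleration.
    """

    def fit(self, X, y) -> "AgeAccelerationRegressor":
        age = np.asarray(X, dtype=float).reshape(-1)
        dnam = np.asarray(y, dtype=float).reshape(-1)
        if age.size != dnam.size:
            raise ValueError("age and methylation-age vectors differ in length")
        if age.size < 3:
            raise ValueError("age-acceleration regression needs at least 3 samples")
        var = np.var(age)
        if var == 0:
            raise ValueError("all ages equal; regression slope undefined")
        self.coef_ = float(np.cov(age, dnam, bias=True)[0, 1] / var)
        self.intercept_ = float(dnam.mean() - self.coef_ * age.mean())
        return self

    def predict(self, X):
        age = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.coef_ * age

    def residuals(self, X, y) -> np.ndarray:
        return np.asarray(y, dtype=float).reshape(-1) - self.predict(X)


def age_acceleration(
    scores: pd.DataFrame, sheet: SampleSheet, clock: str = "DNAmAge"
) -> pd.DataFrame:
    """Residuals of a methylation-age clock regressed on chronological age.

    Samples without a known age are excluded (and logged).  Returns a score
    table with clock name ``"<clock>Accel"``.
    """
    sub = scores[scores["clock"] == clock]
    if sub.empty:
        raise ValueError(f"no scores for clock {clock!r}")
    ages = sheet.ages().reindex(sub["sample_id"])
    known = ages.notna().to_numpy()
    n_excluded = int((~known).sum())
    if n_excluded:
        log.info("excluding %d sample(s) without known age", n_excluded)
    sub = sub.iloc[np.flatnonzero(known)]
    age = ages.to_numpy()[known]
    dnam = sub["score"].to_numpy()
    reg = AgeAccelerationRegressor().fit(age, dnam)
    resid = reg.residuals(age, dnam)
    return make_score_table(
        sub["sample_id"], f"{clock}Accel", resid, sub["n_terms_used"], sub["n_terms_imputed"]
    )
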