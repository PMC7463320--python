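"""Core data containers for methylation-clock analysis.

The central object is the :class:`BetaMatrix`, a probes-by-samples table of
methylation fractions (beta values) in [0, 1] with an optional matrix of
per-entry detection p-values.  Missingness is represented with NaN inside a
float frame; every consumer in this package treats NaN as "not observed" and
never as a numeric value, so rank statistics and means are computed on
observed entries only.

A :class:`SampleSheet` links array columns to subjects, tissue roles
(tumor / adjacent normal / blood), case-control groups, tumor stage, age and
sex, which is what the paired and group-wise comparisons downstream need.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TISSUE_ROLES = ("tumor", "normal", "blood")
GROUPS = ("case", "control", "none")
STAGES = ("I", "II", "III", "IV", "unknown")
SEXES = ("M", "F", "unknown")

SHEET_COLUMNS = ("sample_id", "subject_id", "tissue_role", "group", "stage", "age", "sex")

#: column schema of a score table (one row per sample per clock)
SCORE_COLUMNS = ("sample_id", "clock", "score", "n_terms_used", "n_terms_imputed")


def _first_duplicate(labels: Iterable) -> object | None:
    seen = set()
    for lab in labels:
        if lab in seen:
            return lab
        seen.add(lab)
    return None


class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame with probe ids on the index and sample ids on the columns.
        Entries are methylation fractions in [0, 1]; NaN marks missing.
    detection_p
        Optional DataFrame of per-entry detection p-values with exactly the
        same index and columns as ``values``.
    """

    def __init__(self, values: pd.DataFrame, detection_p: pd.DataFrame | None = None):
        values = values.astype(float)
        dup = _first_duplicate(values.index)
        if dup is not None:
            raise ValueError(f"duplicate probe id: {dup!r}")
        dup = _first_duplicate(values.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = values.to_numpy()
        bad = np.zeros(arr.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            bad |= (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}: {arr[i, j]!r}"
            )
        if detection_p is not None:
            detection_p = detection_p.astype(float)
            if not detection_p.index.equals(values.index) or not detection_p.columns.equals(
                values.columns
            ):
                raise ValueError("detection_p axis labels do not match values")
            parr = detection_p.to_numpy()
            with np.errstate(invalid="ignore"):
                pbad = (parr < 0.0) | (parr > 1.0)
            if pbad.any():
                i, j = np.argwhere(pbad)[0]
                raise ValueError(
                    f"detection p-value out of [0, 1] at probe "
                    f"{detection_p.index[i]!r}, sample {detection_p.columns[j]!r}"
                )
        self.values = values
        self.detection_p = detection_p

    # -- basic introspection -------------------------------------------------
    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing entries per probe."""
        return self.values.isna().mean(axis=1)

    # -- derived matrices ----------------------------------------------------
    def select_probes(self, probes: Iterable) -> "BetaMatrix":
        probes = list(probes)
        dp = self.detection_p.loc[probes] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[probes], dp)

    def select_samples(self, samples: Iterable) -> "BetaMatrix":
        samples = list(samples)
        dp = self.detection_p[samples] if self.detection_p is not None else None
        return BetaMatrix(self.values[samples], dp)

    def with_values(self, values: pd.DataFrame) -> "BetaMatrix":
        """Return a new matrix with ``values`` replaced, detection_p realigned."""
        dp = self.detection_p
        if dp is not None:
            dp = dp.loc[values.index, values.columns]
        return BetaMatrix(values, dp)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"

    def equals(self, other: "BetaMatrix") -> bool:
        if not self.values.equals(other.values):
            return False
        if (self.detection_p is None) != (other.detection_p is None):
            return False
        if self.detection_p is not None and not self.detection_p.equals(other.detection_p):
            return False
        return True


@dataclass
class CoefficientSet:
    """A named linear methylation clock: intercept + sum of probe weights.

    ``transform`` names an optional output transformation applied to the
    linear predictor ("identity", "phenoage" or "horvath"); its constants
    live in ``transform_params`` and are interpreted by
    :mod:`methclocks.clocks`.
    """

    name: str
    terms: dict[str, float]
    intercept: float = 0.0
    transform: str = "identity"
    transform_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("coefficient set must contain at least one term")
        weights = np.asarray(list(self.terms.values()), dtype=float)
        if not np.all(np.isfinite(weights)):
            raise ValueError(f"non-finite weight in coefficient set {self.name!r}")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        if self.transform not in ("identity", "phenoage", "horvath"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def probes(self) -> list[str]:
        return list(self.terms)


class SampleSheet:
    """Validated sample metadata table.

    Columns: sample_id, subject_id, tissue_role, group, stage, age, sex.
    Age may be missing (NaN); the controlled-vocabulary columns may not.
    A subject can contribute at most one tumor and one normal sample, which
    makes tumor-normal pairing unambiguous.
    """

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in SHEET_COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValueError(f"sample sheet missing columns: {missing_cols}")
        data = data.loc[:, list(SHEET_COLUMNS)].reset_index(drop=True).copy()
        dup = _first_duplicate(data["sample_id"])
        if dup is not None:
            raise ValueError(f"duplicate sample_id: {dup!r}")
        for col, vocab in (
            ("tissue_role", TISSUE_ROLES),
            ("group", GROUPS),
            ("stage", STAGES),
            ("sex", SEXES),
        ):
            bad = sorted(set(data[col]) - set(vocab))
            if bad:
                raise ValueError(f"invalid {col} value(s) {bad}; allowed: {list(vocab)}")
        data["age"] = pd.to_numeric(data["age"], errors="raise")
        tn = data[data["tissue_role"].isin(["tumor", "normal"])]
        dup_pairs = tn.duplicated(subset=["subject_id", "tissue_role"])
        if dup_pairs.any():
            row = tn[dup_pairs].iloc[0]
            raise ValueError(
                f"subject {row['subject_id']!r} has more than one "
                f"{row['tissue_role']} sample; pairing would be ambiguous"
            )
        self.data = data

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def ages(self) -> pd.Series:
        """Chronological age indexed by sample_id (NaN where unknown)."""
        return self.data.set_index("sample_id")["age"]

    def complete_pairs(self) -> tuple[pd.DataFrame, list]:
        """Tumor/normal sample-id pairs per subject.

        Returns a frame with columns (subject_id, tumor_sample, normal_sample)
        and the list of subjects excluded because one role is missing.
        """
        tn = self.data[self.data["tissue_role"].isin(["tumor", "normal"])]
        wide = tn.pivot(index="subject_id", columns="tissue_role", values="sample_id")
        for col in ("tumor", "normal"):
            if col not in wide.columns:
                wide[col] = np.nan
        complete = wide.dropna(subset=["tumor", "normal"])
        excluded = sorted(set(wide.index) - set(complete.index))
        pairs = pd.DataFrame(
            {
                "subject_id": complete.index,
                "tumor_sample": complete["tumor"].to_numpy(),
                "normal_sample": complete["normal"].to_numpy(),
            }
        ).reset_index(drop=True)
        return pairs, excluded

    def subject_stage(self) -> pd.Series:
        """Stage per subject (from any of the subject's rows; they agree by
        construction in simulated data, and the first row wins otherwise)."""
        return self.data.groupby("subject_id", sort=False)["stage"].first()


def make_score_table(
    sample_ids: Iterable,
    clock: str,
    scores: Iterable[float],
    n_terms_used: Iterable[int],
    n_terms_imputed: Iterable[int],
) -> pd.DataFrame:
    """Assemble a score table with the canonical column schema."""
    table = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "clock": clock,
            "score": np.asarray(list(scores), dtype=float),
            "n_terms_used": np.asarray(list(n_terms_used), dtype=int),
            "n_terms_imputed": np.asarray(list(n_terms_imputed), dtype=int),
        }
    )
    if not np.all(np.isfinite(table["score"].to_numpy())):
        raise ValueError("non-finite clock score")
    return table


def scores_as_series(scores: pd.DataFrame, clock: str | None = None) -> pd.Series:
    """Extract one clock's scores as a Series indexed by sample_id."""
    if clock is not None:
        scores = scores[scores["clock"] == clock]
        if scores.empty:
            raise ValueError(f"no scores for clock {clock!r}")
    elif scores["clock"].nunique() > 1:
        raise ValueError("score table holds several clocks; pass clock=...")
    return scores.set_index("sample_id")["score"]


@dataclass
class PairedTestResult:
    """Wilcoxon signed-rank comparison of a clock between paired tissues.

    ``n_pairs`` counts the informative (non-zero difference) pairs actually
    ranked; ``n_zero_diffs`` counts pairs dropped because tumor and normal
    scores were identical. ``statistic_w`` is the sum of ranks of positive
    (tumor minus normal) differences.
    """

    clock: str
    stratum: str
    n_pairs: int
    n_zero_diffs: int
    statistic_w: float
    p_value: float
    median_diff: float
    direction: str  # tumor_higher | normal_higher | none

    def __post_init__(self) -> None:
        n = self.n_pairs
        if not (0 <= self.statistic_w <= n * (n + 1) / 2):
            raise ValueError("signed-rank statistic outside [0, n(n+1)/2]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")
        if self.direction not in ("tumor_higher", "normal_higher", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass
class ROCResult:
    """ROC curve and AUC for discriminating a positive class by a score."""

    clock: str
    n_pos: int
    n_neg: int
    points: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str  # delong | logit_wald
    positive_definition: str
    flipped: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not (np.allclose(pts[0], [0.0, 0.0]) and np.allclose(pts[-1], [1.0, 1.0])):
            raise ValueError("ROC curve must start at (0,0) and end at (1,1)")
        if np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12):
            raise ValueError("ROC curve coordinates must be non-decreasing")
        trap = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        if abs(trap - self.auc) > 1e-12:
            raise ValueError(
                f"AUC {self.auc} does not match trapezoidal curve integral {trap}"
            )
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValueError("AUC outside its confidence interval")
        self.points = pts
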