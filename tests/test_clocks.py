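from decimal import Decimal

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import methclocks as mc
from methclocks.clocks import (
    PhenoAgeTransformParams,
    horvath_age_transform,
    phenoage_inverse,
    phenoage_transform,
)

from conftest import MRSCORE_PROBES, indicator_matrix

# the ten published MRscore weights, frozen as decimal strings
MRSCORE_WEIGHTS = {
    "cg01612140": "-0.38253",
    "cg05575921": "-0.92224",
    "cg06126421": "-1.70129",
    "cg08362785": "2.71749",
    "cg10321156": "-0.02073",
    "cg14975410": "-0.04156",
    "cg19572487": "-0.28069",
    "cg23665802": "-0.89440",
    "cg24704287": "-2.98637",
    "cg25983901": "-1.80325",
}


def test_bundled_weights_match_golden_digits():
    c = mc.load_bundled_coefficients("mrscore")
    assert c.n_terms == 10 and c.intercept == 0.0
    for probe, digits in MRSCORE_WEIGHTS.items():
        assert c.terms[probe] == float(Decimal(digits))


@pytest.mark.parametrize("probe", MRSCORE_PROBES)
def test_indicator_vector_recovers_each_weight(probe):
    """beta=1 at one CpG and 0 elsewhere scores exactly that CpG's weight."""
    bm = indicator_matrix(MRSCORE_PROBES, hot_probe=probe)
    table = mc.compute_linear_score(bm, "mrscore", missing_policy="error")
    assert table["score"].iloc[0] == float(Decimal(MRSCORE_WEIGHTS[probe]))


def test_zero_vector_scores_zero():
    bm = indicator_matrix(MRSCORE_PROBES)
    table = mc.compute_linear_score(bm, "mrscore", missing_policy="error")
    assert table["score"].iloc[0] == 0.0


def test_all_ones_scores_decimal_sum():
    """All-ones beta vector reproduces the exact-decimal sum of the weights."""
    bm = indicator_matrix(MRSCORE_PROBES, fill=1.0)
    table = mc.compute_linear_score(bm, "mrscore", missing_policy="error")
    exact = float(sum(Decimal(w) for w in MRSCORE_WEIGHTS.values()))
    assert abs(table["score"].iloc[0] - exact) < 1e-12


@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_score_linearity_in_beta(alpha):
    """score(a*b1 + (1-a)*b2) = a*score(b1) + (1-a)*score(b2)."""
    rng = np.random.default_rng(123)
    b1 = rng.uniform(0, 1, len(MRSCORE_PROBES))
    b2 = rng.uniform(0, 1, len(MRSCORE_PROBES))
    mix = alpha * b1 + (1 - alpha) * b2

    def score(vec):
        vals = pd.DataFrame({"s": vec}, index=MRSCORE_PROBES)
        t = mc.compute_linear_score(mc.BetaMatrix(vals), "mrscore", missing_policy="error")
        return t["score"].iloc[0]

    assert score(mix) == pytest.approx(alpha * score(b1) + (1 - alpha) * score(b2), abs=1e-12)


def test_intercept_and_custom_set():
    c = mc.CoefficientSet(name="toy", terms={"cgA": 2.0, "cgB": -1.0}, intercept=10.0)
    vals = pd.DataFrame({"s1": [0.5, 0.25]}, index=["cgA", "cgB"])
    t = mc.compute_linear_score(mc.BetaMatrix(vals), c, missing_policy="error")
    assert t["score"].iloc[0] == pytest.approx(10.0 + 1.0 - 0.25)


# -- missing policies --------------------------------------------------------

def _matrix_with_hole():
    rng = np.random.default_rng(77)
    vals = pd.DataFrame(
        rng.uniform(0.2, 0.8, (len(MRSCORE_PROBES), 4)),
        index=MRSCORE_PROBES,
        columns=list("abcd"),
    )
    vals.loc["cg05575921", "b"] = np.nan
    return mc.BetaMatrix(vals)


def test_error_policy_aborts_naming_cell():
    with pytest.raises(ValueError, match="cg05575921.*b"):
        mc.compute_linear_score(_matrix_with_hole(), "mrscore", missing_policy="error")


def test_mean_impute_substitutes_probe_mean():
    bm = _matrix_with_hole()
    with pytest.warns(UserWarning, match="mean-imputing"):
        t = mc.compute_linear_score(bm, "mrscore", missing_policy="mean_impute")
    row = t[t["sample_id"] == "b"].iloc[0]
    assert row["n_terms_imputed"] == 1 and row["n_terms_used"] == 9
    # recompute by hand
    c = mc.load_bundled_coefficients("mrscore")
    filled = bm.values.copy()
    filled.loc["cg05575921", "b"] = bm.values.loc["cg05575921"].mean()
    expected = sum(c.terms[p] * filled.loc[p, "b"] for p in c.probes)
    assert row["score"] == pytest.approx(expected, abs=1e-12)


def test_mean_impute_equals_error_policy_without_missingness(small_beta):
    coef = mc.CoefficientSet(name="toy", terms={p: 0.5 for p in small_beta.probe_ids})
    t_err = mc.compute_linear_score(small_beta, coef, missing_policy="error")
    t_imp = mc.compute_linear_score(small_beta, coef, missing_policy="mean_impute")
    assert np.array_equal(t_err["score"].to_numpy(), t_imp["score"].to_numpy())
    assert (t_imp["n_terms_imputed"] == 0).all()


def test_skip_renormalize_preserves_total_absolute_weight():
    bm = _matrix_with_hole()
    t = mc.compute_linear_score(bm, "mrscore", missing_policy="skip_renormalize")
    row = t[t["sample_id"] == "b"].iloc[0]
    c = mc.load_bundled_coefficients("mrscore")
    used = [p for p in c.probes if p != "cg05575921"]
    factor = sum(abs(w) for w in c.terms.values()) / sum(abs(c.terms[p]) for p in used)
    expected = factor * sum(c.terms[p] * bm.values.loc[p, "b"] for p in used)
    assert row["score"] == pytest.approx(expected, abs=1e-12)
    assert row["n_terms_imputed"] == 1


def test_no_overlap_is_error():
    vals = pd.DataFrame({"s1": [0.5]}, index=["cgZZZ"])
    with pytest.raises(ValueError, match="none of clock"):
        mc.compute_linear_score(mc.BetaMatrix(vals), "mrscore")


# -- phenoage-style transform ------------------------------------------------

def test_phenoage_identity_parameterization():
    p = PhenoAgeTransformParams()  # slope 1, offset 0, unit Gompertz scale
    p.validate()
    for x in (-3.0, 0.0, 2.5):
        assert phenoage_transform(x, p) == pytest.approx(x, abs=1e-12)


def test_phenoage_monotone_increasing():
    p = PhenoAgeTransformParams(
        age_offset=141.5, slope=0.09, gomp_coeff=0.005, gamma=0.007, horizon=120.0
    )
    p.validate()
    grid = np.linspace(-20, 10, 50)
    vals = phenoage_transform(grid, p)
    assert np.all(np.diff(vals) > 0)


def test_phenoage_roundtrip_against_numerical_inverse():
    p = PhenoAgeTransformParams(
        age_offset=141.5, slope=0.09, gomp_coeff=0.005, gamma=0.007, horizon=120.0
    )
    for lp in (-8.0, -2.0, 0.0, 3.0):
        age = phenoage_transform(lp, p)
        # independent numerical inverse
        lp_num = brentq(lambda x: phenoage_transform(x, p) - age, -50, 50, xtol=1e-12)
        assert lp_num == pytest.approx(lp, abs=1e-9)
        assert phenoage_inverse(age, p) == pytest.approx(lp, abs=1e-9)


def test_phenoage_invalid_constants_identified():
    with pytest.raises(ValueError, match="gomp_coeff"):
        phenoage_transform(0.0, PhenoAgeTransformParams(gomp_coeff=-1.0))
    with pytest.raises(ValueError, match="Gompertz scale"):
        PhenoAgeTransformParams(horizon=-5.0).validate()


def test_phenoage_transform_applied_through_scorer():
    c = mc.CoefficientSet(
        name="toyage",
        terms={"cgA": 1.0},
        transform="phenoage",
        transform_params={"age_offset": 100.0, "slope": 2.0},
    )
    vals = pd.DataFrame({"s1": [0.5]}, index=["cgA"])
    t = mc.compute_linear_score(mc.BetaMatrix(vals), c, missing_policy="error")
    assert t["score"].iloc[0] == pytest.approx(100.0 + 0.5 / 2.0)


def test_horvath_age_transform_continuous_increasing():
    xs = np.linspace(-3, 3, 121)
    ys = horvath_age_transform(xs)
    assert np.all(np.diff(ys) > 0)
    assert horvath_age_transform(0.0) == pytest.approx(20.0)


# -- age acceleration --------------------------------------------------------

def _age_sheet(ages, prefix="s"):
    rows = [
        dict(sample_id=f"{prefix}{i}", subject_id=f"{prefix}{i}", tissue_role="blood",
             group="none", stage="unknown", age=a, sex="unknown")
        for i, a in enumerate(ages)
    ]
    return mc.SampleSheet(pd.DataFrame(rows))


def _score_table(values, clock="DNAmAge", prefix="s"):
    return mc.containers.make_score_table(
        [f"{prefix}{i}" for i in range(len(values))], clock, values,
        [1] * len(values), [0] * len(values),
    )


def test_age_accel_zero_when_clock_equals_age():
    ages = [50.0, 60.0, 70.0, 80.0]
    accel = mc.age_acceleration(_score_table(ages), _age_sheet(ages))
    assert np.allclose(accel["score"].to_numpy(), 0.0, atol=1e-12)
    assert (accel["clock"] == "DNAmAgeAccel").all()


def test_age_accel_recovers_constructed_residuals():
    """DNAmAge = 2*age + 5 + e with e centered and orthogonal to age."""
    age = np.array([50.0, 55.0, 60.0, 65.0, 70.0])
    centered = age - age.mean()
    e = np.array([1.0, -1.0, 0.5, -1.0, 0.5])
    e = e - e.mean()
    e = e - (e @ centered) / (centered @ centered) * centered
    dnam = 2.0 * age + 5.0 + e
    accel = mc.age_acceleration(_score_table(dnam), _age_sheet(age))
    assert np.allclose(accel["score"].to_numpy(), e, atol=1e-9)


def test_age_accel_residuals_orthogonal_to_age():
    rng = np.random.default_rng(2)
    age = rng.uniform(50, 80, 40)
    dnam = 0.8 * age + rng.normal(0, 5, 40)
    accel = mc.age_acceleration(_score_table(dnam), _age_sheet(age))
    r = accel["score"].to_numpy()
    assert abs(r.sum()) < 1e-8
    assert abs(r @ age) < 1e-6


def test_age_accel_excludes_unknown_ages():
    ages = [50.0, 60.0, 70.0, np.nan]
    accel = mc.age_acceleration(_score_table([48, 61, 72, 55]), _age_sheet(ages))
    assert len(accel) == 3
    assert "s3" not in set(accel["sample_id"])


def test_age_accel_equal_ages_rejected():
    ages = [60.0, 60.0, 60.0]
    with pytest.raises(ValueError, match="slope undefined"):
        mc.age_acceleration(_score_table([50, 60, 70]), _age_sheet(ages))
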