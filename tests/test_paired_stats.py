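import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

import methclocks as mc
from methclocks.paired_stats import wilcoxon_signed_rank


def brute_force_signed_rank_p(diffs):
    """Independent oracle: enumerate every sign assignment explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    tol = 1e-9
    p_ge = np.mean(ws >= w_obs - tol)
    p_le = np.mean(ws <= w_obs + tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def test_all_positive_five_diffs():
    """diffs 1..5: W = 15 and exact two-sided p = 2/32."""
    res = wilcoxon_signed_rank([1, 2, 3, 4, 5], mode="exact")
    assert res.statistic_w == 15
    assert res.p_value == pytest.approx(0.0625)
    assert res.n == 5 and res.method == "exact"


def test_antisymmetric_diffs_give_p_one():
    res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0], mode="exact")
    assert res.p_value == 1.0


@pytest.mark.parametrize("n", range(3, 13))
def test_exact_matches_enumeration_oracle(n):
    """Module p equals full 2^n enumeration for tie-free vectors."""
    rng = np.random.default_rng(100 + n)
    for _ in range(5):
        d = rng.normal(0, 1, n)
        res = wilcoxon_signed_rank(d, mode="exact")
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)


def test_exact_with_ties_matches_enumeration():
    d = np.array([1.0, 1.0, -1.0, 2.0, 3.0, -2.0, 2.0])
    res = wilcoxon_signed_rank(d, mode="exact")
    assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)


def test_exact_agrees_with_scipy():
    """Independent library cross-check of the exact two-sided p."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        d = rng.normal(0, 1, 10)
        res = wilcoxon_signed_rank(d, mode="exact")
        p_sp = scipy_wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(p_sp, abs=1e-12)


def test_negating_diffs_mirrors_w_and_keeps_p():
    rng = np.random.default_rng(4)
    d = rng.normal(0, 1, 15)
    r1 = wilcoxon_signed_rank(d, mode="exact")
    r2 = wilcoxon_signed_rank(-d, mode="exact")
    n = r1.n
    assert r2.statistic_w == pytest.approx(n * (n + 1) / 2 - r1.statistic_w)
    assert r2.p_value == pytest.approx(r1.p_value, abs=1e-12)


def test_exact_and_normal_agree_at_n25():
    """Exact vs continuity-corrected normal p within 0.01, tie-free n=25."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        d = rng.normal(0, 1, 25)
        pe = wilcoxon_signed_rank(d, mode="exact").p_value
        pn = wilcoxon_signed_rank(d, mode="normal").p_value
        assert abs(pe - pn) < 0.01


def test_zero_diffs_dropped():
    res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -0.5])
    assert res.n == 3 and res.n_zero == 2


def test_all_zero_diffs_error():
    with pytest.raises(ValueError, match="all differences are zero"):
        wilcoxon_signed_rank([0.0, 0.0])


def test_exact_guard_above_25():
    with pytest.raises(ValueError, match="exact mode limited"):
        wilcoxon_signed_rank(np.arange(1, 31), mode="exact")


def test_auto_switches_to_normal_on_large_n():
    rng = np.random.default_rng(5)
    res = wilcoxon_signed_rank(rng.normal(0, 1, 60), mode="auto")
    assert res.method == "normal"


def test_normal_mode_agrees_with_scipy_correction():
    rng = np.random.default_rng(6)
    d = rng.normal(0.3, 1, 60)
    res = wilcoxon_signed_rank(d, mode="normal")
    p_sp = scipy_wilcoxon(d, method="approx", correction=True,
                          alternative="two-sided").pvalue
    assert res.p_value == pytest.approx(p_sp, rel=1e-9)


# -- pairing and strata ------------------------------------------------------

def _score_series(sheet, values):
    return pd.Series(values, index=sheet.sample_ids)


def test_pair_samples_excludes_incomplete(paired_sheet):
    values = pd.Series(1.0, index=paired_sheet.sample_ids)
    pv = mc.pair_samples(values, paired_sheet)
    assert len(pv.frame) == 5
    assert pv.n_excluded == 1  # the tumor-only subject


def test_pair_samples_order_invariant(paired_sheet):
    rng = np.random.default_rng(0)
    values = pd.Series(rng.uniform(0, 1, len(paired_sheet.sample_ids)),
                       index=paired_sheet.sample_ids)
    shuffled = mc.SampleSheet(
        paired_sheet.data.sample(frac=1, random_state=9).reset_index(drop=True)
    )
    pv1 = mc.pair_samples(values, paired_sheet)
    pv2 = mc.pair_samples(values, shuffled)
    f1 = pv1.frame.sort_values("subject_id").reset_index(drop=True)
    f2 = pv2.frame.sort_values("subject_id").reset_index(drop=True)
    assert f1.equals(f2)


def test_pair_samples_zero_pairs_error():
    rows = [dict(sample_id="x_T", subject_id="x", tissue_role="tumor",
                 group="none", stage="I", age=60.0, sex="M")]
    sheet = mc.SampleSheet(pd.DataFrame(rows))
    with pytest.raises(ValueError, match="no complete"):
        mc.pair_samples(pd.Series({"x_T": 1.0}), sheet)


def _stage_sheet(stages):
    rows = []
    for i, stage in enumerate(stages):
        subj = f"q{i}"
        for role in ("tumor", "normal"):
            rows.append(dict(sample_id=f"{subj}_{role[0]}", subject_id=subj,
                             tissue_role=role, group="none", stage=stage,
                             age=60.0, sex="F"))
    return mc.SampleSheet(pd.DataFrame(rows))


def _stage_scores(sheet, shift=0.5):
    rng = np.random.default_rng(21)
    vals = {}
    for _, row in sheet.data.iterrows():
        base = rng.uniform(0, 1)
        vals[row["sample_id"]] = base + (shift if row["tissue_role"] == "tumor" else 0.0)
    return mc.containers.make_score_table(
        list(vals), "MRscore", list(vals.values()), [10] * len(vals), [0] * len(vals)
    )


def test_single_stage_stratum_equals_overall():
    sheet = _stage_sheet(["II"] * 8)
    scores = _stage_scores(sheet)
    overall = mc.compare_by_stratum(scores, sheet, strata="overall")
    by_stage = mc.compare_by_stratum(scores, sheet, strata="stage")
    assert len(overall) == 1 and len(by_stage) == 1
    assert by_stage[0].stratum == "II"
    assert by_stage[0].statistic_w == overall[0].statistic_w
    assert by_stage[0].p_value == overall[0].p_value


def test_small_stratum_skipped_not_error():
    sheet = _stage_sheet(["I"] * 6 + ["IV"])  # one lone stage-IV pair
    scores = _stage_scores(sheet)
    results = mc.compare_by_stratum(scores, sheet, strata="stage")
    assert {r.stratum for r in results} == {"I"}


def test_direction_tumor_higher_from_negative_shift():
    """Hypomethylation at negative-weight MRscore CpGs raises the tumor
    score: sign bookkeeping against the generative model."""
    effects = {p: -1.0 for p in ("cg06126421", "cg24704287", "cg25983901")}
    cfg = mc.SimulationConfig(
        n_subjects=80,
        probes=mc.default_probes(mc.load_bundled_coefficients("mrscore").probes, 30),
        effects=effects,
        seed=42,
    )
    beta, sheet = mc.simulate_paired(cfg)
    scores = mc.mrscore(beta)
    (res,) = mc.compare_by_stratum(scores, sheet)
    assert res.direction == "tumor_higher"
    assert res.p_value < 0.01
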