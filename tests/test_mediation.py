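"""Sobel testing, FDR adjustment, alpha-leg OLS, and effect decomposition."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medhaz import (
    SimScenario,
    SurvivalDataset,
    adjust_pvalues,
    decompose,
    fit_alpha,
    fit_alpha_all,
    generate,
    joint_significance_test,
    naive_method,
    refit_and_test,
    sobel_test,
)


# --------------------------------------------------------------------------
# Sobel test
# --------------------------------------------------------------------------

def test_sobel_null_point():
    ie, se, p = sobel_test(2.0, 0.5, 0.0, 1.0)
    assert ie == 0.0
    assert se == pytest.approx(2.0)
    assert p == pytest.approx(1.0)


def test_sobel_closed_form_case():
    ie, se, p = sobel_test(1.0, 0.5, 1.0, 0.5)
    assert ie == 1.0
    assert se == pytest.approx(0.70711, abs=1e-5)
    assert ie / se == pytest.approx(1.41421, abs=1e-5)
    assert p == pytest.approx(0.15730, abs=1e-5)


def test_sobel_monotone_in_standard_errors():
    _, se1, p1 = sobel_test(1.0, 0.3, 0.8, 0.4)
    _, se2, p2 = sobel_test(1.0, 0.6, 0.8, 0.8)
    assert se2 == pytest.approx(2 * se1)
    assert p2 > p1


def test_sobel_degenerate_variance_raises():
    with pytest.raises(ValueError, match="degenerate"):
        sobel_test(1.0, 0.0, 1.0, 0.0)
    ie, se, p = sobel_test(0.0, 0.0, 0.0, 0.0)
    assert (ie, se, p) == (0.0, 0.0, 1.0)


@settings(deadline=None, derandomize=True)
@given(
    a=st.floats(-3, 3),
    sa=st.floats(0.01, 2),
    b=st.floats(-3, 3),
    sb=st.floats(0.01, 2),
)
def test_sobel_symmetric_in_the_two_legs(a, sa, b, sb):
    r1 = sobel_test(a, sa, b, sb)
    r2 = sobel_test(b, sb, a, sa)
    assert r1[1] == pytest.approx(r2[1], rel=1e-12)
    assert r1[2] == pytest.approx(r2[2], rel=1e-12)


# --------------------------------------------------------------------------
# multiplicity adjustment
# --------------------------------------------------------------------------

def test_bh_step_up_hand_computed():
    out = adjust_pvalues([0.01, 0.02, 0.03], "bh")
    assert out == pytest.approx([0.03, 0.03, 0.03])


def test_single_pvalue_unchanged():
    assert adjust_pvalues([0.2], "bh") == pytest.approx([0.2])
    assert adjust_pvalues([0.2], "by") == pytest.approx([0.2])


def test_by_is_bh_times_harmonic_sum():
    p = np.array([0.001, 0.01, 0.04, 0.2, 0.7])
    h = np.sum(1.0 / np.arange(1, 6))
    assert adjust_pvalues(p, "by") == pytest.approx(
        np.minimum(adjust_pvalues(p, "bh") * h, 1.0)
    )


def test_empty_vector_passthrough():
    assert adjust_pvalues([], "bh").size == 0


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
def test_adjustment_ordering_properties(p):
    p = np.array(p)
    bh = adjust_pvalues(p, "bh")
    by = adjust_pvalues(p, "by")
    assert np.all(bh >= p - 1e-12) and np.all(bh <= 1)
    assert np.all(by >= bh - 1e-12)
    # monotone transform: ordering preserved
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(bh[order]) >= -1e-12)


def test_joint_significance_is_max():
    assert joint_significance_test(0.01, 0.20) == 0.20
    assert joint_significance_test(0.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        joint_significance_test(-0.1, 0.5)


# --------------------------------------------------------------------------
# alpha leg
# --------------------------------------------------------------------------

def _alpha_dataset(rng, n=200, q=2, p=3):
    x = (rng.random(n) < 0.5).astype(float)
    Z = rng.standard_normal((n, q))
    M = 0.3 + 1.5 * x[:, None] + Z @ rng.standard_normal((q, p)) * 0.2
    M = M + rng.standard_normal((n, p))
    return SurvivalDataset(
        time=np.ones(n), status=np.ones(n, dtype=int), exposure=x, covariates=Z, mediators=M
    )


def test_exact_linear_mediator_is_degenerate(rng):
    n = 50
    x = rng.standard_normal(n)
    data = SurvivalDataset(
        time=np.ones(n),
        status=np.ones(n, dtype=int),
        exposure=x,
        mediators=(2.0 * x)[:, None],
    )
    f = fit_alpha(data, 0)
    assert f.alpha_hat == pytest.approx(2.0)
    assert f.alpha_se == pytest.approx(0.0, abs=1e-10)
    assert f.degenerate


def test_alpha_matches_statsmodels(rng):
    import statsmodels.api as sm

    data = _alpha_dataset(rng)
    f = fit_alpha(data, 1)
    X = sm.add_constant(np.column_stack([data.exposure, data.covariates]))
    ref = sm.OLS(data.mediators[:, 1], X).fit()
    assert f.alpha_hat == pytest.approx(ref.params[1], rel=1e-10)
    assert f.alpha_se == pytest.approx(ref.bse[1], rel=1e-8)


def test_alpha_vectorised_matches_per_mediator(rng):
    data = _alpha_dataset(rng, p=5)
    a, se = fit_alpha_all(data)
    for k in range(5):
        f = fit_alpha(data, k)
        assert a[k] == pytest.approx(f.alpha_hat, rel=1e-10)
        assert se[k] == pytest.approx(f.alpha_se, rel=1e-10)


def test_alpha_permutation_invariant(rng):
    data = _alpha_dataset(rng)
    perm = rng.permutation(data.n)
    f1 = fit_alpha(data, 0)
    f2 = fit_alpha(data.subset(perm), 0)
    assert f1.alpha_hat == pytest.approx(f2.alpha_hat, rel=1e-10)


def test_constant_exposure_rejected(rng):
    n = 30
    data = SurvivalDataset(
        time=np.ones(n),
        status=np.ones(n, dtype=int),
        exposure=np.full(n, 2.0),
        mediators=rng.standard_normal((n, 1)),
    )
    with pytest.raises(ValueError, match="constant"):
        fit_alpha(data, 0)


def test_alpha_recovery_under_generator():
    scen = SimScenario(n=1000, p=4, target_censoring=0.15, censor_upper=1.3, seed=31)
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(np.random.SeedSequence([31, rep]))
        data, _ = generate(scen, rng=rng)
        f = fit_alpha(data, 0)  # true alpha = 1
        hits += abs(f.alpha_hat - 1.0) < 3 * f.alpha_se
    assert hits >= 19


# --------------------------------------------------------------------------
# refit + test, decomposition
# --------------------------------------------------------------------------

def test_empty_selection_short_circuits(small_data):
    data, _ = small_data
    records, joint = refit_and_test(data, [])
    assert records == [] and joint is None


def test_too_many_selected_raises(small_data):
    data, _ = small_data
    s2 = np.arange(data.n_events + 1)
    with pytest.raises(ValueError, match="events"):
        refit_and_test(data, s2)


def test_record_invariants_and_single_true_mediator():
    scen = SimScenario(
        n=2000,
        p=1,
        alpha_true=np.array([1.0]),
        beta_true=np.array([1.0]),
        target_censoring=0.15,
        censor_upper=1.5,
        seed=13,
    )
    data, _ = generate(scen)
    records, joint = refit_and_test(data, [0])
    (r,) = records
    assert r.ie_hat == r.alpha_hat * r.beta_hat
    assert r.sobel_se**2 == pytest.approx(
        r.alpha_hat**2 * r.beta_se**2 + r.beta_hat**2 * r.alpha_se**2
    )
    assert 0 <= r.p_raw <= r.p_bh <= r.p_by <= 1
    assert r.ci_low <= 1.0 <= r.ci_high  # true IE covered
    assert abs(r.ie_hat - 1.0) < 4 * r.sobel_se


def test_outcome_only_mediator_rarely_significant():
    """A mediator with alpha=0 (pure outcome predictor) should not be flagged."""
    scen = SimScenario(
        n=400,
        p=2,
        alpha_true=np.array([0.0, 1.0]),
        beta_true=np.array([0.5, 1.0]),
        target_censoring=0.15,
        censor_upper=1.3,
        seed=17,
    )
    flagged = 0
    for rep in range(20):
        rng = np.random.default_rng(np.random.SeedSequence([17, rep]))
        data, _ = generate(scen, rng=rng)
        records, _ = refit_and_test(data, [0, 1])
        flagged += records[0].significant
    assert flagged <= 2


def test_decomposition_identity_and_truth_arithmetic():
    recs = [
        dataclasses.replace(_dummy_record(), ie_hat=1.0) for _ in range(4)
    ]
    dec = decompose(1.0, recs, x=0.0, x_star=1.0)
    assert dec.de == 1.0 and dec.ie_total == 4.0 and dec.te == 5.0
    assert dec.te == dec.de + dec.ie_total


def test_decomposition_zero_contrast_warns():
    with pytest.warns(UserWarning):
        dec = decompose(1.0, [_dummy_record()], x=1.0, x_star=1.0)
    assert dec.te == dec.de == dec.ie_total == 0.0


def test_decomposition_sign_flip():
    recs = [_dummy_record()]
    d1 = decompose(0.7, recs, x=0.0, x_star=1.0)
    d2 = decompose(0.7, recs, x=1.0, x_star=0.0)
    assert d2.te == -d1.te and d2.de == -d1.de and d2.ie_total == -d1.ie_total


def _dummy_record():
    from medhaz import MediationRecord

    return MediationRecord(
        mediator="M1",
        index=0,
        alpha_hat=1.0,
        alpha_se=0.1,
        beta_hat=0.5,
        beta_se=0.1,
        ie_hat=0.5,
        sobel_se=0.12,
        p_raw=0.01,
        p_bh=0.02,
        p_by=0.04,
        ci_low=0.26,
        ci_high=0.74,
        significant=True,
    )


def test_naive_single_mediator_equals_refit(rng):
    scen = SimScenario(
        n=400,
        p=1,
        alpha_true=np.array([1.0]),
        beta_true=np.array([1.0]),
        target_censoring=0.15,
        censor_upper=1.4,
        seed=23,
    )
    data, _ = generate(scen)
    df = naive_method(data)
    records, _ = refit_and_test(data, [0])
    r = records[0]
    row = df.iloc[0]
    assert row["beta_hat"] == pytest.approx(r.beta_hat, rel=1e-8)
    assert row["alpha_hat"] == pytest.approx(r.alpha_hat, rel=1e-10)
    assert row["p_raw"] == pytest.approx(r.p_raw, rel=1e-6, abs=1e-12)


def test_naive_all_null_makes_no_discoveries():
    scen = SimScenario(
        n=300,
        p=200,
        alpha_true=np.zeros(200),
        beta_true=np.zeros(200),
        target_censoring=0.15,
        censor_upper=2.0,
        seed=29,
    )
    total = 0
    for rep in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([29, rep]))
        data, _ = generate(scen, rng=rng)
        df = naive_method(data)
        total += int(df["significant_bh"].sum())
    assert total == 0
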