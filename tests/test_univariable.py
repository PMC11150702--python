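"""Univariable MR estimators against closed-form cases and WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
    egger,
    ivw,
    leave_one_out,
    mode_estimators,
    wald_ratio,
    weighted_median,
)
from tests.conftest import hset


@pytest.mark.parametrize(
    "bx, sx, by, sy, beta, se",
    [
        (0.1, 0.01, 0.05, 0.02, 0.5, 0.2),
        (1.0, 0.05, 0.0, 0.02, 0.0, 0.02),
        (-0.1, 0.01, 0.05, 0.02, -0.5, 0.2),
    ],
)
def test_wald_ratio_arithmetic(bx, sx, by, sy, beta, se):
    est = wald_ratio(bx, sx, by, sy)
    assert est.beta == pytest.approx(beta)
    assert est.se == pytest.approx(se)


def test_wald_ratio_zero_exposure_effect_raises():
    with pytest.raises(UndefinedRatioError):
        wald_ratio(0.0, 0.01, 0.1, 0.02)


def test_ivw_exact_consensus_gives_zero_q():
    bx = np.array([0.1, 0.2, -0.15, 0.05])
    c = 0.7
    h = hset(bx, c * bx, [0.01, 0.02, 0.01, 0.03])
    est, het = ivw(h)
    assert est.beta == pytest.approx(c, abs=1e-12)
    assert het.q == pytest.approx(0.0, abs=1e-12)
    assert het.df == 3


def test_ivw_single_snp_equals_wald_ratio():
    h = hset([0.1], [0.05], [0.02], sx=[0.01])
    est, het = ivw(h)
    wald = wald_ratio(0.1, 0.01, 0.05, 0.02)
    assert est.beta == pytest.approx(wald.beta)
    assert est.se == pytest.approx(wald.se)
    assert het.df == 0


def _wls_oracle(bx, by, sy, with_intercept):
    """Independent generic weighted-least-squares fit (statsmodels)."""
    x = sm.add_constant(bx) if with_intercept else bx[:, None]
    return sm.WLS(by, x, weights=1.0 / sy**2).fit()


def test_ivw_matches_generic_wls_oracle():
    rng = np.random.default_rng(1)
    j = 50
    bx = rng.normal(0, 0.1, j)
    sy = np.full(j, 0.02)
    by = 0.35 * bx + rng.normal(0, sy)
    h = hset(bx, by, sy)
    est, het = ivw(h, model="fixed")
    fit = _wls_oracle(bx, by, sy, with_intercept=False)
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    # Q equals the sum of squared standardized residuals
    q_direct = float(np.sum(((by - est.beta * bx) / sy) ** 2))
    assert het.q == pytest.approx(q_direct, abs=1e-10)


def test_egger_exact_directed_pleiotropy_recovered():
    bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
    a, theta = 0.02, 0.4
    by = a + theta * bx
    slope, intercept, het = egger(hset(bx, by, np.full(5, 0.01)))
    assert intercept.beta == pytest.approx(a, abs=1e-10)
    assert slope.beta == pytest.approx(theta, abs=1e-10)
    assert het.q == pytest.approx(0.0, abs=1e-10)
    assert het.df == 3


def test_egger_matches_generic_wls_oracle():
    rng = np.random.default_rng(2)
    j = 40
    bx = np.abs(rng.normal(0.1, 0.05, j)) + 0.01
    sy = rng.uniform(0.01, 0.05, j)
    by = 0.01 + 0.3 * bx + rng.normal(0, 3 * sy)  # overdispersed
    slope, intercept, het = egger(hset(bx, by, sy))
    fit = _wls_oracle(bx, by, sy, with_intercept=True)
    assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
    assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
    # with Q/df > 1 the multiplicative scaling equals the WLS scale
    assert het.q / het.df > 1
    assert slope.se == pytest.approx(fit.bse[1], rel=1e-8)
    assert intercept.pvalue == pytest.approx(fit.pvalues[0], rel=1e-6)


def test_egger_balanced_pleiotropy_type_i_error():
    """Intercept test rejects at roughly the nominal 5% under balanced
    pleiotropy (zero mean)."""
    rng = np.random.default_rng(3)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        j = 30
        bx = np.abs(rng.normal(0.1, 0.03, j)) + 0.02
        sy = np.full(j, 0.01)
        pleio = rng.normal(0.0, 0.01, j)  # balanced
        by = 0.3 * bx + pleio + rng.normal(0, sy)
        _, intercept, _ = egger(hset(bx, by, sy))
        rejections += intercept.pvalue < 0.05
    assert 0.02 <= rejections / reps <= 0.10


def test_weighted_median_equal_weights_is_plain_median():
    h = hset([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], [0.1, 0.1, 0.1])
    est = weighted_median(h, n_boot=200, seed=0)
    assert est.beta == pytest.approx(2.0)


def test_weighted_median_dominant_snp_limit():
    # one SNP with ~99% of the weight pins the estimate to its ratio
    bx = np.array([1.0, 0.05, 0.05])
    by = np.array([0.9, 0.2, 0.3])  # ratios 0.9, 4, 6
    sy = np.array([0.01, 0.1, 0.1])
    est = weighted_median(hset(bx, by, sy), n_boot=100, seed=0)
    assert est.beta == pytest.approx(0.9, abs=1e-3)


def test_weighted_median_robust_to_forty_pct_invalid():
    """With 40% of instruments shifted, the median stays near the valid
    slope while IVW is dragged outside the same band."""
    rng = np.random.default_rng(42)
    j, theta = 30, 0.35
    bx = rng.uniform(0.05, 0.15, j)
    sy = np.full(j, 0.01)
    by = theta * bx + rng.normal(0, sy)
    invalid = rng.choice(j, 12, replace=False)
    by[invalid] += 1.0 * bx[invalid]  # ratios shifted by +1
    h = hset(bx, by, sy)
    wm = weighted_median(h, n_boot=1000, seed=1)
    iv, _ = ivw(h)
    assert abs(wm.beta - theta) < 3 * wm.se
    assert abs(iv.beta - theta) > 3 * wm.se


def test_mode_majority_cluster():
    h = hset([1.0] * 4, [1.0, 1.0, 1.0, 5.0], [0.1] * 4)
    est = mode_estimators(h, mode="simple", n_boot=50, seed=0)
    assert est.beta == pytest.approx(1.0, abs=0.05)


def test_weighted_and_simple_modes_coincide_under_equal_weights():
    bx = np.ones(5)
    by = np.array([0.2, 0.25, 0.3, 0.9, 1.0])
    sy = np.full(5, 0.1)
    w = mode_estimators(hset(bx, by, sy), mode="weighted", n_boot=10, seed=0)
    s = mode_estimators(hset(bx, by, sy), mode="simple", n_boot=10, seed=0)
    assert w.beta == pytest.approx(s.beta, abs=1e-12)


def test_mode_recovers_majority_cluster_in_bimodal_mixture():
    rng = np.random.default_rng(7)
    j, n_valid = 30, 18
    bx = rng.uniform(0.08, 0.15, j)
    ratios = np.where(np.arange(j) < n_valid, 0.3, 1.2)
    by = ratios * bx + rng.normal(0, 0.002, j)
    h = hset(bx, by, np.full(j, 0.005))
    for mode in ("weighted", "simple"):
        est = mode_estimators(h, mode=mode, n_boot=100, seed=2)
        assert 0.2 < est.beta < 0.4


def test_leave_one_out_counts_and_planted_outlier():
    rng = np.random.default_rng(5)
    j = 20
    bx = rng.uniform(0.05, 0.2, j)
    sy = np.full(j, 0.01)
    by = 0.3 * bx + rng.normal(0, sy)
    by[4] += 0.15  # planted outlier
    entries = leave_one_out(hset(bx, by, sy))
    assert len(entries) == j
    full, _ = ivw(hset(bx, by, sy))
    deltas = {e.snp_id: abs(e.estimate.beta - full.beta) for e in entries}
    assert max(deltas, key=deltas.get) == "s4"


def test_leave_one_out_stable_on_homogeneous_data():
    bx = np.linspace(0.05, 0.2, 10)
    by = 0.3 * bx
    entries = leave_one_out(hset(bx, by, np.full(10, 0.01)))
    assert len(entries) == 10
    assert not any(e.flagged for e in entries)
    full, _ = ivw(hset(bx, by, np.full(10, 0.01)))
    assert all(full.ci_low <= e.estimate.beta <= full.ci_high for e in entries)


def test_leave_one_out_three_snps_returns_three():
    entries = leave_one_out(hset([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.01] * 3))
    assert len(entries) == 3


@pytest.mark.parametrize("func", [egger, weighted_median, mode_estimators, leave_one_out])
def test_minimum_instrument_counts_enforced(func):
    h = hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
    with pytest.raises(InsufficientInstrumentsError):
        func(h)


# ---- invariants ----------------------------------------------------------

_arrays = st.integers(3, 12).flatmap(
    lambda j: st.tuples(
        st.lists(
            st.floats(0.01, 1).map(float), min_size=j, max_size=j
        ),
        st.lists(st.floats(-2, 2), min_size=j, max_size=j),
        st.lists(st.floats(0.01, 0.5), min_size=j, max_size=j),
        st.lists(st.booleans(), min_size=j, max_size=j),
    )
)


@given(_arrays)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_ivw_equals_wls_oracle_property(data):
    bx, by, sy, signs = data
    bx = np.where(signs, -np.asarray(bx), np.asarray(bx))
    h = hset(bx, by, sy)
    est, _ = ivw(h, model="fixed")
    fit = _wls_oracle(np.asarray(bx), np.asarray(by), np.asarray(sy), False)
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    assert est.se == pytest.approx(
        float(np.sqrt(1.0 / np.sum(np.asarray(bx) ** 2 / np.asarray(sy) ** 2))),
        rel=1e-12,
    )


@given(_arrays, st.floats(0.1, 10))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_scale_equivariance(data, c):
    """Scaling all outcome effects and SEs by c scales beta and se by c."""
    bx, by, sy, _ = data
    h1 = hset(bx, by, sy)
    h2 = hset(bx, c * np.asarray(by), c * np.asarray(sy))
    for model in ("fixed", "auto"):
        e1, _ = ivw(h1, model=model)
        e2, _ = ivw(h2, model=model)
        assert e2.beta == pytest.approx(c * e1.beta, rel=1e-9, abs=1e-12)
        assert e2.se == pytest.approx(c * e1.se, rel=1e-9)
    m1 = weighted_median(h1, n_boot=10, seed=0)
    m2 = weighted_median(h2, n_boot=10, seed=0)
    assert m2.beta == pytest.approx(c * m1.beta, rel=1e-9, abs=1e-12)


@given(_arrays)
@settings(derandomize=True, max_examples=40, deadline=None)
def test_instrument_orientation_invariance(data):
    """Flipping (bx, by) signs for any subset leaves estimates unchanged."""
    bx, by, sy, flips = data
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sgn = np.where(flips, -1.0, 1.0)
    h1, h2 = hset(bx, by, sy), hset(sgn * bx, sgn * by, sy)
    e1, het1 = ivw(h1)
    e2, het2 = ivw(h2)
    assert e2.beta == pytest.approx(e1.beta, rel=1e-9, abs=1e-12)
    assert het2.q == pytest.approx(het1.q, rel=1e-9, abs=1e-9)
    m1 = weighted_median(h1, n_boot=10, seed=0)
    m2 = weighted_median(h2, n_boot=10, seed=0)
    assert m2.beta == pytest.approx(m1.beta, rel=1e-9, abs=1e-12)
    k1 = mode_estimators(h1, n_boot=5, seed=0)
    k2 = mode_estimators(h2, n_boot=5, seed=0)
    assert k2.beta == pytest.approx(k1.beta, rel=1e-6, abs=1e-9)


def test_q_zero_iff_equal_ratios():
    bx = np.array([0.1, 0.2, 0.4])
    sy = np.array([0.01, 0.02, 0.01])
    _, het_eq = ivw(hset(bx, 0.5 * bx, sy))
    assert het_eq.q < 1e-12
    by = 0.5 * bx
    by[0] += 1e-3
    _, het_ne = ivw(hset(bx, by, sy))
    assert het_ne.q > 1e-12


def test_parameter_recovery_without_pleiotropy():
    """Mean IVW estimate over 500 replicates sits within Monte-Carlo error
    of the generating slope."""
    rng = np.random.default_rng(11)
    theta, j = 0.35, 40
    means = np.empty(500)
    for r in range(500):
        bx = rng.normal(0, 0.1, j)
        sy = np.full(j, 0.02)
        by = theta * bx + rng.normal(0, sy)
        est, _ = ivw(hset(bx, by, sy))
        means[r] = est.beta
    sem = means.std(ddof=1) / np.sqrt(500)
    assert abs(means.mean() - theta) < 4 * sem
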