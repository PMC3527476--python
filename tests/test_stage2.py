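"""Stage-2 maternal model: conjugate limits, summaries, calibration."""

import numpy as np
import pandas as pd
import pytest

from matlact import stage1 as s1
from matlact import stage2 as s2


def _residuals(values, trait="MY"):
    return pd.DataFrame(
        {"cow_id": [f"c{i}" for i in range(len(values))],
         "trait": trait, "e_hat": np.asarray(values, float)}
    )


def _circ(levels, factor="lact_group"):
    return pd.DataFrame(
        {"cow_id": [f"c{i}" for i in range(len(levels))],
         factor: np.asarray(levels, int)}
    )


def _fit(values, levels, factor="lact_group", n_iter=6000, burn_in=500,
         seed=1, prior_variance=1e10):
    model = s2.build_stage2_model(_residuals(values), _circ(levels, factor),
                                  factor, prior_variance=prior_variance)
    return s2.fit_maternal_model(
        model, s1.GibbsConfig(n_iter=n_iter, burn_in=burn_in, seed=seed)
    )


# ---------------------------------------------------------------------------
# sampler correctness
# ---------------------------------------------------------------------------

def test_two_balanced_groups_contrast_is_mean_difference(rng):
    y0 = rng.normal(0.0, 2.0, 400)
    y1 = rng.normal(-5.0, 2.0, 400)
    chain = _fit(np.concatenate([y0, y1]), [0] * 400 + [1] * 400)
    c = s2.contrast(chain, 1)
    assert abs(c.mean - (y1.mean() - y0.mean())) <= 3 * c.mcse


def test_planted_null_contrasts_within_mcse():
    """No planted effect: every contrast is 0 within 3 MCSE, across seeds."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 4, 600)
        y = rng.normal(0.0, 30.0, 600)
        chain = _fit(y, g, seed=seed, n_iter=3000, burn_in=300)
        for lv in (1, 2, 3):
            c = s2.contrast(chain, lv)
            noise = 30.0 * np.sqrt(1 / (g == lv).sum() + 1 / (g == 0).sum())
            assert abs(c.mean) <= 3 * (c.mcse + noise)


def test_published_magnitude_effects_recovered(rng):
    """Group effects of the published milk-yield size planted directly on
    residual-scale data are recovered within 5 kg."""
    planted = np.array([0.0, -18.0, -47.0, -91.0])
    g = rng.integers(0, 4, 8000)
    y = planted[g] + rng.normal(0, 30.0, len(g))
    chain = _fit(y, g, n_iter=10_000, burn_in=1000)
    for lv in (1, 2, 3):
        assert s2.contrast(chain, lv).mean == pytest.approx(planted[lv], abs=5.0)


def test_flat_prior_limit_converges_to_ols(rng):
    y = np.concatenate([rng.normal(3, 1, 300), rng.normal(-3, 1, 300)])
    g = np.array([0] * 300 + [1] * 300)
    ols = y[g == 1].mean() - y[g == 0].mean()
    means = {}
    for v0 in (1e6, 1e10):
        c = s2.contrast(_fit(y, g, prior_variance=v0, seed=9), 1)
        means[v0] = c.mean
        assert abs(c.mean - ols) <= 3 * c.mcse
    assert abs(means[1e10] - ols) <= abs(means[1e6] - ols) + 0.05


# ---------------------------------------------------------------------------
# contrast summaries
# ---------------------------------------------------------------------------

def _chain_from_samples(m0, m1, factor="lact_group"):
    n = len(m0)
    samples = np.column_stack([np.zeros(n), m0, m1, np.ones(n)])
    return s1.PosteriorChain(
        labels=["mu", f"{factor}=0", f"{factor}=1", "sigma2_m"],
        samples=samples, n_iter=n, burn_in=0, seed=0,
        extra={"factor": factor, "levels": [0, 1]},
    )


def test_identical_level_samples_zero_contrast(rng):
    m = rng.normal(0, 1, 1000)
    c = s2.contrast(_chain_from_samples(m, m.copy()), 1)
    assert c.mean == 0.0 and c.hpd_low == 0.0 and c.hpd_high == 0.0


def test_normal_contrast_quantiles_match_closed_form(rng):
    delta = 2.5
    d = rng.normal(delta, 1.0, 9000)
    c = s2.contrast(_chain_from_samples(np.zeros(9000), d), 1)
    assert c.hpd_low == pytest.approx(delta - 1.96, abs=0.08)
    assert c.hpd_high == pytest.approx(delta + 1.96, abs=0.08)
    assert c.prob_negative == pytest.approx((d < 0).mean())  # exact identity


def test_location_shift_invariance(rng):
    m0, m1 = rng.normal(0, 1, 2000), rng.normal(1, 1, 2000)
    shift = rng.normal(0, 5, 2000)
    c1 = s2.contrast(_chain_from_samples(m0, m1), 1)
    c2 = s2.contrast(_chain_from_samples(m0 + shift, m1 + shift), 1)
    assert c2.mean == pytest.approx(c1.mean)
    assert c2.hpd_low == pytest.approx(c1.hpd_low)


def test_contrast_against_itself_raises(rng):
    ch = _chain_from_samples(rng.normal(size=200), rng.normal(size=200))
    with pytest.raises(s2.Stage2Error):
        s2.contrast(ch, 0, 0)


def test_missing_level_raises():
    with pytest.raises(s2.Stage2Error, match="zero observations|reference"):
        s2.build_stage2_model(_residuals([1.0, 2.0]), _circ([1, 1]), "lact_group")


# ---------------------------------------------------------------------------
# Monte-Carlo standard error
# ---------------------------------------------------------------------------

def test_mcse_iid_limit(rng):
    x = rng.normal(0, 1, 10_000)
    assert s2.mcse(x) == pytest.approx(0.01, rel=0.30)


def test_mcse_ar1_closed_form(rng):
    phi, n = 0.9, 120_000
    e = rng.normal(0, 1, n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    sd = x.std()
    expected = sd * np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
    assert s2.mcse(x) == pytest.approx(expected, rel=0.30)


def test_mcse_constant_zero():
    assert s2.mcse(np.full(500, 3.14)) == 0.0


def test_mcse_too_few_samples_raises():
    with pytest.raises(s2.Stage2Error):
        s2.mcse(np.arange(50))


# ---------------------------------------------------------------------------
# interval calibration under the model
# ---------------------------------------------------------------------------

def test_equal_tail_interval_calibration():
    """Across replicate simulations from the model, the 95% equal-tail
    interval covers the true contrast 95% +/- 5% of the time."""
    true = -6.0
    hits = 0
    n_rep = 120
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        g = rng.integers(0, 2, 300)
        y = true * (g == 1) + rng.normal(0, 8.0, 300)
        chain = _fit(y, g, n_iter=2000, burn_in=200, seed=rep)
        c = s2.contrast(chain, 1)
        hits += c.hpd_low <= true <= c.hpd_high
    assert hits / n_rep == pytest.approx(0.95, abs=0.05)


# ---------------------------------------------------------------------------
# merit-stratified generalized linear model
# ---------------------------------------------------------------------------

def test_merit_stratum_recovers_planted_effect(rng):
    n = 800
    conc = rng.integers(0, 2, n)
    ids = [f"c{i}" for i in range(n)]
    res = _residuals(-90.0 * conc + rng.normal(0, 10, n))
    circ = _circ(conc * rng.integers(1, 4, n))
    top = ids[: n // 2]
    bottom = ids[n // 2:]
    out = s2.merit_stratified_fit(res, circ, (bottom, top))
    assert out.estimate.to_numpy() == pytest.approx([-90.0, -90.0], abs=3.0)


def test_null_stratum_within_three_se(rng):
    n = 600
    conc = rng.integers(0, 2, n)
    res = _residuals(rng.normal(0, 20, n))
    circ = _circ(conc)
    out = s2.merit_stratified_fit(res, circ, ([f"c{i}" for i in range(300)],
                                              [f"c{i}" for i in range(300, n)]))
    for _, row in out.iterrows():
        assert abs(row.estimate) <= 3 * row.se


def test_balanced_design_equals_group_mean_difference(rng):
    y = np.concatenate([rng.normal(0, 1, 50), rng.normal(4, 1, 50)])
    conc = np.array([0] * 50 + [1] * 50)
    res = _residuals(y)
    circ = _circ(conc)
    ids = list(res.cow_id)
    out = s2.merit_stratified_fit(res, circ, (ids, ids))
    expected = y[conc == 1].mean() - y[conc == 0].mean()
    assert out.estimate.iloc[0] == pytest.approx(expected)


def test_single_concurrence_level_raises(rng):
    res = _residuals(rng.normal(size=10))
    circ = _circ([1] * 10)
    with pytest.raises(s2.Stage2Error, match="single concurrence"):
        s2.merit_stratified_fit(res, circ, (list(res.cow_id), list(res.cow_id)))
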