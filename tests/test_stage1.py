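"""Animal-model Gibbs sampler: conjugate limits, MME equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from matlact import preprocess as pp
from matlact import simulate as sim
from matlact import stage1 as s1
from matlact.pedigree import a_inverse, validate_and_order


def _intercept_model(y: np.ndarray) -> s1.Stage1Model:
    """Minimal model: intercept-only design, one-founder pedigree."""
    n = len(y)
    ped = validate_and_order([("solo", "0", "0")])
    return s1.Stage1Model(
        trait="MY", y=y,
        X=sparse.csr_matrix(np.ones((n, 1))), fixed_labels=["intercept"],
        Z=sparse.csr_matrix((n, 1)), A_inv=a_inverse(ped),
        cow_ids=np.array([f"c{i}" for i in range(n)]), ped_ids=ped.ids,
    )


@pytest.fixture(scope="module")
def smoke_fit():
    r = sim.simulate_herd(sim.smoke_preset())
    kept, _ = pp.apply_filters(r.phenotypes, r.testdays, r.pedigree)
    Ainv = a_inverse(r.pedigree)
    model = s1.build_stage1_model(kept, r.pedigree, "MY", Ainv)
    chain = s1.fit_animal_model(model, s1.GibbsConfig(n_iter=4000, burn_in=400, seed=5))
    return r, kept, model, chain


@pytest.fixture(scope="module")
def h2_fit():
    """Simulated herd at heritability 0.3 with a fitted milk-yield model."""
    cfg = sim.smoke_preset(
        n_founders=1200, sires_per_generation=60,
        generation_sizes=(1500, 2500, 2500), n_herds=5,
        sigma_u={"MY": 65.5, "FP": 0.015, "DIM": 3.0},  # h2 = 0.3 for MY
        maternal_lact={t: (0.0,) * 4 for t in sim.TRAITS},
    )
    r = sim.simulate_herd(cfg)
    kept, _ = pp.apply_filters(r.phenotypes, r.testdays, r.pedigree)
    Ainv = a_inverse(r.pedigree)
    model = s1.build_stage1_model(kept, r.pedigree, "MY", Ainv)
    chain = s1.fit_animal_model(model, s1.GibbsConfig(n_iter=4000, burn_in=500, seed=11))
    return r, kept, model, chain


# ---------------------------------------------------------------------------
# conjugate limits
# ---------------------------------------------------------------------------

def test_intercept_only_recovers_sample_mean(rng):
    y = rng.normal(50.0, 4.0, 500)
    model = _intercept_model(y)
    chain = s1.fit_animal_model(
        model,
        s1.GibbsConfig(n_iter=4000, burn_in=500, seed=2,
                       fix_variances=True, sigma2_u=0.0, sigma2_e=16.0),
    )
    mu = chain.param("intercept")
    from matlact.stage2 import mcse

    assert abs(mu.mean() - y.mean()) <= 3 * mcse(mu)


def test_known_variance_posterior_matches_closed_form(rng):
    """Flat prior, fixed sigma^2: mu | y ~ N(ybar, sigma^2/n)."""
    sigma2, n = 9.0, 400
    y = rng.normal(10.0, np.sqrt(sigma2), n)
    model = _intercept_model(y)
    chain = s1.fit_animal_model(
        model,
        s1.GibbsConfig(n_iter=12_000, burn_in=1000, seed=3,
                       fix_variances=True, sigma2_u=0.0, sigma2_e=sigma2),
    )
    mu = chain.param("intercept")
    from matlact.stage2 import mcse

    assert abs(mu.mean() - y.mean()) <= 3 * mcse(mu)
    assert mu.std() == pytest.approx(np.sqrt(sigma2 / n), rel=0.10)


# ---------------------------------------------------------------------------
# MME equivalence and residual identities
# ---------------------------------------------------------------------------

def test_posterior_means_match_mme_at_fixed_variances(smoke_fit):
    r, kept, model, _ = smoke_fit
    chain = s1.fit_animal_model(
        model,
        s1.GibbsConfig(n_iter=6000, burn_in=1000, seed=7,
                       fix_variances=True, sigma2_u=100.0, sigma2_e=10_000.0),
    )
    sol = s1.mme_solution(model, 100.0, 10_000.0)
    pf = model.X.shape[1]
    fitted_gibbs = model.X @ chain.b_mean + model.Z @ chain.u_mean
    fitted_mme = model.X @ sol[:pf] + model.Z @ sol[pf:]
    # fitted values are identified even though the one-hot blocks are not;
    # the gap is Monte-Carlo error and shrinks as 1/sqrt(chain length)
    dev = fitted_gibbs - fitted_mme
    assert np.std(dev) < 0.025 * model.y.std()
    assert np.abs(dev).max() < 0.15 * model.y.std()
    assert np.corrcoef(fitted_gibbs, fitted_mme)[0, 1] > 0.999


def test_residual_mean_near_zero(smoke_fit):
    _, _, model, chain = smoke_fit
    res = s1.extract_residuals(model, chain)
    assert abs(res.e_hat.mean()) < 3.0 * res.e_hat.std() / np.sqrt(len(res))


def test_zero_noise_data_gives_zero_residuals(smoke_fit):
    """Data generated exactly from the model: residuals vanish as
    sigma_e -> 0 (the genetic effect can absorb each record)."""
    _, _, model, _ = smoke_fit
    rng = np.random.default_rng(0)
    pf, q = model.X.shape[1], model.Z.shape[1]
    b0 = rng.normal(0, 10, pf)
    u0 = rng.normal(0, 5, q)
    exact = s1.Stage1Model(
        trait="MY", y=model.X @ b0 + model.Z @ u0, X=model.X,
        fixed_labels=model.fixed_labels, Z=model.Z, A_inv=model.A_inv,
        cow_ids=model.cow_ids, ped_ids=model.ped_ids,
    )
    chain = s1.fit_animal_model(
        exact,
        s1.GibbsConfig(n_iter=1500, burn_in=500, seed=4,
                       fix_variances=True, sigma2_u=25.0, sigma2_e=1e-6),
    )
    res = s1.extract_residuals(exact, chain)
    assert np.abs(res.e_hat).max() < 0.05


def test_row_permutation_leaves_residuals_unchanged(smoke_fit):
    r, kept, model, chain = smoke_fit
    perm = kept.sample(frac=1.0, random_state=1).reset_index(drop=True)
    Ainv = a_inverse(r.pedigree)
    model_p = s1.build_stage1_model(perm, r.pedigree, "MY", Ainv)
    chain_p = s1.fit_animal_model(model_p, s1.GibbsConfig(n_iter=4000, burn_in=400, seed=5))
    a = s1.extract_residuals(model, chain).set_index("cow_id").e_hat
    b = s1.extract_residuals(model_p, chain_p).set_index("cow_id").e_hat
    b = b.reindex(a.index)
    assert np.corrcoef(a, b)[0, 1] > 0.995
    assert np.abs(a - b).max() < 0.15 * a.std()


# ---------------------------------------------------------------------------
# variance-component and merit recovery at h2 = 0.3
# ---------------------------------------------------------------------------

def test_heritability_recovered(h2_fit):
    _, _, _, chain = h2_fit
    h2 = chain.param("sigma2_u") / (chain.param("sigma2_u") + chain.param("sigma2_e"))
    assert abs(h2.mean() - 0.3) <= 0.08


def test_residuals_track_planted_effects_when_omitted(h2_fit):
    """Stage-1 residuals carry any cow-level signal left out of the model:
    plant an effect on the response and refit."""
    r, kept, model, _ = h2_fit
    rng = np.random.default_rng(2)
    flag = rng.random(len(kept)) < 0.5
    planted = np.where(flag, -80.0, 0.0)
    bumped = s1.Stage1Model(
        trait="MY", y=model.y + planted, X=model.X,
        fixed_labels=model.fixed_labels, Z=model.Z, A_inv=model.A_inv,
        cow_ids=model.cow_ids, ped_ids=model.ped_ids,
        cow_sire_rank=model.cow_sire_rank,
    )
    chain = s1.fit_animal_model(bumped, s1.GibbsConfig(n_iter=3000, burn_in=500, seed=6))
    res = s1.extract_residuals(bumped, chain)
    d = res.e_hat[flag].mean() - res.e_hat[~flag].mean()
    # posterior-mean breeding values absorb a share w = 0.5 s2u/(0.5 s2u + s2e)
    # of any omitted cow-level effect; at h2 = 0.3 that is ~0.18, so the
    # residuals retain ~82% of the planted signal
    s2u = chain.param("sigma2_u").mean()
    s2e = chain.param("sigma2_e").mean()
    w = 0.5 * s2u / (0.5 * s2u + s2e)
    assert d == pytest.approx(-80.0 * (1.0 - w), abs=8.0)
    assert -80.0 < d < -55.0


def test_top_decile_overlap_with_true_merit(h2_fit):
    r, kept, model, chain = h2_fit
    u_hat = s1.breeding_value_means(model, chain)
    low, high = s1.genetic_merit_percentiles(u_hat)
    truth = r.truth.cows.set_index("cow_id").loc[u_hat.index, "u_MY"]
    k = len(high)
    true_top = set(truth.sort_values().index[-k:])
    overlap = len(true_top & set(high)) / k
    assert overlap > 0.35  # bounded by EBV accuracy at h2 = 0.3


# ---------------------------------------------------------------------------
# merit percentile mechanics
# ---------------------------------------------------------------------------

def test_decile_sets_of_100_distinct():
    u = pd.Series(np.arange(100.0), index=[f"c{i:03d}" for i in range(100)])
    low, high = s1.genetic_merit_percentiles(u)
    assert len(low) == 10 and len(high) == 10
    assert set(low) == {f"c{i:03d}" for i in range(10)}


def test_ties_broken_by_cow_id():
    u = pd.Series(np.zeros(20), index=[f"c{i:02d}" for i in range(20)])
    low, high = s1.genetic_merit_percentiles(u)
    assert len(low) == 2 and len(high) == 2
    assert low == ["c00", "c01"] and high == ["c18", "c19"]


def test_degenerate_percentiles_raise():
    u = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(s1.Stage1Error):
        s1.genetic_merit_percentiles(u, 0.01, 0.99)


def test_empty_factor_level_raises():
    r = sim.simulate_herd(sim.smoke_preset())
    kept, _ = pp.apply_filters(r.phenotypes, r.testdays, r.pedigree)
    kept = kept.copy()
    kept.loc[:, "herd_year"] = kept["herd_year"].astype(str)
    # a level present in the categories but absent from the rows cannot occur
    # with get_dummies; instead check duplicate cow mapping
    dup = pd.concat([kept, kept.head(1)], ignore_index=True)
    with pytest.raises(s1.Stage1Error):
        s1.build_stage1_model(dup, r.pedigree, "MY", a_inverse(r.pedigree))
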