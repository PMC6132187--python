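"""Batch correction / MNAR imputation: filters, mechanism estimation, ECM."""

import numpy as np
import pandas as pd
import pytest

from conftest import abundance_from_values
from oracles import mar_conditional_means

from omicsqc import bcmi, synthetic


def _random_mnar_instance(rng, force_ref=True):
    """One random small ECM problem drawn from the generative model."""
    nb = int(rng.integers(2, 7))
    sizes = rng.integers(3, 11, size=nb)
    batches = np.repeat([f"b{i}" for i in range(nb)], sizes)
    n = len(batches)
    is_ref = rng.random(n) < (0.2 if force_ref else 0.0)
    mu = rng.normal(10, 3)
    alpha = rng.normal(0, 0.5)
    d = rng.uniform(0.2, 1.2)
    sigma = rng.uniform(0.3, 1.0)
    sigma0 = rng.uniform(0.1, 0.4)
    g1 = rng.uniform(0.0, 0.5)
    g0 = -np.log(rng.uniform(0.1, 0.4)) - g1 * mu
    batch_idx = pd.Categorical(batches).codes
    b = rng.normal(0, d, nb)
    e = rng.normal(0, 1, n) * np.where(is_ref, sigma0, sigma)
    y = mu + alpha * is_ref + b[batch_idx] + e
    miss = rng.random(n) < np.minimum(1.0, np.exp(-g0 - g1 * y))
    y = np.where(miss, np.nan, y)
    # keep at least one observed value overall
    if np.isnan(y).all():
        y[0] = mu
    return y, batches, is_ref, (g0, g1)


# ---------------------------------------------------------------------------
# Filter and naive baselines
# ---------------------------------------------------------------------------

def test_missing_rate_filter_strict_boundary_and_idempotence():
    vals = np.zeros((10, 20))
    for i in range(10):
        vals[i, :i] = np.nan  # protein i missing in i of 20 samples
    ab = abundance_from_values(vals, ["b1"] * 10 + ["b2"] * 10)
    out = bcmi.missing_rate_filter(ab, 0.15)
    # rates 0, .05, .10 are < 0.15; the 3/20 = 0.15 protein is removed
    assert list(out.values.index) == ["p0", "p1", "p2"]
    assert out.values.columns.equals(ab.values.columns)
    twice = bcmi.missing_rate_filter(out, 0.15)
    assert twice.values.equals(out.values)


def test_naive_impute_median_minimum_and_errors():
    vals = np.array([[1.0, 2.0, 3.0, np.nan]])
    ab = abundance_from_values(vals, ["b1", "b1", "b2", "b2"])
    assert bcmi.naive_impute(ab, "median").values.iloc[0, 3] == 2.0
    assert bcmi.naive_impute(ab, "minimum").values.iloc[0, 3] == 1.0
    complete = abundance_from_values(np.ones((2, 4)), ["b1"] * 4)
    assert bcmi.naive_impute(complete, "median").values.equals(complete.values)
    all_missing = abundance_from_values(np.full((1, 4), np.nan), ["b1"] * 4)
    with pytest.raises(ValueError):
        bcmi.naive_impute(all_missing, "median")
    with pytest.raises(ValueError):
        bcmi.naive_impute(ab, "mean")


# ---------------------------------------------------------------------------
# Missingness mechanism
# ---------------------------------------------------------------------------

def test_missingness_mechanism_recovers_truth_over_seeds():
    """gamma0 = 1, gamma1 = 0.3 recovered within 10% relative error,
    averaged over 20 seeded cohorts of 2,000 proteins x 300 samples."""
    g0s, g1s = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        cfg = synthetic.ProteomicsSimConfig(
            n_proteins=2000, n_samples=266, mu=rng.normal(3.0, 1.5, 2000),
            d=0.5, sigma=0.5, sigma0=0.2, gamma0=1.0, gamma1=0.3,
            rng_seed=seed,
        )
        ab, _ = synthetic.generate_proteomics(cfg)
        g0, g1 = bcmi.estimate_missingness_mechanism(ab)
        g0s.append(g0)
        g1s.append(g1)
    assert abs(np.mean(g0s) - 1.0) / 1.0 < 0.10
    assert abs(np.mean(g1s) - 0.3) / 0.3 < 0.10


def test_missingness_mechanism_null_slope_and_complete_matrix():
    cfg = synthetic.ProteomicsSimConfig(
        n_proteins=1000, n_samples=200, gamma0=1.2, gamma1=0.0, rng_seed=3
    )
    ab, _ = synthetic.generate_proteomics(cfg)
    g0, g1 = bcmi.estimate_missingness_mechanism(ab)
    # null slope: estimate within ~2 SE of zero (SE from the regression scale)
    assert g1 < 0.02
    assert abs(g0 - 1.2) < 0.1

    complete = abundance_from_values(
        np.random.default_rng(0).normal(20, 1, (30, 10)), ["b1"] * 5 + ["b2"] * 5
    )
    with pytest.warns(UserWarning):
        g0c, g1c = bcmi.estimate_missingness_mechanism(complete)
    assert g1c == 0.0
    assert np.isinf(g0c)


# ---------------------------------------------------------------------------
# ECM
# ---------------------------------------------------------------------------

def test_ecm_reduces_to_gaussian_mle_for_complete_single_batch():
    rng = np.random.default_rng(1)
    y = rng.normal(5.0, 0.7, 60)
    fit = bcmi.ecm_fit(y, ["b1"] * 60, [False] * 60, gamma=(5.0, 0.0), fix_d=0.0)
    assert fit.params.mu == pytest.approx(y.mean(), abs=1e-8)
    assert fit.params.sigma == pytest.approx(y.std(ddof=0), rel=1e-6)


def test_ecm_mar_limit_matches_conditional_normal_oracle():
    """With gamma1 = 0 the imputed values equal the conditional means of a
    standard Gaussian mixed model (independent oracle), to 1e-6."""
    rng = np.random.default_rng(2)
    checked = 0
    for _ in range(40):
        y, batches, is_ref, _ = _random_mnar_instance(rng)
        if not np.isnan(y).any():
            continue
        checked += 1
        if checked > 20:
            break
        fit = bcmi.ecm_fit(y, batches, is_ref, gamma=(2.0, 0.0))
        p = fit.params
        batch_idx = pd.Categorical(pd.Series(batches).astype(str)).codes
        expect = mar_conditional_means(
            y, batch_idx, is_ref, p.mu, p.alpha, p.d, p.sigma, p.sigma0
        )
        miss = np.isnan(y)
        assert np.max(np.abs(fit.imputed[miss] - expect[miss])) < 1e-6


def test_ecm_tilt_pushes_imputed_values_down():
    """For gamma1 > 0 every imputed value sits below its untilted
    conditional mean, by exactly gamma1 * (posterior y variance)."""
    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(30):
        y, batches, is_ref, (g0, g1) = _random_mnar_instance(rng)
        if g1 <= 0 or not np.isnan(y).any():
            continue
        fit = bcmi.ecm_fit(y, batches, is_ref, gamma=(g0, g1))
        miss = np.isnan(y)
        tilt = fit.imputed_untilted[miss] - fit.imputed[miss]
        assert (tilt > 0).all()
        # decomposition: gamma1 * (h_i * v_b + sigma_entry^2)
        b_series = pd.Series(batches).astype(str)
        s2 = np.where(is_ref, fit.params.sigma0**2, fit.params.sigma**2)
        h = b_series[miss].map(b_series[np.isnan(y)].value_counts()).to_numpy()
        vb = fit.v_b[b_series[miss]].to_numpy()
        # only batches with at least one observed entry carry the b tilt
        n_obs_b = b_series[~np.isnan(y)].value_counts()
        has_obs = b_series[miss].isin(n_obs_b.index).to_numpy()
        expected = g1 * (np.where(has_obs, h * vb, 0.0) + s2[miss])
        assert np.allclose(tilt, expected, atol=1e-8)
        checked += 1
    assert checked >= 10


def test_ecm_loglik_monotone_on_random_instances():
    """Observed-data log-likelihood never decreases by more than 1e-8 per
    iteration, on 100 random MNAR instances."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        y, batches, is_ref, gamma = _random_mnar_instance(rng)
        fit = bcmi.ecm_fit(y, batches, is_ref, gamma=gamma, max_iter=200)
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() >= -1e-8


def test_ecm_parameter_recovery_within_15_percent():
    """mu, alpha, d, sigma recovered within 15% relative bias at 8 batches
    x 40 samples, averaged over 20 seeded blocks of 100 proteins."""
    g1 = 0.3
    g0 = -np.log(0.2) - g1 * 20.0
    est = {p: [] for p in ("mu", "alpha", "d", "sigma")}
    truth = {"mu": 20.0, "alpha": 0.5, "d": 0.8, "sigma": 0.6}
    for seed in range(20):
        cfg = synthetic.ProteomicsSimConfig(
            n_proteins=100, n_samples=259, n_batches=8, mu=20.0, alpha=0.5,
            d=0.8, sigma0=0.2, sigma=0.6, gamma0=g0, gamma1=g1,
            n_replicate_pairs=18, rng_seed=100 + seed,
        )
        ab, _ = synthetic.generate_proteomics(cfg)
        res = bcmi.bcmi_run(ab, gamma=(g0, g1))
        for p in est:
            est[p].append(float(res.params[p].mean()))
    for p, t in truth.items():
        bias = abs(np.mean(est[p]) - t) / t
        assert bias < 0.15, f"{p}: relative bias {bias:.3f}"


def test_ecm_handles_fully_missing_batch():
    y = np.array([5.0, 5.2, 4.9, np.nan, np.nan, np.nan])
    batches = ["b1", "b1", "b1", "b2", "b2", "b2"]
    fit = bcmi.ecm_fit(y, batches, [False] * 6, gamma=(1.0, 0.3))
    # empty batch keeps the prior mean
    assert fit.b_hat["b2"] == pytest.approx(0.0, abs=1e-12)
    assert np.isfinite(fit.imputed).all()


# ---------------------------------------------------------------------------
# bcmi_run and replicate correlation
# ---------------------------------------------------------------------------

def test_bcmi_run_contract_and_no_batch_effect_case(default_proteomics):
    ab, _ = default_proteomics
    filt = bcmi.missing_rate_filter(ab, 0.3)
    res = bcmi.bcmi_run(filt)
    assert not res.corrected.isna().any().any()
    assert res.imputed_mask.equals(filt.missing_mask)
    assert res.corrected.shape == filt.values.shape

    # d = 0 truth: corrected observed entries stay close to the input
    cfg = synthetic.ProteomicsSimConfig(
        n_proteins=60, n_samples=140, d=0.0, n_replicate_pairs=10, rng_seed=9
    )
    ab0, _ = synthetic.generate_proteomics(cfg)
    res0 = bcmi.bcmi_run(ab0, gamma=(cfg.gamma0, cfg.gamma1))
    obs = ~ab0.values.isna()
    delta = (res0.corrected - ab0.values)[obs].abs()
    assert float(delta.max().max()) < 0.5
    assert float(delta.mean().mean()) < 0.1


def test_bcmi_run_shrinks_batch_median_spread(default_proteomics):
    ab, _ = default_proteomics
    filt = bcmi.missing_rate_filter(ab, 0.3)
    res = bcmi.bcmi_run(filt)
    obs = ~filt.values.isna()

    def batch_spread(vals):
        meds = []
        for b in filt.samples["batch"].unique():
            cols = filt.samples.index[filt.samples["batch"] == b]
            centered = vals[cols].sub(vals[obs].mean(axis=1), axis=0)
            meds.append(float(centered[obs[cols]].median().median()))
        return np.std(meds)

    assert batch_spread(res.corrected) < batch_spread(filt.values)


def test_replicate_correlation_identical_null_and_short_pairs():
    rng = np.random.default_rng(5)
    vals = rng.normal(20, 2, (400, 3))
    vals[:, 1] = vals[:, 0]  # s1 duplicates s0
    ab = abundance_from_values(vals, ["b1", "b2", "b2"])
    rc = bcmi.replicate_correlation(ab.values, [("s0", "s1"), ("s0", "s2")])
    assert rc.loc[rc["sample_a"] == "s0", "r"].iloc[0] == pytest.approx(1.0)
    null_r = rc["r"].iloc[1]
    assert abs(null_r) < 3.0 / np.sqrt(400)

    short = ab.values.copy()
    short.iloc[3:, 2] = np.nan  # only 3 shared proteins left
    with pytest.warns(UserWarning):
        rc2 = bcmi.replicate_correlation(short, [("s0", "s2")], min_common=10)
    assert rc2.empty
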