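"""Batch-effect Correction and Missing-value Imputation (BCMI).

Label-free LC-MS proteomics run in batches shows (i) strong batch effects
and (ii) abundance-dependent (MNAR) missingness: low-abundance measurements
drop out preferentially.  Each protein is modelled independently with a
Gaussian mixed-effects model

    y_ki = mu + alpha * I_ki + b_i + e_ki,

where I_ki flags pooled reference-standard injections, b_i ~ N(0, d^2) is
the random batch effect and e_ki has SD sigma0 (reference) or sigma
(regular).  The missingness mechanism is the exponential selection model

    P(M_ki = 1 | y_ki) = exp(-gamma0 - gamma1 * y_ki),

shared across proteins and estimated once from the across-protein trend of
missing rate versus observed mean abundance.  With gamma fixed, each
protein is fitted by an expectation conditional maximization (ECM)
algorithm.  Under this selection model the E-step is exact and closed-form:
conditional on the observed entries and missingness pattern, the batch
effect posterior is Gaussian with an exponential tilt (mean shifted by
-gamma1 * h_i * v_b for h_i missing entries in batch i) and each missing
residual is independently N(-gamma1 * sigma^2, sigma^2), so imputed values
sit *below* their untilted conditional means -- exactly the MNAR
correction.  The observed-data log-likelihood is available in closed form
and is monitored; ECM guarantees it never decreases.

Batch-corrected output is (observed or imputed value) - b_hat_i; the
reference-sample fixed effect alpha is retained so regular samples are
untouched by it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Filtering and naive baselines
# ---------------------------------------------------------------------------

def missing_rate_filter(
    matrix: AbundanceMatrix, threshold: float = 0.15
) -> AbundanceMatrix:
    """Retain proteins whose missing-entry fraction is strictly below
    ``threshold``; the sample set is unchanged.  Idempotent."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = matrix.feature_missing_rate() < threshold
    if not keep.any():
        warnings.warn("missing-rate filter removed every protein")
    return matrix.subset_features(keep)


def naive_impute(matrix: AbundanceMatrix, method: str = "median") -> AbundanceMatrix:
    """Impute each missing entry with the per-protein observed median or
    minimum -- the naive baselines BCMI is compared against."""
    if method not in ("median", "minimum"):
        raise ValueError("method must be 'median' or 'minimum'")
    vals = matrix.values.copy()
    obs_count = vals.notna().sum(axis=1)
    if (obs_count == 0).any():
        bad = list(vals.index[obs_count == 0][:5])
        raise ValueError(f"proteins with no observed value: {bad}")
    fill = vals.median(axis=1) if method == "median" else vals.min(axis=1)
    out = matrix.copy()
    out.values = vals.where(vals.notna(), fill, axis=0)
    return out


# ---------------------------------------------------------------------------
# Missingness mechanism
# ---------------------------------------------------------------------------

def estimate_missingness_mechanism(
    matrix: AbundanceMatrix,
) -> tuple[float, float]:
    """Estimate (gamma0, gamma1) of P(missing) = exp(-g0 - g1 * y).

    Fits log(per-protein missing rate) ~ -g0 - g1 * (per-protein observed
    mean) by least squares over proteins with missing rate strictly inside
    (0, 1).  The slope is clamped at zero (abundance-independent
    missingness) when it comes out positive.  With no partially-missing
    protein the mechanism is unidentifiable and (-log(overall missing
    rate), 0) is returned with a warning.
    """
    rates = matrix.feature_missing_rate()
    means = matrix.values.mean(axis=1, skipna=True)
    sel = (rates > 0) & (rates < 1) & means.notna()
    n_sel = int(sel.sum())
    if n_sel == 0:
        overall = float(matrix.values.isna().to_numpy().mean())
        warnings.warn(
            "no protein with partial missingness; mechanism unidentifiable"
        )
        g0 = -np.log(overall) if overall > 0 else np.inf
        return float(g0), 0.0
    if n_sel < 20:
        warnings.warn(
            f"only {n_sel} proteins with partial missingness; "
            "gamma estimates are unstable"
        )
    x = means[sel].to_numpy(dtype=float)
    y = np.log(rates[sel].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    if slope > 0:
        return float(-np.mean(y)), 0.0
    return float(-intercept), float(-slope)


# ---------------------------------------------------------------------------
# ECM fit
# ---------------------------------------------------------------------------

@dataclass
class BCMIParams:
    """Fitted parameters and diagnostics for one protein."""

    mu: float
    alpha: float
    d: float
    sigma0: float
    sigma: float
    gamma0: float
    gamma1: float
    n_iter: int
    converged: bool
    loglik: float


@dataclass
class ECMFit:
    params: BCMIParams
    b_hat: pd.Series          # posterior mean batch effect per batch
    v_b: pd.Series            # posterior variance per batch
    imputed: np.ndarray       # completed abundance vector
    imputed_untilted: np.ndarray  # conditional means ignoring the MNAR tilt
    loglik_trace: np.ndarray


def _prepare(batches, is_reference):
    batches = pd.Series(batches).astype(str)
    levels = pd.unique(batches)
    batch_idx = pd.Categorical(batches, categories=levels).codes.astype(int)
    ref = np.asarray(is_reference, dtype=bool)
    return batch_idx, np.asarray(levels, dtype=object), ref


def _ecm_many(
    Y: np.ndarray,
    batch_idx: np.ndarray,
    ref: np.ndarray,
    gamma: tuple[float, float],
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    fix_d: float | None = None,
):
    """Vectorized ECM over P proteins sharing one sample layout.

    Y is (P, N) with NaN for missing.  Returns a dict of per-protein
    parameter vectors, batch-effect posteriors, completed matrices and
    log-likelihood traces.  All E-step quantities are exact under the
    exponential selection model, so the observed-data log-likelihood is
    non-decreasing across iterations.
    """
    g0, g1 = float(gamma[0]), float(gamma[1])
    P, N = Y.shape
    nb = int(batch_idx.max()) + 1
    O = ~np.isnan(Y)
    Y0 = np.nan_to_num(Y)
    R = ref.astype(float)
    has_ref = bool(ref.any())
    B_ind = np.zeros((N, nb))
    B_ind[np.arange(N), batch_idx] = 1.0
    n_miss_b = (~O).astype(float) @ B_ind  # (P, nb)

    # -- deterministic initialization from observed moments ---------------
    def col_mean(mask):
        cnt = mask.sum(axis=1)
        return np.where(cnt > 0, (Y0 * mask).sum(axis=1) / np.maximum(cnt, 1), np.nan)

    reg_obs = O & ~ref
    ref_obs = O & ref
    mu = col_mean(reg_obs)
    mu = np.where(np.isnan(mu), col_mean(O), mu)
    mu = np.where(np.isnan(mu), 0.0, mu)
    if has_ref:
        alpha = col_mean(ref_obs) - mu
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
    else:
        alpha = np.zeros(P)

    def pooled_sd(mask, center):
        cnt = mask.sum(axis=1)
        resid = (Y0 - center[:, None]) * mask
        var = np.where(cnt > 1, (resid**2).sum(axis=1) / np.maximum(cnt, 1), 1.0)
        return np.sqrt(np.maximum(var, VAR_FLOOR))

    sigma = pooled_sd(reg_obs, mu)
    sigma = np.where(reg_obs.sum(axis=1) > 1, sigma, 1.0)
    sigma0 = pooled_sd(ref_obs, mu + alpha) if has_ref else np.full(P, np.nan)
    # batch-mean spread as a starting value for d
    cnt_b = O.astype(float) @ B_ind
    with np.errstate(invalid="ignore", divide="ignore"):
        bm = ((Y0 - mu[:, None] - alpha[:, None] * R[None, :]) * O) @ B_ind
        bm = np.where(cnt_b > 0, bm / np.maximum(cnt_b, 1), np.nan)
    d = np.sqrt(np.maximum(np.nanvar(bm, axis=1), 0.01))
    if fix_d is not None:
        d = np.full(P, float(fix_d))

    def e_step(mu, alpha, d, sigma, sigma0):
        S2 = np.where(R[None, :] > 0, sigma0[:, None] ** 2, sigma[:, None] ** 2)
        m0 = mu[:, None] + alpha[:, None] * R[None, :]
        with np.errstate(divide="ignore"):
            inv_s2 = np.where(O, 1.0 / S2, 0.0)
        A = inv_s2 @ B_ind
        Bv = (inv_s2 * (Y0 - m0)) @ B_ind
        # the selection tilt on b is dropped for batches with no observed
        # entry: the unclipped exponential mechanism otherwise makes the
        # likelihood unbounded there, so such batches keep their prior
        # (b_hat = 0, variance d^2)
        h_tilt = n_miss_b * (A > 0)
        d2 = d**2
        if fix_d is not None and fix_d == 0.0:
            v_b = np.zeros((P, nb))
            b_hat = np.zeros((P, nb))
            b_hat_u = np.zeros((P, nb))
        else:
            v_b = 1.0 / (1.0 / d2[:, None] + A)
            b_hat = v_b * (Bv - g1 * h_tilt)
            b_hat_u = v_b * Bv  # untilted (MAR) conditional mean
        return S2, m0, A, Bv, v_b, b_hat, b_hat_u, h_tilt

    def loglik(mu, alpha, d, sigma, sigma0, S2, m0, A, Bv, v_b, h_tilt):
        ll = np.zeros(P)
        r0 = Y0 - m0
        # observed entries: Gaussian term + log P(observed | y)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            lin = -g0 - g1 * Y0
            one_minus = -np.expm1(np.clip(lin, None, 0.0))
            log_obs_sel = np.where(O, np.log(np.maximum(one_minus, 1e-300)), 0.0)
        ll += log_obs_sel.sum(axis=1)
        ll += np.where(O, -0.5 * np.log(2 * np.pi * S2) - 0.5 * r0**2 / S2, 0.0).sum(
            axis=1
        )
        # missing entries: marginal selection factor given b
        ll += np.where(~O, -g0 - g1 * m0 + 0.5 * g1**2 * S2, 0.0).sum(axis=1)
        # integrate the batch effect
        G = Bv - g1 * h_tilt
        d2 = d**2
        if fix_d is not None and fix_d == 0.0:
            ll += (G * 0.0).sum(axis=1)  # b identically zero
        else:
            ll += 0.5 * (np.log(v_b / d2[:, None]) + G**2 * v_b).sum(axis=1)
        return ll

    traces = np.full((max_iter + 1, P), np.nan)
    S2, m0, A, Bv, v_b, b_hat, b_hat_u, h_tilt = e_step(mu, alpha, d, sigma, sigma0)
    traces[0] = loglik(mu, alpha, d, sigma, sigma0, S2, m0, A, Bv, v_b, h_tilt)
    converged = np.zeros(P, dtype=bool)
    # Proteins whose fit runs away are frozen at their last stable state.
    # The unclipped exponential mechanism has an unbounded likelihood when
    # missing entries dominate (mu -> -inf inflates the missing factors);
    # such proteins are exactly what the upstream missing-rate filter
    # removes, but the fitter must not return NaNs when handed one.
    frozen = np.zeros(P, dtype=bool)
    mu_init = mu.copy()
    alpha_init = alpha.copy()
    drift_cap = 25.0 + 10.0 * (np.nan_to_num(sigma) + np.nan_to_num(d))
    n_iter = 0

    for it in range(1, max_iter + 1):
        n_iter = it
        old = (mu.copy(), alpha.copy(), d.copy(), sigma.copy(), sigma0.copy())

        # E-step sufficient statistics at old parameters
        b_entry = b_hat[:, batch_idx]
        vb_entry = v_b[:, batch_idx]
        # E[y - b] per entry: observed -> y - b_hat; missing -> m0_old - g1*S2_old
        z = np.where(O, Y0 - b_entry, m0 - g1 * S2)

        # CM 1: mu, alpha (saturated group means; weights equal within group)
        n_reg = (~ref).sum()
        mu_new = (
            (z * ~ref[None, :]).sum(axis=1) / n_reg if n_reg > 0 else z.mean(axis=1)
        )
        if has_ref:
            alpha_new = (z * ref[None, :]).sum(axis=1) / ref.sum() - mu_new
        else:
            alpha_new = np.zeros(P)

        # CM 2: d^2 from posterior second moments of b
        if fix_d is None:
            d_new = np.sqrt(
                np.maximum((b_hat**2 + v_b).mean(axis=1), VAR_FLOOR)
            )
        else:
            d_new = d

        # CM 3: residual variances
        m0_new = mu_new[:, None] + alpha_new[:, None] * R[None, :]
        resid_obs = Y0 - m0_new - b_entry
        contrib = np.where(
            O,
            resid_obs**2 + vb_entry,
            (m0 - g1 * S2 - m0_new) ** 2 + S2,
        )
        n_reg_mask = (~ref)[None, :]
        sigma_new = np.sqrt(
            np.maximum((contrib * n_reg_mask).sum(axis=1) / max(n_reg, 1), VAR_FLOOR)
        )
        if has_ref:
            sigma0_new = np.sqrt(
                np.maximum(
                    (contrib * ref[None, :]).sum(axis=1) / ref.sum(), VAR_FLOOR
                )
            )
        else:
            sigma0_new = sigma0

        # divergence guard: revert runaway fits and stop updating them
        sigma0_check = np.nan_to_num(sigma0_new, nan=0.0)
        bad = (
            ~np.isfinite(mu_new)
            | ~np.isfinite(alpha_new)
            | ~np.isfinite(d_new)
            | ~np.isfinite(sigma_new)
            | (np.abs(mu_new - mu_init) > drift_cap)
            | (np.abs(alpha_new - alpha_init) > drift_cap)
            | (d_new > 1e6)
            | (sigma_new > 1e6)
            | (sigma0_check > 1e6)
        )
        newly_frozen = bad & ~frozen
        frozen |= newly_frozen
        keep = ~frozen
        mu = np.where(keep, mu_new, old[0])
        alpha = np.where(keep, alpha_new, old[1])
        d = np.where(keep, d_new, old[2])
        sigma = np.where(keep, sigma_new, old[3])
        sigma0 = np.where(keep, sigma0_new, old[4])

        S2, m0, A, Bv, v_b, b_hat, b_hat_u, h_tilt = e_step(mu, alpha, d, sigma, sigma0)
        traces[it] = loglik(mu, alpha, d, sigma, sigma0, S2, m0, A, Bv, v_b, h_tilt)
        traces[it, frozen] = traces[it - 1, frozen]

        def rel(new, prev):
            prev = np.where(np.isnan(prev), 0.0, prev)
            new = np.where(np.isnan(new), 0.0, new)
            return np.abs(new - prev) / np.maximum(np.abs(prev), 1.0)

        change = np.max(
            np.stack([rel(n, o) for n, o in zip((mu, alpha, d, sigma, sigma0), old)]),
            axis=0,
        )
        converged = (change < tol) & ~frozen
        if (converged | frozen).all():
            break

    # final completed matrix (tilted) and untilted conditional means
    b_entry = b_hat[:, batch_idx]
    bu_entry = b_hat_u[:, batch_idx]
    imputed = np.where(O, Y0, m0 + b_entry - g1 * S2)
    imputed_untilted = np.where(O, Y0, m0 + bu_entry)

    floored = (
        (d**2 <= VAR_FLOOR * 1.001)
        | (sigma**2 <= VAR_FLOOR * 1.001)
        | (np.nan_to_num(sigma0**2, nan=1.0) <= VAR_FLOOR * 1.001)
    )
    if fix_d is not None:
        floored = floored & False | (sigma**2 <= VAR_FLOOR * 1.001)
    converged = converged & ~floored

    return {
        "mu": mu,
        "alpha": alpha,
        "d": d,
        "sigma": sigma,
        "sigma0": sigma0,
        "b_hat": b_hat,
        "v_b": v_b,
        "imputed": imputed,
        "imputed_untilted": imputed_untilted,
        "traces": traces[: n_iter + 1],
        "converged": converged,
        "n_iter": n_iter,
        "n_miss_b": n_miss_b,
    }


def ecm_fit(
    y,
    batches,
    is_reference,
    gamma: tuple[float, float],
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    fix_d: float | None = None,
) -> ECMFit:
    """Fit the mixed-effects MNAR model for a single protein.

    ``y`` is a 1-D abundance vector with NaN marking missing entries;
    ``batches`` assigns each entry to an MS batch; ``is_reference`` flags
    reference-standard injections; ``gamma = (gamma0, gamma1)`` is held
    fixed.  ``fix_d=0.0`` pins the batch effect at zero (the single-batch /
    plain Gaussian limit).  Returns parameter estimates, per-batch
    posterior batch effects, the completed vector, its untilted (MAR)
    counterpart and the log-likelihood trace.
    """
    y = np.asarray(y, dtype=float)
    batch_idx, levels, ref = _prepare(batches, is_reference)
    if fix_d is None and len(levels) < 2:
        raise ValueError(
            "ecm_fit needs >= 2 batches unless the batch effect is fixed "
            "(pass fix_d=0.0 for a single batch)"
        )
    res = _ecm_many(
        y[None, :], batch_idx, ref, gamma, tol=tol, max_iter=max_iter, fix_d=fix_d
    )
    params = BCMIParams(
        mu=float(res["mu"][0]),
        alpha=float(res["alpha"][0]),
        d=float(res["d"][0]),
        sigma0=float(res["sigma0"][0]),
        sigma=float(res["sigma"][0]),
        gamma0=float(gamma[0]),
        gamma1=float(gamma[1]),
        n_iter=int(res["n_iter"]),
        converged=bool(res["converged"][0]),
        loglik=float(res["traces"][-1, 0]),
    )
    return ECMFit(
        params=params,
        b_hat=pd.Series(res["b_hat"][0], index=levels),
        v_b=pd.Series(res["v_b"][0], index=levels),
        imputed=res["imputed"][0],
        imputed_untilted=res["imputed_untilted"][0],
        loglik_trace=res["traces"][:, 0],
    )


# ---------------------------------------------------------------------------
# Whole-matrix driver
# ---------------------------------------------------------------------------

@dataclass
class BCMIResult:
    """Output of :func:`bcmi_run`.

    ``corrected`` has the batch effect removed and every missing entry
    imputed; ``imputed_mask`` marks which entries were imputed (identical
    in shape to the input missingness mask).
    """

    corrected: pd.DataFrame
    params: pd.DataFrame
    batch_effects: pd.DataFrame
    imputed_mask: pd.DataFrame
    gamma: tuple[float, float]
    warnings: list[str] = field(default_factory=list)


def bcmi_run(
    matrix: AbundanceMatrix,
    *,
    gamma: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BCMIResult:
    """Run BCMI on every protein of an annotated abundance matrix.

    The missingness mechanism is estimated once across proteins (unless
    ``gamma`` is supplied), then each protein is fitted by ECM with gamma
    fixed.  Corrected output is (observed or imputed value) - b_hat_i;
    reference-standard samples are retained and flagged in the sample
    annotations.
    """
    if "batch" not in matrix.samples.columns:
        raise ValueError("sample annotations must include a 'batch' column")
    if gamma is None:
        gamma = estimate_missingness_mechanism(matrix)
    batch_idx, levels, ref = _prepare(matrix.batch, matrix.is_reference)
    if len(levels) < 2:
        raise ValueError("bcmi_run requires at least 2 batches")

    Y = matrix.values.to_numpy(dtype=float)
    res = _ecm_many(Y, batch_idx, ref, gamma, tol=tol, max_iter=max_iter)

    corrected = res["imputed"] - res["b_hat"][:, batch_idx]
    msgs = []
    n_bad = int((~res["converged"]).sum())
    if n_bad:
        msgs.append(f"{n_bad} protein fits did not converge in {max_iter} iterations")
        warnings.warn(msgs[-1])

    params = pd.DataFrame(
        {
            "mu": res["mu"],
            "alpha": res["alpha"],
            "d": res["d"],
            "sigma0": res["sigma0"],
            "sigma": res["sigma"],
            "gamma0": gamma[0],
            "gamma1": gamma[1],
            "converged": res["converged"],
            "loglik": res["traces"][-1],
        },
        index=matrix.values.index,
    )
    return BCMIResult(
        corrected=pd.DataFrame(
            corrected, index=matrix.values.index, columns=matrix.values.columns
        ),
        params=params,
        batch_effects=pd.DataFrame(
            res["b_hat"], index=matrix.values.index, columns=levels
        ),
        imputed_mask=matrix.missing_mask.copy(),
        gamma=(float(gamma[0]), float(gamma[1])),
        warnings=msgs,
    )


# ---------------------------------------------------------------------------
# Replicate-pair evaluation
# ---------------------------------------------------------------------------

def replicate_correlation(
    values: pd.DataFrame,
    replicate_pairs: list[tuple[str, str]],
    *,
    min_common: int = 3,
) -> pd.DataFrame:
    """Pearson correlation across proteins for each technical replicate pair.

    Entries missing in either member are dropped; pairs with fewer than
    ``min_common`` shared proteins are skipped with a warning.  Used to
    compare raw data with BCMI and naive-imputation outputs: good
    imputation should *increase* replicate agreement.
    """
    rows = []
    for a, b in replicate_pairs:
        if a == b:
            raise ValueError(f"replicate pair references one sample: {a}")
        va, vb = values[a], values[b]
        both = va.notna() & vb.notna()
        n = int(both.sum())
        if n < min_common:
            warnings.warn(f"pair ({a}, {b}) has {n} shared proteins; skipped")
            continue
        r = float(np.corrcoef(va[both], vb[both])[0, 1])
        rows.append({"sample_a": a, "sample_b": b, "n_proteins": n, "r": r})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_proteins", "r"])


def compare_imputation_methods(
    matrix: AbundanceMatrix,
    bcmi_result: BCMIResult | None = None,
) -> pd.DataFrame:
    """Replicate-pair correlation summary for raw data, BCMI and naive
    baselines.  Returns one row per method with the median and mean r."""
    pairs = matrix.replicate_pairs
    if not pairs:
        raise ValueError("abundance matrix carries no replicate pairs")
    variants = {"raw": matrix.values}
    if bcmi_result is not None:
        variants["bcmi"] = bcmi_result.corrected
    variants["median_impute"] = naive_impute(matrix, "median").values
    variants["minimum_impute"] = naive_impute(matrix, "minimum").values
    rows = []
    for name, vals in variants.items():
        rc = replicate_correlation(vals, pairs)
        rows.append(
            {
                "method": name,
                "n_pairs": len(rc),
                "median_r": float(rc["r"].median()) if len(rc) else np.nan,
                "mean_r": float(rc["r"].mean()) if len(rc) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("method")
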