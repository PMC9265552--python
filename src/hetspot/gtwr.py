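"""Geographically and temporally weighted regression (GTWR).

Village-year incidence rates are regressed on covariates with a separate
weighted least squares fit at every observation, weights decaying with a
combined space-time distance

    d_ST(i, j)² = d_spatial(i, j)² + (λ_t · Δt(i, j))²,

so λ_t (meters per year) converts temporal separation into the spatial
metric; λ_t = 0 reduces the model to ordinary GWR pooled over years.
Coefficient surfaces β_k(u, v, t) therefore vary over both space and time.

Local inference uses pseudo-t statistics with the effective degrees of
freedom from the hat-matrix trace — the conventional GWR-family approach.
Covariates are z-scored internally for conditioning; coefficients and
standard errors are reported back on the original scale (exactly, via the
linear back-transform of the local covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GtwrSpec",
    "GtwrFit",
    "st_weights",
    "fit_gtwr",
    "significant_coefficients",
    "loocv_score",
    "select_bandwidth",
]


@dataclass(frozen=True)
class GtwrSpec:
    """Kernel configuration for the local fits.

    spatial_bandwidth : meters (np.inf gives uniform weights).
    lambda_t : meters per year of temporal separation (0 → pure GWR).
    kernel : 'gaussian' (exp(−d²/2b²)) or 'bisquare' ((1−(d/b)²)² inside b).
    ridge : non-negative regularizer added to the standardized normal
        equations; resolves locally singular systems.
    min_local_n : minimum count of non-negligible weights for a local fit;
        localities below it get NaN coefficients.
    """

    spatial_bandwidth: float = 5000.0
    lambda_t: float = 1000.0
    kernel: str = "gaussian"
    ridge: float = 0.0
    min_local_n: int = 0

    def __post_init__(self) -> None:
        if self.spatial_bandwidth <= 0:
            raise ValueError("spatial_bandwidth must be positive")
        if self.lambda_t < 0:
            raise ValueError("lambda_t must be non-negative")
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError("kernel must be 'gaussian' or 'bisquare'")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


def st_weights(target_idx: int, coords, years, spec: GtwrSpec) -> np.ndarray:
    """Kernel weights of every observation relative to observation ``target_idx``."""
    coords = np.asarray(coords, dtype=float)
    years = np.asarray(years, dtype=float)
    if len(coords) != len(years):
        raise ValueError("coords and years length mismatch")
    d2 = ((coords - coords[target_idx]) ** 2).sum(axis=1) + (
        spec.lambda_t * (years - years[target_idx])
    ) ** 2
    b = spec.spatial_bandwidth
    if not np.isfinite(b):
        return np.ones(len(coords))
    if spec.kernel == "gaussian":
        return np.exp(-0.5 * d2 / b**2)
    u2 = d2 / b**2
    return np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)


@dataclass
class GtwrFit:
    beta: pd.DataFrame          # n_obs × (intercept + covariates)
    se: pd.DataFrame
    pseudo_t: pd.DataFrame
    local_p: pd.DataFrame
    fitted: pd.Series
    residual: pd.Series
    r2: float
    aicc: float
    edf: float
    spec: GtwrSpec


def fit_gtwr(design: pd.DataFrame, y, coords, years, spec: GtwrSpec) -> GtwrFit:
    """Local WLS at every observation.

    ``design`` holds the covariates (no intercept column — one is added);
    ``coords`` is (n, 2) in meters, ``years`` numeric.  Raises on rank
    deficiency when ``spec.ridge`` is 0, naming the offending locality.
    """
    X_raw = design.to_numpy(dtype=float)
    y = pd.Series(y, dtype=float)
    n, p = X_raw.shape
    if n <= p + 1:
        raise ValueError("need more observations than covariates")
    sd = X_raw.std(axis=0)
    if np.any(sd == 0):
        bad = list(design.columns[sd == 0])
        raise ValueError(f"constant covariates (drop them): {bad}")
    mu = X_raw.mean(axis=0)
    Xs = np.column_stack([np.ones(n), (X_raw - mu) / sd])
    yv = y.to_numpy()
    coords = np.asarray(coords, dtype=float)

    k = p + 1
    betas_s = np.full((n, k), np.nan)
    cov_s = np.full((n, k, k), np.nan)
    s_rows_sq = np.zeros(n)
    hat = np.zeros(n)
    for i in range(n):
        w = st_weights(i, coords, years, spec)
        if spec.min_local_n and (w > 1e-8).sum() < spec.min_local_n:
            continue
        Xw = Xs * w[:, None]
        A = Xs.T @ Xw
        if spec.ridge > 0:
            A = A + spec.ridge * np.eye(k)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular local system at observation index {i} "
                f"({design.index[i]!r}); increase bandwidth or set ridge > 0"
            ) from err
        C = Ainv @ Xw.T  # k × n
        betas_s[i] = C @ yv
        cov_s[i] = C @ C.T  # Var(beta_i) = sigma^2 C C^T
        s_row = Xs[i] @ C
        hat[i] = s_row[i]
        s_rows_sq[i] = float(s_row @ s_row)

    fitted = np.einsum("ij,ij->i", betas_s, Xs)
    resid = yv - fitted
    tr_s = hat.sum()
    tr_sts = s_rows_sq.sum()
    edf = n - 2.0 * tr_s + tr_sts
    edf = max(edf, 1.0)
    rss = float(np.nansum(resid**2))
    sigma2 = rss / edf

    # back-transform: beta_k = beta_ks / sd_k ; beta_0 = beta_0s - Σ beta_ks mu_k/sd_k
    T = np.eye(k)
    T[0, 1:] = -mu / sd
    T[np.arange(1, k), np.arange(1, k)] = 1.0 / sd
    betas = betas_s @ T.T
    ses = np.full_like(betas, np.nan)
    for i in range(n):
        if np.isnan(betas_s[i]).any() or np.isnan(cov_s[i]).any():
            continue
        cov_i = sigma2 * (T @ cov_s[i] @ T.T)
        ses[i] = np.sqrt(np.maximum(np.diag(cov_i), 0.0))

    cols = ["intercept"] + list(design.columns)
    idx = design.index
    beta_df = pd.DataFrame(betas, index=idx, columns=cols)
    se_df = pd.DataFrame(ses, index=idx, columns=cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_df = beta_df / se_df
    p_df = pd.DataFrame(
        2.0 * stats.t.sf(np.abs(t_df.to_numpy()), df=edf), index=idx, columns=cols
    )
    sst = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - rss / sst if sst > 0 else np.nan
    # AICc in the GWR convention
    aicc = (
        n * np.log(rss / n) + n * np.log(2 * np.pi) + n * (n + tr_s) / (n - 2 - tr_s)
        if n - 2 - tr_s > 0
        else np.inf
    )
    return GtwrFit(
        beta_df,
        se_df,
        t_df,
        p_df,
        pd.Series(fitted, index=idx),
        pd.Series(resid, index=idx),
        r2,
        float(aicc),
        float(edf),
        spec,
    )


def significant_coefficients(fit: GtwrFit, alpha: float = 0.01):
    """Coefficients masked where the local p-value is not below ``alpha``.

    Returns ``(masked_beta, sign_summary)`` where the summary gives, per
    covariate, the fraction of observations significant, and among those the
    fractions with positive and negative coefficients.
    """
    mask = fit.local_p < alpha
    masked = fit.beta.where(mask)
    rows = []
    for col in fit.beta.columns:
        sig = masked[col].dropna()
        n_sig = len(sig)
        rows.append(
            {
                "covariate": col,
                "frac_significant": n_sig / len(fit.beta),
                "frac_positive": (sig > 0).mean() if n_sig else np.nan,
                "frac_negative": (sig < 0).mean() if n_sig else np.nan,
            }
        )
    return masked, pd.DataFrame(rows).set_index("covariate")


def loocv_score(design: pd.DataFrame, y, coords, years, spec: GtwrSpec) -> float:
    """Leave-one-out CV sum of squared prediction errors."""
    X_raw = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X_raw.shape
    mu, sd = X_raw.mean(axis=0), X_raw.std(axis=0)
    Xs = np.column_stack([np.ones(n), (X_raw - mu) / np.where(sd == 0, 1.0, sd)])
    coords = np.asarray(coords, dtype=float)
    k = p + 1
    score = 0.0
    for i in range(n):
        w = st_weights(i, coords, years, spec).copy()
        w[i] = 0.0
        Xw = Xs * w[:, None]
        A = Xs.T @ Xw + max(spec.ridge, 1e-12) * np.eye(k)
        try:
            beta = np.linalg.solve(A, Xw.T @ y)
        except np.linalg.LinAlgError:
            return np.inf
        score += float((y[i] - Xs[i] @ beta) ** 2)
    return score


def select_bandwidth(
    design, y, coords, years, bandwidths, lambda_ts, base_spec: GtwrSpec | None = None
) -> GtwrSpec:
    """Joint grid search of (spatial_bandwidth, λ_t) by leave-one-out CV."""
    if base_spec is None:
        base_spec = GtwrSpec()
    best = None
    for b in bandwidths:
        for lt in lambda_ts:
            spec = GtwrSpec(b, lt, base_spec.kernel, base_spec.ridge, base_spec.min_local_n)
            s = loocv_score(design, y, coords, years, spec)
            if best is None or s < best[0]:
                best = (s, spec)
    return best[1]
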