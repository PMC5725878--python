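"""Likelihood- and imputation-based estimation of the unrestricted correlation.

Both estimators treat the applicant pool as a trivariate normal sample in
which the outcome y is missing exactly for rejected applicants. Because
rejection is determined by the observed predictors, the missingness is MAR
and the applicant-pool correlation is identified from the incumbents'
conditional distribution of y given (x1, x2).

* :func:`em_fit` — EM for the trivariate normal mean and covariance with a
  monotone missing-y pattern; the maximum-likelihood route.
* :func:`lawley_oracle` — the closed-form Pearson–Lawley multivariate
  selection correction that the EM fixed point must coincide with; kept as
  an independent cross-check.
* :func:`mice_fit` — multiple imputation by chained equations with a
  proper Bayesian normal-linear imputation model, pooled by the arithmetic
  mean of the per-dataset correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import ApplicantTable, CorrectionEstimate, DomainError, GroupDescriptives

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class EMConfig:
    """EM iteration control.

    Convergence is declared when the largest absolute change across the
    mean vector and covariance entries falls below ``tolerance`` (scores
    are on the standard-normal scale, so this is a correlation-scale
    criterion).
    """

    max_iterations: int = 5000
    tolerance: float = 1e-8
    report_loglik: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise DomainError("tolerance must be positive")


@dataclass(frozen=True)
class MICEConfig:
    """MICE run parameters: m imputed datasets, Gibbs sweeps per dataset, seed."""

    m: int = 20
    iterations: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 2:
            raise DomainError("m must be >= 2")
        if self.iterations < 1:
            raise DomainError("iterations must be >= 1")


def _extract(table: ApplicantTable) -> tuple[np.ndarray, np.ndarray]:
    df = table.to_dataframe()
    data = df[["x1", "x2", "y"]].to_numpy(float)
    missing = np.isnan(data[:, 2])
    if (~missing).sum() < 3:
        raise DomainError("need at least 3 incumbents (observed y)")
    return data, missing


def _observed_loglik(data: np.ndarray, missing: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Observed-data log-likelihood: trivariate for complete rows, bivariate (x1,x2) otherwise."""
    total = 0.0
    for idx, dim in ((~missing, (0, 1, 2)), (missing, (0, 1))):
        if not idx.any():
            continue
        d = list(dim)
        sub = data[np.ix_(idx, d)] - mu[d]
        s = sigma[np.ix_(d, d)]
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise DomainError("covariance became non-positive-definite")
        sol = np.linalg.solve(s, sub.T)
        quad = np.einsum("ij,ji->i", sub, sol)
        total += -0.5 * (len(d) * _LOG2PI + logdet) * idx.sum() - 0.5 * quad.sum()
    return float(total)


def _corr_from_cov(sigma: np.ndarray, i: int, j: int) -> float:
    return float(sigma[i, j] / np.sqrt(sigma[i, i] * sigma[j, j]))


def em_fit(table: ApplicantTable, config: EMConfig = EMConfig()) -> CorrectionEstimate:
    """Maximum-likelihood r̂_yx1|a by EM over the trivariate normal.

    The E-step fills the missing-y sufficient statistics with their
    conditional expectations given (x1, x2) under the current parameters —
    E[y|x], E[y^2|x] (including the conditional variance) and E[y*x|x] —
    and the M-step recomputes the mean vector and covariance from the
    completed statistics. With missingness confined to y the likelihood is
    unimodal and the fixed point equals the Pearson–Lawley correction.
    """
    data, missing = _extract(table)
    n = len(data)
    if not missing.any():
        cov = np.cov(data, rowvar=False, ddof=1)
        return CorrectionEstimate(
            method="em",
            r_hat=_corr_from_cov(cov, 0, 2),
            inputs={"n": n, "n_missing": 0},
            iterations=1,
            converged=True,
            diagnostics={"mu": data.mean(axis=0), "sigma": cov},
        )

    obs = data[~missing]
    x_all = data[:, :2]
    x_mis = data[missing, :2]

    # init: predictor moments from all rows, y moments from incumbents
    mu = np.empty(3)
    mu[:2] = x_all.mean(axis=0)
    mu[2] = obs[:, 2].mean()
    sigma = np.eye(3)
    sigma[:2, :2] = np.cov(x_all, rowvar=False, ddof=0)
    cov_obs = np.cov(obs, rowvar=False, ddof=0)
    sigma[2, 2] = cov_obs[2, 2]
    sigma[:2, 2] = sigma[2, :2] = cov_obs[:2, 2]
    if np.linalg.det(cov_obs[:2, :2]) <= 0:
        raise DomainError("incumbent predictor covariance is singular")

    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        if config.report_loglik:
            logliks.append(_observed_loglik(data, missing, mu, sigma))
        # E-step: conditional moments of y given (x1, x2) for missing rows
        sxx = sigma[:2, :2]
        sxy = sigma[:2, 2]
        beta = np.linalg.solve(sxx, sxy)            # regression of y on x
        resid_var = sigma[2, 2] - sxy @ beta
        ey = mu[2] + (x_mis - mu[:2]) @ beta

        yfill = data[:, 2].copy()
        yfill[missing] = ey
        t1 = np.concatenate([x_all.sum(axis=0), [yfill.sum()]])
        completed = np.column_stack([x_all, yfill])
        t2 = completed.T @ completed
        t2[2, 2] += resid_var * missing.sum()       # E[y^2] correction

        mu_new = t1 / n
        sigma_new = t2 / n - np.outer(mu_new, mu_new)
        # scale-invariant criterion: standardized means, log-SDs, correlations
        sd, sd_new = np.sqrt(np.diag(sigma)), np.sqrt(np.diag(sigma_new))
        corr = sigma / np.outer(sd, sd)
        corr_new = sigma_new / np.outer(sd_new, sd_new)
        delta = max(
            np.abs(corr_new - corr).max(),
            np.abs(np.log(sd_new) - np.log(sd)).max(),
            np.abs(mu_new / sd_new - mu / sd).max(),
        )
        mu, sigma = mu_new, sigma_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"EM did not converge in {config.max_iterations} iterations "
            f"(last change {delta:.3g})",
            stacklevel=2,
        )
    if config.report_loglik:
        logliks.append(_observed_loglik(data, missing, mu, sigma))
    return CorrectionEstimate(
        method="em",
        r_hat=_corr_from_cov(sigma, 0, 2),
        inputs={"n": n, "n_missing": int(missing.sum())},
        iterations=it,
        converged=converged,
        diagnostics={"mu": mu, "sigma": sigma, "loglik": logliks or None},
    )


def lawley_oracle(
    desc_incumbents: GroupDescriptives, desc_applicants: GroupDescriptives
) -> CorrectionEstimate:
    """Closed-form Pearson–Lawley correction for selection on (x1, x2).

    Regresses y on both predictors in the incumbents and propagates the
    regression plane and residual variance through the applicant predictor
    covariance: since selection operates on the predictors alone, the
    conditional law of y given (x1, x2) is the same in both groups.

    Internally uses maximum-likelihood (1/n) covariance normalization so
    the result is the exact fixed point of :func:`em_fit`; the regression
    slopes are unaffected, only the residual-variance and applicant-
    covariance weights change by factors of (n-1)/n.
    """
    cov_i = desc_incumbents.covariance_matrix(("x1", "x2", "y"))
    cov_a_xx = desc_applicants.covariance_matrix(("x1", "x2"))
    # rescale the n-1 convention of GroupDescriptives to ML normalization
    cov_i = cov_i * (desc_incumbents.n - 1) / desc_incumbents.n
    cov_a_xx = cov_a_xx * (desc_applicants.n - 1) / desc_applicants.n
    sxx_i = cov_i[:2, :2]
    sxy_i = cov_i[:2, 2]
    if np.linalg.det(sxx_i) <= 0:
        raise DomainError("incumbent predictor covariance is singular")
    beta = np.linalg.solve(sxx_i, sxy_i)
    resid_var = cov_i[2, 2] - sxy_i @ beta
    sxy_a = cov_a_xx @ beta
    syy_a = beta @ cov_a_xx @ beta + resid_var
    r_hat = sxy_a[0] / np.sqrt(cov_a_xx[0, 0] * syy_a)
    return CorrectionEstimate(
        method="lawley",
        r_hat=float(r_hat),
        inputs={
            "r_yx1_i": desc_incumbents.r("y", "x1"),
            "sd_x1_a": desc_applicants.sd("x1"),
            "sd_x1_i": desc_incumbents.sd("x1"),
        },
        diagnostics={"beta": beta, "resid_var": float(resid_var)},
    )


def mice_fit(table: ApplicantTable, config: MICEConfig = MICEConfig()) -> CorrectionEstimate:
    """Pooled r̂_yx1|a from m multiply-imputed datasets.

    Imputation phase: each of the m chains runs ``iterations`` sweeps of
    the chained-equations Gibbs step for the one incomplete variable: fit
    the normal linear regression of y on (x1, x2) to the rows where y is
    observed, draw the residual variance from its scaled
    inverse-chi-square posterior and the coefficients from their
    conditional normal posterior, and redraw the missing y from the
    posterior predictive (proper Bayesian imputation, the "norm" method of
    chained-equations software). Analysis phase: the Pearson correlation
    of y with x1 over all rows of each completed dataset. Pooling phase:
    the arithmetic mean of the m correlations (Fisher-z averaging via
    :func:`mice_fit_fisher_z`).

    Because y is the only incomplete variable the pattern is monotone and
    the observed-row regression never changes across sweeps: the chain is
    at its stationary distribution after the first sweep, and extra
    iterations are independent redraws.
    """
    return _mice_fit_impl(table, config, fisher_z=False)


def _mice_fit_impl(
    table: ApplicantTable, config: MICEConfig, fisher_z: bool = False
) -> CorrectionEstimate:
    data, missing = _extract(table)
    n = len(data)
    n_mis = int(missing.sum())
    design = np.column_stack([np.ones(n), data[:, :2]])
    k = design.shape[1]
    if n_mis == 0:
        r = float(np.corrcoef(data[:, 0], data[:, 2])[0, 1])
        return CorrectionEstimate(
            method="mice", r_hat=r, inputs={"n": n, "n_missing": 0},
            converged=True, diagnostics={"between_imputation_sd": 0.0, "m": config.m},
        )
    y_obs = data[~missing, 2]
    design_obs = design[~missing]
    n_obs = len(y_obs)
    if n_obs <= k:
        raise DomainError("too few observed outcomes to fit the imputation model")
    beta_hat, _, rank, _ = np.linalg.lstsq(design_obs, y_obs, rcond=None)
    if rank < k:
        raise DomainError("singular design matrix in imputation model")
    rss = float(np.sum((y_obs - design_obs @ beta_hat) ** 2))
    xtx = design_obs.T @ design_obs
    xtx_inv_chol = np.linalg.cholesky(np.linalg.inv(xtx))
    root = np.random.SeedSequence(config.seed)
    estimates = np.empty(config.m)
    for j, ss in enumerate(root.spawn(config.m)):
        rng = np.random.default_rng(ss)
        y = data[:, 2].copy()
        y[missing] = rng.choice(y_obs, size=n_mis, replace=True)
        for _ in range(config.iterations):
            sigma2 = rss / rng.chisquare(n_obs - k)
            beta_draw = beta_hat + np.sqrt(sigma2) * (xtx_inv_chol @ rng.standard_normal(k))
            mean_mis = design[missing] @ beta_draw
            y[missing] = mean_mis + rng.normal(0.0, np.sqrt(sigma2), size=n_mis)
        estimates[j] = np.corrcoef(data[:, 0], y)[0, 1]
    if fisher_z:
        pooled = float(np.tanh(np.mean(np.arctanh(estimates))))
    else:
        pooled = float(estimates.mean())
    return CorrectionEstimate(
        method="mice",
        r_hat=pooled,
        inputs={"n": n, "n_missing": n_mis},
        iterations=config.iterations,
        converged=True,
        diagnostics={
            "between_imputation_sd": float(estimates.std(ddof=1)),
            "per_imputation": estimates,
            "m": config.m,
            "pooling": "fisher_z" if fisher_z else "mean",
        },
    )


def mice_fit_fisher_z(table: ApplicantTable, config: MICEConfig = MICEConfig()) -> CorrectionEstimate:
    """As :func:`mice_fit` but pooling on the Fisher-z scale."""
    return _mice_fit_impl(table, config, fisher_z=True)
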