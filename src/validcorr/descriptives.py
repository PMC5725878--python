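"""Descriptive statistics within the applicant/incumbent partition.

These are the ingredients of every correction: group means and SDs, the
within-group correlation matrix, the u-ratio of unrestricted to restricted
SD, semipartial correlations and standardized regression weights for the
two-predictor case, and within-group residualization.

All SDs and covariances use the n-1 convention.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal

import numpy as np
import pandas as pd

from .types import VARIABLES, ApplicantTable, DomainError, GroupDescriptives, GroupLabel

logger = logging.getLogger(__name__)


def describe(table: ApplicantTable, group: GroupLabel) -> GroupDescriptives:
    """Compute means, SDs and the correlation matrix for one group.

    For the applicant group the outcome is incomplete (y exists only for
    incumbents), so y-involving correlations and moments are computed over
    the observed-y rows only and flagged as such — never silently pooled.
    """
    if group == "applicants":
        df = table.to_dataframe()
    elif group == "incumbents":
        df = table.incumbents()
    else:
        raise DomainError(f"unknown group {group!r}")
    n = len(df)
    if n < 3:
        raise DomainError(f"group {group!r} has n={n} < 3")

    cols = list(VARIABLES)
    sub = df[cols]
    means = sub.mean()
    sds = sub.std(ddof=1)
    degenerate = tuple(c for c in cols if sds[c] == 0)

    corr = sub.corr()  # pandas uses pairwise-complete observations
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    for c in cols:
        if c not in degenerate:
            corr.loc[c, c] = 1.0

    n_y_obs = int(sub["y"].notna().sum())
    y_partial = n_y_obs < n
    if y_partial and n_y_obs < 3:
        corr.loc["y", ["x1", "x2"]] = np.nan
        corr.loc[["x1", "x2"], "y"] = np.nan
    if degenerate:
        logger.warning("group %s has zero-variance columns: %s", group, degenerate)
    return GroupDescriptives(
        group_label=group,
        n=n,
        means=means,
        sds=sds,
        corr=corr,
        n_y_observed=n_y_obs,
        y_from_incumbents_only=y_partial,
        degenerate=degenerate,
    )


def u_ratio(
    desc_applicants: GroupDescriptives,
    desc_incumbents: GroupDescriptives,
    variable: str = "x1",
) -> float:
    """Ratio u = SD(variable | applicants) / SD(variable | incumbents).

    Under range restriction u > 1 is expected; a value below 1 usually
    means the two groups were swapped (or a reciprocal was reported), so a
    warning is emitted rather than silently inverting.
    """
    sd_a = desc_applicants.sd(variable)
    sd_i = desc_incumbents.sd(variable)
    if sd_i <= 0:
        raise DomainError(f"restricted SD of {variable!r} is zero; u-ratio undefined")
    if sd_a <= 0:
        raise DomainError(f"unrestricted SD of {variable!r} is zero; u-ratio undefined")
    u = sd_a / sd_i
    if u < 1.0:
        warnings.warn(
            f"u-ratio for {variable!r} is {u:.4f} < 1: the 'unrestricted' group has the "
            "smaller SD; check group order or whether a reciprocal was intended",
            stacklevel=2,
        )
    return u


def semipartial(r_yx1: float, r_yx2: float, r_x1x2: float) -> float:
    """Semipartial correlation of y with x1 after removing x2 from x1 only.

    r_y(x1.2) = (r_yx1 - r_yx2 * r_x1x2) / sqrt(1 - r_x1x2^2).

    Under compensatory selection the induced negative r_x1x2 suppresses
    each predictor's first-order validity; the semipartial undoes that
    suppression. Bounded in [-1, 1], unlike the beta weight.
    """
    if abs(r_x1x2) >= 1.0:
        raise DomainError("predictors are collinear (|r_x1x2| = 1); semipartial undefined")
    return (r_yx1 - r_yx2 * r_x1x2) / np.sqrt(1.0 - r_x1x2**2)


def beta_coefficients(r_yx1: float, r_yx2: float, r_x1x2: float) -> tuple[float, float]:
    """Standardized regression weights of y on (x1, x2).

    beta1 = (r_yx1 - r_yx2*r_x1x2) / (1 - r_x1x2^2) and symmetrically for
    beta2. Betas are weights, not correlations, and may exceed 1 in
    magnitude.
    """
    if abs(r_x1x2) >= 1.0:
        raise DomainError("predictors are collinear (|r_x1x2| = 1); betas undefined")
    denom = 1.0 - r_x1x2**2
    beta1 = (r_yx1 - r_yx2 * r_x1x2) / denom
    beta2 = (r_yx2 - r_yx1 * r_x1x2) / denom
    return float(beta1), float(beta2)


def residualize(
    table: ApplicantTable,
    target: str = "x1",
    covariate: str = "x2",
    group: GroupLabel = "incumbents",
) -> pd.Series:
    """Within-group least-squares residuals of ``target`` on ``covariate``.

    The residual of x1 given x2 is the observed x1 minus the value the
    within-group regression of x1 on x2 predicts. Residuals have zero mean
    and zero correlation with the covariate inside the fitting group.
    Returns a Series indexed like the group's rows.
    """
    df = table.to_dataframe() if group == "applicants" else table.incumbents()
    if len(df) < 3:
        raise DomainError(f"group {group!r} has n={len(df)} < 3")
    x = df[covariate].to_numpy(float)
    t = df[target].to_numpy(float)
    if np.std(x) == 0:
        raise DomainError(f"covariate {covariate!r} is constant within {group}")
    slope = np.cov(t, x, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = t.mean() - slope * x.mean()
    return pd.Series(t - (intercept + slope * x), index=df.index, name=f"{target}_resid")
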