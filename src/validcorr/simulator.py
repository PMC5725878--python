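"""Applicant-pool simulation with compensatory top-fraction selection.

Pools are drawn from a trivariate standard normal with a specified
correlation structure; selection admits the top fraction on a weighted
composite z and masks the outcome of every rejected applicant, producing
exactly the missing-data pattern of a real admission study. Closed-form
truncated-normal moments are provided as analytic oracles for the
selection effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ApplicantTable, CorrelationSpec, DomainError, SelectionDesign


def generate_applicants(
    spec: CorrelationSpec,
    seed: int | np.random.SeedSequence | np.random.Generator,
    exact_moments: bool = False,
) -> ApplicantTable:
    """Draw an applicant pool from the trivariate standard normal.

    By default this is a random draw: realized sample correlations scatter
    around the population values by ~1/sqrt(n), as they would in a real
    cohort. With ``exact_moments`` the sample is affinely transformed so
    its sample moments match the specification exactly (useful for
    debugging, not for simulation studies).

    The outcome y is present for every row at this stage; selection and
    masking are applied separately by :func:`apply_selection`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = spec.correlation_matrix()  # (x1, x2, y) order
    n = spec.n_applicants
    draws = rng.multivariate_normal(np.zeros(3), corr, size=n, method="cholesky")
    if exact_moments:
        centered = draws - draws.mean(axis=0)
        sample_cov = np.cov(centered, rowvar=False, ddof=1)
        whiten = np.linalg.inv(np.linalg.cholesky(sample_cov))
        color = np.linalg.cholesky(corr)
        draws = centered @ whiten.T @ color.T
    return ApplicantTable.from_arrays(x1=draws[:, 0], x2=draws[:, 1], y=draws[:, 2])


def apply_selection(table: ApplicantTable, design: SelectionDesign) -> ApplicantTable:
    """Admit the top ceil(rate * n) applicants on z and mask rejected outcomes.

    Returns a new table: z computed as w1*x1 + w2*x2, the top fraction by
    z flagged selected (ties broken by stable input order), and y set to
    missing for every rejected row. x1, x2 and row order are unchanged —
    masking is the only mutation.
    """
    df = table.to_dataframe()
    z = design.composite(df["x1"].to_numpy(), df["x2"].to_numpy())
    n = len(df)
    k = math.ceil(design.selection_rate * n)
    order = np.argsort(-z, kind="stable")
    selected = np.zeros(n, dtype=bool)
    selected[order[:k]] = True
    df["z"] = z
    df["selected"] = selected
    df.loc[~selected, "y"] = np.nan
    return ApplicantTable(df)


@dataclass(frozen=True)
class TruncationMoments:
    """Closed-form moments of a standard normal truncated above a cutpoint.

    For selection of the top fraction p, the cutpoint is c = Phi^-1(1-p),
    the hazard lambda = phi(c)/p equals the mean of the selected scores,
    and the variance ratio 1 - lambda*(lambda - c) is the selected-group
    variance relative to the full population.
    """

    cutpoint: float
    hazard: float
    mean_shift: float
    variance_ratio: float


def truncation_moments(selection_rate: float) -> TruncationMoments:
    """Moments of the standard normal above the top-``selection_rate`` cut.

    At rate 1 there is no truncation: (-inf, 0, 0, 1).
    """
    if not 0.0 < selection_rate <= 1.0:
        raise DomainError(f"selection_rate must be in (0, 1], got {selection_rate}")
    if selection_rate == 1.0:
        return TruncationMoments(-math.inf, 0.0, 0.0, 1.0)
    c = stats.norm.ppf(1.0 - selection_rate)
    lam = stats.norm.pdf(c) / selection_rate
    return TruncationMoments(
        cutpoint=float(c),
        hazard=float(lam),
        mean_shift=float(lam),
        variance_ratio=float(1.0 - lam * (lam - c)),
    )


def selected_composite_variance(selection_rate: float, var_z: float = 2.0) -> float:
    """Variance of the composite among the selected, for a normal composite."""
    return var_z * truncation_moments(selection_rate).variance_ratio
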