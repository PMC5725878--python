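"""Domain types for the trivariate selection-validity model.

The model is deliberately trivariate: one predictor of interest ``x1``
(e.g. an admission test), one co-predictor ``x2`` (e.g. high-school GPA),
and one outcome ``y`` (e.g. study success), with selection performed on a
weighted composite ``z = w1*x1 + w2*x2`` and the outcome observed only in
the selected subgroup ("incumbents").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

VARIABLES = ("x1", "x2", "y")

GroupLabel = Literal["applicants", "incumbents"]


class DomainError(ValueError):
    """Invalid statistical input (bad correlation matrix, degenerate data...)."""


class DataError(ValueError):
    """Malformed input data (missing columns, non-numeric cells...)."""


def _check_correlation(name: str, value: float) -> float:
    value = float(value)
    if not -1.0 <= value <= 1.0:
        raise DomainError(f"{name} must lie in [-1, 1], got {value}")
    return value


@dataclass(frozen=True)
class CorrelationSpec:
    """Population correlation structure of the applicant pool.

    Parameters
    ----------
    rho_yx1, rho_yx2, rho_x1x2 :
        Pairwise correlations of the standard trivariate normal pool.
    n_applicants :
        Pool size N (>= 3).
    """

    rho_yx1: float
    rho_yx2: float
    rho_x1x2: float
    n_applicants: int

    def __post_init__(self) -> None:
        for name in ("rho_yx1", "rho_yx2", "rho_x1x2"):
            object.__setattr__(self, name, _check_correlation(name, getattr(self, name)))
        if int(self.n_applicants) < 3:
            raise DomainError(f"n_applicants must be >= 3, got {self.n_applicants}")
        object.__setattr__(self, "n_applicants", int(self.n_applicants))
        # positive semidefiniteness of the implied 3x3 matrix
        eigvals = np.linalg.eigvalsh(self.correlation_matrix())
        if eigvals.min() < -1e-10:
            raise DomainError(
                "correlations do not form a positive semidefinite matrix "
                f"(min eigenvalue {eigvals.min():.3g})"
            )

    def correlation_matrix(self) -> np.ndarray:
        """3x3 correlation matrix in (x1, x2, y) order."""
        return np.array(
            [
                [1.0, self.rho_x1x2, self.rho_yx1],
                [self.rho_x1x2, 1.0, self.rho_yx2],
                [self.rho_yx1, self.rho_yx2, 1.0],
            ]
        )


@dataclass(frozen=True)
class SelectionDesign:
    """Compensatory selection rule: admit the top fraction on z = w1*x1 + w2*x2.

    Negative weights support reversed scales (e.g. German school grades,
    where 1.0 is best).
    """

    weight_x1: float = 1.0
    weight_x2: float = 1.0
    selection_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.weight_x1 == 0 and self.weight_x2 == 0:
            raise DomainError("at least one selection weight must be nonzero")
        if not 0.0 < self.selection_rate <= 1.0:
            raise DomainError(
                f"selection_rate must be in (0, 1], got {self.selection_rate}"
            )

    def composite(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.weight_x1 * np.asarray(x1, float) + self.weight_x2 * np.asarray(x2, float)


@dataclass(frozen=True)
class ReliabilitySpec:
    """Reliabilities for classical-test-theory corrections.

    ``rel_x_applicants`` is the predictor reliability in the unrestricted
    pool; ``rel_y_incumbents`` the criterion reliability in the selected
    group (the only group where the criterion is observed).
    """

    rel_x_applicants: float
    rel_y_incumbents: float

    def __post_init__(self) -> None:
        for name in ("rel_x_applicants", "rel_y_incumbents"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {v}")


class ApplicantTable:
    """Per-applicant scores with the applicant/incumbent partition.

    Wraps a :class:`pandas.DataFrame` with columns ``x1``, ``x2``, ``z``,
    ``selected``, ``y``. Predictors are always complete; once a selection
    has been applied, ``y`` is present if and only if ``selected`` is true
    (outcomes are never observed for rejected applicants).
    """

    COLUMNS = ("x1", "x2", "z", "selected", "y")

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        for col in ("x1", "x2", "y"):
            if col not in df.columns:
                raise DataError(f"missing mandatory column: {col}")
        if "selected" not in df.columns:
            df["selected"] = df["y"].notna()
        if "z" not in df.columns:
            df["z"] = np.nan
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        for col in ("x1", "x2", "z", "y"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["selected"] = df["selected"].astype(bool)
        if df["x1"].isna().any() or df["x2"].isna().any():
            bad = df.index[df[["x1", "x2"]].isna().any(axis=1)].tolist()
            raise DataError(
                f"predictors x1/x2 must be complete for all applicants; missing in rows {bad[:10]}"
            )
        if (df["y"].notna() != df["selected"]).any():
            raise DataError("y must be present if and only if the row is selected")
        self._df = df

    @classmethod
    def from_arrays(
        cls,
        x1: np.ndarray,
        x2: np.ndarray,
        y: np.ndarray,
        z: np.ndarray | None = None,
        selected: np.ndarray | None = None,
    ) -> "ApplicantTable":
        n = len(x1)
        df = pd.DataFrame(
            {
                "x1": np.asarray(x1, float),
                "x2": np.asarray(x2, float),
                "z": np.full(n, np.nan) if z is None else np.asarray(z, float),
                "selected": np.ones(n, bool) if selected is None else np.asarray(selected, bool),
                "y": np.asarray(y, float),
            }
        )
        return cls(df)

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n(self) -> int:
        return len(self._df)

    @property
    def n_selected(self) -> int:
        return int(self._df["selected"].sum())

    @property
    def n_missing_y(self) -> int:
        return int(self._df["y"].isna().sum())

    def incumbents(self) -> pd.DataFrame:
        """Rows of the selected subgroup (complete in y)."""
        return self._df.loc[self._df["selected"]].copy()

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:
        return (
            f"ApplicantTable(n={self.n}, incumbents={self.n_selected}, "
            f"missing_y={self.n_missing_y})"
        )


@dataclass
class GroupDescriptives:
    """Means, SDs and correlation matrix of one group (applicants or incumbents).

    ``corr`` is indexed by variable name; entries involving a degenerate
    (zero-variance) variable, or involving y when y is incomplete in the
    group, are NaN and flagged.
    """

    group_label: GroupLabel
    n: int
    means: pd.Series
    sds: pd.Series
    corr: pd.DataFrame
    n_y_observed: int
    y_from_incumbents_only: bool = False
    degenerate: tuple[str, ...] = ()

    def sd(self, variable: str) -> float:
        return float(self.sds[variable])

    def r(self, a: str, b: str) -> float:
        return float(self.corr.loc[a, b])

    def covariance_matrix(self, variables: tuple[str, ...] = VARIABLES) -> np.ndarray:
        """Covariance matrix reconstructed from sds and correlations."""
        s = self.sds[list(variables)].to_numpy(float)
        r = self.corr.loc[list(variables), list(variables)].to_numpy(float)
        return r * np.outer(s, s)


@dataclass
class CorrectionEstimate:
    """One corrected validity estimate with its provenance.

    ``r_hat`` is the estimated unrestricted predictor-outcome correlation
    r̂_yx1|a; ``u_used`` the SD ratio the method consumed (NaN for methods
    that do not use one); ``inputs`` the restricted statistics consumed.
    """

    method: str
    r_hat: float
    u_used: float = float("nan")
    inputs: Mapping[str, float] = field(default_factory=dict)
    iterations: int | None = None
    converged: bool | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = float(self.r_hat)
        if not np.isfinite(r):
            raise DomainError(f"{self.method}: corrected correlation is not finite")
        if abs(r) > 1.0:
            warnings.warn(
                f"{self.method}: corrected correlation {r:.4f} outside [-1, 1]; clamped",
                stacklevel=2,
            )
            r = float(np.clip(r, -1.0, 1.0))
            self.diagnostics["clamped"] = True
        self.r_hat = r
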