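"""Closed-form range-restriction corrections.

Implements the classical corrections for selection-induced attenuation of
a validity coefficient:

* Thorndike's case A — selection directly on the studied predictor,
  assuming linearity and homoscedasticity of y given the predictor.
* Thorndike's case C — incidental (indirect) selection on an explicit
  composite z of which the studied predictor is only a part.
* Classical-test-theory corrections: disattenuation and the
  Hunter–Schmidt stepwise procedure for indirect range restriction
  (operational validity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import CorrectionEstimate, DomainError, ReliabilitySpec, _check_correlation


def thorndike_case_a(r_i: float, u: float) -> CorrectionEstimate:
    """Correct a restricted correlation for direct selection on the predictor.

    r̂_a = u * r_i / sqrt(1 - r_i**2 + u**2 * r_i**2)

    with u = SD(predictor | applicants) / SD(predictor | incumbents).
    Valid when selection truncated the predictor itself; under selection on
    a composite it systematically understates the unrestricted correlation.
    The result lies in [-1, 1] by construction and equals r_i at u = 1.
    """
    r_i = _check_correlation("r_i", r_i)
    if u <= 0:
        raise DomainError(f"u-ratio must be positive, got {u}")
    r_hat = u * r_i / math.sqrt(1.0 - r_i**2 + u**2 * r_i**2)
    return CorrectionEstimate(
        method="case_a", r_hat=r_hat, u_used=u, inputs={"r_i": r_i, "u": u}
    )


@dataclass(frozen=True)
class CaseCInputs:
    """Restricted statistics consumed by the case C correction.

    All three correlations are computed in the incumbents; ``u_z`` is the
    applicants/incumbents SD ratio of the explicit selection composite z.
    """

    r_yx1_i: float
    r_zx1_i: float
    r_zy_i: float
    u_z: float

    def __post_init__(self) -> None:
        for name in ("r_yx1_i", "r_zx1_i", "r_zy_i"):
            _check_correlation(name, getattr(self, name))
        if self.u_z <= 0:
            raise DomainError(f"u_z must be positive, got {self.u_z}")


def thorndike_case_c(inputs: CaseCInputs) -> CorrectionEstimate:
    """Correct for indirect selection on an explicit composite z.

    r̂_a = [r_yx1|i + r_zx1|i * r_zy|i * (u_z**2 - 1)]
          / sqrt[(1 + r_zx1|i**2 (u_z**2 - 1)) * (1 + r_zy|i**2 (u_z**2 - 1))]

    This is the classical incidental-selection correction (Thorndike's
    third case): the joint distribution of (x1, y) is adjusted for the
    explicit truncation of z, assuming linearity and homoscedasticity of
    (x1, y) on z. At u_z = 1, or when z is unrelated to both x1 and y, the
    restricted correlation is returned unchanged.
    """
    k = inputs.u_z**2 - 1.0
    f1 = 1.0 + inputs.r_zx1_i**2 * k
    f2 = 1.0 + inputs.r_zy_i**2 * k
    if f1 <= 0 or f2 <= 0:
        raise DomainError(
            "case C denominator factor is nonpositive; inputs are inconsistent "
            f"(u_z={inputs.u_z}, r_zx1_i={inputs.r_zx1_i}, r_zy_i={inputs.r_zy_i})"
        )
    num = inputs.r_yx1_i + inputs.r_zx1_i * inputs.r_zy_i * k
    r_hat = num / math.sqrt(f1 * f2)
    return CorrectionEstimate(
        method="case_c",
        r_hat=r_hat,
        u_used=inputs.u_z,
        inputs={
            "r_yx1_i": inputs.r_yx1_i,
            "r_zx1_i": inputs.r_zx1_i,
            "r_zy_i": inputs.r_zy_i,
            "u_z": inputs.u_z,
        },
    )


def disattenuate(r: float, rel: float) -> float:
    """Correct a correlation for unreliability of one of its variables.

    Returns r / sqrt(rel). Raises if the result would exceed 1 in
    magnitude, which signals a reliability inconsistent with the observed
    correlation.
    """
    r = _check_correlation("r", r)
    if not 0.0 < rel <= 1.0:
        raise DomainError(f"reliability must be in (0, 1], got {rel}")
    out = r / math.sqrt(rel)
    if abs(out) > 1.0:
        raise DomainError(
            f"disattenuated correlation {out:.4f} exceeds 1; reliability {rel} is "
            f"inconsistent with |r| = {abs(r)}"
        )
    return out


def hunter_schmidt_operational(
    r_yx1_i: float, u_x: float, rel: ReliabilitySpec
) -> CorrectionEstimate:
    """Hunter–Schmidt stepwise correction for indirect range restriction.

    Estimates the operational validity — the correlation between observed
    predictor scores and the outcome's true score in the applicant pool —
    under the classical-test-theory model in which selection acts on the
    predictor's true score and measurement error has constant variance
    across groups. With u_x = SD(x1|a)/SD(x1|i):

    1. disattenuate the restricted correlation for criterion unreliability
       (rel_y | incumbents);
    2. derive the incumbent predictor reliability
       rel_x|i = 1 - u_x**2 * (1 - rel_x|a);
    3. disattenuate for predictor unreliability in the incumbents, giving
       the restricted true-score correlation;
    4. apply the direct-restriction (case A) correction on the true-score
       SD ratio u_T = u_x * sqrt(rel_x|a / (1 - u_x**2 * (1 - rel_x|a)));
    5. re-attenuate by sqrt(rel_x|a) to report operational validity.

    The diagnostics carry both the true-score correlation (step 4) and the
    operational validity (step 5).
    """
    r_yx1_i = _check_correlation("r_yx1_i", r_yx1_i)
    if u_x <= 0:
        raise DomainError(f"u_x must be positive, got {u_x}")
    rel_x_i = 1.0 - u_x**2 * (1.0 - rel.rel_x_applicants)
    if rel_x_i <= 0:
        raise DomainError(
            "derived incumbent predictor reliability is nonpositive "
            f"({rel_x_i:.4f}); u_x={u_x} and rel_x|a={rel.rel_x_applicants} are "
            "inconsistent with constant error variance"
        )
    r1 = disattenuate(r_yx1_i, rel.rel_y_incumbents)
    r2 = disattenuate(r1, rel_x_i)
    u_t = u_x * math.sqrt(rel.rel_x_applicants / rel_x_i)
    true_score = thorndike_case_a(r2, u_t).r_hat
    operational = true_score * math.sqrt(rel.rel_x_applicants)
    return CorrectionEstimate(
        method="hunter_schmidt",
        r_hat=operational,
        u_used=u_x,
        inputs={
            "r_yx1_i": r_yx1_i,
            "u_x": u_x,
            "rel_x_applicants": rel.rel_x_applicants,
            "rel_y_incumbents": rel.rel_y_incumbents,
        },
        diagnostics={
            "rel_x_incumbents": rel_x_i,
            "u_true_score": u_t,
            "true_score_validity": true_score,
            "operational_validity": operational,
        },
    )
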