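"""Screening arithmetic: PPV and NPV under prevalence, and the inverse
problem of the prevalence needed for a target PPV.

For a test with sensitivity s and specificity sp applied to a population
with disease prevalence p (Bayes' rule):

    PPV = s*p / (s*p + (1 - sp)*(1 - p))
    NPV = sp*(1 - p) / (sp*(1 - p) + (1 - s)*p)

An annual incidence quoted per 10^5 persons is treated as the prevalence
for a single annual screen.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedValueError

__all__ = ["ppv", "npv", "prevalence_for_ppv", "ScreeningMetrics"]


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise UndefinedValueError(f"{name} must be in [0, 1], got {x}")


def ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Positive predictive value under the given prevalence."""
    _check_unit("sensitivity", sensitivity)
    _check_unit("specificity", specificity)
    _check_unit("prevalence", prevalence)
    num = sensitivity * prevalence
    den = num + (1.0 - specificity) * (1.0 - prevalence)
    if den <= 0.0:
        raise UndefinedValueError("PPV undefined: no positive calls in this population")
    return num / den


def npv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Negative predictive value under the given prevalence."""
    _check_unit("sensitivity", sensitivity)
    _check_unit("specificity", specificity)
    _check_unit("prevalence", prevalence)
    num = specificity * (1.0 - prevalence)
    den = num + (1.0 - sensitivity) * prevalence
    if den <= 0.0:
        raise UndefinedValueError("NPV undefined: no negative calls in this population")
    return num / den


def prevalence_for_ppv(
    sensitivity: float, specificity: float, target_ppv: float
) -> float:
    """Prevalence at which the test's PPV equals ``target_ppv``.

    Closed-form inversion of Bayes' rule:
        p = t*(1 - sp) / (s*(1 - t) + t*(1 - sp))
    Exact inverse: ppv(s, sp, result) == target_ppv to floating precision.
    """
    _check_unit("sensitivity", sensitivity)
    _check_unit("specificity", specificity)
    if not 0.0 < target_ppv < 1.0:
        raise UndefinedValueError("target_ppv must be in (0, 1)")
    if sensitivity <= 0.0:
        raise UndefinedValueError("a test with zero sensitivity cannot reach any PPV")
    num = target_ppv * (1.0 - specificity)
    den = sensitivity * (1.0 - target_ppv) + num
    p = num / den
    if not 0.0 < p < 1.0:
        raise UndefinedValueError(
            f"target PPV {target_ppv} unreachable for sens={sensitivity}, "
            f"spec={specificity}"
        )
    return p


@dataclass(frozen=True)
class ScreeningMetrics:
    """Sensitivity/specificity/prevalence triple with derived PPV and NPV."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float

    @classmethod
    def compute(
        cls, sensitivity: float, specificity: float, prevalence: float
    ) -> "ScreeningMetrics":
        return cls(
            sensitivity=sensitivity,
            specificity=specificity,
            prevalence=prevalence,
            ppv=ppv(sensitivity, specificity, prevalence),
            npv=npv(sensitivity, specificity, prevalence),
        )

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        """Reporting helper: PPV/NPV in percent, rounded."""
        return {
            "ppv_percent": round(100.0 * self.ppv, decimals),
            "npv_percent": round(100.0 * self.npv, decimals),
        }
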