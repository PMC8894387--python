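"""E-value sensitivity analysis for unmeasured confounding.

The E-value is the minimum strength of association (risk-ratio scale) an
unmeasured confounder would need with both exposure and outcome to explain
away an observed association: for a risk ratio RR > 1,
``E = RR + sqrt(RR * (RR - 1))``.  For odds ratios of a rare outcome
(prevalence well under 15%, as with ~6% 28-day mortality) the OR is treated
directly as the RR; for common outcomes the square-root approximation
``RR ~ sqrt(OR)`` is applied first.  Protective estimates are inverted before
the formula, so the E-value for OR and 1/OR is identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EValueResult", "evalue_point", "evalue_ci", "evalue_report"]


def _to_rr(or_value: float, rare_outcome: bool) -> float:
    rr = or_value if rare_outcome else float(np.sqrt(or_value))
    return rr if rr >= 1.0 else 1.0 / rr


def evalue_point(or_value: float, rare_outcome: bool = True) -> float:
    """E-value for a point estimate on the odds-ratio scale."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    rr = _to_rr(or_value, rare_outcome)
    return float(rr + np.sqrt(rr * (rr - 1.0)))


def evalue_ci(or_value: float, ci: tuple[float, float], rare_outcome: bool = True) -> float:
    """E-value for the confidence limit nearer the null.

    If the CI contains 1 no confounding at all is needed to reach the null,
    so the E-value is exactly 1.
    """
    lower, upper = ci
    if lower > upper:
        raise ValueError(f"CI lower bound {lower} exceeds upper bound {upper}")
    if lower <= 1.0 <= upper:
        return 1.0
    limit = lower if lower > 1.0 else upper
    return evalue_point(limit, rare_outcome)


@dataclass
class EValueResult:
    """E-values for one estimate (point and, when a CI is given, its limit)."""

    input_or: float
    input_ci: tuple[float, float] | None
    rare_outcome: bool
    evalue_point: float
    evalue_ci: float | None

    def to_dict(self) -> dict:
        return {
            "or": self.input_or,
            "ci": list(self.input_ci) if self.input_ci else None,
            "rare_outcome": self.rare_outcome,
            "evalue_point": self.evalue_point,
            "evalue_ci": self.evalue_ci,
        }

    def __str__(self) -> str:
        ci = "" if self.evalue_ci is None else f"; CI limit E-value {self.evalue_ci:.2f}"
        return (f"OR {self.input_or:.2f}: an unmeasured confounder would need "
                f"RR >= {self.evalue_point:.2f} with both exposure and outcome "
                f"to explain the association away{ci}")


def evalue_report(or_value: float, ci: tuple[float, float] | None = None,
                  rare_outcome: bool = True) -> EValueResult:
    """Point and CI-limit E-values packaged for reporting."""
    return EValueResult(
        input_or=or_value,
        input_ci=ci,
        rare_outcome=rare_outcome,
        evalue_point=evalue_point(or_value, rare_outcome),
        evalue_ci=None if ci is None else evalue_ci(or_value, ci, rare_outcome),
    )
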