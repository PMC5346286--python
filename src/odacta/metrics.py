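"""Effect metrics for 2x2 contingency tables.

Every effect estimate in this package — number needed to harm (NNH), risk
ratio, sensitivity/specificity, predictive values, and the effect strength
for sensitivity (ESS) — reduces to the arithmetic of a single 2x2 table

    =============  ========  ===========
    group          effect    no effect
    =============  ========  ===========
    predictor +    a         b
    predictor -    c         d
    =============  ========  ===========

where "predictor" may be a drug-exposure indicator, a binary risk factor,
or a dichotomized ordered attribute.  ESS is the chance- and
maximum-corrected classification accuracy: 0 is the accuracy expected by
chance, 100 is perfect discrimination; for two classes it equals
sensitivity + specificity - 100 (both in percent).

All internal values are kept at full precision; rounding (round-half-up,
matching how such tables are conventionally printed) happens only at the
presentation layer via :func:`round_half_up`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


class DataError(ValueError):
    """Raised when counts are inconsistent with the stated totals."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables).

    ``round_half_up(17.25, 1) == 17.3`` whereas builtin banker's rounding
    would give 17.2.  Infinities pass through unchanged.
    """
    if math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Counts2x2:
    """Counts a/b/c/d as defined in the module docstring."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise DataError(f"count {name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cases(self) -> int:
        return self.a + self.c

    @property
    def noncases(self) -> int:
        return self.b + self.d

    @property
    def positives(self) -> int:
        return self.a + self.b

    @property
    def negatives(self) -> int:
        return self.c + self.d

    def swapped(self) -> "Counts2x2":
        """Swap predictor polarity (a<->c, b<->d)."""
        return Counts2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class BinaryMetrics:
    """Full-precision effect metrics for one 2x2 table.

    Percent-scaled fields: sensitivity, specificity, ppv, npv, ess.
    ``attributable_risk`` is a proportion (risk difference); ``nnh`` its
    reciprocal.  A metric whose denominator is empty is ``None``
    ("undefined"); a ratio with a zero divisor but well-defined limit is
    ``math.inf`` — never a silent NaN.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    risk_ratio: float | None
    attributable_risk: float | None
    nnh: float | None
    ess: float | None


def metrics_from_counts(t: Counts2x2) -> BinaryMetrics:
    """Compute all effect metrics for a 2x2 table.

    sensitivity = 100*a/(a+c), specificity = 100*d/(b+d),
    ppv = 100*a/(a+b), npv = 100*d/(c+d),
    attributable risk = a/(a+b) - c/(c+d), NNH = 1/attributable risk,
    risk ratio = [a/(a+b)] / [c/(c+d)], ESS = sensitivity + specificity - 100.
    """
    sens = 100.0 * t.a / t.cases if t.cases else None
    spec = 100.0 * t.d / t.noncases if t.noncases else None
    ppv = 100.0 * t.a / t.positives if t.positives else None
    npv = 100.0 * t.d / t.negatives if t.negatives else None

    risk_pos = t.a / t.positives if t.positives else None
    risk_neg = t.c / t.negatives if t.negatives else None

    if risk_pos is None or risk_neg is None:
        ar = nnh = rr = None
    else:
        ar = risk_pos - risk_neg
        nnh = 1.0 / ar if ar != 0.0 else math.inf
        if risk_neg > 0.0:
            rr = risk_pos / risk_neg
        else:
            rr = math.inf if risk_pos > 0.0 else None
    ess = sens + spec - 100.0 if sens is not None and spec is not None else None
    return BinaryMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        risk_ratio=rr, attributable_risk=ar, nnh=nnh, ess=ess,
    )


def complete_counts(
    a: int,
    b: int,
    c: int,
    *,
    unexposed_total: int | None = None,
    cohort_total: int | None = None,
) -> Counts2x2:
    """Complete a 2x2 table whose ``d`` cell is implied by stratum totals.

    Two conventions occur in printed screens:

    - naive exposed-vs-unexposed rows print a, b, c and the unexposed-group
      total, so ``d = unexposed_total - c``;
    - within-cohort predictor rows print a, b, c and the cohort total, so
      ``d = cohort_total - a - b - c``.

    Exactly one of the keyword totals must be given.
    """
    if (unexposed_total is None) == (cohort_total is None):
        raise DataError("give exactly one of unexposed_total or cohort_total")
    if unexposed_total is not None:
        d = unexposed_total - c
    else:
        d = cohort_total - a - b - c
    if d < 0:
        raise DataError(f"implied d={d} is negative; totals inconsistent with counts")
    return Counts2x2(a, b, c, d)
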