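"""Per-study effect estimates for two-arm binary outcomes.

A study is a 2x2 table of event counts: ``e1`` events out of ``n1``
patients in the treatment arm and ``e0`` out of ``n0`` in the control
arm.  Three effect measures are supported:

* odds ratio (OR), analysed as log OR,
* relative risk (RR), analysed as log RR,
* risk difference (RD), analysed on the identity scale.

The null effect is 0 on the analysis scale for all three.  Tables with a
zero cell (zero events or zero non-events in either arm) receive the
classical continuity correction: 0.5 is added to all four cells, so each
arm size grows by one.  Studies with no events in either arm carry no
information about a relative effect; by default they are excluded for
OR/RR and retained (with correction) for RD.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DegenerateStudyError


class EffectMeasure(str, Enum):
    """Effect measure for a binary outcome; OR and RR are analysed on the log scale."""

    OR = "OR"
    RR = "RR"
    RD = "RD"


class DoubleZeroPolicy(str, Enum):
    """How to treat studies with zero events in both arms.

    ``EXCLUDE`` drops them from relative-effect (OR/RR) analyses as
    non-informative; ``CORRECT`` keeps them with the 0.5 correction.
    RD analyses always retain double-zero studies.
    """

    EXCLUDE = "exclude"
    CORRECT = "correct"


@dataclass(frozen=True)
class TwoByTwoTable:
    """Arm-level counts for one study: (e1, n1) treatment, (e0, n0) control."""

    e1: int
    n1: int
    e0: int
    n0: int

    def __post_init__(self) -> None:
        for name in ("e1", "n1", "e0", "n0"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
        if self.n1 <= 0 or self.n0 <= 0:
            raise ValueError(f"arm sizes must be positive, got n1={self.n1}, n0={self.n0}")
        if not (0 <= self.e1 <= self.n1):
            raise ValueError(f"e1 must satisfy 0 <= e1 <= n1, got e1={self.e1}, n1={self.n1}")
        if not (0 <= self.e0 <= self.n0):
            raise ValueError(f"e0 must satisfy 0 <= e0 <= n0, got e0={self.e0}, n0={self.n0}")

    @property
    def total_n(self) -> int:
        return self.n1 + self.n0

    @property
    def total_events(self) -> int:
        return self.e1 + self.e0

    @property
    def has_zero_cell(self) -> bool:
        """True if any of events/non-events in either arm is zero."""
        return (
            self.e1 == 0
            or self.e1 == self.n1
            or self.e0 == 0
            or self.e0 == self.n0
        )

    @property
    def is_double_zero(self) -> bool:
        return self.e1 == 0 and self.e0 == 0


@dataclass(frozen=True)
class StudyEffect:
    """Point estimate ``y`` and standard error ``s`` on the analysis scale.

    ``corrected`` records whether the continuity correction fired;
    ``informative`` is False for studies excluded from the fit (e.g.
    double-zero studies under OR/RR), in which case ``s`` is +inf.
    """

    y: float
    s: float
    corrected: bool
    informative: bool


def apply_continuity_correction(
    table: TwoByTwoTable,
) -> tuple[tuple[float, float, float, float], bool]:
    """Return corrected cells ``(a, b, c, d)`` and whether correction fired.

    ``a = e1``, ``b = n1 - e1`` (treatment non-events), ``c = e0``,
    ``d = n0 - e0``.  If any cell is zero, 0.5 is added to all four.
    The correction is re-resolved on every call: fragility searches
    mutate counts, which can create or remove zero cells between fits.
    """
    a = float(table.e1)
    b = float(table.n1 - table.e1)
    c = float(table.e0)
    d = float(table.n0 - table.e0)
    corrected = table.has_zero_cell
    if corrected:
        a += 0.5
        b += 0.5
        c += 0.5
        d += 0.5
    return (a, b, c, d), corrected


def compute_effect(
    table: TwoByTwoTable,
    measure: EffectMeasure | str,
    dz_policy: DoubleZeroPolicy | str = DoubleZeroPolicy.EXCLUDE,
) -> StudyEffect:
    """Estimate the study effect and its standard error on the analysis scale.

    Closed forms over the (possibly corrected) cells ``(a, b, c, d)``
    with corrected arm sizes ``m1 = a + b``, ``m0 = c + d``:

    * log OR: ``y = log(a d / (b c))``, ``s = sqrt(1/a + 1/b + 1/c + 1/d)``
    * log RR: ``y = log((a/m1) / (c/m0))``, ``s = sqrt(1/a - 1/m1 + 1/c - 1/m0)``
    * RD: ``y = a/m1 - c/m0``, ``s = sqrt(p1 (1-p1)/m1 + p0 (1-p0)/m0)``
    """
    measure = EffectMeasure(measure)
    dz_policy = DoubleZeroPolicy(dz_policy)

    if (
        table.is_double_zero
        and measure in (EffectMeasure.OR, EffectMeasure.RR)
        and dz_policy is DoubleZeroPolicy.EXCLUDE
    ):
        return StudyEffect(y=0.0, s=math.inf, corrected=False, informative=False)

    (a, b, c, d), corrected = apply_continuity_correction(table)
    m1 = a + b
    m0 = c + d

    if measure is EffectMeasure.OR:
        y = math.log(a * d) - math.log(b * c)
        var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    elif measure is EffectMeasure.RR:
        y = math.log(a / m1) - math.log(c / m0)
        var = 1.0 / a - 1.0 / m1 + 1.0 / c - 1.0 / m0
    else:
        p1 = a / m1
        p0 = c / m0
        y = p1 - p0
        var = p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0

    s = math.sqrt(var)
    if not math.isfinite(s) or s <= 0.0:
        raise DegenerateStudyError(
            f"non-finite or zero standard error for table {table} under {measure.value}"
        )
    return StudyEffect(y=y, s=s, corrected=corrected, informative=True)
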