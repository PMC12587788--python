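"""Agreement statistics: Lin's CCC, Bland-Altman, and the composite verdict.

Lin's concordance correlation coefficient (CCC)

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

measures agreement between paired readings as the Pearson correlation
penalized by location and scale shifts.  Moments use 1/n denominators by
default (Lin's original estimator); a 1/(n-1) variant is available through
``ddof=1``.  The confidence interval is formed on the Fisher-z scale with
Lin's asymptotic variance (with the published correction to the original
variance expression) and back-transformed, which keeps both bounds inside
(-1, 1).

The Bland-Altman analysis summarises the paired differences d = x - y by
their mean (the bias), the 95% limits of agreement bias +/- 1.96 sd(d), a
t-based confidence interval for the bias, and confidence intervals for each
limit of agreement using the exact standard error

    se(LoA) = sd(d) * sqrt(1/n + z^2 / (2 (n - 1)))

with the same t quantile (n - 1 degrees of freedom).

The composite concordance rule deems two reading sets concordant when the
CCC point estimate exceeds ``ccc_min`` (default 0.81, strict) AND the
absolute bias is within ``bias_limit`` (default 1 unit) AND both limits of
agreement fall inside ``+/- loa_limit`` (1 unit for single items, 2 units
for CIBDAI/CCECAI totals).  Two relaxed presets widen the LoA thresholds to
(+/-1.5, +/-2.5) and (+/-2, +/-3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateCIError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "PairedMeasurements",
    "CCCResult",
    "BlandAltmanResult",
    "AgreementCriteria",
    "ConcordanceVerdict",
    "lin_ccc",
    "ccc_confidence_interval",
    "bland_altman",
    "bland_altman_from_summary",
    "concordance_verdict",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two aligned reading sets of the same variable on the same forms.

    Pairs with a missing value on either side are dropped (pairwise
    deletion); at least 3 complete pairs are required.
    """

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValidationError("x and y must be one-dimensional")
        if x.shape != y.shape:
            raise ValidationError(
                f"length mismatch: len(x)={x.size}, len(y)={y.size}"
            )
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise InsufficientDataError(
                f"need >= 3 complete pairs, got {x.size}"
                + (f" for {self.label!r}" if self.label else "")
            )
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class CCCResult:
    n: int
    estimate: float
    pearson_r: float
    location_shift: float  # standardized mean difference u
    scale_shift: float  # SD ratio s_x / s_y
    z_se: float  # SE of atanh(rho_c); nan when degenerate
    ci_low: float
    ci_high: float
    level: float
    label: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    bias_ci_low: float
    bias_ci_high: float
    loa_multiplier: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    level: float
    label: str = ""


@dataclass(frozen=True)
class AgreementCriteria:
    """Composite concordance thresholds.

    ``loa_limit_item`` applies to single clinical items, ``loa_limit_total``
    to the CIBDAI/CCECAI index totals.
    """

    ccc_min: float = 0.81
    bias_limit: float = 1.0
    loa_limit_item: float = 1.0
    loa_limit_total: float = 2.0
    name: str = "paper"

    def __post_init__(self) -> None:
        for attr in ("ccc_min", "bias_limit", "loa_limit_item", "loa_limit_total"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")

    def loa_limit(self, is_total: bool) -> float:
        return self.loa_limit_total if is_total else self.loa_limit_item

    @classmethod
    def preset(cls, name: str) -> "AgreementCriteria":
        presets = {
            "paper": cls(loa_limit_item=1.0, loa_limit_total=2.0, name="paper"),
            "relaxed_1": cls(loa_limit_item=1.5, loa_limit_total=2.5, name="relaxed_1"),
            "relaxed_2": cls(loa_limit_item=2.0, loa_limit_total=3.0, name="relaxed_2"),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValidationError(
                f"unknown criteria preset {name!r}; choose from {sorted(presets)}"
            ) from None


@dataclass(frozen=True)
class ConcordanceVerdict:
    concordant: bool
    ccc_pass: bool
    bias_pass: bool
    loa_pass: bool
    failure_reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# Lin's CCC
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray, y: np.ndarray, ddof: int):
    n = x.size
    mx, my = float(x.mean()), float(y.mean())
    denom = n - ddof
    sx2 = float(((x - mx) ** 2).sum()) / denom
    sy2 = float(((y - my) ** 2).sum()) / denom
    sxy = float(((x - mx) * (y - my)).sum()) / denom
    return mx, my, sx2, sy2, sxy


def lin_ccc(
    pairs: PairedMeasurements,
    level: float = 0.95,
    ddof: int = 0,
) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ``ddof=0`` (default) uses 1/n moment denominators; ``ddof=1`` the sample
    variant.  The point estimate is invariant to this choice up to the common
    factor cancelling; the small-sample values differ only through the
    squared mean-difference term.

    Raises :class:`UndefinedStatisticError` when both reading sets are
    constant and equal (agreement is undefined, not perfect, in that case).
    """
    x, y = pairs.x, pairs.y
    n = pairs.n
    mx, my, sx2, sy2, sxy = _moments(x, y, ddof)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise UndefinedStatisticError(
            "both reading sets are constant and identical; CCC is undefined"
            + (f" for {pairs.label!r}" if pairs.label else "")
        )
    est = 2.0 * sxy / denom
    sx, sy = math.sqrt(sx2), math.sqrt(sy2)
    r = sxy / (sx * sy) if sx > 0 and sy > 0 else math.nan
    u = (mx - my) / math.sqrt(sx * sy) if sx > 0 and sy > 0 else math.nan
    v = sx / sy if sy > 0 else math.nan

    z_se = _ccc_z_se(n, est, r, u)
    result = CCCResult(
        n=n,
        estimate=est,
        pearson_r=r,
        location_shift=u,
        scale_shift=v,
        z_se=z_se,
        ci_low=math.nan,
        ci_high=math.nan,
        level=level,
        label=pairs.label,
    )
    if math.isfinite(z_se) and abs(est) < 1.0:
        result = ccc_confidence_interval(result, level)
    return result


def _ccc_z_se(n: int, rho_c: float, r: float, u: float) -> float:
    """Asymptotic SE of atanh(rho_c) (Lin's corrected variance)."""
    if n <= 2 or not math.isfinite(r) or r == 0.0 or abs(rho_c) >= 1.0:
        return math.nan
    one_m = 1.0 - rho_c**2
    var = (
        (1.0 - r**2) * rho_c**2 / (one_m * r**2)
        + 2.0 * rho_c**3 * (1.0 - rho_c) * u**2 / (r * one_m**2)
        - rho_c**4 * u**4 / (2.0 * r**2 * one_m**2)
    ) / (n - 2)
    return math.sqrt(var) if var > 0 else math.nan


def ccc_confidence_interval(result: CCCResult, level: float = 0.95) -> CCCResult:
    """Recompute the CI of a :class:`CCCResult` at ``level``.

    Bounds are atanh(rho_c) +/- z_{(1+level)/2} * z_se back-transformed with
    tanh, hence always inside (-1, 1).
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must lie in (0, 1), got {level!r}")
    if abs(result.estimate) >= 1.0:
        raise DegenerateCIError(
            "CCC estimate is exactly +/-1; the Fisher-z interval is "
            "degenerate -- report the point estimate or bootstrap instead"
        )
    if not math.isfinite(result.z_se):
        raise DegenerateCIError("z_se is undefined for this result")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    zc = math.atanh(result.estimate)
    return replace(
        result,
        ci_low=math.tanh(zc - z * result.z_se),
        ci_high=math.tanh(zc + z * result.z_se),
        level=level,
    )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(
    pairs: PairedMeasurements,
    level: float = 0.95,
    loa_multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement for d = x - y."""
    d = pairs.x - pairs.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bland_altman_from_summary(
        n=pairs.n,
        bias=bias,
        sd_diff=sd,
        level=level,
        loa_multiplier=loa_multiplier,
        label=pairs.label,
    )


def bland_altman_from_summary(
    n: int,
    bias: float,
    sd_diff: float,
    level: float = 0.95,
    loa_multiplier: float = 1.96,
    label: str = "",
) -> BlandAltmanResult:
    """Bland-Altman intervals from summary statistics (n, bias, sd of d).

    Useful for re-deriving confidence intervals from published bias/LoA
    values when raw readings are unavailable.
    """
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 paired differences, got {n}")
    if sd_diff < 0:
        raise ValidationError(f"sd_diff must be >= 0, got {sd_diff!r}")
    if not 0 < level < 1:
        raise ValidationError(f"level must lie in (0, 1), got {level!r}")
    t = float(stats.t.ppf(0.5 * (1.0 + level), n - 1))
    half = loa_multiplier * sd_diff
    bias_hw = t * sd_diff / math.sqrt(n)
    loa_se = sd_diff * math.sqrt(1.0 / n + loa_multiplier**2 / (2.0 * (n - 1)))
    loa_hw = t * loa_se
    lower, upper = bias - half, bias + half
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd_diff,
        bias_ci_low=bias - bias_hw,
        bias_ci_high=bias + bias_hw,
        loa_multiplier=loa_multiplier,
        loa_lower=lower,
        loa_upper=upper,
        loa_lower_ci=(lower - loa_hw, lower + loa_hw),
        loa_upper_ci=(upper - loa_hw, upper + loa_hw),
        level=level,
        label=label,
    )


# ---------------------------------------------------------------------------
# Composite verdict
# ---------------------------------------------------------------------------

def concordance_verdict(
    ccc: Optional[CCCResult],
    ba: BlandAltmanResult,
    criteria: AgreementCriteria,
    is_total: bool = False,
    ccc_estimate: Optional[float] = None,
) -> ConcordanceVerdict:
    """Apply the composite concordance rule.

    ``ccc`` may be replaced by a bare ``ccc_estimate`` when only the point
    estimate is available (e.g. published tables).  The CCC criterion is a
    strict inequality on the point estimate.
    """
    if ccc is not None and ccc_estimate is not None:
        raise ValidationError("pass either ccc or ccc_estimate, not both")
    if ccc is not None:
        if ccc.n != ba.n:
            raise ValidationError(
                f"inconsistent n between CCC ({ccc.n}) and Bland-Altman ({ba.n})"
            )
        estimate = ccc.estimate
    elif ccc_estimate is not None:
        estimate = float(ccc_estimate)
    else:
        raise ValidationError("a CCC estimate is required for the verdict")

    limit = criteria.loa_limit(is_total)
    ccc_pass = estimate > criteria.ccc_min
    bias_pass = abs(ba.bias) <= criteria.bias_limit
    loa_pass = ba.loa_lower >= -limit and ba.loa_upper <= limit
    reasons = []
    if not ccc_pass:
        reasons.append("ccc_below")
    if not bias_pass:
        reasons.append("bias_exceeds")
    if not loa_pass:
        reasons.append("loa_exceeds")
    return ConcordanceVerdict(
        concordant=ccc_pass and bias_pass and loa_pass,
        ccc_pass=ccc_pass,
        bias_pass=bias_pass,
        loa_pass=loa_pass,
        failure_reasons=tuple(reasons),
    )
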