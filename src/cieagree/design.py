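"""Reliability-study sample size for demonstrating a minimum CCC.

Number of subjects n needed so that, with k ratings per subject, a test of
H0: rho = rho0 against H1: rho = rho1 (> rho0) at significance ``alpha``
reaches the requested power.  The classical reliability-design formula
(Walter, Eliasziw & Donner) gives

    n = 1 + 2 k (z_{1-alpha} + z_{power})^2 / ((k - 1) (ln C0)^2)

with

    C0 = (1 + k rho0 / (1 - rho0)) / (1 + k rho1 / (1 - rho1)),

rounded up to guarantee the nominal power.  ``alpha`` is one-sided by
default, which is the natural sidedness for demonstrating a *minimum*
agreement level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InfeasibleDesignError, ValidationError

__all__ = ["SampleSizeSpec", "required_sample_size", "sample_size_details"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design inputs for the reliability sample-size calculation.

    ccc_null
        rho0, the minimum acceptable concordance (must be exceeded).
    ccc_expected
        rho1, the anticipated concordance (> rho0).
    ratings_per_subject
        k, the number of ratings per subject (>= 2), e.g. 2 reading sessions.
    alpha
        Significance level; one-sided unless ``two_sided``.
    power
        Target probability of demonstrating rho > rho0 when rho = rho1.
    """

    ccc_null: float
    ccc_expected: float
    ratings_per_subject: int = 2
    alpha: float = 0.05
    power: float = 0.80
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ccc_null < 1:
            raise ValidationError(f"ccc_null must lie in (0, 1), got {self.ccc_null!r}")
        if not 0 < self.ccc_expected < 1:
            raise ValidationError(
                f"ccc_expected must lie in (0, 1), got {self.ccc_expected!r}"
            )
        if self.ccc_expected <= self.ccc_null:
            raise InfeasibleDesignError(
                f"expected CCC ({self.ccc_expected}) must exceed the null CCC "
                f"({self.ccc_null}); the design is infeasible otherwise"
            )
        if self.ratings_per_subject < 2:
            raise ValidationError(
                f"ratings_per_subject must be >= 2, got {self.ratings_per_subject!r}"
            )
        for attr in ("alpha", "power"):
            if not 0 < getattr(self, attr) < 1:
                raise ValidationError(f"{attr} must lie in (0, 1)")


def sample_size_details(spec: SampleSizeSpec) -> dict[str, float]:
    """Intermediate quantities of the sample-size formula.

    Returns C0, the two normal quantiles, the continuous solution
    ``n_exact`` and the rounded-up ``n``.
    """
    k = spec.ratings_per_subject
    r0, r1 = spec.ccc_null, spec.ccc_expected
    alpha = spec.alpha / 2 if spec.two_sided else spec.alpha
    z_alpha = float(stats.norm.ppf(1.0 - alpha))
    z_beta = float(stats.norm.ppf(spec.power))
    c0 = (1.0 + k * r0 / (1.0 - r0)) / (1.0 + k * r1 / (1.0 - r1))
    n_exact = 1.0 + 2.0 * k * (z_alpha + z_beta) ** 2 / ((k - 1) * math.log(c0) ** 2)
    return {
        "c0": c0,
        "z_alpha": z_alpha,
        "z_power": z_beta,
        "n_exact": n_exact,
        "n": max(2, math.ceil(n_exact)),
    }


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Required number of subjects (e.g. consultation forms) per observer."""
    return int(sample_size_details(spec)["n"])
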