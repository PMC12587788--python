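"""CIBDAI / CCECAI scoring engine.

Converts raw clinical observations into the ordinal 0-3 item scores of the
Canine Inflammatory Bowel Disease Activity Index (CIBDAI, six items) and the
Canine Chronic Enteropathy Clinical Activity Index (CCECAI, the same six plus
albumin, ascites/peripheral edema and pruritus), computes index totals, and
classifies disease severity and treatment response.

The mappers follow the published item scales together with the standardized
scoring-guide conventions: stool consistency is scored from the mean Purina
fecal score (PSFS, 1-7), vomiting and defecation frequency strictly from the
reported weekly/daily counts, and any sign flagged as a problem for the animal
carries a minimum score of 1.  The printed integer bands are extended to real
inputs by midpoint binning so every mapper is piecewise-constant and monotone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

#: Canonical item names, in index order.  The first six form the CIBDAI;
#: all nine form the CCECAI.
CIBDAI_ITEMS: tuple[str, ...] = (
    "attitude_activity",
    "appetite",
    "vomiting",
    "stool_consistency",
    "stool_frequency",
    "weight_loss",
)
CCECAI_EXTRA_ITEMS: tuple[str, ...] = ("albumin", "ascites_edema", "pruritus")
ALL_ITEMS: tuple[str, ...] = CIBDAI_ITEMS + CCECAI_EXTRA_ITEMS

SEVERITY_LABELS = ("insignificant", "mild", "moderate", "severe", "very_severe")


def _check_ordinal(name: str, value) -> int:
    if value is None or value != int(value) or not (0 <= int(value) <= 3):
        raise ValidationError(
            f"{name} must be an integer in {{0,1,2,3}}, got {value!r}"
        )
    return int(value)


@dataclass(frozen=True)
class ItemScores:
    """One form's ordinal item grades.

    The six CIBDAI items are mandatory; the three CCECAI extras are either
    all present or all absent.
    """

    attitude_activity: int
    appetite: int
    vomiting: int
    stool_consistency: int
    stool_frequency: int
    weight_loss: int
    albumin: Optional[int] = None
    ascites_edema: Optional[int] = None
    pruritus: Optional[int] = None

    def __post_init__(self) -> None:
        for name in CIBDAI_ITEMS:
            object.__setattr__(self, name, _check_ordinal(name, getattr(self, name)))
        extras = [getattr(self, name) for name in CCECAI_EXTRA_ITEMS]
        present = [v is not None for v in extras]
        if any(present) and not all(present):
            raise ValidationError(
                "CCECAI extras (albumin, ascites_edema, pruritus) must be "
                "all present or all absent; got "
                + ", ".join(f"{n}={v!r}" for n, v in zip(CCECAI_EXTRA_ITEMS, extras))
            )
        if all(present):
            for name in CCECAI_EXTRA_ITEMS:
                object.__setattr__(
                    self, name, _check_ordinal(name, getattr(self, name))
                )

    @property
    def has_ccecai_items(self) -> bool:
        return self.albumin is not None

    def as_dict(self) -> dict[str, int]:
        """Mapping item name -> score, omitting absent extras."""
        out = {name: getattr(self, name) for name in CIBDAI_ITEMS}
        if self.has_ccecai_items:
            out.update({name: getattr(self, name) for name in CCECAI_EXTRA_ITEMS})
        return out


@dataclass(frozen=True)
class ClinicalObservation:
    """Raw clinical inputs for one consultation form.

    ``problem_flags`` lists item names the clinician marked as a problem for
    the animal; flagged items carry a minimum score of 1 regardless of the
    numeric bands.
    """

    attitude_grade: int
    appetite_grade: int
    vomits_per_week: float
    mean_psfs: float
    stools_per_day: float
    blood_or_mucus: bool
    weight_loss_pct: float
    albumin_g_per_l: Optional[float] = None
    ascites_edema_grade: Optional[int] = None
    pruritus_grade: Optional[int] = None
    problem_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_ordinal("attitude_grade", self.attitude_grade)
        _check_ordinal("appetite_grade", self.appetite_grade)
        if not 1.0 <= self.mean_psfs <= 7.0:
            raise ValidationError(
                f"mean_psfs must lie in [1, 7], got {self.mean_psfs!r}"
            )
        if self.vomits_per_week < 0:
            raise ValidationError(
                f"vomits_per_week must be >= 0, got {self.vomits_per_week!r}"
            )
        if self.stools_per_day < 0:
            raise ValidationError(
                f"stools_per_day must be >= 0, got {self.stools_per_day!r}"
            )
        if not 0.0 <= self.weight_loss_pct <= 100.0:
            raise ValidationError(
                f"weight_loss_pct must lie in [0, 100], got {self.weight_loss_pct!r}"
            )
        if self.albumin_g_per_l is not None and self.albumin_g_per_l <= 0:
            raise ValidationError(
                f"albumin_g_per_l must be > 0, got {self.albumin_g_per_l!r}"
            )
        for name in ("ascites_edema_grade", "pruritus_grade"):
            v = getattr(self, name)
            if v is not None:
                _check_ordinal(name, v)
        unknown = set(self.problem_flags) - set(ALL_ITEMS)
        if unknown:
            raise ValidationError(
                f"unknown item(s) in problem_flags: {sorted(unknown)}"
            )
        object.__setattr__(self, "problem_flags", frozenset(self.problem_flags))


# ---------------------------------------------------------------------------
# Item mappers
# ---------------------------------------------------------------------------

def score_stool_consistency(mean_psfs: float) -> int:
    """Stool-consistency score from the mean Purina fecal score.

    PSFS 1-2 -> 0, 3-4 -> 1, 5-6 -> 2, 7 -> 3; real-valued means are binned
    at the midpoints between the printed integer bands.
    """
    if not 1.0 <= mean_psfs <= 7.0:
        raise ValidationError(f"mean_psfs must lie in [1, 7], got {mean_psfs!r}")
    if mean_psfs < 2.5:
        return 0
    if mean_psfs < 4.5:
        return 1
    if mean_psfs < 6.5:
        return 2
    return 3


def score_vomiting(vomits_per_week: float, is_problem: bool = False) -> int:
    """Vomiting score from the weekly vomiting count.

    <1/week -> 0 (unless vomiting is flagged as a problem, which floors the
    score at 1), about 1/week -> 1, 2-3/week -> 2, >3/week -> 3.
    """
    if vomits_per_week < 0:
        raise ValidationError(
            f"vomits_per_week must be >= 0, got {vomits_per_week!r}"
        )
    if vomits_per_week < 1:
        score = 0
    elif vomits_per_week < 2:
        score = 1
    elif vomits_per_week <= 3:
        score = 2
    else:
        score = 3
    return max(score, 1) if is_problem else score


def score_stool_frequency(stools_per_day: float, blood_or_mucus: bool = False) -> int:
    """Defecation-frequency score.

    2-3/day -> 1, 4-5/day -> 2, >5/day -> 3, with midpoint binning for real
    frequencies; fecal blood or mucus imposes a floor of 1, combined with
    the frequency band by maximum.
    """
    if stools_per_day < 0:
        raise ValidationError(
            f"stools_per_day must be >= 0, got {stools_per_day!r}"
        )
    if stools_per_day < 2:
        score = 0
    elif stools_per_day < 3.5:
        score = 1
    elif stools_per_day < 5.5:
        score = 2
    else:
        score = 3
    return max(score, 1 if blood_or_mucus else 0)


def score_weight_loss(weight_loss_pct: float) -> int:
    """Weight-loss score: none -> 0, <5% -> 1, 5-10% -> 2, >10% -> 3."""
    if weight_loss_pct < 0:
        raise ValidationError(
            f"weight_loss_pct must be >= 0, got {weight_loss_pct!r}"
        )
    if weight_loss_pct == 0:
        return 0
    if weight_loss_pct < 5:
        return 1
    if weight_loss_pct <= 10:
        return 2
    return 3


def score_albumin(albumin_g_per_l: float) -> int:
    """Serum-albumin score (for a lower reference limit of 24 g/L).

    >=20 g/L -> 0, 15-19.9 -> 1, 12-14.9 -> 2, <12 -> 3; the printed decimal
    gaps are closed with half-open bands.
    """
    if albumin_g_per_l <= 0:
        raise ValidationError(
            f"albumin_g_per_l must be > 0, got {albumin_g_per_l!r}"
        )
    if albumin_g_per_l >= 20:
        return 0
    if albumin_g_per_l >= 15:
        return 1
    if albumin_g_per_l >= 12:
        return 2
    return 3


def score_items(obs: ClinicalObservation) -> ItemScores:
    """Score all items of one observation.

    Graded items (attitude, appetite, ascites/edema, pruritus) pass through;
    numeric items go through their mappers; every item flagged in
    ``obs.problem_flags`` is floored at 1 (the minimum-score rule).
    """
    flags = obs.problem_flags
    scores = {
        "attitude_activity": obs.attitude_grade,
        "appetite": obs.appetite_grade,
        "vomiting": score_vomiting(obs.vomits_per_week, "vomiting" in flags),
        "stool_consistency": score_stool_consistency(obs.mean_psfs),
        "stool_frequency": score_stool_frequency(obs.stools_per_day, obs.blood_or_mucus),
        "weight_loss": score_weight_loss(obs.weight_loss_pct),
    }
    if obs.albumin_g_per_l is not None:
        scores["albumin"] = score_albumin(obs.albumin_g_per_l)
    if obs.ascites_edema_grade is not None:
        scores["ascites_edema"] = obs.ascites_edema_grade
    if obs.pruritus_grade is not None:
        scores["pruritus"] = obs.pruritus_grade
    for name in flags:
        if name in scores:
            scores[name] = max(scores[name], 1)
    return ItemScores(**scores)


# ---------------------------------------------------------------------------
# Totals
# ---------------------------------------------------------------------------

def cibdai_total(items: ItemScores) -> int:
    """CIBDAI total: sum of the six core item scores (range 0-18)."""
    return sum(getattr(items, name) for name in CIBDAI_ITEMS)


def ccecai_total(items: ItemScores) -> int:
    """CCECAI total: sum of all nine item scores (range 0-27)."""
    if not items.has_ccecai_items:
        raise ValidationError(
            "ccecai_total requires albumin, ascites_edema and pruritus scores"
        )
    return cibdai_total(items) + sum(
        getattr(items, name) for name in CCECAI_EXTRA_ITEMS
    )


# ---------------------------------------------------------------------------
# Severity and treatment response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityScheme:
    """Total-score cutoffs mapping an index total to a severity category.

    ``cutoffs[i]`` is the smallest total belonging to category
    ``SEVERITY_LABELS[i + 1]``; totals below ``cutoffs[0]`` are
    clinically insignificant.
    """

    index_kind: str  # "CIBDAI" or "CCECAI"
    cutoffs: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.index_kind not in ("CIBDAI", "CCECAI"):
            raise ValidationError(f"unknown index kind {self.index_kind!r}")
        if list(self.cutoffs) != sorted(set(self.cutoffs)):
            raise ValidationError("cutoffs must be strictly increasing")
        if len(self.cutoffs) >= 4 and self.index_kind != "CCECAI":
            raise ValidationError("very_severe is defined for CCECAI only")

    @property
    def max_total(self) -> int:
        return 18 if self.index_kind == "CIBDAI" else 27


#: Published severity categories: 4-5 mild, 6-8 moderate, CIBDAI >=9 severe,
#: CCECAI 9-11 severe and >=12 very severe; totals 0-3 are insignificant.
CIBDAI_SEVERITY = SeverityScheme("CIBDAI", (4, 6, 9))
CCECAI_SEVERITY = SeverityScheme("CCECAI", (4, 6, 9, 12))


def classify_severity(total: int, scheme: SeverityScheme) -> str:
    """Severity category for an index total under ``scheme``."""
    if total != int(total) or not 0 <= total <= scheme.max_total:
        raise ValidationError(
            f"{scheme.index_kind} total must be an integer in "
            f"[0, {scheme.max_total}], got {total!r}"
        )
    label_idx = 0
    for cutoff in scheme.cutoffs:
        if total >= cutoff:
            label_idx += 1
    return SEVERITY_LABELS[label_idx]


def classify_response(baseline_total: int, final_total: int) -> bool:
    """Treatment-response flag.

    A responder shows a more than 50% reduction of the baseline total
    (strict) or a final total of at most 3.  A zero baseline is decided by
    the final-score branch alone (no ratio is formed).
    """
    if baseline_total < 0 or final_total < 0:
        raise ValidationError("index totals must be non-negative")
    if final_total <= 3:
        return True
    if baseline_total == 0:
        return False
    return final_total < 0.5 * baseline_total
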