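"""Repeatability / reproducibility orchestration.

Data model: one :class:`ScoreRecord` per (form, observer, session) holding
the nine (or six) item scores with recomputed CIBDAI/CCECAI totals; a
:class:`StudyDataset` is the full score grid.  Intra-observer repeatability
compares one observer's first (T1) and second (T2) reading sessions;
inter-observer reproducibility compares two observers' first sessions.
Every analyzable variable (each item plus the index totals) yields a Lin
CCC, a Bland-Altman summary and the composite concordance verdict; index
totals use the wider limit-of-agreement threshold.

Variables that are constant and identical in both reading sets (typically
ascites/edema, almost always zero) are reported as not assessable rather
than failing the run.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .agreement import (
    AgreementCriteria,
    BlandAltmanResult,
    CCCResult,
    ConcordanceVerdict,
    PairedMeasurements,
    bland_altman,
    concordance_verdict,
    lin_ccc,
)
from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError
from .scoring import (
    ALL_ITEMS,
    CIBDAI_ITEMS,
    ItemScores,
    ccecai_total,
    cibdai_total,
)

__all__ = [
    "ScoreRecord",
    "StudyDataset",
    "StratificationRule",
    "AgreementRow",
    "StratifiedResult",
    "repeatability_analysis",
    "reproducibility_analysis",
    "mean_score_per_form",
    "severity_stratified_analysis",
    "build_report",
    "parse_report",
]

SESSIONS = ("T1", "T2")
EXPERTISE_LEVELS = ("expert", "non_expert", "unspecified")
TOTAL_VARIABLES = ("CIBDAI", "CCECAI")


@dataclass(frozen=True)
class ScoreRecord:
    """One observer's scoring of one form in one session."""

    form_id: str
    dog_id: str
    observer_id: str
    session: str
    items: ItemScores
    expertise: str = "unspecified"
    cibdai: int = field(init=False)
    ccecai: Optional[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValidationError(
                f"session must be one of {SESSIONS}, got {self.session!r}"
            )
        if self.expertise not in EXPERTISE_LEVELS:
            raise ValidationError(
                f"expertise must be one of {EXPERTISE_LEVELS}, got {self.expertise!r}"
            )
        object.__setattr__(self, "cibdai", cibdai_total(self.items))
        object.__setattr__(
            self,
            "ccecai",
            ccecai_total(self.items) if self.items.has_ccecai_items else None,
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.form_id, self.observer_id, self.session)

    def value(self, variable: str) -> Optional[float]:
        """Value of an item or index total; None when unavailable."""
        if variable == "CIBDAI":
            return float(self.cibdai)
        if variable == "CCECAI":
            return None if self.ccecai is None else float(self.ccecai)
        if variable in ALL_ITEMS:
            v = getattr(self.items, variable)
            return None if v is None else float(v)
        raise ValidationError(f"unknown variable {variable!r}")


@dataclass(frozen=True)
class StudyDataset:
    """Score grid over (form x observer x session)."""

    records: tuple[ScoreRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        keys = [r.key for r in records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (form, observer, session) keys: {dupes}")
        object.__setattr__(self, "records", records)

    @property
    def forms(self) -> tuple[str, ...]:
        return tuple(sorted({r.form_id for r in self.records}))

    @property
    def observers(self) -> tuple[str, ...]:
        return tuple(sorted({r.observer_id for r in self.records}))

    @property
    def has_ccecai(self) -> bool:
        return any(r.ccecai is not None for r in self.records)

    @property
    def variables(self) -> tuple[str, ...]:
        """Analyzable variables: items present in the data plus totals."""
        items = list(CIBDAI_ITEMS)
        totals = ["CIBDAI"]
        if self.has_ccecai:
            items += ["albumin", "ascites_edema", "pruritus"]
            totals += ["CCECAI"]
        return tuple(items + totals)

    def expertise_of(self, observer_id: str) -> str:
        for r in self.records:
            if r.observer_id == observer_id:
                return r.expertise
        raise ValidationError(f"unknown observer {observer_id!r}")

    def lookup(self) -> dict[tuple[str, str, str], ScoreRecord]:
        return {r.key: r for r in self.records}

    def subset(self, form_ids: Iterable[str]) -> "StudyDataset":
        wanted = set(form_ids)
        return StudyDataset(tuple(r for r in self.records if r.form_id in wanted))


@dataclass(frozen=True)
class StratificationRule:
    """Severity split on the per-form mean index total.

    Membership: low-severity group has mean total < cutoff, high-severity
    group has mean total >= cutoff (ties go high).
    """

    index_kind: str = "CIBDAI"
    cutoff: float = 5.5

    def __post_init__(self) -> None:
        if self.index_kind not in TOTAL_VARIABLES:
            raise ValidationError(f"index_kind must be one of {TOTAL_VARIABLES}")
        upper = 18 if self.index_kind == "CIBDAI" else 27
        if not 0 < self.cutoff < upper:
            raise ValidationError(
                f"cutoff must lie in (0, {upper}) for {self.index_kind}"
            )

    @classmethod
    def default(cls, index_kind: str) -> "StratificationRule":
        return cls(index_kind, 5.5 if index_kind == "CIBDAI" else 7.0)


@dataclass(frozen=True)
class AgreementRow:
    """Agreement statistics and verdict for one variable in one comparison."""

    label: str
    comparison: str  # e.g. "repeatability:E1" or "reproducibility:E1|E2"
    n: int
    is_total: bool
    assessable: bool
    ccc: Optional[CCCResult]
    ba: Optional[BlandAltmanResult]
    verdict: Optional[ConcordanceVerdict]
    note: str = ""

    def to_record(self) -> dict:
        """Flat record mirroring the published table layout."""
        ccc, ba, verdict = self.ccc, self.ba, self.verdict
        nan = float("nan")
        return {
            "comparison": self.comparison,
            "label": self.label,
            "n": self.n,
            "ccc": ccc.estimate if ccc else nan,
            "ccc_ci_low": ccc.ci_low if ccc else nan,
            "ccc_ci_high": ccc.ci_high if ccc else nan,
            "bias": ba.bias if ba else nan,
            "bias_ci_low": ba.bias_ci_low if ba else nan,
            "bias_ci_high": ba.bias_ci_high if ba else nan,
            "loa_lower": ba.loa_lower if ba else nan,
            "loa_lower_ci_low": ba.loa_lower_ci[0] if ba else nan,
            "loa_lower_ci_high": ba.loa_lower_ci[1] if ba else nan,
            "loa_upper": ba.loa_upper if ba else nan,
            "loa_upper_ci_low": ba.loa_upper_ci[0] if ba else nan,
            "loa_upper_ci_high": ba.loa_upper_ci[1] if ba else nan,
            "agreement": (
                "NA" if not self.assessable else ("Yes" if verdict.concordant else "No")
            ),
            "reasons": ";".join(verdict.failure_reasons) if verdict else "",
        }


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------

def _paired_values(
    ds: StudyDataset,
    variable: str,
    side_a: tuple[str, str],
    side_b: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Aligned (x, y) values of ``variable`` for two (observer, session)
    sides, over forms with a record on both sides (pairwise deletion)."""
    table = ds.lookup()
    xs, ys = [], []
    for form in ds.forms:
        ra = table.get((form, side_a[0], side_a[1]))
        rb = table.get((form, side_b[0], side_b[1]))
        if ra is None or rb is None:
            continue
        va, vb = ra.value(variable), rb.value(variable)
        if va is None or vb is None:
            continue
        xs.append(va)
        ys.append(vb)
    return np.asarray(xs, float), np.asarray(ys, float), len(xs)


def _analyze_pairs(
    ds: StudyDataset,
    comparison: str,
    side_a: tuple[str, str],
    side_b: tuple[str, str],
    criteria: AgreementCriteria,
    who: str,
) -> list[AgreementRow]:
    shared = _paired_values(ds, "CIBDAI", side_a, side_b)[2]
    if shared < 3:
        raise InsufficientDataError(
            f"{who}: only {shared} shared forms between "
            f"{side_a[0]}@{side_a[1]} and {side_b[0]}@{side_b[1]} (need >= 3)"
        )
    rows = []
    for variable in ds.variables:
        x, y, n = _paired_values(ds, variable, side_a, side_b)
        is_total = variable in TOTAL_VARIABLES
        if n < 3:
            rows.append(
                AgreementRow(
                    variable, comparison, n, is_total, False, None, None, None,
                    note=f"only {n} complete pairs",
                )
            )
            continue
        pairs = PairedMeasurements(x, y, label=variable)
        ba = bland_altman(pairs)
        try:
            ccc = lin_ccc(pairs)
        except UndefinedStatisticError:
            rows.append(
                AgreementRow(
                    variable, comparison, n, is_total, False, None, ba, None,
                    note="constant and identical in both reading sets",
                )
            )
            continue
        verdict = concordance_verdict(ccc, ba, criteria, is_total=is_total)
        rows.append(
            AgreementRow(variable, comparison, n, is_total, True, ccc, ba, verdict)
        )
    return rows


# ---------------------------------------------------------------------------
# Study analyses
# ---------------------------------------------------------------------------

def repeatability_analysis(
    ds: StudyDataset,
    observer: str,
    criteria: AgreementCriteria = AgreementCriteria(),
) -> list[AgreementRow]:
    """Intra-observer repeatability: observer's T1 vs T2 readings.

    Differences are oriented first-minus-second (T1 - T2).
    """
    return _analyze_pairs(
        ds,
        f"repeatability:{observer}",
        (observer, "T1"),
        (observer, "T2"),
        criteria,
        who=f"repeatability of {observer!r}",
    )


def reproducibility_analysis(
    ds: StudyDataset,
    observer_a: str,
    observer_b: str,
    criteria: AgreementCriteria = AgreementCriteria(),
) -> list[AgreementRow]:
    """Inter-observer reproducibility: both observers' T1 readings.

    Differences are oriented first-listed minus second-listed observer, so
    swapping the observers negates every bias and mirrors the LoA.
    """
    return _analyze_pairs(
        ds,
        f"reproducibility:{observer_a}|{observer_b}",
        (observer_a, "T1"),
        (observer_b, "T1"),
        criteria,
        who=f"reproducibility of {observer_a!r} vs {observer_b!r}",
    )


def mean_score_per_form(ds: StudyDataset, index_kind: str = "CIBDAI") -> dict[str, float]:
    """Per-form mean index total over all available observer x session
    ratings; forms with no rating of that index are excluded."""
    if index_kind not in TOTAL_VARIABLES:
        raise ValidationError(f"index_kind must be one of {TOTAL_VARIABLES}")
    sums: dict[str, list[float]] = {}
    for r in ds.records:
        v = r.value(index_kind)
        if v is not None:
            sums.setdefault(r.form_id, []).append(v)
    return {form: float(np.mean(vals)) for form, vals in sorted(sums.items())}


@dataclass(frozen=True)
class StratifiedResult:
    """Subgroup analyses and per-subgroup concordance counts for the
    stratification index."""

    rule: StratificationRule
    low_forms: tuple[str, ...]
    high_forms: tuple[str, ...]
    low_rows: tuple[AgreementRow, ...]
    high_rows: tuple[AgreementRow, ...]
    low_concordant: int
    low_combinations: int
    high_concordant: int
    high_combinations: int

    @property
    def low_fraction(self) -> float:
        if self.low_combinations == 0:
            return math.nan
        return self.low_concordant / self.low_combinations

    @property
    def high_fraction(self) -> float:
        if self.high_combinations == 0:
            return math.nan
        return self.high_concordant / self.high_combinations


def _index_rows_for_subgroup(
    sub: StudyDataset, index_kind: str, criteria: AgreementCriteria
) -> list[AgreementRow]:
    rows: list[AgreementRow] = []
    for obs in sub.observers:
        rows.extend(
            r for r in repeatability_analysis(sub, obs, criteria)
            if r.label == index_kind
        )
    for a, b in itertools.combinations(sub.observers, 2):
        rows.extend(
            r for r in reproducibility_analysis(sub, a, b, criteria)
            if r.label == index_kind
        )
    return rows


def severity_stratified_analysis(
    ds: StudyDataset,
    rule: StratificationRule = StratificationRule(),
    criteria: AgreementCriteria = AgreementCriteria(),
) -> StratifiedResult:
    """Repeatability and reproducibility of the stratification index within
    low- and high-severity subgroups.

    Forms are assigned by their mean index total across all observers and
    sessions (low < cutoff <= high).  Each subgroup contributes one verdict
    per observer (repeatability) and per observer pair (reproducibility);
    the reported fractions are concordant combinations over all assessable
    combinations.
    """
    means = mean_score_per_form(ds, rule.index_kind)
    low = tuple(f for f, m in means.items() if m < rule.cutoff)
    high = tuple(f for f, m in means.items() if m >= rule.cutoff)
    # a cutoff outside the observed range gives a trivial (but valid) split;
    # a subgroup too small to analyze is an error
    if (0 < len(low) < 3) or (0 < len(high) < 3) or (not low and not high):
        raise InsufficientDataError(
            f"degenerate severity split at cutoff {rule.cutoff}: "
            f"{len(low)} low-severity and {len(high)} high-severity forms "
            "(need >= 3 in each non-empty subgroup)"
        )
    low_rows = (
        _index_rows_for_subgroup(ds.subset(low), rule.index_kind, criteria)
        if low else []
    )
    high_rows = (
        _index_rows_for_subgroup(ds.subset(high), rule.index_kind, criteria)
        if high else []
    )

    def counts(rows: list[AgreementRow]) -> tuple[int, int]:
        assessable = [r for r in rows if r.assessable]
        return sum(r.verdict.concordant for r in assessable), len(assessable)

    lc, lt = counts(low_rows)
    hc, ht = counts(high_rows)
    return StratifiedResult(
        rule=rule,
        low_forms=low,
        high_forms=high,
        low_rows=tuple(low_rows),
        high_rows=tuple(high_rows),
        low_concordant=lc,
        low_combinations=lt,
        high_concordant=hc,
        high_combinations=ht,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_HEADER = (
    "Comparison", "Score", "n", "Lin's CCC [95% CI]", "Bias [95% CI]",
    "Lower 95% LoA [95% CI]", "Upper 95% LoA [95% CI]", "Agreement",
)


def _fmt_ci(value: float, lo: float, hi: float, nd: int) -> str:
    if math.isnan(value):
        return "NA"
    if math.isnan(lo) or math.isnan(hi):
        return f"{value:.{nd}f} [NA]"
    return f"{value:.{nd}f} [{lo:.{nd}f}; {hi:.{nd}f}]"


def build_report(
    rows: Sequence[AgreementRow],
    decimals_ccc: int = 2,
    decimals_ba: int = 3,
) -> str:
    """Render agreement rows as a Markdown table.

    Rows keep their input order (analyses emit variables in index order);
    an empty input yields a header-only table.
    """
    lines = [
        "| " + " | ".join(_HEADER) + " |",
        "|" + "|".join("---" for _ in _HEADER) + "|",
    ]
    for row in rows:
        rec = row.to_record()
        cells = (
            row.comparison,
            row.label,
            str(row.n),
            _fmt_ci(rec["ccc"], rec["ccc_ci_low"], rec["ccc_ci_high"], decimals_ccc),
            _fmt_ci(rec["bias"], rec["bias_ci_low"], rec["bias_ci_high"], decimals_ba),
            _fmt_ci(
                rec["loa_lower"], rec["loa_lower_ci_low"],
                rec["loa_lower_ci_high"], decimals_ba,
            ),
            _fmt_ci(
                rec["loa_upper"], rec["loa_upper_ci_low"],
                rec["loa_upper_ci_high"], decimals_ba,
            ),
            rec["agreement"],
        )
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


_CI_RE = re.compile(
    r"^(?P<v>-?\d+\.\d+)(?: \[(?:NA|(?P<lo>-?\d+\.\d+); (?P<hi>-?\d+\.\d+))\])?$"
)


def _parse_ci(cell: str) -> tuple[float, float, float]:
    if cell == "NA":
        return (math.nan,) * 3
    m = _CI_RE.match(cell)
    if m is None:
        raise ValidationError(f"cannot parse statistic cell {cell!r}")
    lo = float(m["lo"]) if m["lo"] else math.nan
    hi = float(m["hi"]) if m["hi"] else math.nan
    return float(m["v"]), lo, hi


def parse_report(text: str) -> list[dict]:
    """Parse a :func:`build_report` table back into flat records
    (at the rendered rounding precision)."""
    out = []
    for line in text.strip().splitlines()[2:]:
        cells = [c.strip() for c in line.strip().strip("|").split("|")]
        if len(cells) != len(_HEADER):
            raise ValidationError(f"malformed report line: {line!r}")
        ccc, ccc_lo, ccc_hi = _parse_ci(cells[3])
        bias, bias_lo, bias_hi = _parse_ci(cells[4])
        lo, lo_lo, lo_hi = _parse_ci(cells[5])
        up, up_lo, up_hi = _parse_ci(cells[6])
        out.append(
            {
                "comparison": cells[0],
                "label": cells[1],
                "n": int(cells[2]),
                "ccc": ccc, "ccc_ci_low": ccc_lo, "ccc_ci_high": ccc_hi,
                "bias": bias, "bias_ci_low": bias_lo, "bias_ci_high": bias_hi,
                "loa_lower": lo, "loa_lower_ci_low": lo_lo, "loa_lower_ci_high": lo_hi,
                "loa_upper": up, "loa_upper_ci_low": up_lo, "loa_upper_ci_high": up_hi,
                "agreement": cells[7],
            }
        )
    return out
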