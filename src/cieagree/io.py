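"""Readers, writers and the end-to-end pipeline.

Score files are long-format CSV (UTF-8, comma-delimited, header required)
with columns ``form_id, dog_id, observer_id, expertise, session, item,
value`` -- one row per item score.  Raw-observation files carry one row per
form with columns named after the clinical inputs.  Both schemas are
documented in ``docs/io_formats.md``; malformed rows are rejected with
row-addressed messages.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AgreementCriteria
from .errors import ValidationError
from .reliability import (
    SESSIONS,
    AgreementRow,
    ScoreRecord,
    StratificationRule,
    StudyDataset,
    build_report,
    mean_score_per_form,
    repeatability_analysis,
    reproducibility_analysis,
    severity_stratified_analysis,
)
from .scoring import (
    ALL_ITEMS,
    CCECAI_EXTRA_ITEMS,
    CIBDAI_ITEMS,
    ClinicalObservation,
    ItemScores,
    score_items,
)

logger = logging.getLogger("cieagree")

SCORE_COLUMNS = (
    "form_id", "dog_id", "observer_id", "expertise", "session", "item", "value",
)

OBSERVATION_COLUMNS = (
    "form_id", "attitude_grade", "appetite_grade", "vomits_per_week",
    "mean_psfs", "stools_per_day", "blood_or_mucus", "weight_loss_pct",
)
OBSERVATION_OPTIONAL = (
    "albumin_g_per_l", "ascites_edema_grade", "pruritus_grade", "problem_flags",
)

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"row {row}: column {column!r}: not a boolean: {value!r}")


# ---------------------------------------------------------------------------
# Long-format score files
# ---------------------------------------------------------------------------

def read_scores(path: Union[str, Path]) -> StudyDataset:
    """Read a long-format score CSV into a validated :class:`StudyDataset`.

    Totals are recomputed from the item scores; duplicate
    (form, observer, session, item) rows and out-of-range values are
    rejected with the offending row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {sorted(missing)}"
        )
    groups: dict[tuple[str, str, str], dict] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        item = row.item.strip()
        if item not in ALL_ITEMS:
            raise ValidationError(
                f"{path}: row {idx}: unknown item {item!r} "
                f"(expected one of {list(ALL_ITEMS)})"
            )
        try:
            value = int(row.value)
            if not 0 <= value <= 3 or row.value.strip() != str(value):
                raise ValueError
        except ValueError:
            raise ValidationError(
                f"{path}: row {idx}: item {item!r} value {row.value!r} "
                "out of range (integers 0-3)"
            ) from None
        key = (row.form_id, row.observer_id, row.session)
        group = groups.setdefault(
            key, {"dog_id": row.dog_id, "expertise": row.expertise, "items": {}}
        )
        if item in group["items"]:
            raise ValidationError(
                f"{path}: row {idx}: duplicate score for "
                f"(form {key[0]!r}, observer {key[1]!r}, session {key[2]!r}, "
                f"item {item!r})"
            )
        group["items"][item] = value
    records = []
    for (form, observer, session), group in groups.items():
        try:
            items = ItemScores(**group["items"])
            records.append(
                ScoreRecord(
                    form_id=form,
                    dog_id=group["dog_id"],
                    observer_id=observer,
                    session=session,
                    items=items,
                    expertise=group["expertise"] or "unspecified",
                )
            )
        except ValidationError as exc:
            raise ValidationError(
                f"{path}: (form {form!r}, observer {observer!r}, "
                f"session {session!r}): {exc}"
            ) from None
    ds = StudyDataset(tuple(records))
    logger.info(
        "read %d records (%d forms, %d observers) from %s",
        len(ds.records), len(ds.forms), len(ds.observers), path,
    )
    return ds


def scores_frame(ds: StudyDataset) -> pd.DataFrame:
    """Long-format DataFrame of a dataset (one row per item score)."""
    rows = []
    for r in sorted(ds.records, key=lambda r: r.key):
        for item, value in r.items.as_dict().items():
            rows.append(
                (r.form_id, r.dog_id, r.observer_id, r.expertise, r.session,
                 item, value)
            )
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS))


def write_scores(ds: StudyDataset, path: Union[str, Path]) -> None:
    """Write a dataset as long-format CSV (inverse of :func:`read_scores`)."""
    scores_frame(ds).to_csv(path, index=False)


def wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide score sheet (one column per item) to the long schema."""
    id_cols = ["form_id", "dog_id", "observer_id", "expertise", "session"]
    missing = set(id_cols) - set(df.columns)
    if missing:
        raise ValidationError(f"wide table missing column(s): {sorted(missing)}")
    items = [c for c in df.columns if c in ALL_ITEMS]
    if not items:
        raise ValidationError("wide table has no item columns")
    long = df.melt(
        id_vars=id_cols, value_vars=items, var_name="item", value_name="value"
    ).dropna(subset=["value"])
    return long[list(SCORE_COLUMNS)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Raw clinical observations
# ---------------------------------------------------------------------------

def read_observations(
    path: Union[str, Path]
) -> list[tuple[str, ClinicalObservation]]:
    """Read a raw-observation CSV: one row per form, columns named after
    the clinical inputs; ``problem_flags`` is a semicolon-separated list of
    item names."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {sorted(missing)}"
        )

    def num(row_idx, row, column, optional=False):
        raw = getattr(row, column, "").strip() if hasattr(row, column) else ""
        if raw == "":
            if optional:
                return None
            raise ValidationError(f"{path}: row {row_idx}: {column!r} is empty")
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}: row {row_idx}: {column!r} is not numeric: {raw!r}"
            ) from None

    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        flags_raw = getattr(row, "problem_flags", "") or ""
        flags = frozenset(f.strip() for f in flags_raw.split(";") if f.strip())
        grade = lambda col, optional=False: (
            None if (v := num(idx, row, col, optional)) is None else int(v)
        )
        try:
            obs = ClinicalObservation(
                attitude_grade=grade("attitude_grade"),
                appetite_grade=grade("appetite_grade"),
                vomits_per_week=num(idx, row, "vomits_per_week"),
                mean_psfs=num(idx, row, "mean_psfs"),
                stools_per_day=num(idx, row, "stools_per_day"),
                blood_or_mucus=_parse_bool(row.blood_or_mucus, idx, "blood_or_mucus"),
                weight_loss_pct=num(idx, row, "weight_loss_pct"),
                albumin_g_per_l=num(idx, row, "albumin_g_per_l", optional=True),
                ascites_edema_grade=grade("ascites_edema_grade", optional=True),
                pruritus_grade=grade("pruritus_grade", optional=True),
                problem_flags=flags,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        out.append((row.form_id, obs))
    return out


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end reliability run."""

    input: Path
    outdir: Path
    criteria: AgreementCriteria = AgreementCriteria()
    stratification: Optional[StratificationRule] = None  # None: per-index default
    decimals_ccc: int = 2
    decimals_ba: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "input", Path(self.input))
        object.__setattr__(self, "outdir", Path(self.outdir))
        if not self.input.exists():
            raise ValidationError(f"input file does not exist: {self.input}")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    criteria = AgreementCriteria.preset(raw.get("criteria", "paper"))
    overrides = {
        k: raw[k]
        for k in ("ccc_min", "bias_limit", "loa_limit_item", "loa_limit_total")
        if k in raw
    }
    if overrides:
        criteria = AgreementCriteria(
            **{**asdict(criteria), **overrides, "name": criteria.name + "+overrides"}
        )
    strat = None
    if "stratify" in raw:
        strat = StratificationRule(
            index_kind=raw["stratify"].get("index", "CIBDAI"),
            cutoff=raw["stratify"].get("cutoff", 5.5),
        )
    return RunConfig(
        input=Path(raw["input"]),
        outdir=Path(raw.get("outdir", "cieagree-out")),
        criteria=criteria,
        stratification=strat,
        decimals_ccc=int(raw.get("decimals_ccc", 2)),
        decimals_ba=int(raw.get("decimals_ba", 3)),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def rows_frame(rows: list[AgreementRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in rows])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full study analysis on a score file.

    Runs repeatability for every observer, reproducibility for every
    observer pair, and a severity-stratified subgroup analysis per index,
    then writes ``results.csv``, ``results.json``, ``report.md`` and
    ``run_log.json`` to the output directory.  Outputs are a pure function
    of (input file, configuration).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    ds = read_scores(cfg.input)
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    rows: list[AgreementRow] = []
    try:
        stage = "repeatability"
        for observer in ds.observers:
            rows.extend(repeatability_analysis(ds, observer, cfg.criteria))
        stage = "reproducibility"
        for a, b in itertools.combinations(ds.observers, 2):
            rows.extend(reproducibility_analysis(ds, a, b, cfg.criteria))
        stage = "stratification"
        indices = ["CIBDAI"] + (["CCECAI"] if ds.has_ccecai else [])
        stratified = {}
        for index_kind in indices:
            rule = cfg.stratification
            if rule is None or rule.index_kind != index_kind:
                rule = StratificationRule.default(index_kind)
            res = severity_stratified_analysis(ds, rule, cfg.criteria)
            stratified[index_kind] = {
                "cutoff": rule.cutoff,
                "n_low_forms": len(res.low_forms),
                "n_high_forms": len(res.high_forms),
                "low_concordant": res.low_concordant,
                "low_combinations": res.low_combinations,
                "high_concordant": res.high_concordant,
                "high_combinations": res.high_combinations,
            }
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    frame = rows_frame(rows)
    frame.to_csv(cfg.outdir / "results.csv", index=False)
    report = build_report(rows, cfg.decimals_ccc, cfg.decimals_ba)
    (cfg.outdir / "report.md").write_text(report)
    results = {
        "version": __version__,
        "criteria": asdict(cfg.criteria),
        "n_forms": len(ds.forms),
        "observers": list(ds.observers),
        "rows": [
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in rec.items()}
            for rec in frame.to_dict("records")
        ],
        "stratified": stratified,
    }
    (cfg.outdir / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n"
    )
    run_log = {
        "version": __version__,
        "input": str(cfg.input),
        "seed": cfg.seed,
        "criteria": asdict(cfg.criteria),
        "effective_n": {
            f"{r.comparison}/{r.label}": r.n for r in rows
        },
    }
    (cfg.outdir / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    logger.info("wrote %d result rows to %s", len(rows), cfg.outdir)
    return results
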