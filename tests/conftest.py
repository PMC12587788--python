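"""Shared fixtures and independent oracles."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from cieagree.reliability import ScoreRecord, StudyDataset
from cieagree.scoring import ItemScores
from cieagree.simulate import preset, simulate_study


def ccc_bruteforce(x, y) -> float:
    """Independent CCC re-derivation from raw sums (1/n moments).

    Deliberately avoids numpy vectorised moments so it shares no code path
    with the implementation under test.
    """
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    mx, my = sx / n, sy / n
    vx = sxx / n - mx * mx
    vy = syy / n - my * my
    cxy = sxy / n - mx * my
    return 2.0 * cxy / (vx + vy + (mx - my) ** 2)


def make_records(
    grids: dict[tuple[str, str], list[dict]],
    expertise: str = "unspecified",
) -> StudyDataset:
    """Build a dataset from {(observer, session): [item-dict per form]}."""
    records = []
    for (observer, session), forms in grids.items():
        for i, items in enumerate(forms):
            records.append(
                ScoreRecord(
                    form_id=f"F{i + 1:03d}",
                    dog_id=f"D{i + 1:03d}",
                    observer_id=observer,
                    session=session,
                    items=ItemScores(**items),
                    expertise=expertise,
                )
            )
    return StudyDataset(tuple(records))


def core_items(*values: int) -> dict:
    """Six CIBDAI item scores from a tuple."""
    from cieagree.scoring import CIBDAI_ITEMS

    return dict(zip(CIBDAI_ITEMS, values))


@pytest.fixture(scope="session")
def phase2_dataset():
    """Default phase-2-like simulated study (59 forms, 4 observers)."""
    cfg, observers = preset("phase2", seed=2024)
    return simulate_study(cfg, observers)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Phase-2 structure with all observer/session noise and biases off."""
    cfg, observers = preset("phase2", seed=7)
    cfg = dataclasses.replace(
        cfg, within_observer_sd=0.0, between_observer_sd=0.0, observer_biases={}
    )
    return simulate_study(cfg, observers)
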