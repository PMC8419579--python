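"""Shared fixtures: synthesized calls and small synthetic colonies.

All fixtures are generated programmatically at test time; nothing is read
from disk. The ``annotation_features`` helper turns a colony annotation
table into "perfect" per-call features (F0 = planted F0), providing an
audio-free fast path for tests of the matching and similarity stages that
do not exercise the signal chain itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pupcall.audio import CallFeatures
from pupcall.colony import DevelopmentalConfig, PupRecord, simulate_colony
from pupcall.stimuli import make_source_call

RATE_FAST = 16_000.0  # colony tests run at a lower rate than the 96 kHz default


@pytest.fixture(scope="session")
def source_call():
    """The 119 Hz baseline template call at the full 96 kHz rate."""
    return make_source_call()


@pytest.fixture(scope="session")
def source_call_fast():
    return make_source_call(rate=RATE_FAST)


def annotation_features(
    annotations: pd.DataFrame,
) -> tuple[dict[tuple[str, int], list[CallFeatures]], pd.DataFrame]:
    """Per-session CallFeatures built directly from planted annotations."""
    session_calls: dict[tuple[str, int], list[CallFeatures]] = {}
    rows = []
    for (pup_id, age), grp in annotations.groupby(["pup_id", "age_days"]):
        grp = grp.sort_values("onset_s").reset_index(drop=True)
        feats = []
        for i, row in grp.iterrows():
            f = CallFeatures(
                duration=row.offset_s - row.onset_s,
                f0_contour=np.array([row.f0_hz]),
                peak_contour=np.array([row.f0_hz]),
                mean_f0=row.f0_hz,
                min_f0=row.f0_hz,
                max_f0=row.f0_hz,
                mean_peak=row.f0_hz,
                onset_s=row.onset_s,
                offset_s=row.offset_s,
            )
            feats.append(f)
            rows.append(
                {
                    "pup_id": pup_id,
                    "age_days": age,
                    "call_index": i,
                    "onset_s": f.onset_s,
                    "offset_s": f.offset_s,
                    "duration_s": f.duration,
                    "mean_f0": f.mean_f0,
                    "min_f0": f.min_f0,
                    "max_f0": f.max_f0,
                    "mean_peak": f.mean_peak,
                    "n_frames": 1,
                }
            )
        session_calls[(pup_id, age)] = feats
    return session_calls, pd.DataFrame(rows)


def pup_meta(pups: list[PupRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pup_id": p.pup_id,
                "condition": p.condition,
                "stimulus_id": p.stimulus_id,
                "sex": p.sex,
            }
            for p in pups
        ]
    )


@pytest.fixture(scope="session")
def small_colony():
    """A 4-pup colony with audio at 16 kHz, early and weaning days only."""
    pups = [
        PupRecord("C0", "M", "control", "none"),
        PupRecord("C1", "F", "control", "none"),
        PupRecord("V0", "F", "varied", "a"),
        PupRecord("V1", "M", "varied", "ab"),
    ]
    cfg = DevelopmentalConfig(rate=RATE_FAST, calls_per_day=30, seed=20211025)
    col = simulate_colony(pups, cfg, days=[0, 1, 18, 19])
    return col


def random_call_features(
    rng: np.random.Generator,
    n: int,
    gap_range=(0.3, 1.6),
    f0_range=(100.0, 500.0),
) -> list[CallFeatures]:
    """Random time-ordered call lists for match-rule oracle tests."""
    onsets = np.cumsum(rng.uniform(*gap_range, n))
    f0s = rng.uniform(*f0_range, n)
    return [
        CallFeatures(
            duration=0.5,
            f0_contour=np.array([f]),
            peak_contour=np.array([f]),
            mean_f0=float(f),
            min_f0=float(f),
            max_f0=float(f),
            mean_peak=float(f),
            onset_s=float(t),
            offset_s=float(t) + 0.5,
        )
        for t, f in zip(onsets, f0s)
    ]
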