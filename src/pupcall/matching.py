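"""Template-match classification of call sequences.

A pup's calling counts as a match when two or three calls (depending on the
stimulus) occur within 1 s of each other and the mean fundamental frequency
changes by at least 100 Hz between successive calls, in the same directions
as in the template. Control pups received no playbacks, so any of the three
templates counts for them (the chance-match rate).

"Within 1 s" is interpreted as every successive onset-to-onset gap <= 1 s:
stimulus calls are 0.75 s apart onset-to-onset while distinct sequences are
over 1 s apart, so this separates sequences as designed. Overlapping
candidate windows are resolved greedily left to right (earliest window
wins, no call reuse), and every call of a matched window is flagged,
because the statistical model's unit is the individual call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import CallFeatures
from .stimuli import StimulusTemplate, TEMPLATES, get_template

F0_MATCH_THRESHOLD_HZ = 100.0
MAX_ONSET_GAP_S = 1.0


@dataclass(frozen=True)
class MatchResult:
    """One evaluated window of consecutive calls."""

    call_indices: tuple[int, ...]
    template_id: str
    is_match: bool
    f0_deltas: tuple[float, ...]


def _window_matches(
    f0s: np.ndarray, template: StimulusTemplate, threshold: float
) -> tuple[bool, tuple[float, ...]]:
    deltas = tuple(float(d) for d in np.diff(f0s))
    signs = {"up": 1.0, "down": -1.0}
    ok = all(
        abs(d) >= threshold and np.sign(d) == signs[direction]
        for d, direction in zip(deltas, template.direction_pattern)
    )
    return ok, deltas


def _check_sorted(onsets: np.ndarray) -> None:
    if np.any(np.diff(onsets) < 0):
        raise ValueError("calls must be sorted by onset time")


def find_matches(
    calls: list[CallFeatures],
    template: StimulusTemplate | str,
    threshold_hz: float = F0_MATCH_THRESHOLD_HZ,
    max_gap_s: float = MAX_ONSET_GAP_S,
) -> list[MatchResult]:
    """Scan a time-ordered call list for windows matching one template.

    Every window of ``k`` consecutive calls whose successive onset-to-onset
    gaps are all <= ``max_gap_s`` is evaluated; matched windows are
    assigned greedily left to right without call reuse. Returns one
    :class:`MatchResult` per evaluated window.
    """
    if isinstance(template, str):
        template = get_template(template)
    k = template.n_calls
    if k not in (2, 3):
        raise ValueError("templates must have 2 or 3 calls")
    onsets = np.array([c.onset_s for c in calls])
    _check_sorted(onsets)
    f0s = np.array([c.mean_f0 for c in calls])
    used = np.zeros(len(calls), dtype=bool)
    results = []
    for i in range(len(calls) - k + 1):
        gaps = np.diff(onsets[i : i + k])
        if np.any(gaps > max_gap_s):
            continue
        ok, deltas = _window_matches(f0s[i : i + k], template, threshold_hz)
        ok = ok and not np.any(used[i : i + k])
        if ok:
            used[i : i + k] = True
        results.append(
            MatchResult(tuple(range(i, i + k)), template.template_id, ok, deltas)
        )
    return results


def control_chance_matches(
    calls: list[CallFeatures],
    threshold_hz: float = F0_MATCH_THRESHOLD_HZ,
    max_gap_s: float = MAX_ONSET_GAP_S,
) -> list[MatchResult]:
    """Any-template matching for control pups.

    A window is a chance match if it satisfies the rule for any of the
    three templates. Longer templates are tried first at each start so a
    full three-call up-down sequence is credited as one ``ab`` match rather
    than an ``a`` pair plus an orphan call.
    """
    onsets = np.array([c.onset_s for c in calls])
    _check_sorted(onsets)
    f0s = np.array([c.mean_f0 for c in calls])
    by_len = sorted(TEMPLATES.values(), key=lambda t: -t.n_calls)
    used = np.zeros(len(calls), dtype=bool)
    results = []
    for i in range(len(calls)):
        for template in by_len:
            k = template.n_calls
            if i + k > len(calls):
                continue
            gaps = np.diff(onsets[i : i + k])
            if np.any(gaps > max_gap_s):
                continue
            ok, deltas = _window_matches(f0s[i : i + k], template, threshold_hz)
            if ok and not np.any(used[i : i + k]):
                used[i : i + k] = True
                results.append(
                    MatchResult(
                        tuple(range(i, i + k)), template.template_id, True, deltas
                    )
                )
                break
    return results


def matched_call_indices(results: list[MatchResult]) -> set[int]:
    """Indices of calls participating in any matched window."""
    out: set[int] = set()
    for r in results:
        if r.is_match:
            out.update(r.call_indices)
    return out


def build_match_table(
    session_calls: dict[tuple[str, int], list[CallFeatures]],
    pup_meta: pd.DataFrame,
    threshold_hz: float = F0_MATCH_THRESHOLD_HZ,
    max_gap_s: float = MAX_ONSET_GAP_S,
) -> pd.DataFrame:
    """Assemble the call-level binary match table for the GLMM.

    Parameters
    ----------
    session_calls
        ``(pup_id, age_days) -> time-ordered CallFeatures list``.
    pup_meta
        One row per pup with columns ``pup_id``, ``condition``,
        ``stimulus_id`` (and optionally ``sex``).

    Returns
    -------
    DataFrame
        Columns (pup_id, age_days, condition, call_index, is_match,
        window_id); ``window_id`` is -1 for unmatched calls.
    """
    meta = pup_meta.set_index("pup_id")
    rows = []
    for (pup_id, age), calls in sorted(session_calls.items()):
        if pup_id not in meta.index:
            raise ValueError(f"no metadata for pup {pup_id!r}")
        condition = meta.loc[pup_id, "condition"]
        if condition == "control":
            results = control_chance_matches(calls, threshold_hz, max_gap_s)
        else:
            template = get_template(meta.loc[pup_id, "stimulus_id"])
            results = find_matches(calls, template, threshold_hz, max_gap_s)
        window_of: dict[int, int] = {}
        template_of: dict[int, str] = {}
        for w, r in enumerate(m for m in results if m.is_match):
            for idx in r.call_indices:
                window_of[idx] = w
                template_of[idx] = r.template_id
        for idx in range(len(calls)):
            rows.append(
                {
                    "pup_id": pup_id,
                    "age_days": age,
                    "condition": condition,
                    "call_index": idx,
                    "is_match": idx in window_of,
                    "window_id": window_of.get(idx, -1),
                    # for controls this is the template the window happened
                    # to realize; for playback pups it is their stimulus
                    "window_template": template_of.get(idx, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pup_id", "age_days", "condition", "call_index",
            "is_match", "window_id", "window_template",
        ],
    )
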