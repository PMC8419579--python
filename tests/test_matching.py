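"""Template-match rule: worked examples, brute-force oracle, properties."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import annotation_features, pup_meta, random_call_features
from pupcall.audio import CallFeatures
from pupcall.colony import DevelopmentalConfig, PupRecord, simulate_colony
from pupcall.matching import (
    build_match_table,
    control_chance_matches,
    find_matches,
    matched_call_indices,
)
from pupcall.stimuli import TEMPLATES, get_template


def calls_from(f0s, gap=0.3):
    onsets = np.arange(len(f0s)) * gap
    return [
        CallFeatures(
            duration=0.2,
            f0_contour=np.array([f]),
            peak_contour=np.array([f]),
            mean_f0=float(f),
            min_f0=float(f),
            max_f0=float(f),
            mean_peak=float(f),
            onset_s=float(t),
            offset_s=float(t) + 0.2,
        )
        for t, f in zip(onsets, f0s)
    ]


def brute_force_match_windows(calls, template, threshold=100.0, max_gap=1.0):
    """All-windows enumeration oracle: every window satisfying the rule."""
    signs = {"up": 1.0, "down": -1.0}
    k = template.n_calls
    out = []
    for i in range(len(calls) - k + 1):
        window = calls[i : i + k]
        gaps = [b.onset_s - a.onset_s for a, b in zip(window, window[1:])]
        if any(g > max_gap for g in gaps):
            continue
        deltas = [b.mean_f0 - a.mean_f0 for a, b in zip(window, window[1:])]
        if all(
            abs(d) >= threshold and np.sign(d) == signs[s]
            for d, s in zip(deltas, template.direction_pattern)
        ):
            out.append(tuple(range(i, i + k)))
    return out


class TestRule:
    def test_up_step_of_140_matches_template_a(self):
        results = find_matches(calls_from([120.0, 260.0]), "a")
        assert [r.is_match for r in results] == [True]
        assert results[0].f0_deltas == (140.0,)

    def test_step_below_100_is_no_match(self):
        results = find_matches(calls_from([120.0, 190.0]), "a")
        assert [r.is_match for r in results] == [False]

    def test_wrong_direction_is_no_match(self):
        assert matched_call_indices(find_matches(calls_from([260.0, 120.0]), "a")) == set()

    def test_calls_over_one_second_apart_never_window(self):
        results = find_matches(calls_from([120.0, 260.0], gap=1.2), "a")
        assert results == []

    def test_down_step_chance_match_via_template_b(self):
        results = control_chance_matches(calls_from([260.0, 120.0]))
        assert len(results) == 1 and results[0].template_id == "b"

    def test_small_steps_match_nothing(self):
        assert control_chance_matches(calls_from([150.0, 180.0, 150.0])) == []

    def test_unsorted_input_rejected(self):
        calls = calls_from([120.0, 260.0])[::-1]
        with pytest.raises(ValueError):
            find_matches(calls, "a")


class TestOracleEquivalence:
    def test_greedy_equals_brute_force_on_random_lists(self):
        """200 random call lists: identical match sets when windows do not
        overlap; greedy earliest-first subset otherwise."""
        rng = np.random.default_rng(12345)
        checked_exact = 0
        for _ in range(200):
            calls = random_call_features(rng, int(rng.integers(3, 15)))
            for template in TEMPLATES.values():
                oracle = brute_force_match_windows(calls, template)
                greedy = [
                    r.call_indices
                    for r in find_matches(calls, template)
                    if r.is_match
                ]
                flat = list(itertools.chain.from_iterable(oracle))
                if len(flat) == len(set(flat)):  # no overlapping windows
                    assert greedy == oracle
                    checked_exact += 1
                else:
                    # greedy picks a maximal non-overlapping earliest-first subset
                    assert set(greedy) <= set(oracle)
                    used = set()
                    for w in oracle:
                        if not used & set(w):
                            assert w in greedy
                            used |= set(w)
        assert checked_exact > 100

    def test_direction_antisymmetry_of_rule(self):
        """Reversing the F0 sequence maps template-a windows onto template-b
        windows exactly (all-windows rule; the greedy assignment then picks
        the mirrored earliest-first subset)."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            f0s = rng.uniform(100, 500, 8)
            fwd = brute_force_match_windows(calls_from(list(f0s)), get_template("a"))
            rev = brute_force_match_windows(
                calls_from(list(f0s[::-1])), get_template("b")
            )
            n = len(f0s)
            mirrored = sorted(tuple(sorted(n - 1 - i for i in w)) for w in fwd)
            assert mirrored == sorted(rev)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            calls = random_call_features(rng, 10)
            counts = [
                len(matched_call_indices(find_matches(calls, "a", threshold_hz=thr)))
                for thr in (50.0, 100.0, 150.0, 200.0)
            ]
            assert counts == sorted(counts, reverse=True)


class TestMatchTable:
    def test_both_calls_of_window_flagged(self):
        f0s = [200.0, 330.0] + [250.0] * 8  # one matched pair among 10 calls
        calls = calls_from(f0s, gap=1.05)
        calls[1] = calls_from([200.0, 330.0], gap=0.4)[1]  # bring pair within 1 s
        meta = pd.DataFrame(
            [{"pup_id": "P", "condition": "varied", "stimulus_id": "a", "sex": "F"}]
        )
        table = build_match_table({("P", 3): calls}, meta)
        assert len(table) == 10
        assert table.is_match.sum() == 2
        assert set(table.loc[table.is_match, "call_index"]) == {0, 1}

    def test_empty_session_gives_no_rows(self):
        meta = pd.DataFrame(
            [{"pup_id": "P", "condition": "control", "stimulus_id": "none", "sex": "F"}]
        )
        assert len(build_match_table({("P", 0): []}, meta)) == 0

    def test_missing_metadata_rejected(self):
        meta = pd.DataFrame(
            [{"pup_id": "Q", "condition": "control", "stimulus_id": "none", "sex": "F"}]
        )
        with pytest.raises(ValueError):
            build_match_table({("P", 0): calls_from([200.0, 330.0])}, meta)

    def test_colony_fractions_track_generator(self):
        """Planted and classified match fractions agree on annotation-level
        features (the audio-free fast path)."""
        pups = [
            PupRecord("C0", "M", "control", "none"),
            PupRecord("V0", "F", "varied", "a"),
        ]
        cfg = DevelopmentalConfig(calls_per_day=60, seed=5)
        col = simulate_colony(pups, cfg, days=[0, 1, 18, 19], synthesize=False)
        session_calls, _ = annotation_features(col.annotations)
        table = build_match_table(session_calls, pup_meta(pups))
        ann = col.annotations.sort_values(["pup_id", "age_days", "onset_s"])
        got = table.sort_values(["pup_id", "age_days", "call_index"])
        assert (
            ann.is_planted_match.to_numpy() == got.is_match.to_numpy()
        ).mean() > 0.99
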