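"""Gower distance and Mantel test: oracles, identities, null calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupcall.similarity import (
    DEFAULT_FEATURES,
    gower_matrix,
    mantel,
    session_similarity,
    template_feature_table,
)


def gower_loop_oracle(table: pd.DataFrame, ordinal=("position",)) -> np.ndarray:
    """Direct per-pair, per-variable loop implementation."""
    work = {}
    for c in table.columns:
        x = table[c].to_numpy(float)
        if c in ordinal:
            x = pd.Series(x).rank(na_option="keep").to_numpy()
        span = np.nanmax(x) - np.nanmin(x)
        if span > 0:
            work[c] = (x, span)
    n = len(table)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for x, span in work.values():
                if not np.isnan(x[i]) and not np.isnan(x[j]):
                    vals.append(abs(x[i] - x[j]) / span)
            d[i, j] = d[j, i] = float(np.mean(vals))
    return d


def random_mixed_table(rng, n):
    return pd.DataFrame(
        {
            "duration_s": rng.uniform(0.3, 0.9, n),
            "mean_f0": rng.uniform(100, 500, n),
            "mean_peak": rng.uniform(100, 500, n),
            "position": rng.integers(0, 3, n).astype(float),
        }
    )


class TestGower:
    def test_identical_vectors_have_zero_distance(self):
        t = pd.DataFrame({"a": [1.0, 1.0], "b": [3.0, 3.0], "c": [2.0, 5.0]})
        d = gower_matrix(t)
        assert d[0, 1] > 0  # c differs
        t2 = pd.DataFrame({"a": [1.0, 1.0], "c": [2.0, 2.0], "d": [0.0, 4.0]})
        assert gower_matrix(t2.iloc[[0, 0]].reset_index(drop=True), ranges={"a": 1, "c": 1, "d": 1})[0, 1] == 0.0

    def test_single_variable_definition(self):
        t = pd.DataFrame({"x": [0.0, 5.0]})
        d = gower_matrix(t, ranges={"x": 10.0})
        assert d[0, 1] == pytest.approx(0.5)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t = random_mixed_table(rng, 6)
            np.testing.assert_allclose(gower_matrix(t), gower_loop_oracle(t), atol=1e-12)

    def test_bounds_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = random_mixed_table(rng, int(rng.integers(3, 10)))
            if rng.random() < 0.3:  # inject missingness
                t.iloc[0, 0] = np.nan
            d = gower_matrix(t)
            assert np.all(d >= 0) and np.all(d <= 1)
            np.testing.assert_allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            assert not np.any(np.isnan(d))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 1.0, allow_nan=False),
                st.floats(-100.0, 100.0, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_gower_metric_axioms_hold_for_arbitrary_tables(self, rows):
        t = pd.DataFrame(rows, columns=["u", "v"])
        if (t.nunique() <= 1).all():
            return  # all variables constant: matrix undefined by contract
        with pytest.warns() if (t.nunique() <= 1).any() else np.errstate():
            d = gower_matrix(t, ordinal=())
        assert np.all((0.0 <= d) & (d <= 1.0))
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)

    def test_zero_range_variable_dropped_with_warning(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_matrix(t)
        assert d[0, 2] == pytest.approx(1.0)

    def test_all_missing_variable_rejected(self):
        t = pd.DataFrame({"x": [np.nan, np.nan], "y": [0.0, 1.0]})
        with pytest.raises(ValueError):
            gower_matrix(t)


class TestMantel:
    def _random_dm(self, rng, n):
        x = rng.uniform(0, 1, (n, 2))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        return d

    def test_self_association_is_one(self):
        d = self._random_dm(np.random.default_rng(0), 8)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_positive_affine_transform_keeps_r_one(self):
        d = self._random_dm(np.random.default_rng(1), 8)
        res = mantel(d, 0.2 + 3.0 * d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_seeded_reproducibility_and_r_independent_of_n_perm(self):
        rng = np.random.default_rng(2)
        a, b = self._random_dm(rng, 9), self._random_dm(rng, 9)
        r1 = mantel(a, b, n_perm=99, seed=42)
        r2 = mantel(a, b, n_perm=99, seed=42)
        r3 = mantel(a, b, n_perm=499, seed=7)
        assert r1.p_value == r2.p_value and r1.r == r2.r
        assert r3.r == r1.r

    def test_size_mismatch_and_constant_matrix_rejected(self):
        rng = np.random.default_rng(3)
        a = self._random_dm(rng, 6)
        with pytest.raises(ValueError):
            mantel(a, self._random_dm(rng, 7))
        with pytest.raises(ValueError):
            mantel(a, np.zeros((6, 6)))
        with pytest.raises(ValueError):
            mantel(a[:2, :2], a[:2, :2])

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        a, b = self._random_dm(rng, 10), self._random_dm(rng, 10)
        ours = mantel(a, b, n_perm=999, seed=5)
        r_ref, p_ref, _ = skbio_distance.mantel(
            a, b, method="pearson", permutations=999, alternative="greater"
        )
        assert ours.r == pytest.approx(float(r_ref), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_null_p_values_calibrated(self):
        """Independent matrices: ~5% of permutation p-values fall below 0.05."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = self._random_dm(rng, 10)
            b = self._random_dm(rng, 10)
            res = mantel(a, b, n_perm=99, seed=int(rng.integers(2**31)))
            if res.p_value <= 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep == pytest.approx(0.05, abs=3 * se + 1 / 100)

    def test_null_p_super_uniform(self):
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(100):
            a = self._random_dm(rng, 8)
            b = self._random_dm(rng, 8)
            ps.append(mantel(a, b, n_perm=49, seed=int(rng.integers(2**31))).p_value)
        ps = np.array(ps)
        for alpha in (0.1, 0.25, 0.5):
            assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 100)


class TestSessionSimilarity:
    def _matched_frame(self, rng, n, template_like=True):
        pos = np.tile([0, 1], n // 2)
        base = np.where(pos == 0, 119.0, 153.0)
        if not template_like:
            base = rng.uniform(100, 500, n)
        f0 = base + rng.normal(0, 2.0, n)
        return pd.DataFrame(
            {
                "pup_id": "P",
                "age_days": 2,
                "duration_s": 0.7 + rng.normal(0, 0.01, n),
                "mean_f0": f0,
                "min_f0": f0 - 1,
                "max_f0": f0 + 1,
                "mean_peak": f0,
                "inter_call_interval_s": np.where(pos == 0, np.nan, 0.75),
                "position": pos,
            }
        )

    def test_template_copies_score_r_near_one(self):
        rng = np.random.default_rng(1)
        df = self._matched_frame(rng, 12)
        res = session_similarity(df, "a", n_perm=99, seed=3)
        assert len(res) == 1
        assert res.r.iloc[0] > 0.95

    def test_position_independent_features_score_near_zero(self):
        """With the sequence-position feature excluded (it is aligned by
        construction), features independent of template position give mean
        r near zero."""
        rng = np.random.default_rng(6)
        acoustic = ("duration_s", "mean_f0", "min_f0", "max_f0", "mean_peak")
        rs = []
        for _ in range(20):
            df = self._matched_frame(rng, 12, template_like=False)
            df["position"] = rng.integers(0, 2, len(df))
            res = session_similarity(
                df, "a", n_perm=49, seed=int(rng.integers(2**31)), features=acoustic
            )
            if len(res):
                rs.append(res.r.iloc[0])
        assert abs(float(np.mean(rs))) <= 0.15

    def test_bins_with_too_few_calls_skipped(self):
        rng = np.random.default_rng(2)
        df = self._matched_frame(rng, 2)
        assert session_similarity(df, "a", n_perm=49, seed=1).empty

    def test_template_table_shape(self):
        t = template_feature_table("ab")
        assert list(t.columns) == list(DEFAULT_FEATURES)
        assert len(t) == 3
        assert t.inter_call_interval_s.iloc[1] == pytest.approx(0.75)
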