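"""Cross-pair correlations and the shared-gene time screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pogdiv import (
    TaxonPairRecord,
    gene_level_time_correlation,
    pair_level_associations,
    pearson_r,
)


def _brute_force_r(x, y):
    """Independent oracle: covariance / (sigma_x sigma_y) from first
    principles."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


class TestPearson:
    def test_perfect_positive(self):
        r, p = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        r, _ = pearson_r([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_textbook_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 5])
        assert r == pytest.approx(_brute_force_r([1, 2, 3, 4], [1, 3, 2, 5]), abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=30,
        ).filter(lambda xs: np.ptp(xs) > 1e-6)
    )
    def test_matches_brute_force(self, xs):
        rng = np.random.default_rng(len(xs))
        ys = np.asarray(xs) * 0.5 + rng.normal(0, 10, len(xs))
        if np.ptp(ys) <= 1e-9:
            return
        r, _ = pearson_r(xs, ys)
        assert r == pytest.approx(_brute_force_r(xs, ys), abs=1e-12)


def _records(n=10, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        time = 1.5 + i
        peak = 0.005 + 0.004 * time + rng.normal(0, 0.002)
        moderate = 0.4 + 0.02 * time + rng.normal(0, 0.01)
        strong = 0.4 - 0.02 * time + rng.normal(0, 0.01)
        rest = 1 - moderate - strong
        recs.append(
            TaxonPairRecord(
                pair_id=f"p{i:02d}",
                divergence_time_mya=time,
                peak_ks=max(peak, 0.001),
                modified_peak_ks=max(peak, 0.001),
                category_props={
                    "strong_purifying": strong,
                    "moderate_purifying": moderate,
                    "relaxed_purifying": rest * 0.7,
                    "near_neutral": rest * 0.1,
                    "weak_positive": rest * 0.15,
                    "strong_positive": rest * 0.05,
                },
                prop_positive_ge1=rest * 0.25,
            )
        )
    return recs


class TestPairLevel:
    def test_generating_sign_pattern_recovered(self):
        df = pair_level_associations(_records())
        by = {(row.x, row.y): row.r for row in df.itertuples()}
        assert by[("time", "peak_ks")] > 0.8
        assert by[("peak_ks", "moderate_purifying")] > 0
        assert by[("peak_ks", "strong_purifying")] < 0
        assert by[("time", "moderate_purifying")] > 0
        assert by[("time", "strong_purifying")] < 0

    def test_order_and_time_unit_invariance(self):
        recs = _records()
        df1 = pair_level_associations(recs)
        shuffled = list(reversed(recs))
        df2 = pair_level_associations(shuffled)
        pd.testing.assert_frame_equal(df1, df2)
        # affine rescaling of time does not change r
        for r in recs:
            r.divergence_time_mya = 3.0 * r.divergence_time_mya + 2.0
        df3 = pair_level_associations(recs)
        np.testing.assert_allclose(df1["r"], df3["r"], atol=1e-12)

    def test_modified_peak_preserves_signs(self):
        recs = _records()
        df = pair_level_associations(recs)
        plain = df[df.x == "peak_ks"].set_index("y")["r"]
        modified = df[df.x == "modified_peak_ks"].set_index("y")["r"]
        assert all(np.sign(plain[y]) == np.sign(modified[y]) for y in plain.index)

    def test_requires_three_records(self):
        with pytest.raises(ValueError):
            pair_level_associations(_records(2))

    def test_constant_column_skipped(self):
        recs = _records(5)
        for r in recs:
            r.category_props["near_neutral"] = 0.05
        df = pair_level_associations(recs)
        assert ("peak_ks", "near_neutral") not in set(zip(df.x, df.y))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            TaxonPairRecord("p", -1.0, 0.01, 0.01, {})


class TestGeneScreen:
    def _table(self, seed=1):
        rng = np.random.default_rng(seed)
        pairs = [f"p{i:02d}" for i in range(20)]
        times = {p: 1.5 + i * 0.5 for i, p in enumerate(pairs)}
        t = np.array(list(times.values()))
        rows = {}
        # 2 planted positive trends, 6 planted negative, 71 noise genes
        for g in range(2):
            rows[f"up{g}"] = 0.1 + 0.03 * t + rng.normal(0, 0.01, 20)
        for g in range(6):
            rows[f"down{g}"] = 0.5 - 0.03 * t + rng.normal(0, 0.01, 20)
        for g in range(71):
            rows[f"noise{g:02d}"] = np.clip(rng.normal(0.3, 0.05, 20), 0.01, None)
        return pd.DataFrame(rows, index=pairs).T, times

    def test_planted_trends_recovered(self):
        table, times = self._table()
        screen, summary = gene_level_time_correlation(table, times, r_threshold=0.5)
        assert summary["n_genes"] == 79
        passed = screen[screen.passed].set_index("gene_id")
        # every planted gene is recovered with the planted sign
        for g in range(2):
            assert passed.loc[f"up{g}", "sign"] == "+"
        for g in range(6):
            assert passed.loc[f"down{g}", "sign"] == "-"
        # false positives among the 71 noise genes stay rare
        assert summary["n_passed"] <= 8 + 4

    def test_constant_ratios_never_pass(self):
        pairs = [f"p{i}" for i in range(5)]
        times = {p: 2.0 + i for i, p in enumerate(pairs)}
        table = pd.DataFrame({p: [0.3, 0.2] for p in pairs}, index=["g1", "g2"])
        screen, summary = gene_level_time_correlation(table, times)
        assert summary["n_passed"] == 0

    def test_zero_and_sentinel_removed_pairwise(self):
        pairs = [f"p{i}" for i in range(6)]
        times = {p: 2.0 + i for i, p in enumerate(pairs)}
        vals = [0.1, 99.0, 0.2, 0.0, 0.3, 0.4]  # sentinel and zero dropped
        table = pd.DataFrame({p: [v] for p, v in zip(pairs, vals)}, index=["g"])
        screen, _ = gene_level_time_correlation(table, times, min_presence=0.5)
        assert screen.iloc[0]["n"] == 4

    def test_sparse_gene_skipped(self):
        pairs = [f"p{i}" for i in range(10)]
        times = {p: 2.0 + i for i, p in enumerate(pairs)}
        sparse = [0.1, 0.2, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan]
        table = pd.DataFrame({p: [v] for p, v in zip(pairs, sparse)}, index=["g"])
        screen, summary = gene_level_time_correlation(table, times, min_presence=0.9)
        assert summary["n_genes"] == 0
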