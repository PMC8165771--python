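"""Concordance accounting and the contingency/rank tests with oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cftriage.concordance import (
    ContingencyTable2x2,
    chi2_yates,
    fisher_exact_2x2,
    mann_whitney_u,
    partition_mutations,
    tmb_concordance,
)
from cftriage.errors import DomainError, InputError


def fisher_oracle(a, b, c, d):
    """Exact-rational minimum-likelihood two-sided Fisher p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = math.comb(r1, k) * math.comb(r2, c1 - k)
        if pk <= obs:
            num += pk
    return float(Fraction(num, math.comb(r1 + r2, c1)))


class TestFisher:
    def test_degenerate_margins_give_one(self):
        _, p = fisher_exact_2x2([[1, 0], [0, 1]])
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_table(self):
        _, p = fisher_exact_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70)

    def test_negative_cell_rejected(self):
        with pytest.raises(DomainError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_odds_ratio(self):
        odds, _ = fisher_exact_2x2([[20, 5], [5, 20]])
        assert odds == pytest.approx(16.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.tuples(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)).filter(lambda t: sum(t) > 0))
    def test_matches_exact_rational_oracle(self, cells):
        a, b, c, d = cells
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_matches_scipy_on_large_table(self):
        from scipy.stats import fisher_exact

        for table in ([[207, 76], [160, 160]], [[70, 3], [97, 54]], [[99, 23], [25, 59]], [[12, 300], [250, 40]]):
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(fisher_exact(table)[1], rel=1e-8)


class TestChi2Yates:
    def test_balanced_table_is_null(self):
        chi2, p = chi2_yates([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        # 50*(|400-25| - 25)^2 / 25^4 = 15.68
        chi2, _ = chi2_yates([[20, 5], [5, 20]])
        assert chi2 == pytest.approx(15.68)

    def test_doubling_cells_increases_statistic(self):
        c1, _ = chi2_yates([[20, 5], [5, 20]])
        c2, _ = chi2_yates([[40, 10], [10, 40]])
        assert c2 > c1

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            chi2_yates([[0, 0], [5, 5]])

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 60, size=(2, 2))
            chi2, p = chi2_yates(t.tolist())
            ref_chi2, ref_p = chi2_contingency(t, correction=True)[:2]
            assert chi2 == pytest.approx(ref_chi2, rel=1e-10)
            assert p == pytest.approx(ref_p, rel=1e-10)


class TestMannWhitney:
    def test_exact_extreme_configuration(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))  # 0.1

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(4)
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(2, 8)))
            y = rng.normal(size=int(rng.integers(2, 8)))
            u, p = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_sample_type_i_error(self):
        # two n=50 samples from the same law: rejection rate at alpha=0.05
        # stays within 0.05 +/- 0.02 over 1000 replicates
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) < 0.02


def simple_calls(sample, positions):
    return pd.DataFrame(
        [{"sample": sample, "chrom": "chr1", "pos": p, "ref": "C", "alt": "T"} for p in positions]
    )


class TestPartition:
    def test_identical_sets(self):
        t = simple_calls("s1", range(5))
        out = partition_mutations(t, t.copy())
        row = out.loc[out["sample"] == "s1"].iloc[0]
        assert row["shared"] == 5 and row["tumor_only"] == 0 and row["plasma_only"] == 0

    def test_set_algebra(self):
        tumor = simple_calls("s1", [1, 2, 3])
        plasma = simple_calls("s1", [2, 3, 4])
        row = partition_mutations(tumor, plasma).iloc[0]
        assert (row["shared"], row["tumor_only"], row["plasma_only"]) == (2, 1, 1)

    def test_empty_plasma(self):
        tumor = simple_calls("s1", [1, 2])
        plasma = simple_calls("s2", [9])  # different sample; s1 has no plasma calls
        out = partition_mutations(tumor, plasma).set_index("sample")
        assert out.loc["s1", "shared"] == 0 and out.loc["s1", "tumor_only"] == 2

    def test_duplicate_key_rejected(self):
        tumor = simple_calls("s1", [1, 1])
        with pytest.raises(InputError):
            partition_mutations(tumor, simple_calls("s1", [2]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.sets(st.integers(0, 30), max_size=15),
        st.sets(st.integers(0, 30), max_size=15),
    )
    def test_conservation(self, tset, pset):
        tumor = simple_calls("s1", sorted(tset))
        plasma = simple_calls("s1", sorted(pset))
        if not len(tumor) and not len(plasma):
            return
        out = partition_mutations(
            tumor if len(tumor) else simple_calls("sX", [99]),
            plasma if len(plasma) else simple_calls("sX", [98]),
        )
        for _, row in out.iterrows():
            assert row["shared"] + row["tumor_only"] == row["tumor_total"]
            assert row["shared"] + row["plasma_only"] == row["plasma_total"]


class TestTmbConcordance:
    def test_identity_line(self):
        df = pd.DataFrame({"tumor_tmb": [1, 2, 3.0], "plasma_tmb": [1, 2, 3.0], "tf_class": "high"})
        out = tmb_concordance(df).set_index("stratum")
        assert out.loc["overall", "r"] == pytest.approx(1.0)
        assert out.loc["overall", "slope"] == pytest.approx(1.0)

    def test_closed_form_slope_two(self):
        df = pd.DataFrame({"tumor_tmb": [1, 2, 3.0], "plasma_tmb": [2, 4, 6.0], "tf_class": "high"})
        out = tmb_concordance(df).set_index("stratum")
        assert out.loc["overall", "r"] == pytest.approx(1.0)
        assert out.loc["overall", "slope"] == pytest.approx(2.0)

    def test_degenerate_variance_reported_absent(self):
        df = pd.DataFrame({"tumor_tmb": [2, 2, 2.0], "plasma_tmb": [1, 2, 3.0], "tf_class": "low"})
        out = tmb_concordance(df).set_index("stratum")
        assert np.isnan(out.loc["overall", "r"])

    def test_contingency_validation(self):
        with pytest.raises(DomainError):
            ContingencyTable2x2(0, 0, 0, 0)
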