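"""Blind-zone statistics: Wilcoxon, Bonferroni, z-tests, Wilson intervals."""

import numpy as np
import pytest
import scipy.stats as sps

from vpmkit.core import LEVELS, VertebralLevel
from vpmkit.stats import (
    DegenerateTestError,
    PairedLevelSamples,
    binomial_ci,
    bonferroni,
    effect_size_r,
    run_paired_tests,
    two_proportion_ztest,
    wilcoxon_signed_rank,
)

T7 = VertebralLevel.T7


def samples(a, b, level=T7):
    return PairedLevelSamples(level=level, a=tuple(a), b=tuple(b))


class TestWilcoxon:
    def test_exact_small_sample(self):
        """Differences (.1, -.2, .3, .4, .5): W+ = 13, W- = 2; enumerating all
        2^5 sign patterns gives one-sided 3/32, two-sided 6/32."""
        res = wilcoxon_signed_rank(
            samples((0.1, 0.0, 0.3, 0.4, 0.5), (0.0, 0.2, 0.0, 0.0, 0.0))
        )
        assert res.statistic == 13.0
        assert res.p_value == pytest.approx(6 / 32)
        assert res.method == "exact"

    def test_degenerate_all_zero(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank(samples((0.5, 0.5), (0.5, 0.5)))

    def test_antisymmetry(self, rng):
        a, b = rng.random(12), rng.random(12)
        r1 = wilcoxon_signed_rank(samples(a, b))
        r2 = wilcoxon_signed_rank(samples(b, a))
        assert r1.z_value == pytest.approx(-r2.z_value)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.effect_size_r == pytest.approx(r2.effect_size_r)

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        for _ in range(20):
            a, b = rng.random(10), rng.random(10)
            mine = wilcoxon_signed_rank(samples(a, b))
            ref = sps.wilcoxon(a - b, method="exact", alternative="two-sided")
            assert mine.p_value == pytest.approx(ref.pvalue)

    def test_approx_agrees_with_scipy(self, rng):
        a, b = rng.random(40), rng.random(40)
        mine = wilcoxon_signed_rank(samples(a, b))
        assert mine.method == "normal-approx"
        ref = sps.wilcoxon(a - b, method="approx", correction=False)
        assert mine.p_value == pytest.approx(ref.pvalue)
        assert abs(mine.z_value) == pytest.approx(abs(ref.zstatistic))

    def test_exact_handles_tied_ranks(self):
        # tied |differences| get average ranks; p stays a valid probability
        res = wilcoxon_signed_rank(
            samples((0.2, 0.2, 0.0, 0.4), (0.0, 0.0, 0.2, 0.0))
        )
        assert 0.0 < res.p_value <= 1.0
        assert res.method == "exact"

    def test_type_i_error_under_null(self, rng):
        """Empirical rejection rate at nominal 0.05 under a simulated null
        (paired samples from the same distribution) stays within 3
        Monte-Carlo standard errors of 0.05."""
        n_reps, n_pairs, alpha = 2000, 20, 0.05
        rejections = 0
        for _ in range(n_reps):
            a = rng.random(n_pairs)
            b = rng.random(n_pairs)
            res = wilcoxon_signed_rank(samples(a, b))
            rejections += res.p_value < alpha
        rate = rejections / n_reps
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rate - alpha) <= 3 * se


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,n,expected", [(0.0, 5, 0.0), (2.0, 16, 0.5), (-1.5, 9, 0.5)]
    )
    def test_values(self, z, n, expected):
        assert effect_size_r(z, n) == pytest.approx(expected)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)


class TestBonferroni:
    def test_adjustment_and_flags(self):
        ps = [0.001] + [0.01] + [1.0] + [0.5] * 14
        out = bonferroni(ps)
        assert out[0] == (pytest.approx(0.017), True)
        assert out[1] == (pytest.approx(0.17), False)
        assert out[2] == (1.0, False)

    def test_family_size_enforced(self):
        with pytest.raises(ValueError, match="17"):
            bonferroni([0.5] * 16)

    def test_monotone_flags(self, rng):
        ps = list(rng.random(17))
        flags = [sig for _, sig in bonferroni(ps)]
        lowered = [p / 10 for p in ps]
        flags2 = [sig for _, sig in bonferroni(lowered)]
        assert all(f2 >= f1 for f1, f2 in zip(flags, flags2))


class TestTwoProportion:
    def test_blind_zone_contrast(self):
        """T7 (35/48) against the pooled remaining levels (573/681)."""
        z, p = two_proportion_ztest(35, 48, 573, 681)
        assert z == pytest.approx(-2.020, abs=0.001)
        assert p == pytest.approx(0.043, abs=0.0005)

    def test_equal_proportions(self):
        z, p = two_proportion_ztest(5, 10, 50, 100)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        z, p = two_proportion_ztest(8, 10, 2, 10)
        z_oracle = (0.8 - 0.2) / np.sqrt(0.5 * 0.5 * (1 / 10 + 1 / 10))
        assert z == pytest.approx(z_oracle)
        assert z == pytest.approx(2.683, abs=0.001)
        assert p == pytest.approx(2 * sps.norm.sf(z_oracle))

    def test_antisymmetric(self):
        z1, p1 = two_proportion_ztest(35, 48, 573, 681)
        z2, p2 = two_proportion_ztest(573, 681, 35, 48)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_pool(self):
        with pytest.raises(DegenerateTestError):
            two_proportion_ztest(0, 10, 0, 10)


class TestBinomialCI:
    def test_reference_interval(self):
        low, high = binomial_ci(35, 48)
        assert low == pytest.approx(0.590, abs=0.001)
        assert high == pytest.approx(0.834, abs=0.001)

    def test_boundaries(self):
        low, high = binomial_ci(10, 10)
        assert high <= 1.0
        low, high = binomial_ci(0, 10)
        assert low >= 0.0

    def test_contains_point_estimate_and_shrinks(self):
        for k, n in [(3, 7), (35, 48), (51, 66)]:
            low, high = binomial_ci(k, n)
            assert low <= k / n <= high
        w_small = np.subtract(*binomial_ci(35, 48)[::-1])
        w_large = np.subtract(*binomial_ci(350, 480)[::-1])
        assert w_large < w_small


class TestPairedTable:
    def test_full_table_runs_and_flags(self, rng):
        import pandas as pd

        rows = []
        for lvl in LEVELS:
            for f in range(15):
                a = int(rng.random() < 0.9)
                # configuration b is strictly worse at T7
                p_b = 0.2 if lvl is T7 else 0.9
                b = int(rng.random() < p_b)
                rows.append(
                    dict(frame_id=f"f{f}", level=lvl.name, config_a=a, config_b=b)
                )
        out = run_paired_tests(pd.DataFrame(rows))
        assert len(out) == 17
        t7 = out[out.level == "T7"].iloc[0]
        assert t7.p < 0.05

    def test_missing_level_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            dict(frame_id=["f0"], level=["T1"], config_a=[1], config_b=[0])
        )
        with pytest.raises(ValueError, match="no rows"):
            run_paired_tests(df)
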