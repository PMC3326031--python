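"""Statistics layer vs independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

from snprank import (
    ContingencyTable,
    chi_square,
    crosstab,
    percent,
    spearman_rho,
    validation_concordance,
)
from snprank.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

# --- independent oracles -----------------------------------------------------


def midranks(values):
    """Midrank of each value computed by explicit comparison counting."""
    return [
        sum(1 for w in values if w < v) + (sum(1 for w in values if w == v) + 1) / 2
        for v in values
    ]


def spearman_oracle(pairs):
    """Pearson correlation applied to midranks, p via the t approximation."""
    xs = midranks([p[0] for p in pairs])
    ys = midranks([p[1] for p in pairs])
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    rho = sxy / math.sqrt(sxx * syy)
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, 2 * t_dist.sf(abs(t), df=n - 2)


def chi_square_oracle(counts):
    """Explicit observed-vs-expected loop over all cells."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - expected) ** 2 / expected
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, chi2_dist.sf(stat, df), df


class TestPercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (42, 168, 25.0),
            (126, 168, 75.0),
            (117, 168, 69.6),
            (51, 168, 30.4),
            (84, 168, 50.0),
            (12, 168, 7.1),
            (36, 168, 21.4),
            (0, 7, 0.0),
            (1, 8, 12.5),
        ],
    )
    def test_one_decimal_half_away_rounding(self, k, n, expected):
        assert percent(k, n) == expected

    def test_half_cases_round_away_from_zero(self):
        assert percent(1, 16) == 6.3  # 6.25 -> 6.3, not banker's 6.2
        assert percent(3, 16) == 18.8  # 18.75 -> 18.8

    @given(st.integers(1, 500).flatmap(lambda n: st.tuples(st.integers(0, n), st.just(n))))
    def test_complement_sums_to_about_100(self, kn):
        k, n = kn
        assert 99.9 <= percent(k, n) + percent(n - k, n) <= 100.1

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            percent(0, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(DomainError):
            percent(5, 4)


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        pairs = [(1.0, 10.0), (2.0, 20.0), (3.0, 25.0), (4.0, 40.0)]
        assert spearman_rho(pairs).statistic == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        pairs = [(1.0, 9.0), (2.0, 7.0), (3.0, 3.0), (4.0, 1.0)]
        assert spearman_rho(pairs).statistic == pytest.approx(-1.0)

    def test_tied_input_matches_midrank_oracle(self):
        pairs = [(1.0, 3.0), (2.0, 3.0), (2.0, 5.0), (3.0, 1.0), (4.0, 4.0), (5.0, 2.0)]
        result = spearman_rho(pairs)
        rho, p = spearman_oracle(pairs)
        assert result.statistic == pytest.approx(rho)
        assert result.p_value == pytest.approx(p)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_small_instances_match_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            pairs = list(zip(rng.integers(0, 4, n).astype(float),
                             rng.integers(0, 4, n).astype(float)))
            if np.ptp([p[0] for p in pairs]) == 0 or np.ptp([p[1] for p in pairs]) == 0:
                continue
            result = spearman_rho(pairs)
            rho, p = spearman_oracle(pairs)
            assert result.statistic == pytest.approx(rho, abs=1e-12)
            assert result.p_value == pytest.approx(p, abs=1e-9)

    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.integers(-50, 50)),
            min_size=4,
            max_size=12,
        ).filter(
            lambda ps: len({p[0] for p in ps}) > 1 and len({p[1] for p in ps}) > 1
        )
    )
    def test_invariant_under_monotone_transform(self, pairs):
        # strictly monotone maps that stay exact in float arithmetic
        base = spearman_rho([(float(x), float(y)) for x, y in pairs]).statistic
        transformed = [(2.0 * x + 1.0, float(y**3)) for x, y in pairs]
        assert spearman_rho(transformed).statistic == pytest.approx(base, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman_rho([(1.0, 2.0), (2.0, 1.0)])

    def test_constant_coordinate_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


class TestCrosstab:
    def test_single_pair(self):
        table = crosstab(["Benign"], ["Tolerated"])
        assert table.counts.tolist() == [[1]]
        assert table.total == 1

    def test_empty_lists_give_all_zero_table(self):
        table = crosstab([], [], row_labels=["a", "b"], col_labels=["x"])
        assert table.counts.tolist() == [[0], [0]]
        assert table.total == 0

    def test_matches_nested_count_oracle(self):
        rng = np.random.default_rng(5)
        rows = list(rng.choice(["r1", "r2", "r3"], 40))
        cols = list(rng.choice(["c1", "c2"], 40))
        table = crosstab(rows, cols, ["r1", "r2", "r3"], ["c1", "c2"])
        for i, r in enumerate(["r1", "r2", "r3"]):
            for j, c in enumerate(["c1", "c2"]):
                assert table.counts[i, j] == sum(
                    1 for a, b in zip(rows, cols) if a == r and b == c
                )
        assert table.total == 40
        assert table.row_margins.sum() == table.col_margins.sum() == 40

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            crosstab(["a"], ["x", "y"])


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 20], [5, 10]]))
        assert chi_square(table).statistic == pytest.approx(0.0)

    def test_uniform_2x2_gives_p_one(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), np.array([[10, 10], [10, 10]]))
        result = chi_square(table)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 1

    def test_2x2_matches_closed_form(self):
        a, b, c, d = 9, 6, 17, 20
        table = ContingencyTable(("s", "t"), ("v", "u"), np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi_square(table).statistic == pytest.approx(closed)

    def test_all_small_2x2_tables_match_oracle(self):
        """Exhaustive over every 2x2 table with cells in 1..4."""
        for a in range(1, 5):
            for b in range(1, 5):
                for c in range(1, 5):
                    for d in range(1, 5):
                        counts = np.array([[a, b], [c, d]])
                        result = chi_square(
                            ContingencyTable(("r0", "r1"), ("c0", "c1"), counts)
                        )
                        stat, p, df = chi_square_oracle(counts)
                        assert result.statistic == pytest.approx(stat, abs=1e-10)
                        assert result.p_value == pytest.approx(p, abs=1e-10)
                        assert result.df == df

    def test_invariant_under_row_and_column_permutation(self):
        counts = np.array([[13, 2, 16], [20, 4, 31], [32, 8, 32]])
        base = chi_square(ContingencyTable(("a", "b", "c"), ("x", "y", "z"), counts))
        permuted = chi_square(
            ContingencyTable(("b", "a", "c"), ("z", "x", "y"), counts[[1, 0, 2]][:, [2, 0, 1]])
        )
        assert permuted.statistic == pytest.approx(base.statistic)

    def test_zero_margin_instructs_collapse(self):
        table = ContingencyTable(("a", "b"), ("x", "y"), np.array([[0, 0], [5, 10]]))
        with pytest.raises(DomainError, match="collapse"):
            chi_square(table)


class TestValidationConcordance:
    @pytest.mark.parametrize(
        "predicted,validated,expected",
        [(42, 26, 61.9), (117, 79, 67.5), (5, 5, 100.0)],
    )
    def test_validated_fraction(self, predicted, validated, expected):
        assert validation_concordance(predicted, validated) == expected

    def test_zero_predicted_rejected(self):
        with pytest.raises(DomainError):
            validation_concordance(0, 0)

    def test_validated_exceeding_predicted_rejected(self):
        with pytest.raises(DomainError):
            validation_concordance(5, 6)
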