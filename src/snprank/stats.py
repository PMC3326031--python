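"""Statistical layer: rank correlation, cross-tabulation, chi-square,
percentage reporting and validated-fraction concordance.

Spearman's rho (tie-corrected, two-sided p via the t approximation) and
Pearson's chi-square (no continuity correction) are delegated to scipy;
``percent`` rounds half-away-from-zero to one decimal, which is the rounding
that reproduces published percentage tables (banker's rounding does not).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError, UndefinedCorrelationError


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value (df for chi-square)."""

    statistic: float
    p_value: float
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value {self.p_value} not in [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """Labeled contingency table with margins derived from the cells."""

    row_labels: tuple[Hashable, ...]
    col_labels: tuple[Hashable, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise DomainError("counts shape does not match labels")
        if (counts < 0).any():
            raise DomainError("contingency cells must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, margins: bool = True):
        """Render as a pandas DataFrame, optionally with Total margins."""
        import pandas as pd

        frame = pd.DataFrame(self.counts, index=list(self.row_labels),
                             columns=list(self.col_labels))
        if margins:
            frame["Total"] = self.row_margins
            total_row = list(self.col_margins) + [self.total]
            frame.loc["Total"] = total_row
        return frame


def percent(k: int, n: int) -> float:
    """100*k/n rounded half-away-from-zero to one decimal place."""
    if n == 0:
        raise DomainError("percent undefined for n = 0")
    if not 0 <= k <= n:
        raise DomainError(f"count k={k} must satisfy 0 <= k <= n={n}")
    value = Decimal(100 * k) / Decimal(n)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def spearman_rho(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Tie-corrected Spearman rank correlation on raw score pairs.

    Two-sided p-value from the t approximation. Requires n >= 3 and
    non-constant coordinates.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be a sequence of (x, y) tuples")
    if arr.shape[0] < 3:
        raise InsufficientDataError(
            f"Spearman correlation needs n >= 3, got n = {arr.shape[0]}"
        )
    if not np.isfinite(arr).all():
        raise DomainError("pairs must be finite; missing values are not allowed")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            "correlation undefined: one coordinate is constant"
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(min(max(p, 0.0), 1.0)))


def crosstab(
    calls_a: Sequence[Hashable],
    calls_b: Sequence[Hashable],
    row_labels: Sequence[Hashable] | None = None,
    col_labels: Sequence[Hashable] | None = None,
) -> ContingencyTable:
    """Cross-tabulate paired category calls (rows = calls_a, cols = calls_b).

    Label order defaults to first-appearance order, so passing enum-ordered
    label lists reproduces a fixed table layout.
    """
    if len(calls_a) != len(calls_b):
        raise DomainError(
            f"paired call lists differ in length: {len(calls_a)} vs {len(calls_b)}"
        )

    def _labels(observed, given):
        if given is not None:
            labels = list(given)
            extra = [v for v in dict.fromkeys(observed) if v not in labels]
            if extra:
                raise DomainError(f"calls outside the given labels: {extra!r}")
            return labels
        return list(dict.fromkeys(observed))

    rows = _labels(calls_a, row_labels)
    cols = _labels(calls_b, col_labels)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    r_index = {lab: i for i, lab in enumerate(rows)}
    c_index = {lab: j for j, lab in enumerate(cols)}
    for a, b in zip(calls_a, calls_b):
        counts[r_index[a], c_index[b]] += 1
    return ContingencyTable(tuple(rows), tuple(cols), counts)


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise DomainError(
            "chi-square undefined with a zero margin; collapse the empty "
            "row(s)/column(s) first"
        )
    res = sps.chi2_contingency(table.counts, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, 0.0), 1.0)),
        df=int(res.dof),
    )


def validation_concordance(predicted_deleterious: int, validated_among_them: int) -> float:
    """Percent of predicted-deleterious variants with experimental support."""
    if predicted_deleterious == 0:
        raise DomainError("no predicted-deleterious variants: concordance undefined")
    if validated_among_them > predicted_deleterious:
        raise DomainError(
            f"validated count {validated_among_them} exceeds predicted "
            f"count {predicted_deleterious}"
        )
    return percent(validated_among_them, predicted_deleterious)
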