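"""Exact and rank-based statistics for small clinical samples.

The centrepiece is the Freeman–Halton test: the generalisation of Fisher's
exact test to r x c contingency tables. Under the null hypothesis of no
association, conditional on both sets of margins, the probability of a table
follows the multivariate hypergeometric law

    P(T) = (prod_i R_i!) (prod_j C_j!) / (N! prod_ij n_ij!)

and the two-sided p-value is the total probability of every margin-consistent
table that is no more probable than the observed one. The test is the tool of
choice for feature-by-category tables whose expected counts are too small for
a chi-square approximation — exactly the situation in a ~40-lesion dermoscopy
cohort split over six histological subtypes or three size classes.

Full enumeration is exact but its cost grows quickly with the margins, so a
margin-conditional Monte Carlo estimator is provided as the documented
fallback for large tables.

Pearson and Spearman correlations are computed from first principles; their
two-sided p-values use the t transform ``r * sqrt((n-2)/(1-r^2))`` against
Student's t with n-2 degrees of freedom (for Spearman this is the usual
large-sample approximation, applied at every n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import rankdata
from scipy.stats import t as _student_t

__all__ = [
    "ContingencyTable",
    "ExactTestResult",
    "CorrelationResult",
    "EnumerationCapError",
    "table_probability",
    "enumerate_tables",
    "fh_exact_test",
    "fh_monte_carlo",
    "pearson",
    "spearman",
    "mean_sd",
]

#: Relative tolerance when deciding whether an enumerated table is "no more
#: probable" than the observed one; exact equality of floating-point
#: log-probabilities is unreliable.
TIE_RTOL = 1e-12

#: Default ceiling on the number of tables full enumeration may visit.
DEFAULT_ENUMERATION_CAP = 5_000_000


class EnumerationCapError(RuntimeError):
    """Raised when full enumeration would visit too many tables.

    Use :func:`fh_monte_carlo` instead for such tables.
    """


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of nonnegative integer counts with derived margins."""

    counts: tuple[tuple[int, ...], ...]
    row_margins: tuple[int, ...] = field(init=False)
    col_margins: tuple[int, ...] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("counts must be a non-empty 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            arr = arr.astype(int)
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        total = int(arr.sum())
        if total == 0:
            raise ValueError("table total must be positive")
        object.__setattr__(self, "counts", tuple(tuple(int(x) for x in row) for row in arr))
        object.__setattr__(self, "row_margins", tuple(int(x) for x in arr.sum(axis=1)))
        object.__setattr__(self, "col_margins", tuple(int(x) for x in arr.sum(axis=0)))
        object.__setattr__(self, "total", total)

    @classmethod
    def from_counts(cls, counts: Sequence[Sequence[int]]) -> "ContingencyTable":
        return cls(tuple(tuple(int(x) for x in row) for row in counts))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_margins), len(self.col_margins))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: Literal["enumeration", "monte_carlo"]
    observed_prob: float
    tables_enumerated: int | None = None
    n_samples: int | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation estimate with its two-sided p-value.

    ``estimate`` and ``p_value`` are ``None`` when the correlation is
    undefined: fewer than three pairs, or zero variance in either variable.
    """

    estimate: float | None
    p_value: float | None
    n: int
    method: Literal["pearson", "spearman"]

    @property
    def defined(self) -> bool:
        return self.estimate is not None


def _log_factorials(n: int) -> np.ndarray:
    return gammaln(np.arange(n + 1) + 1.0)


def _log_table_probability(
    cells: Sequence[int],
    row_margins: Sequence[int],
    col_margins: Sequence[int],
    lf: np.ndarray,
) -> float:
    total = sum(row_margins)
    num = sum(lf[m] for m in row_margins) + sum(lf[m] for m in col_margins)
    den = lf[total] + sum(lf[c] for c in cells)
    return float(num - den)


def table_probability(table: ContingencyTable) -> float:
    """Multivariate hypergeometric probability of a table given its margins."""
    lf = _log_factorials(table.total)
    cells = [c for row in table.counts for c in row]
    return math.exp(_log_table_probability(cells, table.row_margins, table.col_margins, lf))


def enumerate_tables(
    row_margins: Sequence[int],
    col_margins: Sequence[int],
    cap: int | None = DEFAULT_ENUMERATION_CAP,
) -> Iterator[tuple[int, ...]]:
    """Yield every nonnegative integer table with the given margins.

    Tables are produced row by row as flat tuples (row-major). Each partial
    row is pruned against the remaining column capacity, so only feasible
    prefixes are extended. Raises :class:`EnumerationCapError` if more than
    ``cap`` tables would be produced.
    """
    row_margins = [int(m) for m in row_margins]
    col_margins = [int(m) for m in col_margins]
    if sum(row_margins) != sum(col_margins):
        raise ValueError("row and column margins must have equal totals")
    r, c = len(row_margins), len(col_margins)
    count = 0

    def rows(i: int, remaining_cols: tuple[int, ...], prefix: tuple[int, ...]):
        nonlocal count
        if i == r - 1:
            # last row forced by the remaining column margins
            if sum(remaining_cols) == row_margins[i]:
                count += 1
                if cap is not None and count > cap:
                    raise EnumerationCapError(
                        f"more than {cap} tables share these margins; "
                        "use fh_monte_carlo for an estimated p-value"
                    )
                yield prefix + remaining_cols
            return
        yield from _fill_row(i, 0, row_margins[i], remaining_cols, prefix, rows)

    def _fill_row(i, j, rem, remaining_cols, prefix, rows):
        if j == c - 1:
            if rem <= remaining_cols[j]:
                new_cols = tuple(
                    rc - v for rc, v in zip(remaining_cols, prefix[i * c : i * c + j] + (rem,))
                )
                yield from rows(i + 1, new_cols, prefix + (rem,))
            return
        # feasibility: the rest of this row must fit in the remaining columns
        tail_capacity = sum(remaining_cols[j + 1 :])
        lo = max(0, rem - tail_capacity)
        hi = min(rem, remaining_cols[j])
        for v in range(lo, hi + 1):
            yield from _fill_row(i, j + 1, rem - v, remaining_cols, prefix + (v,), rows)

    yield from rows(0, tuple(col_margins), ())


def fh_exact_test(
    table: ContingencyTable,
    cap: int | None = DEFAULT_ENUMERATION_CAP,
) -> ExactTestResult:
    """Freeman–Halton exact test by full enumeration.

    The two-sided p-value is the total null probability of every table with
    the observed margins whose probability does not exceed the observed
    table's (up to a relative tie tolerance of ``TIE_RTOL``). For 2x2 tables
    this reduces to the usual two-sided Fisher exact test.
    """
    lf = _log_factorials(table.total)
    rm, cm = table.row_margins, table.col_margins
    obs_cells = [c for row in table.counts for c in row]
    log_obs = _log_table_probability(obs_cells, rm, cm, lf)
    threshold = log_obs + math.log1p(TIE_RTOL)

    p = 0.0
    n_tables = 0
    for cells in enumerate_tables(rm, cm, cap=cap):
        n_tables += 1
        lp = _log_table_probability(cells, rm, cm, lf)
        if lp <= threshold:
            p += math.exp(lp)
    return ExactTestResult(
        p_value=min(p, 1.0),
        method="enumeration",
        observed_prob=math.exp(log_obs),
        tables_enumerated=n_tables,
    )


def fh_monte_carlo(
    table: ContingencyTable,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> ExactTestResult:
    """Monte Carlo Freeman–Halton test by margin-conditional resampling.

    Tables are drawn exactly from the multivariate hypergeometric null by
    randomly permuting column labels against fixed row labels (a permutation
    of the underlying N units), which conditions on both margins. The
    estimate uses the add-one rule p̂ = (1 + #{P(T*) <= P(obs)}) / (1 + B),
    which is never zero and is a valid p-value.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r, c = table.shape
    rm = np.asarray(table.row_margins)
    cm = np.asarray(table.col_margins)
    n = table.total
    lf = _log_factorials(n)
    log_obs = _log_table_probability(
        [x for row in table.counts for x in row], table.row_margins, table.col_margins, lf
    )
    threshold = log_obs + math.log1p(TIE_RTOL)

    row_labels = np.repeat(np.arange(r), rm)
    col_labels = np.repeat(np.arange(c), cm)
    const = float(lf[rm].sum() + lf[cm].sum() - lf[n])

    hits = 0
    chunk = max(1, min(n_samples, 20_000))
    done = 0
    while done < n_samples:
        b = min(chunk, n_samples - done)
        keys = rng.random((b, n))
        order = np.argsort(keys, axis=1, kind="stable")
        permuted = col_labels[order]
        flat = row_labels[None, :] * c + permuted
        offsets = np.arange(b)[:, None] * (r * c)
        counts = np.bincount((flat + offsets).ravel(), minlength=b * r * c).reshape(b, r * c)
        logp = const - lf[counts].sum(axis=1)
        hits += int((logp <= threshold).sum())
        done += b

    return ExactTestResult(
        p_value=(1 + hits) / (1 + n_samples),
        method="monte_carlo",
        observed_prob=math.exp(log_obs),
        n_samples=n_samples,
    )


def _corr_undefined(n: int, method: Literal["pearson", "spearman"]) -> CorrelationResult:
    return CorrelationResult(estimate=None, p_value=None, n=n, method=method)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        return _corr_undefined(n, "pearson")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        return _corr_undefined(n, "pearson")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _student_t.sf(abs(tstat), n - 2))
    return CorrelationResult(estimate=r, p_value=p, n=n, method="pearson")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation: Pearson on mid-ranks (ties get average rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    res = pearson(rankdata(x), rankdata(y))
    return CorrelationResult(estimate=res.estimate, p_value=res.p_value, n=res.n, method="spearman")


def mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    The SD is ``None`` for a single observation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_sd requires at least one value")
    mean = float(v.mean())
    if v.size == 1:
        return mean, None
    return mean, float(v.std(ddof=1))
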