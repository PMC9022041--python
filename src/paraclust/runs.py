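"""Parametric multi-category runs test with a bootstrap null.

The classical Wald-Wolfowitz runs test asks whether a two-category data
string is randomly ordered by counting maximal blocks ("runs") of identical
categories. Here the string is built from the selected sites of two
paralogs laid out along their pairwise alignment: each selected column is
labelled ``A_ONLY``, ``B_ONLY`` or ``BOTH`` (selected in both paralogs),
and the null distribution of the run count is obtained by simulation
rather than from the classical normal approximation, which does not extend
to three categories.

Under the null, each of the L alignment columns is independently selected
in paralog A with probability p_a and in paralog B with probability p_b,
where p_a and p_b are the observed marginal selection proportions (a
shared column counts towards both). Columns selected in neither paralog
are dropped, the remaining columns form a category string, and its runs
are counted. The one-sided p-value is the fraction of simulated strings
with run count less than or equal to the observed count: few, long runs
mean clustering.

A second variant drops the ``BOTH`` columns entirely (from both the
observed string and each simulated string), leaving a two-category string.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .io_mapping import SiteSet

__all__ = [
    "Category",
    "CategoryString",
    "RunsNull",
    "RunsTestResult",
    "build_category_string",
    "count_runs",
    "simulate_null",
    "empirical_p_value",
    "runs_test",
]

DEFAULT_N_REPS = 1000  # simulated data strings per test


class Category(str, Enum):
    A_ONLY = "A"
    B_ONLY = "B"
    BOTH = "AB"


@dataclass(frozen=True)
class CategoryString:
    """Ordered selection categories over the selected alignment columns."""

    categories: tuple[Category, ...]
    source_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.source_columns):
            raise ValueError("categories and source_columns length mismatch")
        if any(b <= a for a, b in zip(self.source_columns, self.source_columns[1:])):
            raise ValueError("source_columns must be strictly ascending")

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class RunsNull:
    """Bootstrap null distribution of the run count."""

    length: int
    p_a: float
    p_b: float
    n_reps: int
    seed: int | None
    run_counts: np.ndarray
    exclude_both: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_a <= 1.0 and 0.0 <= self.p_b <= 1.0):
            raise ValueError("selection proportions must lie in [0, 1]")
        if len(self.run_counts) != self.n_reps:
            raise ValueError("run_counts length != n_reps")

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "exclude_both": self.exclude_both,
            "mean_runs": float(np.mean(self.run_counts)),
        }


@dataclass(frozen=True)
class RunsTestResult:
    observed_runs: int
    p_value: float
    variant: str  # "three_category" | "two_category"
    null: RunsNull

    def to_dict(self) -> dict:
        return {
            "observed_runs": self.observed_runs,
            "p_value": self.p_value,
            "variant": self.variant,
            "null": self.null.to_dict(),
        }


def build_category_string(
    sites_a: SiteSet,
    sites_b: SiteSet,
    aln_length: int,
    exclude_both: bool = False,
) -> CategoryString:
    """Order the selected columns of both paralogs into a category string.

    Columns selected in both paralogs become ``BOTH``, or are dropped when
    ``exclude_both`` is set (the shared-sites-excluded test variant).

    Raises
    ------
    ValueError
        If any column exceeds ``aln_length`` or the resulting string is
        empty.
    """
    cols_a, cols_b = set(sites_a.columns), set(sites_b.columns)
    over = [c for c in cols_a | cols_b if c > aln_length or c < 1]
    if over:
        raise ValueError(
            f"columns {sorted(over)} outside alignment of length {aln_length}"
        )
    cats: list[Category] = []
    cols: list[int] = []
    for c in sorted(cols_a | cols_b):
        if c in cols_a and c in cols_b:
            if exclude_both:
                continue
            cats.append(Category.BOTH)
        elif c in cols_a:
            cats.append(Category.A_ONLY)
        else:
            cats.append(Category.B_ONLY)
        cols.append(c)
    if not cats:
        raise ValueError("no selected sites: category string is empty")
    return CategoryString(categories=tuple(cats), source_columns=tuple(cols))


def count_runs(s: CategoryString | Sequence) -> int:
    """Number of runs: adjacent category changes plus one.

    Accepts a :class:`CategoryString` or any sequence of hashable labels.
    """
    cats = s.categories if isinstance(s, CategoryString) else tuple(s)
    if not cats:
        raise ValueError("cannot count runs of an empty string")
    return 1 + sum(a != b for a, b in zip(cats, cats[1:]))


def _runs_from_codes(codes: np.ndarray) -> np.ndarray:
    """Run counts per replicate from an (n_reps, length) code matrix.

    Code 0 means "selected in neither paralog" and is dropped before
    counting; an all-zero replicate scores 0 runs (below any attainable
    observed count, hence conservative).
    """
    out = np.zeros(codes.shape[0], dtype=np.int64)
    for i, row in enumerate(codes):
        s = row[row != 0]
        if s.size:
            out[i] = 1 + int(np.count_nonzero(s[1:] != s[:-1]))
    return out


def simulate_null(
    p_a: float,
    p_b: float,
    length: int,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    exclude_both: bool = False,
) -> RunsNull:
    """Simulate the bootstrap null distribution of the run count.

    Per replicate, each of ``length`` positions draws selection
    independently for paralog A (probability ``p_a``) and paralog B
    (``p_b``); a position selected in both is a ``BOTH`` column (dropped
    when ``exclude_both``), and positions selected in neither are dropped.
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("selection proportions must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    sel_a = rng.random((n_reps, length)) < p_a
    sel_b = rng.random((n_reps, length)) < p_b
    codes = sel_a.astype(np.int8) + 2 * sel_b.astype(np.int8)  # 0,1=A,2=B,3=BOTH
    if exclude_both:
        codes[codes == 3] = 0
    return RunsNull(
        length=length, p_a=p_a, p_b=p_b, n_reps=n_reps, seed=seed,
        run_counts=_runs_from_codes(codes), exclude_both=exclude_both,
    )


def empirical_p_value(null_run_counts: np.ndarray, observed_runs: int) -> float:
    """Fraction of simulated strings with runs <= observed.

    No pseudo-count is added ("divided by the total number of simulated
    data strings" taken literally), so the minimum attainable p-value is 0;
    the replicate count is always reported alongside.
    """
    counts = np.asarray(null_run_counts)
    if counts.size == 0:
        raise ValueError("empty null distribution")
    return float(np.count_nonzero(counts <= observed_runs) / counts.size)


def runs_test(
    sites_a: SiteSet,
    sites_b: SiteSet,
    aln_length: int,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    exclude_both: bool = False,
) -> RunsTestResult:
    """Run the full bootstrap runs test.

    The null proportions are the observed marginal selection proportions
    |A|/L and |B|/L, where a column selected in both paralogs counts in
    each paralog's proportion (the null marks a position BOTH when both
    Bernoulli draws succeed, so the marginals must match).

    Small p-values indicate fewer, longer runs — i.e. selected sites of the
    two paralogs clustering in distinct alignment regions — than expected
    under independent placement.
    """
    observed = count_runs(
        build_category_string(sites_a, sites_b, aln_length, exclude_both)
    )
    p_a = len(sites_a.columns) / aln_length
    p_b = len(sites_b.columns) / aln_length
    null = simulate_null(p_a, p_b, aln_length, n_reps, seed, exclude_both)
    return RunsTestResult(
        observed_runs=observed,
        p_value=empirical_p_value(null.run_counts, observed),
        variant="two_category" if exclude_both else "three_category",
        null=null,
    )
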