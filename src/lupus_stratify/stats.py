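"""Exact and asymptotic statistical primitives shared by every pipeline stage.

Conventions follow clinical-table practice for 2x2 comparisons:

* Fisher's exact test is two-sided by the probability-mass rule: the p-value
  sums hypergeometric probabilities of all tables with the observed margins
  whose probability does not exceed that of the observed table (with a small
  relative tolerance so ties of equal mass are included).
* The chi-squared test applies the Yates continuity correction, with the
  correction term floored at zero so equal-proportion tables give chi2 = 0.
* Reported p-values are conventionally rounded to three decimals in tables;
  raw values are always kept on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_two_sided",
    "yates_chi2",
    "select_categorical_test",
    "mann_whitney",
    "spearman",
    "bh_fdr",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts ``[[a, b], [c, d]]``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name!r} must be a non-negative integer, got {v!r}")

    @classmethod
    def from_rows(cls, rows) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(int(a), int(b), int(c), int(d))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def min_expected(self) -> float:
        """Smallest expected cell count r_i * c_j / N."""
        if self.n == 0:
            raise ValueError("empty table has no expected counts")
        r = self.row_margins
        c = self.col_margins
        return min(ri * cj for ri in r for cj in c) / self.n

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the chi2, U, rho or exact-tail mass depending on
    ``method``; ``p_value`` is the raw two-sided p; ``p_round`` gives the
    3-decimal table convention.
    """

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n: int | None = None
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        self.p_value = min(float(self.p_value), 1.0)

    @property
    def p_round(self) -> float:
        return round(self.p_value, 3)


def fisher_two_sided(t: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (probability-mass rule)."""
    if t.n == 0:
        raise ValueError("degenerate table: all cells are zero")
    res = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return TestResult(statistic=float(res.statistic) if math.isfinite(res.statistic) else float("inf"),
                      p_value=float(res.pvalue), method="fisher", n=t.n)


def yates_chi2(t: ContingencyTable2x2) -> TestResult:
    """Continuity-corrected chi-squared test, 1 df.

    chi2 = N * (max(0, |ad - bc| - N/2))^2 / (r1 r2 c1 c2); a zero margin
    yields chi2 = 0 and p = 1 (no contrast to test).
    """
    r1, r2 = t.row_margins
    c1, c2 = t.col_margins
    if min(r1, r2, c1, c2) == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="yates_chi2", df=1, n=t.n,
                          note="zero margin")
    num = max(0.0, abs(t.a * t.d - t.b * t.c) - t.n / 2.0)
    chi2 = t.n * num * num / (r1 * r2 * c1 * c2)
    return TestResult(statistic=chi2, p_value=float(sps.chi2.sf(chi2, 1)),
                      method="yates_chi2", df=1, n=t.n)


def select_categorical_test(
    t: ContingencyTable2x2, policy: str = "expected_lt5_fisher"
) -> TestResult:
    """Dispatch a 2x2 table to Fisher or Yates chi2 under a named policy.

    ``expected_lt5_fisher``: Fisher when any expected cell count < 5, Yates
    otherwise (the druggability-comparison convention); ``always_yates`` is
    the clinical-characteristics-table convention.
    """
    if policy == "always_fisher":
        return fisher_two_sided(t)
    if policy == "always_yates":
        return yates_chi2(t)
    if policy == "expected_lt5_fisher":
        if t.min_expected() < 5:
            res = fisher_two_sided(t)
        else:
            res = yates_chi2(t)
        res.extra["policy"] = policy
        return res
    raise ValueError(f"unknown policy {policy!r}")


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact enumeration when min(nx, ny) <= 8 and there are no ties; otherwise
    the normal approximation with tie correction and continuity correction.
    Identical pooled values give p = 1 (no evidence either way).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0,
                          method="mann_whitney", n=pooled.size, note="all values identical")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mann_whitney", n=pooled.size,
                      extra={"branch": method})


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with a t-distribution p-value (n-2 df).

    Perfect monotone inputs (|rho| = 1) are flagged ``exact-monotone`` and
    reported with p below the machine floor (0.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, _ = sps.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if abs(rho) >= 1.0 - 1e-12:
        return TestResult(statistic=rho, p_value=0.0, method="spearman", n=n,
                          note="exact-monotone")
    tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(sps.t.sf(abs(tstat), n - 2))
    return TestResult(statistic=rho, p_value=min(p, 1.0), method="spearman",
                      df=n - 2, n=n)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
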