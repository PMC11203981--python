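"""Method-comparison statistics: Shapiro-Wilk normality screening and paired
t-tests over stressed body parts.

For every worker, zone and method pair, the paired observation unit is the
stressed body part: the two samples are the part-wise time-in-zone
percentages of the two methods.  The protocol tests the null hypothesis of
equal means with a two-sided paired t-test at significance level alpha
(default 0.05), after screening each sample for normality with the
Shapiro-Wilk test.  With 5 workers, 3 zones and 3 method pairs this yields
exactly 45 tests.  No multiple-testing correction is applied by default; a
Bonferroni or Benjamini-Hochberg adjustment can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assessment import METHOD_PAIRS, ZONES, ExposureSummary

__all__ = [
    "NormalityResult",
    "PairedTestResult",
    "SignificanceTable",
    "DegenerateSampleError",
    "shapiro_wilk_test",
    "paired_t_test",
    "compare_methods",
]

DEFAULT_ALPHA = 0.05


class DegenerateSampleError(ValueError):
    """Raised when a sample has no variance and the statistic is undefined."""


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk test outcome; null = the sample is normally distributed."""

    statistic: float
    p_value: float
    alpha: float = DEFAULT_ALPHA

    @property
    def normal(self) -> bool:
        """True when normality is not rejected at alpha."""
        return self.p_value >= self.alpha


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test outcome.

    ``conclusion`` is ``"SD"`` (significant difference, null of equal means
    rejected) iff ``p_value < alpha``, else ``"N"``.
    """

    statistic: float
    df: int
    p_value: float
    n: int
    alpha: float = DEFAULT_ALPHA

    @property
    def conclusion(self) -> str:
        return "SD" if self.p_value < self.alpha else "N"


def shapiro_wilk_test(sample, alpha: float = DEFAULT_ALPHA) -> NormalityResult:
    """Shapiro-Wilk W and p for a small-to-medium sample (3 <= n <= 2000)."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample must be one-dimensional")
    if not 3 <= x.size <= 2000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 2000, got n={x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("constant sample: W is undefined")
    res = sps.shapiro(x)
    return NormalityResult(float(res.statistic), float(res.pvalue), alpha)


def paired_t_test(x, y, alpha: float = DEFAULT_ALPHA) -> PairedTestResult:
    """Two-sided paired t-test: one-sample t on the differences d = x - y,
    t = mean(d) / (sd(d)/sqrt(n)) with n - 1 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d samples")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateSampleError("zero-variance differences: t is undefined")
    res = sps.ttest_rel(x, y)
    return PairedTestResult(
        statistic=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
        n=n,
        alpha=alpha,
    )


@dataclass
class SignificanceTable:
    """All paired-test verdicts of a method comparison.

    ``table`` has one row per (worker, zone, pair) with the t statistic,
    degrees of freedom, p-value, sample size, normality flags and the SD/N
    verdict.  Rows whose difference vector is constant are reported as
    degenerate with verdict N.
    """

    table: pd.DataFrame
    alpha: float = DEFAULT_ALPHA
    correction: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.table)


def _normality_flag(sample: np.ndarray, alpha: float):
    try:
        return bool(shapiro_wilk_test(sample, alpha).normal)
    except (DegenerateSampleError, ValueError):
        return None


def compare_methods(
    summaries_by_worker: dict[str, dict[str, ExposureSummary]],
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> SignificanceTable:
    """Run the full comparison protocol over a cohort.

    *summaries_by_worker* maps worker id -> {method id -> ExposureSummary}
    with methods L, S and C.  For each worker, zone and method pair the
    paired t-test is run across the stressed parts assessed by both methods.
    ``correction`` in {None, "bonferroni", "bh"} adjusts the p-values across
    all rows before verdicts are taken.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in (None, "bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    rows = []
    warnings: list[str] = []
    for worker, methods in summaries_by_worker.items():
        if len(methods) < 2:
            raise ValueError(f"worker {worker}: need at least 2 methods")
        for zone in ZONES:
            for pair_name, m_a, m_b in METHOD_PAIRS:
                if m_a not in methods or m_b not in methods:
                    continue
                a, b = methods[m_a], methods[m_b]
                labels = a.table.index.intersection(b.table.index)
                x = a.table.loc[labels, zone].to_numpy()
                y = b.table.loc[labels, zone].to_numpy()
                row = {
                    "worker": worker,
                    "zone": zone,
                    "pair": pair_name,
                    "n": len(labels),
                    "normal_a": _normality_flag(x, alpha),
                    "normal_b": _normality_flag(y, alpha),
                }
                for key in ("normal_a", "normal_b"):
                    if row[key] is False:
                        warnings.append(
                            f"{worker}/{zone}/{pair_name}: normality rejected for "
                            "one sample; t-test reported anyway"
                        )
                try:
                    res = paired_t_test(x, y, alpha)
                    row.update(
                        t=res.statistic, df=res.df, p_value=res.p_value, degenerate=False
                    )
                except DegenerateSampleError:
                    row.update(t=np.nan, df=len(labels) - 1, p_value=np.nan, degenerate=True)
                rows.append(row)
    table = pd.DataFrame(rows)
    if correction and not table.empty:
        p = table["p_value"].to_numpy()
        ok = np.isfinite(p)
        adj = p.copy()
        if correction == "bonferroni":
            adj[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
        else:
            adj[ok] = sps.false_discovery_control(p[ok])
        table["p_value"] = adj
    if not table.empty:
        table["conclusion"] = np.where(table["p_value"] < alpha, "SD", "N")
    return SignificanceTable(
        table=table, alpha=alpha, correction=correction, warnings=warnings
    )
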