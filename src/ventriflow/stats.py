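"""Paired rest-vs-stress comparisons with normality-gated test selection.

For each derived quantity the rest and stress values form a paired sample.
Normality of the paired differences is assessed with the Shapiro-Wilk test;
if they pass (p >= alpha) a paired t-test is used, otherwise the Wilcoxon
signed-rank test (exact null distribution for n <= 25, normal approximation
with continuity correction above; zero differences dropped, ties mid-ranked).
Two-sided p-values throughout; no multiple-testing correction. Summaries are
"mean +/- SD" for normal samples and "median [Q1; Q3]" otherwise, with
quartiles linearly interpolated between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateInputError, SizeError


@dataclass(frozen=True)
class PairedSample:
    subjects: tuple
    rest: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        rest = np.asarray(self.rest, float)
        stress = np.asarray(self.stress, float)
        object.__setattr__(self, "rest", rest)
        object.__setattr__(self, "stress", stress)
        if rest.shape != stress.shape or rest.ndim != 1:
            raise DataError("rest and stress must be 1D arrays of equal length")
        if len(self.subjects) != rest.size:
            raise DataError("subject ids must match the number of pairs")
        if not (np.isfinite(rest).all() and np.isfinite(stress).all()):
            raise DataError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return self.rest.size


@dataclass(frozen=True)
class TestResult:
    test_name: str       # "paired-t" | "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    n: int
    rest_summary: str
    stress_summary: str


def check_normality(values, alpha: float = 0.05) -> tuple[float, float]:
    """Shapiro-Wilk (W, p); a sample is treated as normal when p >= alpha."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise SizeError(f"Shapiro-Wilk needs n >= 3, got {values.size}")
    if values.size > 50:
        raise SizeError("Shapiro-Wilk restricted to n <= 50 here")
    if np.ptp(values) == 0:
        raise DegenerateInputError("constant sample: normality undefined")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def _wilcoxon(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs[diffs != 0].size
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(
        diffs, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def paired_compare(
    sample: PairedSample,
    alpha: float = 0.05,
    normality_gate: str = "differences",
) -> TestResult:
    """Paired t or Wilcoxon signed-rank on a rest/stress sample.

    ``normality_gate`` selects what the Shapiro-Wilk gate is applied to:
    ``"differences"`` (default; the quantity the t-test assumes normal) or
    ``"conditions"`` (both rest and stress must pass).
    """
    if sample.n < 3:
        raise SizeError(f"need >= 3 pairs, got {sample.n}")
    diffs = sample.stress - sample.rest
    if np.ptp(diffs) == 0:
        if np.all(diffs == 0):
            raise DataError("all differences are zero: no effect to test")
        raise DataError("differences have zero variance: t statistic undefined")
    if normality_gate == "differences":
        normal = check_normality(diffs, alpha)[1] >= alpha
    elif normality_gate == "conditions":
        try:
            normal = (
                check_normality(sample.rest, alpha)[1] >= alpha
                and check_normality(sample.stress, alpha)[1] >= alpha
            )
        except DegenerateInputError:
            normal = False
    else:
        raise DataError(f"unknown normality_gate {normality_gate!r}")
    if normal:
        res = sps.ttest_rel(sample.stress, sample.rest)
        name, stat, p = "paired-t", float(res.statistic), float(res.pvalue)
    else:
        stat, p = _wilcoxon(diffs)
        name = "wilcoxon"
    return TestResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        n=sample.n,
        rest_summary=summarize(sample.rest, normal),
        stress_summary=summarize(sample.stress, normal),
    )


def _fmt_center(x: float) -> str:
    return f"{x:g}"


def summarize(values, normal: bool) -> str:
    """"mean +/- SD" (one decimal) if normal, else "median [Q1; Q3]".

    The median is printed in general format, the quartiles with one decimal;
    quartiles interpolate linearly between order statistics. SD uses the n-1
    (sample) denominator.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise SizeError("empty sample")
    if normal:
        mean = values.mean()
        sd = values.std(ddof=1) if values.size > 1 else 0.0
        return f"{mean:.1f} ± {sd:.1f}"
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    return f"{_fmt_center(med)} [{q1:.1f}; {q3:.1f}]"


def compare_cohort(df: pd.DataFrame, alpha: float = 0.05,
                   normality_gate: str = "differences") -> pd.DataFrame:
    """Run paired comparisons for every variable in a long-format table.

    Input columns: ``subject``, ``condition`` ("rest"/"stress"),
    ``variable``, ``value``. Returns one row per variable with the selected
    test, statistic, p, significance flag and per-condition summaries.
    """
    required = {"subject", "condition", "variable", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"cohort table must have columns {sorted(required)}")
    rows = []
    for var, g in df.groupby("variable", sort=True):
        wide = g.pivot_table(index="subject", columns="condition", values="value")
        if not {"rest", "stress"}.issubset(wide.columns):
            raise DataError(f"variable {var!r} lacks rest/stress pairs")
        wide = wide.dropna(subset=["rest", "stress"])
        sample = PairedSample(
            subjects=tuple(wide.index),
            rest=wide["rest"].to_numpy(),
            stress=wide["stress"].to_numpy(),
        )
        res = paired_compare(sample, alpha=alpha, normality_gate=normality_gate)
        rows.append(
            {
                "variable": var,
                "n": res.n,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p_value,
                "significant": res.significant,
                "rest_summary": res.rest_summary,
                "stress_summary": res.stress_summary,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
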