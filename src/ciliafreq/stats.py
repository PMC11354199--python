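"""Cohort-comparison statistics for CBF studies.

Implements the normality-routed workflow typical of two-cohort CBF
comparisons: per-group Kolmogorov-Smirnov normality assessment; Welch's
t test when both groups look normal, otherwise a one-sample Wilcoxon
signed-rank test of the patient group's values against the control group's
median; Pearson correlation of each software method against the manual count
for parametric data, Spearman otherwise; and descriptive summaries (median,
IQR, actual median difference) laid out per method and group.

The one-sample Wilcoxon p-value is exact by enumeration (dynamic
programming over the signed mid-ranks) up to n = 25 and uses the normal
approximation with continuity correction and tie correction above that.
Zero differences are dropped; tied magnitudes receive mid-ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "MethodSummary",
    "ComparisonReport",
    "ks_normality",
    "welch_t",
    "wilcoxon_one_sample",
    "correlate",
    "build_report",
    "ALPHA",
]

#: Two-tailed significance level used for normality routing.
ALPHA = 0.05

#: Quartile rule used for all IQRs (stated in output metadata because
#: different conventions shift quartiles on small samples).
QUARTILE_RULE = "inclusive linear interpolation (numpy percentile, method='linear')"


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    test: str  # welch_t | wilcoxon_one_sample | ks_normality
    statistic: float
    p_value: float
    n: tuple[int, ...]
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def normal(self) -> bool:
        """For a normality test: does the sample look normal at alpha?"""
        return self.p_value > ALPHA


def ks_normality(values: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample SD).

    Parameters are estimated from the sample (no Lilliefors correction); the
    sample "passes" normality when the two-tailed p exceeds 0.05.  Requires
    n >= 5 and nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError(f"need at least 5 values for a normality assessment, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: normality is undefined for a constant sample")
    res = sps.kstest(v, "norm", args=(v.mean(), sd))
    return TestResult("ks_normality", float(res.statistic), float(res.pvalue), (v.size,))


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test, two-tailed.

    t = (mean a - mean b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(
        "welch_t", float(res.statistic), float(res.pvalue), (a.size, b.size),
        df=float(res.df),
    )


def _signed_rank_exact_p(ranks2: np.ndarray, signs: np.ndarray) -> float:
    """Exact two-tailed p over all sign assignments, via DP on doubled ranks.

    ``ranks2`` are mid-ranks times two (integers even with ties).  The null
    distribution of W+ (sum of positively-signed ranks) is enumerated by
    dynamic programming; two-tailed p doubles the smaller tail and caps at 1.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(ranks2[signs > 0].sum())
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_one_sample(
    values: Sequence[float], hypothesized_median: float, *, exact_max_n: int = 25
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a hypothesized median.

    Differences equal to the hypothesized median are dropped; tied magnitudes
    get mid-ranks.  The two-tailed p-value is exact by enumeration for
    n <= ``exact_max_n`` and uses the normal approximation with continuity
    and tie corrections above.
    """
    v = np.asarray(values, dtype=float)
    d = v - hypothesized_median
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal the hypothesized median")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(ranks2, np.sign(d))
        method = "exact enumeration"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction on the variance of W+
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        diff = w_plus - mu
        cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
        z = (diff - cc) / sigma if sigma > 0 else 0.0
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal approximation"
    return TestResult(
        "wilcoxon_one_sample", w_plus, p, (n,),
        extra={"hypothesized_median": hypothesized_median, "p_method": method},
    )


def correlate(
    x: Sequence[float], y: Sequence[float], parametric: bool
) -> tuple[float, float]:
    """Pearson (parametric) or Spearman (nonparametric) correlation, two-tailed p.

    Spearman is Pearson on mid-ranks, so it is invariant to monotone
    transformations of either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    if parametric:
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MethodSummary:
    """Per-method slice of the comparison report."""

    method: str
    medians: dict[str, float]  # group -> median Hz
    iqrs: dict[str, float]  # group -> IQR Hz
    quartiles: dict[str, tuple[float, float]]  # group -> (Q1, Q3)
    n: dict[str, int]  # group -> recording count
    median_difference: float  # control median - case median
    normality: dict[str, bool | None]  # group -> KS verdict (None if not assessable)
    test: TestResult | None
    test_note: str | None = None
    correlation_vs_manual: float | None = None
    correlation_p: float | None = None
    correlation_type: str | None = None  # pearson | spearman
    correlation_note: str | None = None
    # per-cohort correlations vs manual, mirroring the per-group layout of
    # published comparison tables: group -> (r, p, type)
    correlations_by_group: dict[str, tuple[float, float, str]] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Cohort comparison laid out per method, plus study-level counts.

    ``median_difference`` is control minus case, so a positive value means
    the patient group beats slower.  ``observation_points`` is the sum of
    per-group recording counts.
    """

    methods: dict[str, MethodSummary]
    recording_counts: dict[str, int]
    observation_points: int
    case_group: str
    control_group: str
    alpha: float = ALPHA
    quartile_rule: str = QUARTILE_RULE

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.methods.values():
            row: dict = {"method": m.method}
            for g in (self.case_group, self.control_group):
                row[f"median_{g}"] = m.medians[g]
                row[f"iqr_{g}"] = m.iqrs[g]
                row[f"n_{g}"] = m.n[g]
            row["median_difference"] = m.median_difference
            row["test"] = m.test.test if m.test else None
            row["p_value"] = m.test.p_value if m.test else None
            row["r_vs_manual"] = m.correlation_vs_manual
            row["correlation_type"] = m.correlation_type
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha,
            "quartile_rule": self.quartile_rule,
            "case_group": self.case_group,
            "control_group": self.control_group,
            "recording_counts": self.recording_counts,
            "observation_points": self.observation_points,
            "methods": {},
        }
        for name, m in self.methods.items():
            out["methods"][name] = {
                "medians": m.medians,
                "iqrs": m.iqrs,
                "quartiles": {g: list(q) for g, q in m.quartiles.items()},
                "n": m.n,
                "median_difference": m.median_difference,
                "normality": m.normality,
                "test": None
                if m.test is None
                else {
                    "name": m.test.test,
                    "statistic": m.test.statistic,
                    "p_value": m.test.p_value,
                    "df": m.test.df,
                },
                "test_note": m.test_note,
                "correlation_vs_manual": m.correlation_vs_manual,
                "correlation_p": m.correlation_p,
                "correlation_type": m.correlation_type,
                "correlation_note": m.correlation_note,
                "correlations_by_group": {
                    g: {"r": r, "p": p, "type": kind}
                    for g, (r, p, kind) in m.correlations_by_group.items()
                },
            }
        return out


_REQUIRED_COLUMNS = ("subject", "group", "recording", "method", "cbf_hz")


def build_report(
    table: pd.DataFrame,
    case_group: str = "PCD",
    control_group: str = "HC",
    manual_method: str = "manual",
) -> ComparisonReport:
    """Build the per-method cohort comparison from a long-format CBF table.

    ``table`` columns: subject, group, recording, method, cbf_hz; every
    method must have rows for both groups.  Per method: group medians and
    IQRs (inclusive linear-interpolation quartiles), actual median difference
    (control - case), KS-routed group test (Welch's t when both groups pass
    normality, else one-sample Wilcoxon of case values against the control
    median), and KS-routed Pearson/Spearman correlation against the manual
    method on per-recording pairs.  Statistics whose preconditions fail on
    the data at hand (too few values, zero variance) are reported as None
    with a note rather than aborting the report.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if (table["cbf_hz"] <= 0).any():
        raise ValueError("cbf_hz values must be positive")
    dup = table.duplicated(subset=["subject", "recording", "method"])
    if dup.any():
        raise ValueError("duplicate (subject, recording, method) rows in cohort table")

    methods = list(dict.fromkeys(table["method"]))
    for m in methods:
        sub = table[table["method"] == m]
        for g in (case_group, control_group):
            if not (sub["group"] == g).any():
                raise ValueError(f"method {m!r} has no rows for group {g!r}")

    # recording counts, taken over unique recordings per group
    rec_counts = {
        g: int(table.loc[table["group"] == g, "recording"].nunique())
        for g in (case_group, control_group)
    }

    summaries: dict[str, MethodSummary] = {}
    for m in methods:
        sub = table[table["method"] == m]
        values = {
            g: sub.loc[sub["group"] == g, "cbf_hz"].to_numpy(dtype=float)
            for g in (case_group, control_group)
        }
        medians = {g: float(np.median(v)) for g, v in values.items()}
        quartiles = {
            g: tuple(np.percentile(v, [25, 75], method="linear")) for g, v in values.items()
        }
        iqrs = {g: float(q[1] - q[0]) for g, q in quartiles.items()}
        n = {g: int(v.size) for g, v in values.items()}
        diff = medians[control_group] - medians[case_group]

        normality: dict[str, bool | None] = {}
        for g, v in values.items():
            try:
                normality[g] = ks_normality(v).normal
            except ValueError:
                normality[g] = None

        test: TestResult | None = None
        test_note: str | None = None
        both_normal = normality[case_group] is True and normality[control_group] is True
        try:
            if both_normal:
                test = welch_t(values[case_group], values[control_group])
            else:
                test = wilcoxon_one_sample(values[case_group], medians[control_group])
        except ValueError as exc:
            test_note = str(exc)

        corr = corr_p = None
        corr_type = corr_note = None
        corr_by_group: dict[str, tuple[float, float, str]] = {}
        if m != manual_method and manual_method in methods:
            pair = _paired_values(table, m, manual_method)
            parametric = both_normal
            corr_type = "pearson" if parametric else "spearman"
            try:
                corr, corr_p = correlate(pair[:, 0], pair[:, 1], parametric)
            except ValueError as exc:
                corr = corr_p = None
                corr_note = str(exc)
            for g in (case_group, control_group):
                gpair = _paired_values(table[table["group"] == g], m, manual_method)
                g_param = normality[g] is True
                try:
                    r_g, p_g = correlate(gpair[:, 0], gpair[:, 1], g_param)
                    corr_by_group[g] = (r_g, p_g, "pearson" if g_param else "spearman")
                except ValueError:
                    pass

        summaries[m] = MethodSummary(
            method=m,
            medians=medians,
            iqrs=iqrs,
            quartiles=quartiles,
            n=n,
            median_difference=diff,
            normality=normality,
            test=test,
            test_note=test_note,
            correlation_vs_manual=corr,
            correlation_p=corr_p,
            correlation_type=corr_type,
            correlation_note=corr_note,
            correlations_by_group=corr_by_group,
        )

    return ComparisonReport(
        methods=summaries,
        recording_counts=rec_counts,
        observation_points=sum(rec_counts.values()),
        case_group=case_group,
        control_group=control_group,
    )


def _paired_values(table: pd.DataFrame, method: str, manual_method: str) -> np.ndarray:
    """(n, 2) array of per-recording (method, manual) CBF pairs."""
    a = table[table["method"] == method].set_index(["subject", "recording"])["cbf_hz"]
    b = table[table["method"] == manual_method].set_index(["subject", "recording"])["cbf_hz"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["m", "manual"])
    return joined.to_numpy(dtype=float)
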