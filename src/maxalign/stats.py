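"""Cohort statistics: operator averaging, group summaries, normality, t-tests.

Per case the RMS 3D error is measured independently by several operators
(replicated ROI selections) and the case value is their arithmetic mean.
Group accuracy is summarized as mean +/- sample SD (n-1 denominator), and
groups are compared with a Student t-test at a 5% significance level.
Normality is checked with a Kolmogorov-Smirnov test against a normal law
with the sample's own mean and SD (Lilliefors plug-in correction, which is
stricter than the naive KS when parameters are estimated).

The default group contrast is the independent-samples pooled t-test: the
two surgical-transfer arms contain different patients, so a paired test is
undefined between them; paired mode remains available for genuinely coupled
designs (e.g. two measurements of the same patients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .errors import MaxalignError

__all__ = [
    "CaseResult",
    "GroupSummary",
    "GroupComparison",
    "average_operators",
    "group_summary",
    "ks_normality",
    "t_test",
]

ALPHA_DEFAULT = 0.05


@dataclass
class CaseResult:
    """Per-patient 3D error with group labels."""

    case_id: str
    group: str  # "splintless" | "splint"
    subgroup: str  # "monobloc" | "segmental"
    operator_values: list[float]
    rms_3d_error: float
    acceptable: bool

    def __post_init__(self) -> None:
        if not self.operator_values:
            raise MaxalignError("operator_values must be non-empty")
        if any(v < 0 for v in self.operator_values):
            raise MaxalignError("operator RMS values must be non-negative")
        if not np.isclose(self.rms_3d_error, np.mean(self.operator_values)):
            raise MaxalignError("rms_3d_error must equal the operator mean")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float  # nan when n < 2
    n: int


@dataclass
class GroupComparison:
    """Two-group comparison of 3D errors."""

    group_labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    n: tuple[int, int]
    test_used: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    alpha: float = ALPHA_DEFAULT


def average_operators(operator_values) -> float:
    """Arithmetic mean of per-operator RMS values (mm)."""
    vals = np.asarray(list(operator_values), dtype=np.float64)
    if len(vals) == 0:
        raise MaxalignError("no operator values to average")
    if np.any(vals < 0):
        raise MaxalignError("operator values must be non-negative")
    if len(vals) == 1:
        warnings.warn("single operator value; no replication", stacklevel=2)
    return float(vals.mean())


def group_summary(values) -> GroupSummary:
    """Mean and sample standard deviation (n-1 denominator)."""
    vals = np.asarray(list(values), dtype=np.float64)
    if len(vals) == 0:
        raise MaxalignError("cannot summarize an empty group")
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return GroupSummary(mean=float(vals.mean()), sd=sd, n=len(vals))


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Returns (statistic, p_value). The reference normal uses the sample's own
    mean and SD (Lilliefors plug-in), so critical values are the corrected
    small-sample ones, not the naive KS table.
    """
    vals = np.asarray(list(values), dtype=np.float64)
    if len(vals) < 3:
        raise MaxalignError("normality test requires n >= 3")
    if np.std(vals) == 0:
        raise MaxalignError("constant sample: normality test undefined (SD = 0)")
    stat, p = lilliefors(vals, dist="norm")
    return float(stat), float(p)


def t_test(
    values_a,
    values_b,
    mode: str = "independent-pooled",
    alpha: float = ALPHA_DEFAULT,
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sample Student t-test of 3D errors.

    Modes: "independent-pooled" (equal-variance, df = n_a + n_b - 2),
    "independent-welch", and "paired". Two-tailed p-values.
    """
    a = np.asarray(list(values_a), dtype=np.float64)
    b = np.asarray(list(values_b), dtype=np.float64)
    if mode == "paired":
        if len(a) != len(b):
            raise MaxalignError("paired mode requires equal-length samples")
        if len(a) < 2:
            raise MaxalignError("paired mode requires n >= 2")
    else:
        if len(a) < 2 or len(b) < 2:
            raise MaxalignError("independent modes require n >= 2 per group")
    sa = group_summary(a)
    sb = group_summary(b)
    na, nb = len(a), len(b)
    if mode == "independent-pooled":
        sp2 = ((na - 1) * sa.sd**2 + (nb - 1) * sb.sd**2) / (na + nb - 2)
        df = float(na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        num = sa.mean - sb.mean
    elif mode == "independent-welch":
        va, vb = sa.sd**2 / na, sb.sd**2 / nb
        denom = np.sqrt(va + vb)
        if va + vb > 0:
            df = float((va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1)))
        else:
            df = float(na + nb - 2)
        num = sa.mean - sb.mean
    elif mode == "paired":
        d = a - b
        sd_d = float(np.std(d, ddof=1))
        denom = sd_d / np.sqrt(na)
        df = float(na - 1)
        num = float(d.mean())
    else:
        raise MaxalignError(f"unknown t-test mode {mode!r}")
    if denom == 0:
        # zero variance: identical means -> no evidence, by convention
        t_stat, p = (0.0, 1.0) if np.isclose(num, 0.0) else (np.inf * np.sign(num), 0.0)
    else:
        t_stat = float(num / denom)
        p = float(2.0 * sps.t.sf(abs(t_stat), df))
    return GroupComparison(
        group_labels=group_labels,
        means=(sa.mean, sb.mean),
        sds=(sa.sd, sb.sd),
        n=(na, nb),
        test_used=mode,
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )
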