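"""ROI-level agreement statistics for paired kidney perfusion values.

Per-subject cortical RBF pairs (left/right kidney, one side diseased in
a unilateral injury model) measured by two modalities are compared by

* group summaries (mean +/- SD of diseased and healthy kidneys),
* a two-sided paired t-test on the healthy-minus-diseased differences,
* Bland-Altman analysis (mean difference and 1.96 SD limits of
  agreement), and
* per-subject left/right flow ratios, which index relative perfusion
  independently of each modality's absolute calibration.

SD conventions are explicit throughout: group summaries use the sample
SD (ddof 1); difference and repeatability summaries use the population
SD (ddof 0).  Reporting helpers round the way RBF values are
conventionally printed — integers for flows, two decimals for ratios,
p-values in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "TTestResult",
    "BlandAltmanResult",
    "load_table",
    "group_summary",
    "healthy_values",
    "diseased_values",
    "paired_differences",
    "paired_t_test",
    "bland_altman",
    "lr_ratio",
    "repeatability_summary",
    "full_report",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (print-style, not banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class PairedComparison:
    """Per-subject left/right cortical RBF pairs for one modality.

    ``diseased_side`` is ``"left"``, ``"right"`` or ``"none"`` per
    subject; subjects with two healthy kidneys contribute both values to
    the healthy group and are excluded from paired differences.
    """

    subject_ids: np.ndarray
    left_values: np.ndarray
    right_values: np.ndarray
    method: str
    diseased_side: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.left_values = np.asarray(self.left_values, dtype=float)
        self.right_values = np.asarray(self.right_values, dtype=float)
        self.diseased_side = np.asarray(self.diseased_side, dtype=str)
        n = len(self.subject_ids)
        if not (len(self.left_values) == len(self.right_values)
                == len(self.diseased_side) == n):
            raise ValueError("all per-subject columns must have equal length")
        if np.any(self.left_values <= 0) or np.any(self.right_values <= 0):
            raise ValueError("RBF values must be positive")
        bad = set(self.diseased_side.tolist()) - {"left", "right", "none"}
        if bad:
            raise ValueError(f"invalid diseased_side labels: {sorted(bad)}")
        if self.method not in ("ASL", "DCE"):
            raise ValueError("method must be 'ASL' or 'DCE'")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method: str) -> "PairedComparison":
        """Build from a table with columns
        (subject, method, left_rbf, right_rbf, diseased_side)."""
        sel = df[df["method"] == method]
        if sel.empty:
            raise ValueError(f"no rows for method {method!r}")
        return cls(
            subject_ids=sel["subject"].to_numpy(),
            left_values=sel["left_rbf"].to_numpy(),
            right_values=sel["right_rbf"].to_numpy(),
            method=method,
            diseased_side=sel["diseased_side"].to_numpy(),
        )


@dataclass(frozen=True)
class TTestResult:
    """Paired t-test result: t statistic, degrees of freedom (n-1) and
    the two-sided p-value."""

    t_stat: float
    df: int
    p_two_sided: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, population SD (ddof 0) and the 1.96 SD limits of
    agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged study-table fixture (``"table1"`` or ``"table2"``)."""
    ref = resources.files("renperf.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def group_summary(values: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """Mean and SD (with the stated ddof) of a group of RBF values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a group summary")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    return float(values.mean()), float(values.std(ddof=ddof))


def healthy_values(pc: PairedComparison) -> np.ndarray:
    """All healthy-kidney values: the non-diseased side of injured
    subjects, plus both kidneys of uninjured subjects."""
    out = []
    for left, right, side in zip(pc.left_values, pc.right_values, pc.diseased_side):
        if side == "none":
            out.extend([left, right])
        elif side == "left":
            out.append(right)
        else:
            out.append(left)
    return np.array(out)


def diseased_values(pc: PairedComparison) -> np.ndarray:
    """Diseased-kidney values of the injured subjects only."""
    out = [
        left if side == "left" else right
        for left, right, side in zip(pc.left_values, pc.right_values, pc.diseased_side)
        if side != "none"
    ]
    if not out:
        raise ValueError("no diseased subjects")
    return np.array(out)


def paired_differences(pc: PairedComparison) -> np.ndarray:
    """Per-subject healthy-minus-diseased difference (injured subjects
    only)."""
    diffs = [
        (right - left) if side == "left" else (left - right)
        for left, right, side in zip(pc.left_values, pc.right_values, pc.diseased_side)
        if side != "none"
    ]
    if not diffs:
        raise ValueError("no diseased subjects to difference")
    return np.array(diffs)


def paired_t_test(diffs: np.ndarray) -> TTestResult:
    """Two-sided one-sample t-test of the paired differences against 0:
    ``t = mean(d) / (sd(d, ddof 1) / sqrt(n))`` with n-1 degrees of
    freedom."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 differences")
    if diffs.std(ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(diffs, 0.0)
    return TTestResult(
        t_stat=float(res.statistic), df=n - 1, p_two_sided=float(res.pvalue)
    )


def bland_altman(diffs: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman summary of the differences: mean, population SD and
    mean +/- 1.96 SD limits of agreement."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need at least 2 differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=0))
    return BlandAltmanResult(
        mean_diff=mean, sd_diff=sd,
        loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
    )


def lr_ratio(pc: PairedComparison) -> np.ndarray:
    """Per-subject left/right flow ratio (report to 2 decimals)."""
    if np.any(pc.right_values == 0):
        raise ValueError("zero right-kidney value: ratio undefined")
    return pc.left_values / pc.right_values


def repeatability_summary(
    repeated: dict[str, np.ndarray], ddof: int = 0
) -> dict[str, tuple[float, float]]:
    """Per-kidney mean and SD over repeated measurements of the same
    subject (population SD by default)."""
    out = {}
    for kidney, values in repeated.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            raise ValueError(f"{kidney}: need at least 2 repeats")
        out[kidney] = (float(values.mean()), float(values.std(ddof=ddof)))
    return out


def _report_group(values: np.ndarray, ddof: int) -> dict:
    mean, sd = group_summary(values, ddof=ddof)
    return {"mean": round_half_up(mean), "sd": round_half_up(sd)}


def full_report(
    table1: pd.DataFrame,
    table2: pd.DataFrame | None = None,
    ddof_groups: int = 1,
    ddof_diffs: int = 0,
) -> dict:
    """Complete ROI-statistics report from a per-subject RBF table.

    Group summaries use ``ddof_groups`` (sample SD), difference and
    repeatability summaries ``ddof_diffs`` (population SD).  Values are
    rounded print-style: integer flows, 2-decimal ratios, p in percent
    with 2 decimals.
    """
    report: dict = {"methods": {}}
    for method in ("ASL", "DCE"):
        pc = PairedComparison.from_frame(table1, method)
        diffs = paired_differences(pc)
        tt = paired_t_test(diffs)
        ba = bland_altman(diffs)
        ratios = lr_ratio(pc)
        report["methods"][method] = {
            "diseased": _report_group(diseased_values(pc), ddof_groups),
            "healthy": _report_group(healthy_values(pc), ddof_groups),
            "difference": {
                "mean": round_half_up(ba.mean_diff),
                "sd": round_half_up(float(np.std(diffs, ddof=ddof_diffs))),
                "loa_low": round_half_up(ba.loa_low, 1),
                "loa_high": round_half_up(ba.loa_high, 1),
            },
            "t_test": {
                "t": round_half_up(tt.t_stat, 2),
                "df": tt.df,
                "p_percent": round_half_up(100.0 * tt.p_two_sided, 2),
            },
            "lr_ratios": {
                str(sid): round_half_up(r, 2)
                for sid, r in zip(pc.subject_ids, ratios)
            },
        }
    if table2 is not None:
        repeated = {
            f"rat{sid}_{kidney}": grp.sort_values("measurement")["rbf"].to_numpy()
            for (sid, kidney), grp in table2.groupby(["subject", "kidney"])
        }
        report["repeatability"] = {
            kidney: {"mean": round_half_up(m), "sd": round_half_up(s)}
            for kidney, (m, s) in repeatability_summary(
                repeated, ddof=ddof_diffs
            ).items()
        }
    return report
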