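"""Group-comparison statistics and report generation.

Implements the study's statistical layer: per-unit (animal or scene)
aggregation, mean +/- SEM, percent reduction between control and ablated
group means, pooled percentages from raw counts, the unpaired Welch
two-sample t-test, and a deterministic summary table / text report. The
unit of replication is the animal (scene in synthetic mode), never the
individual cell, and no multiple-testing correction is applied (stated in
the report header).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WelchResult",
    "mean_sem",
    "percent_reduction",
    "percent_remaining",
    "welch_t",
    "pooled_percentage",
    "simulate_null_rejection_rate",
    "build_report",
]

CONTROL = "control"
ABLATED = "ablated"


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error (SD with n-1 denominator over sqrt n).

    SEM is NaN for a single value; empty input is an error.
    """
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def percent_reduction(mean_control: float, mean_ablated: float) -> float:
    """100 * (1 - ablated/control); negative for increases.

    Full precision is returned; round only for display.
    """
    if mean_control <= 0:
        raise ValueError("mean_control must be > 0 to express a reduction")
    return 100.0 * (1.0 - mean_ablated / mean_control)


def percent_remaining(mean_control: float, mean_ablated: float) -> float:
    """Complement of :func:`percent_reduction`: 100 * ablated/control."""
    if mean_control <= 0:
        raise ValueError("mean_control must be > 0")
    return 100.0 * mean_ablated / mean_control


def _welch_arrays(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Vectorized Welch t, df and two-sided p along ``axis``."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va, vb = a.var(axis=axis, ddof=1), b.var(axis=axis, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na**2 * (na - 1)) + vb**2 / (nb**2 * (nb - 1)))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> WelchResult:
    """Unpaired two-sample t-test with Welch's correction.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), degrees of freedom
    by the Welch-Satterthwaite formula, two-sided p from the t
    distribution. Both groups need n >= 2. With zero variance in both
    groups: equal means give t = 0, p = 1; unequal means are an error
    (the statistic is undefined).
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test requires n >= 2 in both groups")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float("nan"), p=1.0)
        raise ValueError("degenerate variance with unequal means: t undefined")
    t, df, p = _welch_arrays(a, b)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def pooled_percentage(
    positives: Sequence[float] | float, totals: Sequence[float] | float
) -> float | None:
    """100 * sum(positives) / sum(totals); None when the total is zero."""
    pos = float(np.sum(positives))
    tot = float(np.sum(totals))
    if pos < 0 or tot < 0 or pos > tot:
        raise ValueError("need 0 <= positives <= totals")
    if tot == 0:
        return None
    return 100.0 * pos / tot


def simulate_null_rejection_rate(
    n_reps: int = 10000,
    n_per_group: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo type-I error of the Welch test under the normal null.

    Both groups are drawn from the same standard normal; returns the
    fraction of replicates with two-sided p < alpha.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    _, _, p = _welch_arrays(a, b, axis=-1)
    return float(np.mean(p < alpha))


REQUIRED_COLUMNS = ("group", "unit", "measure", "region", "value")


def build_report(samples: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Summarize a per-unit sample table into one row per (measure, region).

    ``samples`` columns: group (control|ablated), unit, measure, region,
    value — one value per (unit, measure, region). Each summary row holds
    group means/SEM/n, percent reduction of the ablated relative to the
    control mean, and Welch t/df/p when both groups have n >= 2. Measures
    present in only one group are summarized without a test and flagged.
    The output is a pure, order-invariant function of the samples.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"samples table is missing columns {missing}")
    bad_groups = set(samples["group"]) - {CONTROL, ABLATED}
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    dup = samples.duplicated(subset=["group", "unit", "measure", "region"])
    if dup.any():
        raise ValueError("duplicate (unit, measure, region) rows in samples")
    if samples.empty:
        raise ValueError("samples table is empty")

    rows = []
    for (measure, region), sub in sorted(
        samples.groupby(["measure", "region"], sort=True),
        key=lambda kv: kv[0],
    ):
        by_group = {
            g: np.sort(gsub["value"].to_numpy(dtype=np.float64))
            for g, gsub in sub.groupby("group")
        }
        row: dict = {"measure": measure, "region": region}
        for g in (CONTROL, ABLATED):
            vals = by_group.get(g, np.asarray([]))
            row[f"n_{g}"] = int(vals.size)
            if vals.size:
                m, s = mean_sem(vals)
                row[f"mean_{g}"], row[f"sem_{g}"] = m, s
            else:
                row[f"mean_{g}"] = row[f"sem_{g}"] = float("nan")
        one_group_only = not (len(by_group.get(CONTROL, [])) and len(by_group.get(ABLATED, [])))
        row["flag"] = "one group only" if one_group_only else ""
        if not one_group_only and row["mean_control"] > 0:
            row["percent_reduction"] = percent_reduction(
                row["mean_control"], row["mean_ablated"]
            )
        else:
            row["percent_reduction"] = float("nan")
        if (
            not one_group_only
            and row["n_control"] >= 2
            and row["n_ablated"] >= 2
            and not (
                np.var(by_group[CONTROL], ddof=1) == 0
                and np.var(by_group[ABLATED], ddof=1) == 0
                and by_group[CONTROL].mean() != by_group[ABLATED].mean()
            )
        ):
            res = welch_t(by_group[CONTROL], by_group[ABLATED])
            row["welch_t"], row["welch_df"], row["welch_p"] = res.t, res.df, res.p
        else:
            row["welch_t"] = row["welch_df"] = row["welch_p"] = float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows)

    lines = [
        "Group comparison report",
        "Data are represented as mean +/- SEM per unit (animal/scene).",
        "Unpaired t test with Welch's correction; no multiple-testing correction applied.",
        "",
    ]
    for _, r in summary.iterrows():
        red = (
            f"{r['percent_reduction']:+.0f}% reduction"
            if np.isfinite(r["percent_reduction"])
            else "reduction n/a"
        )
        test = (
            f"t={r['welch_t']:.3f}, df={r['welch_df']:.2f}, p={r['welch_p']:.4g}"
            if np.isfinite(r["welch_p"])
            else "no test"
        )
        lines.append(
            f"{r['measure']} [{r['region']}]: control "
            f"{r['mean_control']:.3g} +/- {r['sem_control']:.2g} (n={r['n_control']}) "
            f"vs ablated {r['mean_ablated']:.3g} +/- {r['sem_ablated']:.2g} "
            f"(n={r['n_ablated']}); {red}; {test}"
            + (f" [{r['flag']}]" if r["flag"] else "")
        )
    return summary, "\n".join(lines)
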