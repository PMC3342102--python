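"""Mutant-vs-wild-type relative expression of transposon piRNAs.

Relative expression (RE) is a sample library's per-transposon piRNA RPM
divided by the wild-type baseline's (WT = 1), computed separately for
sense, antisense, and total abundance.  REs are classified into the
three heat-map bands used for silencing surveys — reduced (RE < 0.6),
unchanged (0.6 <= RE <= 1.6, boundaries inclusive), elevated (RE > 1.6) —
and replicate libraries are summarized as mean +/- sample SD with the
percent reduction 100 x (1 - mean RE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BAND_LOWER = 0.6
BAND_UPPER = 1.6

STRAND_CLASSES = ("sense", "antisense", "total")


@dataclass
class RERecord:
    transposon_id: str
    strand_class: str  # {sense, antisense, total}
    library_id: str
    re: float  # nan marks undefined (baseline RPM was zero)
    band: Optional[str]  # {reduced, unchanged, elevated}; None when re is nan


@dataclass
class ReplicateSummary:
    label: str
    mean: float
    sd: float  # nan when n < 2
    n: int


def relative_expression(sample_rpm: float, baseline_rpm: float) -> float:
    """RE = sample RPM / baseline RPM; nan when the baseline is zero.

    A zero baseline makes the ratio undefined — the record is emitted with
    a missing-value marker rather than a fabricated number.
    """
    if sample_rpm < 0 or baseline_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    if baseline_rpm == 0:
        return math.nan
    return sample_rpm / baseline_rpm


def classify_band(re: float, lower: float = BAND_LOWER, upper: float = BAND_UPPER) -> str:
    """Heat-map band of a defined RE; both boundaries belong to "unchanged"."""
    if math.isnan(re):
        raise ValueError("cannot classify an undefined RE")
    if re < 0:
        raise ValueError("RE must be non-negative")
    if re < lower:
        return "reduced"
    if re > upper:
        return "elevated"
    return "unchanged"


def summarize_replicates(values: Sequence[float], label: str = "") -> ReplicateSummary:
    """Mean and sample standard deviation (divisor n - 1) of replicates.

    With fewer than two values the mean is still reported but the SD is
    marked undefined (nan).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else math.nan
    return ReplicateSummary(label=label, mean=mean, sd=sd, n=int(arr.size))


def percent_reduction(mean_re: float) -> float:
    """100 x (1 - mean RE); negative when the sample is overexpressed."""
    return 100.0 * (1.0 - mean_re)


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Classical two-sample Student's t (pooled variance), two-sided p.

    Degenerate zero-variance groups are resolved explicitly: equal means
    give (0, 1); unequal means give the limit (+/-inf, 0) with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means: p -> 0 limit")
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _rpm_frame(profile) -> pd.DataFrame:
    df = profile.table[["sense_rpm", "antisense_rpm"]].copy()
    df.columns = ["sense", "antisense"]
    df["total"] = df["sense"] + df["antisense"]
    return df


def compare_profiles(
    baseline,
    samples: Sequence,
    lower: float = BAND_LOWER,
    upper: float = BAND_UPPER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transposon RE records and replicate summaries vs a WT baseline.

    ``baseline`` is one LibraryProfile or a list of them; several baseline
    replicates are averaged (mean RPM per transposon) before normalizing.
    Returns ``(records, summary)``: records has one row per (transposon,
    strand_class, sample library) with ``re`` and ``band``; summary
    aggregates the sample replicates per (transposon, strand_class) with
    mean_re, sd_re, n, percent_reduction, and — when at least two baseline
    replicates were supplied — a pooled-variance t statistic and two-sided
    p value of per-baseline-library REs against the sample REs (reported
    raw, with no multiple-testing correction).
    """
    baselines = list(baseline) if isinstance(baseline, (list, tuple)) else [baseline]
    base_frames = [_rpm_frame(p) for p in baselines]
    base = sum(base_frames[1:], base_frames[0].copy()) / len(base_frames)

    records = []
    for prof in samples:
        samp = _rpm_frame(prof)
        for tid in base.index:
            for sc in STRAND_CLASSES:
                s = float(samp.loc[tid, sc]) if tid in samp.index else 0.0
                re = relative_expression(s, float(base.loc[tid, sc]))
                band = None if math.isnan(re) else classify_band(re, lower, upper)
                records.append(
                    {
                        "transposon_id": tid,
                        "strand_class": sc,
                        "library_id": prof.library_id,
                        "re": re,
                        "band": band,
                    }
                )
    records_df = pd.DataFrame.from_records(records)

    summary_rows = []
    for (tid, sc), grp in records_df.groupby(["transposon_id", "strand_class"], sort=True):
        res = grp["re"].to_numpy(dtype=float)
        if np.isnan(res).any():
            summary_rows.append(
                {
                    "transposon_id": tid, "strand_class": sc,
                    "mean_re": math.nan, "sd_re": math.nan, "n": len(res),
                    "percent_reduction": math.nan, "t": math.nan, "p": math.nan,
                }
            )
            continue
        summ = summarize_replicates(res)
        t = p = math.nan
        if len(baselines) >= 2 and len(res) >= 2:
            base_res = [
                relative_expression(float(_rpm_frame(bp).loc[tid, sc]), float(base.loc[tid, sc]))
                for bp in baselines
            ]
            if not any(math.isnan(v) for v in base_res):
                t, p = two_sample_t(base_res, res)
        summary_rows.append(
            {
                "transposon_id": tid, "strand_class": sc,
                "mean_re": summ.mean, "sd_re": summ.sd, "n": summ.n,
                "percent_reduction": percent_reduction(summ.mean),
                "t": t, "p": p,
            }
        )
    summary_df = pd.DataFrame(summary_rows)
    return records_df, summary_df


def plot_re_heatmap(records: pd.DataFrame, strand_class: str = "total", ax=None):
    """Three-color heat map of RE bands (rows: transposons, cols: libraries)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    sub = records[records["strand_class"] == strand_class]
    pivot = sub.pivot(index="transposon_id", columns="library_id", values="re")
    coded = pivot.copy()
    coded[:] = 1.0
    coded[pivot < BAND_LOWER] = 0.0
    coded[pivot > BAND_UPPER] = 2.0
    cmap = ListedColormap(["lightblue", "blue", "red"])
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5], cmap.N)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, max(2, 0.2 * len(pivot))))
    ax.imshow(coded.to_numpy(dtype=float), aspect="auto", cmap=cmap, norm=norm)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=5)
    ax.set_xlabel("library")
    ax.set_title(f"relative expression ({strand_class})")
    return ax
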