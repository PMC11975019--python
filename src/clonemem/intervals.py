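"""Deterministic genomic bookkeeping.

Summit-based construction of fixed-width non-overlapping peak sets,
pseudobulking with RPM normalisation, expression filters, and variable-peak
selection.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAD = 400
PEAK_HALF_WIDTH = 150  # final peaks are summit +/- 150 -> 301 bp


@dataclass
class SummitRecord:
    """A called peak summit with its significance score."""

    chrom: str
    summit: int  # 0-based bp
    significance: float


@dataclass
class PeakSet:
    """Non-overlapping fixed-width peaks, each centred on a kept summit."""

    intervals: pd.DataFrame  # columns: chrom, start, end, summit, significance

    def __len__(self) -> int:
        return len(self.intervals)


def filter_summits(
    summits: list[SummitRecord] | pd.DataFrame,
    pad: int = PAD,
    half_width: int = PEAK_HALF_WIDTH,
) -> PeakSet:
    """Build a non-overlapping fixed-width peak set from summits.

    Each summit is padded to ``[summit - pad, summit + pad + 1)``; summits are
    processed in decreasing significance and a summit is kept iff its padded
    window overlaps no previously kept padded window.  Kept summits are then
    resized to ``[summit - half_width, summit + half_width + 1)`` (301 bp at
    the default).  Ties in significance are broken by (chrom, summit) order.
    Negative starts after padding are clamped to 0.
    """
    if isinstance(summits, pd.DataFrame):
        df = summits[["chrom", "summit", "significance"]].copy()
    else:
        df = pd.DataFrame(
            [(s.chrom, s.summit, s.significance) for s in summits],
            columns=["chrom", "summit", "significance"],
        )
    if (df["summit"] < 0).any():
        raise ValueError("summit positions must be >= 0")
    df = df.sort_values(
        ["significance", "chrom", "summit"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    kept_rows = []
    kept_windows: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        w_start = max(0, row.summit - pad)
        w_end = row.summit + pad + 1
        overlaps = any(
            w_start < e and s < w_end for s, e in kept_windows.get(row.chrom, ())
        )
        if not overlaps:
            kept_windows.setdefault(row.chrom, []).append((w_start, w_end))
            kept_rows.append(row)

    out = pd.DataFrame(
        {
            "chrom": [r.chrom for r in kept_rows],
            "start": [max(0, r.summit - half_width) for r in kept_rows],
            "end": [r.summit + half_width + 1 for r in kept_rows],
            "summit": [r.summit for r in kept_rows],
            "significance": [r.significance for r in kept_rows],
        }
    )
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(intervals=out)


def pseudobulk(
    counts: pd.DataFrame, groups: pd.Series, min_rpm: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Sum raw counts over cell groups and compute RPM.

    Parameters
    ----------
    counts
        cells x features raw counts (rows indexed by cell id).
    groups
        cell -> group label, aligned to ``counts.index``.
    min_rpm
        a feature "passes" if its RPM is >= ``min_rpm`` in at least one group.

    Returns
    -------
    (group x feature counts, group x feature RPM, per-feature pass flag)
    """
    groups = groups.reindex(counts.index)
    if groups.isna().any():
        raise ValueError("every cell must have a group label")
    bulk = counts.groupby(groups, observed=True).sum()
    totals = bulk.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty pseudobulk group(s): {empty}")
    rpm = bulk.div(totals, axis=0) * 1e6
    passes = (rpm >= min_rpm).any(axis=0)
    return bulk, rpm, passes


def variable_peaks(
    rpm: pd.DataFrame, raw: pd.DataFrame, min_raw: int = 20, top_n: int = 10_000
) -> pd.Index:
    """Select the most variable peaks across samples.

    Peaks must reach ``min_raw`` raw reads in at least one sample; survivors
    are ranked by the standard deviation of their RPM values across samples
    and the ``top_n`` are returned (all survivors if fewer).
    """
    eligible = raw.max(axis=0) >= min_raw
    sds = rpm.loc[:, eligible].std(axis=0, ddof=1)
    return sds.sort_values(ascending=False, kind="mergesort").index[:top_n]


def zscore_change(
    values: pd.DataFrame, control_samples: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Z-score per feature across samples; change relative to control mean.

    ``values`` is samples x features.  z uses the n-1 standard deviation
    across all samples; change subtracts, per feature, the mean z over the
    control samples.  Features with zero SD are flagged and left NaN.
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    z = (values - mean).div(sd.where(~degenerate), axis=1)
    change = z - z.loc[control_samples].mean(axis=0)
    return z, change, degenerate
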