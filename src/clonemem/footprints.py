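"""TF footprint post-processing and co-binding analysis.

Footprint scores arrive as (peak, 10-bp bin, condition) tables produced by an
upstream sequence-attribution model; this module bins/filters them, maps them
onto a common per-condition quantile scale, calls "memory" sites — bins whose
score gains at least ``delta_min`` in a disease or recovered condition over
its matched control — and quantifies whether two TF families' memory sites
co-occur in the same peaks more often than chance, via a 2x2 odds ratio
normalised to a co-binding score in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import quantile_transform as _sk_quantile_transform

BIN_WIDTH = 10
MIN_MAX_SCORE = 0.2
DELTA_MIN = 0.2


@dataclass
class MemorySiteSet:
    """Memory footprint sites for one TF family.

    ``sites`` has columns peak, bin_start, delta, midpoint (bp, peak-relative
    midpoint of the 10-bp bin).
    """

    family: str
    sites: pd.DataFrame

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class CobindingResult:
    family_a: str
    family_b: str
    both: int
    first_only: int
    second_only: int
    neither: int
    odds_ratio: float
    log2_or: float
    score: float = float("nan")


def filter_low_bins(table: pd.DataFrame, min_max_score: float = MIN_MAX_SCORE) -> pd.DataFrame:
    """Drop (peak, bin) entries whose max score across conditions is < threshold."""
    key = ["peak", "bin_start"]
    max_score = table.groupby(key)["score"].transform("max")
    return table[max_score >= min_max_score].reset_index(drop=True)


def quantile_transform_scores(
    table: pd.DataFrame, n_quantiles: int = 100_000
) -> pd.DataFrame:
    """Map scores to their empirical uniform quantiles within each condition.

    Monotone within condition; two conditions with identical score ranks get
    identical transformed vectors regardless of scale.
    """
    out = table.reset_index(drop=True)
    for cond in out["condition"].unique():
        mask = (out["condition"] == cond).to_numpy()
        vals = out.loc[mask, "score"].to_numpy(dtype=float)
        nq = min(n_quantiles, len(vals))
        out.loc[mask, "score"] = _sk_quantile_transform(
            vals[:, None], n_quantiles=nq, output_distribution="uniform", copy=True
        )[:, 0]
    return out


def call_memory_sites(
    table: pd.DataFrame,
    condition: str,
    control: str,
    family_sites: pd.DataFrame,
    delta_min: float = DELTA_MIN,
    bin_width: int = BIN_WIDTH,
    sign: int = +1,
) -> dict[str, MemorySiteSet]:
    """Call memory footprints: bins gaining >= ``delta_min`` over control.

    ``family_sites`` maps motif occurrences to footprint bins (columns:
    family, peak, bin_start); a site is attributed to the family occupying
    that bin.  ``sign=-1`` calls losses (decrease of at least ``delta_min``)
    instead of gains.  The delta at exactly ``delta_min`` is included.
    """
    wide = table.pivot_table(
        index=["peak", "bin_start"], columns="condition", values="score"
    )
    for c in (condition, control):
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} missing from footprint table")
    delta = (wide[condition] - wide[control]).dropna()
    passing = delta[sign * delta >= delta_min]
    passing = passing.rename("delta").reset_index()

    out: dict[str, MemorySiteSet] = {}
    for family, fam_df in family_sites.groupby("family"):
        merged = passing.merge(
            fam_df[["peak", "bin_start"]].drop_duplicates(),
            on=["peak", "bin_start"],
            how="inner",
        )
        merged["midpoint"] = merged["bin_start"] + bin_width / 2
        out[str(family)] = MemorySiteSet(family=str(family), sites=merged)
    return out


def _odds_ratio(both: int, first_only: int, second_only: int, neither: int) -> float:
    """Cross-product odds ratio with Haldane-Anscombe 0.5 when any cell is 0."""
    cells = np.array([both, first_only, second_only, neither], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    b, f, s, n = cells
    return (b * n) / (f * s)


def cobinding_score(
    memory_sets: dict[str, MemorySiteSet],
    peak_universe: pd.Index | list,
) -> pd.DataFrame:
    """Co-binding scores for every unordered pair of families.

    For each pair, peaks in the universe are classified as containing memory
    sites of both families, the first only, the second only, or neither; the
    2x2 odds ratio is log2-transformed and, across all pairs, positive values
    are clipped to their 10th-90th percentile range and scaled linearly to
    [0, 1] (negatives to [-1, 0]).  Pairs involving a family with no memory
    sites get NaN scores.
    """
    universe = pd.Index(peak_universe)
    families = sorted(memory_sets)
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    peak_members = {
        f: set(memory_sets[f].sites["peak"]) & set(universe) for f in families
    }

    rows: list[CobindingResult] = []
    for i, fa in enumerate(families):
        for fb in families[i + 1 :]:
            if not peak_members[fa] or not peak_members[fb]:
                rows.append(
                    CobindingResult(fa, fb, 0, 0, 0, 0, float("nan"), float("nan"))
                )
                continue
            in_a = np.array([p in peak_members[fa] for p in universe])
            in_b = np.array([p in peak_members[fb] for p in universe])
            both = int((in_a & in_b).sum())
            first = int((in_a & ~in_b).sum())
            second = int((~in_a & in_b).sum())
            neither = int((~in_a & ~in_b).sum())
            odds = _odds_ratio(both, first, second, neither)
            rows.append(
                CobindingResult(fa, fb, both, first, second, neither, odds, np.log2(odds))
            )

    df = pd.DataFrame([vars(r) for r in rows])
    df["score"] = _normalize_log2_or(df["log2_or"].to_numpy())
    return df


def _normalize_log2_or(log2_or: np.ndarray) -> np.ndarray:
    """10th-90th quantile normalisation, positives to [0,1], negatives to [-1,0].

    Degenerate sign classes (10th percentile == 90th) map to +/-1.
    """
    out = np.full(log2_or.shape, np.nan)
    zero = np.isfinite(log2_or) & (log2_or == 0)
    out[zero] = 0.0
    for sign in (+1, -1):
        mask = np.isfinite(log2_or) & (sign * log2_or > 0)
        if not mask.any():
            continue
        vals = sign * log2_or[mask]  # positive magnitudes
        lo, hi = np.percentile(vals, [10, 90])
        if hi == lo:
            out[mask] = sign * 1.0
            continue
        scaled = np.clip((np.clip(vals, lo, hi) - lo) / (hi - lo), 0.0, 1.0)
        out[mask] = sign * scaled
    return out


def site_distances(set_a: MemorySiteSet, set_b: MemorySiteSet) -> np.ndarray:
    """All |midpoint - midpoint| distances between the two families' memory
    sites lying in the same peak."""
    merged = set_a.sites.merge(
        set_b.sites, on="peak", suffixes=("_a", "_b"), how="inner"
    )
    return np.abs(merged["midpoint_a"] - merged["midpoint_b"]).to_numpy()


def collapse_overlapping_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping motif sites within a peak into one site.

    ``sites`` has columns peak, start, end, delta; overlapping (or abutting
    half-open) intervals in the same peak are merged, keeping the delta of
    largest magnitude.
    """
    rows = []
    for peak, grp in sites.sort_values(["peak", "start"]).groupby("peak"):
        cur = None
        for r in grp.itertuples(index=False):
            if cur is None or r.start >= cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {"peak": peak, "start": r.start, "end": r.end, "delta": r.delta}
            else:
                cur["end"] = max(cur["end"], r.end)
                if abs(r.delta) > abs(cur["delta"]):
                    cur["delta"] = r.delta
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["peak", "start", "end", "delta"])


def footprint_vs_binding_performance(
    site_deltas: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Sensitivity/specificity sweep for predicting differential binding.

    Each peak's delta is the site delta of largest magnitude among its
    (collapsed) motif sites; ``labels`` marks truly differential peaks.  For
    each threshold t over the sorted unique per-peak deltas, predicted
    positive means delta >= t; returns a DataFrame with columns threshold,
    sensitivity, specificity.
    """
    idx = site_deltas.groupby("peak")["delta"].apply(lambda s: s.abs().idxmax())
    per_peak = site_deltas.loc[idx].set_index("peak")["delta"]
    common = per_peak.index.intersection(labels.index)
    per_peak = per_peak.loc[common]
    y = labels.loc[common].astype(bool)

    thresholds = np.unique(per_peak.to_numpy())
    rows = []
    for t in thresholds:
        pred = per_peak >= t
        tp = int((pred & y).sum())
        fn = int((~pred & y).sum())
        tn = int((~pred & ~y).sum())
        fp = int((pred & ~y).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        rows.append({"threshold": t, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
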