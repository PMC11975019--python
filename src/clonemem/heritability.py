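"""Permutation test for clonal heritability of single-cell feature scores.

The statistic: for one feature, take the standard deviation of the
single-cell scores within each clone, then square the median of these SDs
across clones — the "observed clonal variance".  If a state is clonally
heritable, cells within a clone resemble each other and the within-clone
SDs shrink relative to a random grouping of the same sizes, so the observed
statistic falls below its permutation null.  Cell→clone assignments are
permuted (clone sizes preserved), the statistic recomputed per permutation,
and

    Z = (observed - mean_shuffled) / sd_shuffled,   p = 2 * Phi(-|Z|),

with BH-adjusted FDR across the tested features.  An exact rank-based
permutation p-value is reported alongside as a diagnostic for cases where
the normal approximation to the permutation null is poor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clonemem._rng import stream

N_PERM = 1000
HIGH_CLONE_THRESHOLD = 1.25


def clonal_variance(scores: np.ndarray | pd.Series, clone_labels) -> float:
    """(median over clones of the within-clone score SD) squared.

    SDs use the n-1 denominator; clones with fewer than 2 cells are excluded.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    labels = pd.Series(np.asarray(clone_labels), index=s.index)
    sds = s.groupby(labels).std(ddof=1)
    sds = sds[labels.value_counts() >= 2]
    if sds.empty:
        raise ValueError("no clone with at least 2 cells")
    return float(np.median(sds)) ** 2


def _grouped_stat(X: np.ndarray, X2: np.ndarray, starts: np.ndarray,
                  sizes: np.ndarray, eligible: np.ndarray) -> np.ndarray:
    """Clonal-variance statistic per feature for rows already in clone order."""
    sums = np.add.reduceat(X, starts, axis=0)
    sumsq = np.add.reduceat(X2, starts, axis=0)
    n = sizes[:, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sumsq - sums**2 / n) / (n - 1)
    sd = np.sqrt(np.clip(var[eligible], 0.0, None))
    return np.median(sd, axis=0) ** 2


def permutation_test(
    scores: pd.DataFrame,
    clone_labels: pd.Series,
    n_perm: int = N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Clonal-heritability permutation test per feature.

    One shared set of ``n_perm`` label permutations (clone sizes preserved)
    is used for all features.  Returns a DataFrame indexed by feature with
    observed statistic, shuffled mean/SD, Z, p, BH fdr, an exact two-sided
    permutation p-value (``p_exact``), and a ``degenerate`` flag for features
    where the shuffled SD is 0 (p reported as 1).
    """
    labels = clone_labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every cell needs a clone label")
    if labels.nunique() < 2:
        # permutation-invariant: every shuffle reproduces the observed value
        obs = {c: clonal_variance(scores[c], labels) for c in scores.columns}
        return pd.DataFrame(
            {
                "observed": pd.Series(obs),
                "mean_shuffled": pd.Series(obs),
                "sd_shuffled": 0.0,
                "Z": np.nan,
                "p": 1.0,
                "p_exact": 1.0,
                "fdr": 1.0,
                "degenerate": True,
            }
        )

    order = np.argsort(labels.to_numpy(), kind="mergesort")
    X = scores.to_numpy(dtype=float)[order]
    if not np.isfinite(X).all():
        raise ValueError("scores must be finite")
    X2 = X**2
    sorted_labels = labels.to_numpy()[order]
    starts = np.concatenate(([0], np.nonzero(sorted_labels[1:] != sorted_labels[:-1])[0] + 1))
    sizes = np.diff(np.concatenate((starts, [len(sorted_labels)])))
    eligible = sizes >= 2
    if not eligible.any():
        raise ValueError("no clone with at least 2 cells")

    observed = _grouped_stat(X, X2, starts, sizes, eligible)

    rng = stream(seed, "heritability-permutations")
    n = X.shape[0]
    shuffled = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        idx = rng.permutation(n)
        shuffled[b] = _grouped_stat(X[idx], X2[idx], starts, sizes, eligible)

    mean_sh = shuffled.mean(axis=0)
    sd_sh = shuffled.std(axis=0, ddof=1)
    degenerate = sd_sh == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (observed - mean_sh) / sd_sh
    p = 2 * stats.norm.cdf(-np.abs(Z))
    p[degenerate] = 1.0
    Z[degenerate] = np.nan

    lo = (1 + (shuffled <= observed).sum(axis=0)) / (n_perm + 1)
    hi = (1 + (shuffled >= observed).sum(axis=0)) / (n_perm + 1)
    p_exact = np.minimum(1.0, 2 * np.minimum(lo, hi))

    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "observed": observed,
            "mean_shuffled": mean_sh,
            "sd_shuffled": sd_sh,
            "Z": Z,
            "p": p,
            "p_exact": p_exact,
            "fdr": fdr,
            "degenerate": degenerate,
        },
        index=scores.columns,
    )


def clone_summaries(
    scores: pd.Series,
    clone_labels: pd.Series,
    clone_conditions: pd.Series,
) -> pd.DataFrame:
    """Per-clone median, SD and size of single-cell scores, with condition."""
    labels = clone_labels.reindex(scores.index)
    grouped = scores.groupby(labels)
    out = pd.DataFrame(
        {
            "median_score": grouped.median(),
            "sd_score": grouped.std(ddof=1),
            "n_cells": grouped.size(),
        }
    )
    out["condition"] = clone_conditions.reindex(out.index)
    return out


def compare_clone_distributions(
    summaries: pd.DataFrame,
    case: str,
    control: str,
    high_threshold: float = HIGH_CLONE_THRESHOLD,
) -> dict:
    """Compare clone-level score distributions between two conditions.

    Returns the KS p-value on the per-clone SDs, the case-minus-control shift
    of the median clone median and median clone SD, and per-condition
    fractions of "high" clones (median score strictly above
    ``high_threshold``).
    """
    by_cond = {c: summaries[summaries["condition"] == c] for c in (case, control)}
    for c, df in by_cond.items():
        if len(df) < 3:
            raise ValueError(f"need >=3 clones in condition {c!r}")
    ks = stats.ks_2samp(
        by_cond[case]["sd_score"].dropna(), by_cond[control]["sd_score"].dropna()
    )
    return {
        "ks_p_sd": float(ks.pvalue),
        "median_shift": float(
            by_cond[case]["median_score"].median()
            - by_cond[control]["median_score"].median()
        ),
        "sd_shift": float(
            by_cond[case]["sd_score"].median() - by_cond[control]["sd_score"].median()
        ),
        "high_fraction": {
            c: float((df["median_score"] > high_threshold).mean())
            for c, df in by_cond.items()
        },
    }


def correlate_motifs_programs(
    motif_scores: pd.DataFrame,
    program_scores: pd.DataFrame,
    clone_labels: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlation of clone-mean motif and program scores.

    Scores are averaged within each clone; the clone-mean vectors of every
    motif-program pair are correlated across clones.  Returns the correlation
    matrix (motifs x programs) and, per motif, the argmax program.
    Zero-variance clone-mean vectors yield NaN.
    """
    labels = clone_labels.reindex(motif_scores.index)
    if labels.nunique() < 3:
        raise ValueError("need >=3 clones")
    m = motif_scores.groupby(labels).mean()
    g = program_scores.groupby(labels.reindex(program_scores.index)).mean()
    g = g.loc[m.index]

    corr = pd.DataFrame(index=m.columns, columns=g.columns, dtype=float)
    for motif in m.columns:
        mv = m[motif].to_numpy()
        for program in g.columns:
            gv = g[program].to_numpy()
            if np.std(mv) == 0 or np.std(gv) == 0:
                corr.loc[motif, program] = np.nan
            else:
                corr.loc[motif, program] = stats.pearsonr(mv, gv).statistic
    corr = corr.astype(float)
    top = corr.apply(
        lambda row: row.idxmax() if row.notna().any() else np.nan, axis=1
    )
    return corr, top
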