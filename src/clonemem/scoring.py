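"""Background-corrected deviation scoring of single cells.

For an annotated feature set (peaks carrying a TF motif, or a weighted gene
program), each cell's observed counts in the set are compared with the
expectation under its sequencing depth and the features' population-level
accessibility/expression; the raw deviation is then z-scored against
matched background sets sampled from features of similar mean abundance.
The construction controls for depth and feature abundance, so scores are
comparable across cells and conditions.

Also here: greedy bagging of motifs into families by sequence-similarity
q-values, per-sample summary statistics with BH-adjusted tests, activated-
cell fractions, distributional heterogeneity tests, and LDA gene-program
fitting (programs are scored with the same deviation machinery, swapping
the motif-by-peak membership matrix for the topic-by-gene probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import LatentDirichletAllocation
from statsmodels.stats.multitest import multipletests

from clonemem._rng import stream

N_BACKGROUND = 250
N_EXPRESSION_BINS = 20
ACTIVATED_THRESHOLD = 1.5
TOP_VARIABLE_FAMILIES = 50
MIN_STEM_CELLS = 200


@dataclass
class AnnotationSet:
    """A named feature set, optionally weighted (gene programs)."""

    name: str
    members: np.ndarray  # feature indices
    weights: np.ndarray | None = None  # nonneg, aligned to members

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=np.intp)
        if self.members.size == 0:
            raise ValueError(f"annotation set {self.name!r} is empty")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.members.shape:
                raise ValueError("weights must align with members")
            if (self.weights < 0).any():
                raise ValueError("weights must be nonnegative")


@dataclass
class ScoreMatrix:
    """Cells x annotation-sets deviation z-scores."""

    scores: pd.DataFrame
    n_background: int = N_BACKGROUND
    n_bins: int = N_EXPRESSION_BINS
    seed: int = 0
    raw: pd.DataFrame | None = None  # uncorrected (obs - E) / E deviations


@dataclass
class MotifFamilyBag:
    leader: str
    members: set[str]
    variability: dict[str, float] = field(default_factory=dict)


def _as_csr(counts) -> tuple[sp.csr_matrix, pd.Index]:
    if isinstance(counts, pd.DataFrame):
        return sp.csr_matrix(counts.to_numpy(dtype=float)), counts.index
    mat = sp.csr_matrix(counts, dtype=float)
    return mat, pd.RangeIndex(mat.shape[0])


def _abundance_bins(col_frac: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Group features into equal-size bins of mean abundance (rank-based)."""
    order = np.lexsort((np.arange(col_frac.size), col_frac))
    return [np.sort(chunk) for chunk in np.array_split(order, n_bins)]


def deviation_scores(
    counts,
    sets: list[AnnotationSet],
    n_background: int = N_BACKGROUND,
    seed: int = 0,
    n_bins: int = N_EXPRESSION_BINS,
    cell_index: pd.Index | None = None,
) -> ScoreMatrix:
    """Deviation z-scores for each cell and annotation set.

    For cell i and set m with weights w: expected counts
    ``E[i,m] = depth_i * sum_{j in m} w_j f_j`` where ``f_j`` is feature j's
    fraction of all counts; raw deviation is ``(obs - E) / E``.  The z-score
    standardises the raw deviation against ``n_background`` background sets,
    each built by resampling every member feature from its mean-abundance bin
    (``n_bins`` equal-size bins), keeping the member's weight.  Cells with
    E = 0 get NaN and are excluded from summaries.
    """
    X, index = _as_csr(counts)
    if cell_index is not None:
        index = pd.Index(cell_index)
    n_cells, n_features = X.shape
    depth = np.asarray(X.sum(axis=1)).ravel()
    total = depth.sum()
    if total == 0:
        raise ValueError("count matrix is empty")
    col_sums = np.asarray(X.sum(axis=0)).ravel()
    f = col_sums / total

    bins = _abundance_bins(f, n_bins)
    feature_bin = np.empty(n_features, dtype=np.intp)
    for b, members in enumerate(bins):
        feature_bin[members] = b

    rng = stream(seed, "deviation-background")
    out = np.full((n_cells, len(sets)), np.nan)
    raw_out = np.full((n_cells, len(sets)), np.nan)

    for si, aset in enumerate(sets):
        if aset.members.max() >= n_features:
            raise ValueError(f"set {aset.name!r} has out-of-bounds features")
        w = (
            np.ones(aset.members.size)
            if aset.weights is None
            else aset.weights
        )
        obs = X[:, aset.members] @ w
        p_m = float(f[aset.members] @ w)
        E = depth * p_m

        # sample background features bin-matched per member
        B = np.empty((n_background, aset.members.size), dtype=np.intp)
        for k, j in enumerate(aset.members):
            pool = bins[feature_bin[j]]
            B[:, k] = pool[rng.integers(0, pool.size, size=n_background)]

        # sparse feature x background-set weight matrix
        rows = B.ravel()
        cols = np.repeat(np.arange(n_background), aset.members.size)
        data = np.tile(w, n_background)
        Wb = sp.csr_matrix((data, (rows, cols)), shape=(n_features, n_background))
        obs_b = X @ Wb  # cells x backgrounds
        obs_b = np.asarray(obs_b.todense()) if sp.issparse(obs_b) else obs_b
        p_b = f @ Wb
        p_b = np.asarray(p_b).ravel()
        E_b = depth[:, None] * p_b[None, :]

        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(E > 0, (obs - E) / E, np.nan)
            raw_b = np.where(E_b > 0, (obs_b - E_b) / E_b, np.nan)
        mean_b = np.nanmean(raw_b, axis=1)
        sd_b = np.nanstd(raw_b, axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (raw - mean_b) / sd_b
        out[:, si] = z
        raw_out[:, si] = raw

    cols = [s.name for s in sets]
    scores = pd.DataFrame(out, index=index, columns=cols)
    raw_df = pd.DataFrame(raw_out, index=index, columns=cols)
    return ScoreMatrix(
        scores=scores, n_background=n_background, n_bins=n_bins, seed=seed, raw=raw_df
    )


def bag_motif_families(
    similarity_q: pd.DataFrame,
    scores: pd.DataFrame | ScoreMatrix,
    q_threshold: float = 0.05,
) -> list[MotifFamilyBag]:
    """Greedy bagging of motifs into families by similarity q-values.

    Motifs are sorted by decreasing cross-cell variability (SD of scores);
    each motif becomes a leader unless its q-value to an existing leader is
    <= ``q_threshold``, in which case it joins the first qualifying leader in
    variability order.  Missing similarity entries count as dissimilar
    (q = 1); asymmetric entries are reconciled by taking the minimum of the
    two directions.  The result is a partition of the motifs.
    """
    sc = scores.scores if isinstance(scores, ScoreMatrix) else scores
    variability = sc.std(axis=0, ddof=1)
    motifs = variability.sort_values(ascending=False, kind="mergesort").index

    def q(a: str, b: str) -> float:
        vals = []
        for x, y in ((a, b), (b, a)):
            if x in similarity_q.index and y in similarity_q.columns:
                v = similarity_q.loc[x, y]
                if pd.notna(v):
                    vals.append(float(v))
        return min(vals) if vals else 1.0

    bags: list[MotifFamilyBag] = []
    for motif in motifs:
        joined = False
        for bag in bags:
            if q(motif, bag.leader) <= q_threshold:
                bag.members.add(motif)
                bag.variability[motif] = float(variability[motif])
                joined = True
                break
        if not joined:
            bags.append(
                MotifFamilyBag(
                    leader=motif,
                    members={motif},
                    variability={motif: float(variability[motif])},
                )
            )
    return bags


def per_sample_stats(
    scores: pd.DataFrame | ScoreMatrix,
    cell_to_sample: pd.Series,
    sample_to_condition: pd.Series,
    control_condition: str = "control",
    cell_mask: pd.Series | None = None,
    top_n_variable: int = TOP_VARIABLE_FAMILIES,
    min_cells: int = MIN_STEM_CELLS,
) -> dict:
    """Per-sample mean scores, change vs control, and per-family tests.

    Single-cell scores are averaged within each sample (optionally over a
    cell-type mask); change is each sample's mean minus the average over
    control samples.  For the ``top_n_variable`` families (by SD of
    per-sample means), each non-control condition is compared with control by
    a two-sided Welch t-test over sample means, BH-adjusted within condition.
    Samples with fewer than ``min_cells`` masked cells are flagged.
    """
    sc = scores.scores if isinstance(scores, ScoreMatrix) else scores
    if cell_mask is not None:
        sc = sc.loc[cell_mask.reindex(sc.index).fillna(False).astype(bool)]
    samples = cell_to_sample.reindex(sc.index)
    sample_means = sc.groupby(samples).mean()
    n_cells_per_sample = sc.groupby(samples).size()
    flagged = n_cells_per_sample[n_cells_per_sample < min_cells].index.tolist()

    cond = sample_to_condition.reindex(sample_means.index)
    control_samples = cond.index[cond == control_condition]
    if len(control_samples) == 0:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    change = sample_means - sample_means.loc[control_samples].mean()

    variability = sample_means.std(axis=0, ddof=1)
    top = variability.sort_values(ascending=False, kind="mergesort").index[:top_n_variable]

    rows = []
    for condition in cond.dropna().unique():
        if condition == control_condition:
            continue
        cond_samples = cond.index[cond == condition]
        for family in top:
            a = sample_means.loc[cond_samples, family].to_numpy()
            b = sample_means.loc[control_samples, family].to_numpy()
            if len(a) < 2 or len(b) < 2:
                p = np.nan
            else:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            rows.append({"family": family, "condition": condition, "p": p})
    tests = pd.DataFrame(rows)
    if not tests.empty:
        tests["q"] = np.nan
        for condition, grp in tests.groupby("condition"):
            ok = grp["p"].notna()
            if ok.any():
                tests.loc[grp.index[ok], "q"] = multipletests(
                    grp.loc[ok, "p"], method="fdr_bh"
                )[1]

    return {
        "sample_means": sample_means,
        "change": change,
        "tests": tests,
        "low_cell_samples": flagged,
    }


def activated_fraction(
    scores: pd.Series,
    cell_to_sample: pd.Series,
    threshold: float = ACTIVATED_THRESHOLD,
) -> pd.Series:
    """Per-sample fraction of cells with score strictly above ``threshold``."""
    samples = cell_to_sample.reindex(scores.index)
    return (scores > threshold).groupby(samples).mean()


def heterogeneity_test(
    scores: pd.DataFrame | pd.Series,
    condition_labels: pd.Series,
    condition_pair: tuple[str, str],
    n_downsample: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sample KS test of score distributions after condition downsampling.

    Each condition is randomly downsampled to ``n_downsample`` cells (all
    cells, flagged, if fewer) before the Kolmogorov-Smirnov test.  Returns a
    DataFrame with p-value and downsampling flag per score column.
    """
    sc = scores.to_frame() if isinstance(scores, pd.Series) else scores
    labels = condition_labels.reindex(sc.index)
    rng = stream(seed, "heterogeneity-downsample")
    rows = []
    sampled = {}
    undersized = False
    for cond in condition_pair:
        cells = sc.index[labels == cond]
        if len(cells) == 0:
            raise ValueError(f"no cells in condition {cond!r}")
        if len(cells) > n_downsample:
            cells = pd.Index(rng.choice(cells, size=n_downsample, replace=False))
        else:
            undersized = True
        sampled[cond] = cells
    for col in sc.columns:
        a = sc.loc[sampled[condition_pair[0]], col].dropna()
        b = sc.loc[sampled[condition_pair[1]], col].dropna()
        p = stats.ks_2samp(a, b, method="asymp").pvalue if len(a) and len(b) else np.nan
        rows.append({"family": col, "p": p, "undersized": undersized})
    return pd.DataFrame(rows)


@dataclass
class ProgramModel:
    """A fitted gene-program (topic) model."""

    n_topics: int
    topic_gene: pd.DataFrame  # topics x genes, rows sum to 1
    cell_topic: pd.DataFrame  # cells x topics, rows sum to 1
    log_likelihoods: dict[int, float]


def fit_gene_programs(
    counts,
    topic_range: list[int],
    seed: int = 0,
    max_iter: int = 20,
) -> ProgramModel:
    """Fit LDA gene programs over a range of topic numbers, keep the best.

    Counts stay raw (no normalisation or binarisation).  One model is fitted
    per topic number and the one with the highest log-likelihood (variational
    bound on the training data) is selected.  All-zero cells are dropped with
    a warning.
    """
    if not topic_range:
        raise ValueError("topic_range must be non-empty")
    if isinstance(counts, pd.DataFrame):
        X = counts.to_numpy(dtype=float)
        cells, genes = counts.index, counts.columns
    else:
        X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
        cells = pd.RangeIndex(X.shape[0])
        genes = pd.RangeIndex(X.shape[1])
    nz = X.sum(axis=1) > 0
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} all-zero cells")
        X, cells = X[nz], cells[nz]

    fits: dict[int, LatentDirichletAllocation] = {}
    lls: dict[int, float] = {}
    for k in topic_range:
        lda = LatentDirichletAllocation(
            n_components=k, random_state=seed, max_iter=max_iter
        ).fit(X)
        fits[k] = lda
        lls[k] = float(lda.score(X))
    best_k = max(lls, key=lambda k: (lls[k], -k))
    best = fits[best_k]

    topic_gene = best.components_ / best.components_.sum(axis=1, keepdims=True)
    cell_topic = best.transform(X)
    topics = [f"program_{i}" for i in range(best_k)]
    return ProgramModel(
        n_topics=best_k,
        topic_gene=pd.DataFrame(topic_gene, index=topics, columns=genes),
        cell_topic=pd.DataFrame(cell_topic, index=cells, columns=topics),
        log_likelihoods=lls,
    )


def program_gene_lists(topic_gene: pd.Series | np.ndarray, top_n: int = 150):
    """Top ``top_n`` genes of a program by descending weight (ties by index)."""
    if isinstance(topic_gene, pd.Series):
        w = topic_gene.to_numpy()
        order = np.lexsort((np.arange(w.size), -w))[: min(top_n, w.size)]
        return topic_gene.index[order]
    w = np.asarray(topic_gene)
    return np.lexsort((np.arange(w.size), -w))[: min(top_n, w.size)]


def program_annotation_sets(topic_gene: pd.DataFrame) -> list[AnnotationSet]:
    """Weighted annotation sets (one per program) for deviation scoring."""
    sets = []
    for name, row in topic_gene.iterrows():
        w = row.to_numpy(dtype=float)
        members = np.nonzero(w > 0)[0]
        sets.append(AnnotationSet(name=str(name), members=members, weights=w[members]))
    return sets
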