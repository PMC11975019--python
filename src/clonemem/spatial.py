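"""Spatial tumor identification, segmentation and program scoring.

From a binned spatial expression section: QC-filter and depth-normalise
bins, call adenoma bins by smoothed marker-gene z-score, segment individual
tumors by community detection on a spatial k-NN graph of adenoma bins only,
and score each tumor's pseudobulk for a gene program with the same
background-corrected deviation statistic used for single cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from clonemem.neighbors import knn_smooth
from clonemem.scoring import AnnotationSet, deviation_scores

MIN_BIN_READS = 300
ADENOMA_Z_MIN = 1.0
HIGH_TUMOR_THRESHOLD = 1.5
SPATIAL_KNN = 5
SMOOTH_KNN = 20
N_PCS = 20


@dataclass
class SpatialSection:
    """A binned spatial expression section.

    ``bins`` carries (x, y) coordinates per bin; ``counts`` is bins x genes.
    ``truth`` holds generator ground truth when the section is synthetic.
    """

    bins: pd.DataFrame
    counts: pd.DataFrame
    tumor_label: pd.Series | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class TumorCall:
    tumor: int
    bins: list
    pseudobulk: pd.Series
    program_score: float = float("nan")

    @property
    def is_high(self) -> bool:
        return self.program_score > HIGH_TUMOR_THRESHOLD


def qc_and_normalize(
    section: SpatialSection, min_reads: int = MIN_BIN_READS
) -> tuple[SpatialSection, pd.DataFrame]:
    """Drop low-depth bins and normalise to the mean retained depth.

    Bins with fewer than ``min_reads`` total reads are dropped; remaining
    counts are scaled so every bin's total equals the mean depth of retained
    bins.  Returns the filtered/normalised section and the log2(x+1)
    transform of the normalised counts (used for embeddings).
    """
    depth = section.counts.sum(axis=1)
    keep = depth[depth >= min_reads].index
    if len(keep) == 0:
        raise ValueError("no bins pass the read-depth filter")
    counts = section.counts.loc[keep]
    mean_depth = counts.sum(axis=1).mean()
    norm = counts.div(counts.sum(axis=1), axis=0) * mean_depth
    filtered = SpatialSection(
        bins=section.bins.loc[keep], counts=norm, truth=section.truth
    )
    return filtered, np.log2(norm + 1)


def call_adenoma_bins(
    section: SpatialSection,
    log_counts: pd.DataFrame,
    marker: str,
    k_smooth: int = SMOOTH_KNN,
    z_min: float = ADENOMA_Z_MIN,
    n_pcs: int = N_PCS,
    seed: int = 0,
) -> tuple[pd.Series, dict]:
    """Call adenoma bins from smoothed, z-scored marker expression.

    The normalised counts' log transform is embedded with PCA (top
    ``n_pcs``); marker expression is mean-smoothed over each bin's
    ``k_smooth`` nearest neighbors in that embedding, z-scored across bins,
    and bins at z >= ``z_min`` are called.  A uniform marker (zero SD) yields
    no calls with a ``degenerate`` flag.
    """
    if marker not in section.counts.columns:
        raise ValueError(f"marker {marker!r} not in section genes")
    n_comp = min(n_pcs, log_counts.shape[0] - 1, log_counts.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(
        log_counts.to_numpy()
    )
    smoothed = knn_smooth(section.counts[marker].to_numpy(), pcs, k=k_smooth)
    sd = smoothed.std(ddof=1)
    if sd == 0:
        mask = pd.Series(False, index=section.counts.index)
        return mask, {"degenerate": True}
    z = (smoothed - smoothed.mean()) / sd
    mask = pd.Series(z >= z_min, index=section.counts.index)
    return mask, {"degenerate": False, "z": pd.Series(z, index=section.counts.index)}


def segment_tumors(
    coords: pd.DataFrame,
    k: int = SPATIAL_KNN,
    seed: int = 0,
    resolution: float = 0.1,
) -> tuple[pd.Series, dict]:
    """Segment adenoma bins into tumors via spatial k-NN + Louvain.

    ``coords`` holds (x, y) for adenoma bins only.  A symmetrised k-NN graph
    on bin-centre Euclidean distance is clustered with Louvain communities;
    each community is one tumor.  Fewer than k+1 bins yields a single tumor,
    flagged.  The default resolution is low (0.1): on k-NN graphs of a few
    hundred bins, modularity at resolution 1 splits a single contiguous
    region into several communities, while disconnected regions are never
    merged at any resolution, so a low resolution recovers contiguous
    tumors without risking under-segmentation of separated ones.
    """
    n = len(coords)
    if n == 0:
        raise ValueError("no adenoma bins to segment")
    if n < k + 1:
        return pd.Series(0, index=coords.index), {"too_few_bins": True}
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i][1:]:
            G.add_edge(i, int(j))
    comms = nx.algorithms.community.louvain_communities(
        G, seed=seed, resolution=resolution
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for t, members in enumerate(comms):
        labels[members] = t
    return pd.Series(labels, index=coords.index), {"too_few_bins": False}


def score_tumors(
    raw_counts: pd.DataFrame,
    tumor_labels: pd.Series,
    program_genes: list[str],
    n_background: int = 250,
    n_bins: int = 20,
    seed: int = 0,
) -> list[TumorCall]:
    """Score each tumor's pseudobulk for a gene program.

    Raw expression is pseudobulked by tumor call and the pseudobulks are
    scored with the deviation statistic, treating tumors as cells; a tumor is
    "high" iff its score is strictly above the high-tumor threshold.
    """
    labels = tumor_labels.reindex(raw_counts.index).dropna()
    bulk = raw_counts.loc[labels.index].groupby(labels).sum()
    genes = [g for g in program_genes if g in raw_counts.columns]
    if not genes:
        raise ValueError("no program genes present in the section")
    members = np.array([raw_counts.columns.get_loc(g) for g in genes])
    n_bins = min(n_bins, bulk.shape[1])
    sm = deviation_scores(
        bulk,
        [AnnotationSet(name="program", members=members)],
        n_background=n_background,
        seed=seed,
        n_bins=n_bins,
    )
    calls = []
    for tumor, score in sm.scores["program"].items():
        member_bins = labels.index[labels == tumor].tolist()
        calls.append(
            TumorCall(
                tumor=int(tumor),
                bins=member_bins,
                pseudobulk=bulk.loc[tumor],
                program_score=float(score),
            )
        )
    return calls


def find_tumors(
    section: SpatialSection,
    marker: str,
    program_genes: list[str],
    min_reads: int = MIN_BIN_READS,
    z_min: float = ADENOMA_Z_MIN,
    k_spatial: int = SPATIAL_KNN,
    seed: int = 0,
) -> tuple[list[TumorCall], pd.Series, dict]:
    """Full spatial pipeline: QC, adenoma calling, segmentation, scoring.

    Returns (tumor calls, per-bin tumor labels over adenoma bins, QC info).
    """
    filtered, log_counts = qc_and_normalize(section, min_reads=min_reads)
    mask, info = call_adenoma_bins(filtered, log_counts, marker, z_min=z_min, seed=seed)
    if not mask.any():
        return [], pd.Series(dtype=int), {"adenoma": info, "n_adenoma_bins": 0}
    coords = filtered.bins.loc[mask[mask].index]
    labels, seg_info = segment_tumors(coords, k=k_spatial, seed=seed)
    # score on raw (pre-normalisation) counts of the retained bins
    raw = section.counts.loc[filtered.counts.index]
    calls = score_tumors(raw, labels, program_genes, seed=seed)
    qc = {"adenoma": info, "segmentation": seg_info, "n_adenoma_bins": int(mask.sum())}
    return calls, labels, qc
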