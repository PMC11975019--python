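"""Synthetic-data generators for every pipeline stage.

Each generator plants the statistical structure the corresponding analysis
assumes — clone-structured score matrices with a within-clone variance
component, barcode reads with the vector's invariant stagger layout plus
sequencing errors, condition-dependent accessibility shifts with a
high-scoring subpopulation, footprint tables with co-occurring planted
memory gains, and spatial sections with contiguous marker-high tumor
regions — and returns the ground truth alongside the data so downstream
recovery is testable.  All randomness flows from ``SimulationConfig.seed``
through named independent streams, so the same config reproduces the same
data bit for bit and each modality can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from clonemem._rng import stream
from clonemem.barcode import BASES, DEFAULT_TEMPLATE, BarcodeTemplate
from clonemem.clones import CloneMap, levenshtein
from clonemem.scoring import AnnotationSet
from clonemem.spatial import SpatialSection

MIN_BARCODE_SEPARATION = 8  # planted clone barcodes: pairwise Levenshtein > 8


@dataclass
class SimulationConfig:
    """Shared knobs for the synthetic generators.

    ``clone_sd`` scales the planted within-clone score shift (a clone-level
    random effect); ``noise_sd`` is the per-cell score noise; ``conditions``
    maps condition labels to mean score shifts; ``frac_high_subpop`` is the
    fraction of case-condition clones/cells carrying an exceptionally high
    planted signal; ``error_rate`` is the per-base substitution probability
    for barcode reads; ``depth_lognormal`` gives (mu, sigma) of per-cell
    total counts.
    """

    seed: int = 0
    n_cells: int = 1000
    n_clones: int = 50
    n_features: int = 100
    clone_sd: float = 1.0
    noise_sd: float = 1.0
    conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 0.0, "recovered": 0.5}
    )
    frac_high_subpop: float = 0.1
    frac_high_control: float = 0.0
    high_shift: float = 3.0
    frac_heritable: float = 0.5
    error_rate: float = 0.0
    depth_lognormal: tuple[float, float] = (8.5, 0.35)

    def __post_init__(self):
        for name in ("n_cells", "n_clones", "n_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clones > self.n_cells:
            raise ValueError("n_clones must be <= n_cells")
        for name in ("frac_high_subpop", "frac_high_control", "frac_heritable",
                     "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clone_sd < 0:
            raise ValueError("clone_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.conditions:
            raise ValueError("at least one condition required")


# ---------------------------------------------------------------------------
# clone-structured score matrices


@dataclass
class ClonalScores:
    scores: pd.DataFrame  # cells x features
    clone_map: CloneMap
    cell_conditions: pd.Series
    truth: dict


def _clone_sizes(n_cells: int, n_clones: int) -> np.ndarray:
    base = n_cells // n_clones
    sizes = np.full(n_clones, base, dtype=int)
    sizes[: n_cells - base * n_clones] += 1
    return sizes


def simulate_clonal_scores(config: SimulationConfig) -> ClonalScores:
    """Scores with a planted clone-level variance component.

    The first ``frac_heritable`` fraction of features are "heritable": each
    clone draws an effect ~ N(0, clone_sd) added to all its cells, plus its
    condition's mean shift; the remaining features are null (clone effect 0,
    no shift).  On the first heritable feature, a ``frac_high_subpop``
    fraction of case-condition clones (``frac_high_control`` of control
    clones) get an extra ``high_shift``, creating the exceptional-memory
    subpopulation.  Per-cell noise is N(0, noise_sd) everywhere.
    """
    rng = stream(config.seed, "clonal-scores")
    sizes = _clone_sizes(config.n_cells, config.n_clones)
    clone_ids = [f"clone{j:04d}" for j in range(config.n_clones)]
    cells = pd.Index([f"cell{i:05d}" for i in range(config.n_cells)])
    cell_clone = pd.Series(np.repeat(clone_ids, sizes), index=cells)

    cond_labels = list(config.conditions)
    clone_condition = pd.Series(
        [cond_labels[j % len(cond_labels)] for j in range(config.n_clones)],
        index=clone_ids,
    )
    cell_conditions = cell_clone.map(clone_condition)

    n_her = int(round(config.frac_heritable * config.n_features))
    features = [
        f"feat{j:04d}_{'her' if j < n_her else 'null'}"
        for j in range(config.n_features)
    ]

    effects = np.zeros((config.n_clones, config.n_features))
    effects[:, :n_her] = rng.normal(0, config.clone_sd, size=(config.n_clones, n_her))

    # exceptional-memory clones on the first heritable feature
    high_clones = np.zeros(config.n_clones, dtype=bool)
    if n_her > 0:
        control = cond_labels[0]
        for cond in cond_labels:
            frac = (
                config.frac_high_control if cond == control else config.frac_high_subpop
            )
            members = np.nonzero((clone_condition == cond).to_numpy())[0]
            n_high = int(round(frac * members.size))
            if n_high:
                chosen = rng.choice(members, size=n_high, replace=False)
                high_clones[chosen] = True
                effects[chosen, 0] += config.high_shift

    shift = np.zeros((config.n_clones, config.n_features))
    if n_her > 0:
        shift[:, :n_her] = np.array(
            [config.conditions[c] for c in clone_condition]
        )[:, None]

    clone_idx = np.repeat(np.arange(config.n_clones), sizes)
    noise = rng.normal(0, config.noise_sd, size=(config.n_cells, config.n_features))
    X = effects[clone_idx] + shift[clone_idx] + noise
    scores = pd.DataFrame(X, index=cells, columns=features)

    clone_map = CloneMap(
        consensus_barcodes=set(clone_ids),
        cell_to_clone=cell_clone,
        clone_to_sample=clone_condition,
        clone_sizes=pd.Series(sizes, index=clone_ids),
        clone_purity=pd.Series(1.0, index=clone_ids),
    )
    truth = {
        "clone_effects": pd.DataFrame(effects, index=clone_ids, columns=features),
        "heritable_features": features[:n_her],
        "null_features": features[n_her:],
        "high_clones": pd.Series(high_clones, index=clone_ids),
        "signal_feature": features[0] if n_her else None,
    }
    return ClonalScores(scores, clone_map, cell_conditions, truth)


# ---------------------------------------------------------------------------
# barcode reads


@dataclass
class BarcodeReads:
    reads: pd.DataFrame  # columns: cell, umi, sequence
    clone_barcodes: dict[str, str]
    n_decoys: int


def _random_umi(rng: np.random.Generator, length: int) -> str:
    while True:
        umi = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        if umi != "G" * length:
            return umi


def sample_clone_barcodes(
    clones: list[str],
    template: BarcodeTemplate,
    rng: np.random.Generator,
    min_separation: int = MIN_BARCODE_SEPARATION,
    max_tries: int = 10_000,
) -> dict[str, str]:
    """Rejection-sample one template-valid 48-mer per clone, pairwise
    Levenshtein distance strictly greater than ``min_separation``."""
    chosen: list[str] = []
    for _ in range(len(clones)):
        for _ in range(max_tries):
            cand = template.render(rng)
            if all(levenshtein(cand, c) > min_separation for c in chosen):
                chosen.append(cand)
                break
        else:
            raise RuntimeError("could not sample well-separated barcodes")
    return dict(zip(clones, chosen))


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_barcode_reads(
    clone_map: CloneMap,
    config: SimulationConfig,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    reads_per_triple: int = 10,
    umis_per_cell: int = 3,
    decoy_fraction: float = 0.0,
    prefix: str = "CCGGA",
) -> BarcodeReads:
    """Barcode reads for every cell in ``clone_map``.

    Each read is prefix + anchor + the cell's clone barcode, with per-base
    substitutions at ``config.error_rate``; each cell emits
    ``umis_per_cell`` UMIs with ``reads_per_triple`` reads each.  A
    ``decoy_fraction`` of additional reads lack the anchor entirely (drawn
    from an A/C/G alphabet so no window comes within one mismatch of the
    anchor), exercising the parser's rejection path.
    """
    rng = stream(config.seed, "barcode-reads")
    clones = sorted(clone_map.consensus_barcodes)
    barcodes = sample_clone_barcodes(clones, template, rng)
    missing = set(clone_map.cell_to_clone.unique()) - set(barcodes)
    if missing:
        raise ValueError(f"clones without barcodes: {sorted(missing)[:3]}")

    rows = []
    for cell, clone in clone_map.cell_to_clone.items():
        clean = prefix + template.anchor + barcodes[clone]
        for _ in range(umis_per_cell):
            umi = _random_umi(rng, template.umi_length)
            for _ in range(reads_per_triple):
                rows.append((cell, umi, _mutate(clean, config.error_rate, rng)))

    n_decoys = int(round(decoy_fraction * len(rows) / max(1e-12, 1 - decoy_fraction))) \
        if decoy_fraction < 1 else 0
    cells = list(clone_map.cell_to_clone.index)
    decoy_len = len(prefix) + len(template.anchor) + template.barcode_length
    acg = "ACG"
    for _ in range(n_decoys):
        cell = cells[rng.integers(0, len(cells))]
        umi = _random_umi(rng, template.umi_length)
        seq = "".join(acg[b] for b in rng.integers(0, 3, size=decoy_len))
        rows.append((cell, umi, seq))

    reads = pd.DataFrame(rows, columns=["cell", "umi", "sequence"])
    # shuffle so decoys are interleaved like real data
    reads = reads.iloc[rng.permutation(len(reads))].reset_index(drop=True)
    return BarcodeReads(reads=reads, clone_barcodes=barcodes, n_decoys=n_decoys)


def write_fastq(reads: pd.DataFrame, path) -> None:
    """Write reads as 4-line FASTQ records (read name carries cell and UMI)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, r in enumerate(reads.itertuples(index=False)):
            fh.write(f"@read{i}:{r.cell}:{r.umi}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


# ---------------------------------------------------------------------------
# count matrices with motif-family annotations


@dataclass
class CountsAndAnnotations:
    counts: sp.csr_matrix  # cells x features
    cells: pd.Index
    cell_conditions: pd.Series
    annotation_sets: list[AnnotationSet]
    truth: dict


def simulate_counts_and_annotations(
    config: SimulationConfig,
    n_families: int = 5,
    family_size: int = 50,
    target_family: int = 0,
    condition_fold: float = 1.0,
    high_fold: float = 2.0,
) -> CountsAndAnnotations:
    """Sparse counts with annotated peak families and a planted shift.

    Per-cell depth is lognormal (``config.depth_lognormal``), rounded;
    counts are multinomial over per-feature rates (the Poisson model
    conditioned on the cell's total, so column sums conserve the drawn
    depth).  Cells in the case condition carry ``condition_fold`` on the
    target family's peaks, and a ``frac_high_subpop`` fraction of them an
    extra ``high_fold`` (the high subpopulation).
    """
    rng = stream(config.seed, "counts")
    n_cells, n_feat = config.n_cells, config.n_features
    if n_families * family_size > n_feat:
        raise ValueError("families do not fit in n_features")
    base = rng.gamma(2.0, 1.0, size=n_feat)

    sets = [
        AnnotationSet(
            name=f"family_{i}",
            members=np.arange(i * family_size, (i + 1) * family_size),
        )
        for i in range(n_families)
    ]
    cond_labels = list(config.conditions)
    control, case = cond_labels[0], cond_labels[-1]
    cell_conditions = pd.Series(
        [cond_labels[i % len(cond_labels)] for i in range(n_cells)],
        index=pd.Index([f"cell{i:05d}" for i in range(n_cells)]),
    )
    case_cells = np.nonzero((cell_conditions == case).to_numpy())[0]
    n_high = int(round(config.frac_high_subpop * case_cells.size))
    high = np.zeros(n_cells, dtype=bool)
    if n_high and case != control:
        high[rng.choice(case_cells, size=n_high, replace=False)] = True

    mu, sigma = config.depth_lognormal
    depths = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n_cells))).astype(int)

    target = sets[target_family].members
    rows = []
    for i in range(n_cells):
        w = base.copy()
        if cell_conditions.iloc[i] == case and case != control:
            w[target] *= condition_fold
        if high[i]:
            w[target] *= high_fold
        rows.append(rng.multinomial(depths[i], w / w.sum()))
    counts = sp.csr_matrix(np.asarray(rows))

    truth = {
        "depths": depths,
        "high_cells": pd.Series(high, index=cell_conditions.index),
        "target_family": sets[target_family].name,
        "case_condition": case,
        "control_condition": control,
    }
    return CountsAndAnnotations(
        counts=counts,
        cells=cell_conditions.index,
        cell_conditions=cell_conditions,
        annotation_sets=sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# footprint tables


@dataclass
class FootprintSim:
    table: pd.DataFrame  # peak, bin_start, condition, score
    family_sites: pd.DataFrame  # family, peak, bin_start
    peak_universe: pd.Index
    truth: dict


def simulate_footprints(
    config: SimulationConfig,
    n_peaks: int = 400,
    peak_length: int = 300,
    conditions: tuple[str, str] = ("control", "recovered"),
    families: tuple[str, str] = ("famA", "famB"),
    contingency: tuple[int, int, int, int] = (40, 20, 20, 320),
    delta: float = 0.3,
    pair_distance: int = 20,
    score_noise: float = 0.0,
) -> FootprintSim:
    """Per-condition footprint tables with planted co-occurring memory gains.

    Peaks are tiled in 10-bp bins with a shared baseline score drawn uniform
    on [0.25, 0.6] (above the exclusion threshold).  ``contingency`` =
    (both, first-only, second-only, neither) fixes which peaks carry memory
    sites of each family; planted sites gain ``delta`` in the case
    condition.  In "both" peaks the two families' sites sit ``pair_distance``
    bp apart (rounded to bin resolution).
    """
    both, first, second, neither = contingency
    if both + first + second + neither != n_peaks:
        raise ValueError("contingency must sum to n_peaks")
    rng = stream(config.seed, "footprints")
    n_bins = peak_length // 10
    peaks = pd.Index([f"peak{j:04d}" for j in range(n_peaks)])
    control, case = conditions

    baseline = rng.uniform(0.25, 0.6, size=(n_peaks, n_bins))

    order = rng.permutation(n_peaks)
    both_p = order[:both]
    first_p = order[both : both + first]
    second_p = order[both + first : both + first + second]

    bins_apart = max(1, round(pair_distance / 10))
    site_rows, planted = [], []
    for p in both_p:
        a_bin = int(rng.integers(0, n_bins - bins_apart))
        b_bin = a_bin + bins_apart
        site_rows += [
            (families[0], peaks[p], a_bin * 10),
            (families[1], peaks[p], b_bin * 10),
        ]
        planted += [
            (families[0], peaks[p], a_bin * 10),
            (families[1], peaks[p], b_bin * 10),
        ]
    for fam, plist in ((families[0], first_p), (families[1], second_p)):
        for p in plist:
            b = int(rng.integers(0, n_bins))
            site_rows.append((fam, peaks[p], b * 10))
            planted.append((fam, peaks[p], b * 10))
    family_sites = pd.DataFrame(site_rows, columns=["family", "peak", "bin_start"])

    planted_set = {(f, p, b) for f, p, b in planted}
    records = []
    peak_of = {pk: j for j, pk in enumerate(peaks)}
    gain = np.zeros((n_peaks, n_bins))
    for f, pk, b in planted_set:
        gain[peak_of[pk], b // 10] = delta
    for cond in conditions:
        scores = baseline.copy()
        if cond == case:
            scores = scores + gain
        if score_noise > 0:
            scores = scores + rng.normal(0, score_noise, size=scores.shape)
        for j, pk in enumerate(peaks):
            for b in range(n_bins):
                records.append((pk, b * 10, cond, scores[j, b]))
    table = pd.DataFrame(records, columns=["peak", "bin_start", "condition", "score"])

    truth = {
        "planted_sites": {
            fam: {(p, b) for f, p, b in planted_set if f == fam} for fam in families
        },
        "contingency": dict(zip(("both", "first_only", "second_only", "neither"),
                                contingency)),
        "delta": delta,
        "pair_distance_bp": bins_apart * 10,
        "case": case,
        "control": control,
    }
    return FootprintSim(table, family_sites, peaks, truth)


# ---------------------------------------------------------------------------
# spatial sections


def simulate_spatial_section(
    config: SimulationConfig,
    shape: tuple[int, int] = (40, 40),
    n_blobs: int = 2,
    blob_radius: float = 4.0,
    min_separation: float = 15.0,
    n_genes: int = 60,
    marker: str = "Axin2",
    n_program_genes: int = 15,
    marker_fold: float = 5.0,
    program_fold: float = 3.0,
    frac_high: float = 0.5,
    depth_mean: float = 1200.0,
) -> SpatialSection:
    """A gridded spatial section with planted marker-high tumor blobs.

    Bins lie on a regular grid; ``n_blobs`` circular tumor regions (radius
    ``blob_radius`` bins, centres at least ``min_separation`` apart) carry
    ``marker_fold`` elevated marker expression, and a ``frac_high`` fraction
    of blobs additionally carry ``program_fold`` on the program genes.
    Ground truth (per-bin tumor id, high-blob flags, program gene names) is
    stored on the section.
    """
    rng = stream(config.seed, "spatial")
    nx_, ny = shape
    xs, ys = np.meshgrid(np.arange(nx_), np.arange(ny), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n_bins = coords.shape[0]
    bin_ids = pd.Index([f"bin{j:05d}" for j in range(n_bins)])

    # place blob centres with rejection sampling for separation
    centres: list[np.ndarray] = []
    margin = blob_radius + 1
    for _ in range(100_000):
        if len(centres) == n_blobs:
            break
        cand = rng.uniform([margin, margin], [nx_ - margin, ny - margin])
        if all(np.linalg.norm(cand - c) >= min_separation for c in centres):
            centres.append(cand)
    if len(centres) < n_blobs:
        raise RuntimeError("could not place blobs with the requested separation")

    tumor_label = np.full(n_bins, -1, dtype=int)
    for t, c in enumerate(centres):
        inside = np.linalg.norm(coords - c, axis=1) <= blob_radius
        tumor_label[inside] = t

    n_high = int(round(frac_high * n_blobs))
    high_blobs = np.zeros(n_blobs, dtype=bool)
    if n_high:
        high_blobs[rng.choice(n_blobs, size=n_high, replace=False)] = True

    genes = [marker] + [f"gene{j:03d}" for j in range(n_genes - 1)]
    program_genes = genes[1 : 1 + n_program_genes]
    base = rng.gamma(2.0, 1.0, size=n_genes)
    marker_idx = 0
    program_idx = np.arange(1, 1 + n_program_genes)

    depths = np.maximum(
        1, np.round(rng.lognormal(np.log(depth_mean), 0.25, size=n_bins))
    ).astype(int)
    counts = np.zeros((n_bins, n_genes), dtype=int)
    for j in range(n_bins):
        w = base.copy()
        t = tumor_label[j]
        if t >= 0:
            w[marker_idx] *= marker_fold
            if high_blobs[t]:
                w[program_idx] *= program_fold
        counts[j] = rng.multinomial(depths[j], w / w.sum())

    return SpatialSection(
        bins=pd.DataFrame(coords, index=bin_ids, columns=["x", "y"]),
        counts=pd.DataFrame(counts, index=bin_ids, columns=genes),
        tumor_label=pd.Series(tumor_label, index=bin_ids),
        truth={
            "tumor_label": pd.Series(tumor_label, index=bin_ids),
            "high_blobs": pd.Series(high_blobs, index=range(n_blobs)),
            "program_genes": program_genes,
            "marker": marker,
            "centres": np.array(centres),
        },
    )
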