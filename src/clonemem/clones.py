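"""Clone assignment from expressed lineage-barcode reads.

The pipeline: (1) locate the anchor 7-mer in each read (at most one
mismatch), trim it and everything before it, and validate the following
48-mer against the invariant stagger layout; (2) count reads per
cell-UMI-barcode triple and drop poorly supported triples; (3) collapse
sequencing errors into consensus barcodes with a two-stage Levenshtein
procedure; (4) assign each cell to the clone supported by the plurality of
its UMIs, assign each clone to the sample contributing most of its cells,
and keep only clones with enough cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from clonemem.barcode import DEFAULT_TEMPLATE, BarcodeTemplate

# rejection categories (parser totality: every read gets exactly one)
OK = "OK"
NO_ANCHOR = "NO_ANCHOR"
SHORT = "SHORT"
INVARIANT_FAIL = "INVARIANT_FAIL"
POLYG_UMI = "POLYG_UMI"

MIN_READS = 5
MIN_CELLS = 5
COLLAPSE_D1 = 4
COLLAPSE_D2 = 2


@dataclass
class CloneMap:
    """Cell→clone and clone→sample assignments with supporting evidence."""

    consensus_barcodes: set[str]
    cell_to_clone: pd.Series  # cell id -> clone id (a consensus barcode)
    clone_to_sample: pd.Series
    clone_sizes: pd.Series
    clone_purity: pd.Series  # fraction of member cells from the majority sample
    ambiguous_cells: list = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.clone_sizes)


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def _hamming_le(window: str, anchor: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(window, anchor):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def parse_read(
    sequence: str,
    umi: str,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    max_anchor_mismatch: int = 1,
) -> tuple[str | None, str]:
    """Extract the 48-bp barcode from a read, or categorise the rejection.

    The anchor is the FIRST window (left to right) within Hamming distance
    ``max_anchor_mismatch`` of the anchor 7-mer; the anchor and all preceding
    bases are trimmed.  Rejections: NO_ANCHOR, SHORT (fewer than 48 bp after
    the anchor), POLYG_UMI (UMI is all G), INVARIANT_FAIL (a stagger 2-mer is
    wrong).  Exactly one category is returned per read.
    """
    anchor = template.anchor
    la = len(anchor)
    pos = -1
    for i in range(len(sequence) - la + 1):
        if _hamming_le(sequence[i : i + la], anchor, max_anchor_mismatch):
            pos = i
            break
    if pos < 0:
        return None, NO_ANCHOR
    rest = sequence[pos + la :]
    if len(rest) < template.barcode_length:
        return None, SHORT
    if umi == "G" * len(umi):
        return None, POLYG_UMI
    barcode = rest[: template.barcode_length]
    if not template.check_invariants(barcode):
        return None, INVARIANT_FAIL
    return barcode, OK


def count_triples(
    reads: pd.DataFrame, template: BarcodeTemplate = DEFAULT_TEMPLATE
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Parse reads and count them per (cell, UMI, barcode) triple.

    ``reads`` has columns cell, umi, sequence.  Returns the triple table
    (cell, umi, barcode48, read_count) and per-category rejection counts.
    """
    categories = {OK: 0, NO_ANCHOR: 0, SHORT: 0, INVARIANT_FAIL: 0, POLYG_UMI: 0}
    rows = []
    for r in reads.itertuples(index=False):
        barcode, why = parse_read(r.sequence, r.umi, template)
        categories[why] += 1
        if barcode is not None:
            rows.append((r.cell, r.umi, barcode))
    if rows:
        triples = (
            pd.DataFrame(rows, columns=["cell", "umi", "barcode48"])
            .groupby(["cell", "umi", "barcode48"], sort=False)
            .size()
            .rename("read_count")
            .reset_index()
        )
    else:
        triples = pd.DataFrame(columns=["cell", "umi", "barcode48", "read_count"])
    return triples, categories


def filter_support(triples: pd.DataFrame, min_reads: int = MIN_READS) -> pd.DataFrame:
    """Keep exactly the triples with read_count >= ``min_reads``."""
    return triples[triples["read_count"] >= min_reads].reset_index(drop=True)


def collapse_barcodes(
    abundances: pd.Series | dict,
    d1: int = COLLAPSE_D1,
    d2: int = COLLAPSE_D2,
) -> tuple[set[str], dict[str, str]]:
    """Two-stage Levenshtein collapse of observed barcodes.

    Stage 1: each barcode maps to the most abundant barcode within edit
    distance ``d1`` of it (itself included); ties broken lexicographically.
    Stage 2: among the resulting representatives, any representative within
    distance ``d2`` of a more abundant one collapses to it (one pass, with
    equal-abundance ties again lexicographic).  Returns the consensus set and
    the full barcode→consensus mapping.  Raises if the final consensus set is
    not pairwise separated by more than ``d2``.
    """
    ab = pd.Series(abundances, dtype=float)
    if ab.empty:
        return set(), {}
    if (ab <= 0).any():
        raise ValueError("abundances must be positive")
    seqs = list(ab.index)

    def best(candidates: list[str]) -> str:
        top = max(ab[c] for c in candidates)
        return min(c for c in candidates if ab[c] == top)

    # stage 1: map to most abundant within d1
    map1: dict[str, str] = {}
    for s in seqs:
        cands = [t for t in seqs if levenshtein(s, t) <= d1]
        map1[s] = best(cands)

    # stage 2: one pass over representatives within d2
    reps = sorted(set(map1.values()))
    map2: dict[str, str] = {}
    for r in reps:
        cands = [t for t in reps if levenshtein(r, t) <= d2]
        map2[r] = best(cands)

    def resolve(r: str) -> str:
        seen = {r}
        while map2[r] != r:
            r = map2[r]
            if r in seen:  # defensive; tie rule prevents cycles
                break
            seen.add(r)
        return r

    mapping = {s: resolve(map1[s]) for s in seqs}
    consensus = set(mapping.values())
    final = sorted(consensus)
    for i, a in enumerate(final):
        for b in final[i + 1 :]:
            if levenshtein(a, b) <= d2:
                raise RuntimeError(
                    "consensus barcodes not separated by more than "
                    f"{d2} edits: {a!r} vs {b!r}"
                )
    return consensus, mapping


def assign_clones(
    triples: pd.DataFrame,
    consensus_map: dict[str, str],
    cell_samples: pd.Series,
    min_cells: int = MIN_CELLS,
) -> CloneMap:
    """Assign cells to clones and clones to samples.

    A cell goes to the clone supported by the plurality of its UMIs (triples
    mapped through ``consensus_map``); cells with a tied plurality are
    flagged ambiguous and excluded.  Clones with fewer than ``min_cells``
    cells are dropped.  Each surviving clone is assigned to the sample
    contributing the most member cells, with the majority fraction reported
    as purity.
    """
    t = triples.copy()
    t["clone"] = t["barcode48"].map(consensus_map)
    if t["clone"].isna().any():
        missing = t.loc[t["clone"].isna(), "barcode48"].unique()[:3]
        raise ValueError(f"barcodes without consensus assignment, e.g. {missing}")

    cell_clone: dict = {}
    ambiguous = []
    for cell, grp in t.groupby("cell", sort=False):
        support = grp.groupby("clone", sort=False)["umi"].nunique()
        top = support.max()
        winners = support.index[support == top]
        if len(winners) > 1:
            ambiguous.append(cell)
        else:
            cell_clone[cell] = winners[0]

    assigned = pd.Series(cell_clone, name="clone")
    sizes = assigned.value_counts()
    keep = sizes.index[sizes >= min_cells]
    assigned = assigned[assigned.isin(keep)]
    sizes = sizes.loc[keep]

    clone_sample = {}
    purity = {}
    samples = cell_samples.reindex(assigned.index)
    for clone, members in assigned.groupby(assigned):
        counts = samples.loc[members.index].value_counts()
        clone_sample[clone] = counts.index[0]
        purity[clone] = counts.iloc[0] / counts.sum()

    return CloneMap(
        consensus_barcodes=set(sizes.index),
        cell_to_clone=assigned,
        clone_to_sample=pd.Series(clone_sample),
        clone_sizes=sizes,
        clone_purity=pd.Series(purity),
        ambiguous_cells=ambiguous,
    )


def call_clones(
    reads: pd.DataFrame,
    cell_samples: pd.Series,
    template: BarcodeTemplate = DEFAULT_TEMPLATE,
    min_reads: int = MIN_READS,
    min_cells: int = MIN_CELLS,
    d1: int = COLLAPSE_D1,
    d2: int = COLLAPSE_D2,
) -> tuple[CloneMap, dict]:
    """Full clone-calling pipeline from raw reads; returns (CloneMap, QC)."""
    triples, categories = count_triples(reads, template)
    kept = filter_support(triples, min_reads)
    if kept.empty:
        raise ValueError("no triples survive the read-support filter")
    abundance = kept.groupby("barcode48")["read_count"].sum()
    consensus, mapping = collapse_barcodes(abundance, d1=d1, d2=d2)
    clone_map = assign_clones(kept, mapping, cell_samples, min_cells=min_cells)
    qc = {
        "rejections": categories,
        "n_triples": int(len(triples)),
        "n_triples_supported": int(len(kept)),
        "n_raw_barcodes": int(abundance.size),
        "n_consensus": len(consensus),
        "n_ambiguous_cells": len(clone_map.ambiguous_cells),
    }
    return clone_map, qc
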