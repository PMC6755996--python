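"""ChIP binding scores and cross-dataset consensus peaks.

Mirrors the expression-score idea on the binding side: a gene's binding
score for a factor is the number of ChIP datasets that place a peak near
its transcription start site (midpoint within a strand-agnostic window,
±5 kb for p53 and ±1 kb for E2F4/DREAM by convention). Peaks from many
datasets are also merged into *consensus peaks* — single-linkage unions of
overlapping intervals — whose support (number of distinct contributing
datasets) defines high-confidence binding-site sets.

All intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusPeak",
    "peak_midpoints",
    "tss_binding_hits",
    "assign_peaks_to_tss",
    "build_consensus_peaks",
    "consensus_to_frame",
]

#: TSS window defaults per factor (bp each side of the TSS)
DEFAULT_WINDOWS = {"p53": 5000, "E2F4_DREAM": 1000}


@dataclass
class ConsensusPeak:
    """Merged interval spanning the union of overlapping peaks across datasets."""

    chrom: str
    start: int
    end: int
    dataset_ids: frozenset = field(default_factory=frozenset)

    @property
    def support(self) -> int:
        return len(self.dataset_ids)

    @property
    def midpoint(self) -> int:
        # even-length convention: start + floor(len/2)
        return self.start + (self.end - self.start) // 2


def peak_midpoints(peaks: pd.DataFrame) -> np.ndarray:
    """Integer midpoints, start + floor(len/2), of a BED-like frame."""
    start = peaks["start"].to_numpy(dtype=np.int64)
    end = peaks["end"].to_numpy(dtype=np.int64)
    return start + (end - start) // 2


def tss_binding_hits(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int,
) -> pd.DataFrame:
    """Per-gene, per-dataset TSS-proximal binding events.

    A dataset hits a gene iff at least one of its peaks has its midpoint
    within ``[tss - window, tss + window]`` inclusive. Returns one row per
    (gene_id, dataset_id) hit; multiple qualifying peaks from the same
    dataset still yield one row.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    known = set(annotation["chrom"].unique())
    bad = set(peaks["chrom"].unique()) - known
    if bad:
        warnings.warn(
            f"skipping peaks on chromosomes absent from annotation: {sorted(bad)}"
        )
        peaks = peaks[peaks["chrom"].isin(known)]

    rows: list[tuple[str, str]] = []
    for chrom, ann_c in annotation.groupby("chrom"):
        pk_c = peaks[peaks["chrom"] == chrom]
        if pk_c.empty:
            continue
        mids = peak_midpoints(pk_c)
        order = np.argsort(mids, kind="stable")
        mids = mids[order]
        ds = pk_c["dataset_id"].to_numpy()[order]
        tss = ann_c["tss"].to_numpy(dtype=np.int64)
        lo = np.searchsorted(mids, tss - window, side="left")
        hi = np.searchsorted(mids, tss + window, side="right")
        for gene_id, a, b in zip(ann_c["gene_id"], lo, hi):
            if b > a:
                rows.extend((gene_id, d) for d in set(ds[a:b]))
    return pd.DataFrame(rows, columns=["gene_id", "dataset_id"])


def assign_peaks_to_tss(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    window: int,
) -> pd.DataFrame:
    """Count, per gene, the datasets with a peak midpoint near its TSS.

    Parameters
    ----------
    peaks
        Frame with columns chrom, start, end, dataset_id (peaks pooled
        over datasets); each dataset contributes at most 1 per gene.
    annotation
        Frame with columns gene_id, chrom, tss (strand is irrelevant for
        a symmetric window).
    window
        Half-width of the promoter window in bp, > 0.

    Returns
    -------
    DataFrame gene_id, n_datasets_bound covering every annotated gene
    (zero where no dataset has a nearby peak).
    """
    hits = tss_binding_hits(peaks, annotation, window)
    counts = hits.groupby("gene_id").size() if not hits.empty else pd.Series(dtype=int)
    out = pd.DataFrame({"gene_id": sorted(annotation["gene_id"].unique())})
    out["n_datasets_bound"] = out["gene_id"].map(counts).fillna(0).astype(int)
    return out


def build_consensus_peaks(
    peak_sets: dict[str, pd.DataFrame],
    min_support: int = 1,
) -> list[ConsensusPeak]:
    """Merge peaks across datasets into consensus intervals.

    Peaks overlapping by >= 1 bp (half-open: touching intervals do not
    overlap) are merged transitively, so a chain A-B-C collapses into one
    interval spanning their union even if A and C are disjoint. Support
    counts distinct contributing datasets, not peaks. Consensus peaks with
    support below ``min_support`` are dropped; output is sorted by
    (chrom, start).
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    frames = []
    for dataset_id, df in peak_sets.items():
        f = df[["chrom", "start", "end"]].copy()
        f["dataset_id"] = dataset_id
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    if (pooled["start"] >= pooled["end"]).any():
        raise ValueError("peak with start >= end")

    out: list[ConsensusPeak] = []
    for chrom, grp in pooled.groupby("chrom"):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur_start = cur_end = None
        cur_ds: set = set()
        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_ds = row.start, row.end, {row.dataset_id}
            elif row.start < cur_end:  # >=1 bp overlap under half-open coords
                cur_end = max(cur_end, row.end)
                cur_ds.add(row.dataset_id)
            else:
                out.append(
                    ConsensusPeak(chrom, int(cur_start), int(cur_end), frozenset(cur_ds))
                )
                cur_start, cur_end, cur_ds = row.start, row.end, {row.dataset_id}
        if cur_start is not None:
            out.append(
                ConsensusPeak(chrom, int(cur_start), int(cur_end), frozenset(cur_ds))
            )
    out = [p for p in out if p.support >= min_support]
    out.sort(key=lambda p: (p.chrom, p.start))
    return out


def consensus_to_frame(consensus: list[ConsensusPeak]) -> pd.DataFrame:
    """BED-like frame (chrom, start, end, support) from consensus peaks."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in consensus],
            "start": [p.start for p in consensus],
            "end": [p.end for p in consensus],
            "support": [p.support for p in consensus],
        }
    )
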