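"""Cross-genome projection of binding sites and conservation profiles.

Binding-site *turnover* — evolutionary gain and loss of transcription
factor binding sites — is measured by projecting one species' sites
through a chain-style pairwise genome alignment onto the other genome and
asking whether the projected interval overlaps a binding site there.
Sites falling outside alignable sequence are *unmappable* and excluded
from the conserved fraction, which is computed only over sites present in
both genomes:

    conserved fraction = overlapping / (overlapping + non-overlapping).

Per-base conservation tracks (phastCons-style) are averaged in a fixed
window around site centers to profile the evolutionary constraint on the
underlying DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Chain",
    "AlignmentMap",
    "MappedInterval",
    "parse_chain_file",
    "invert_alignment",
    "map_intervals",
    "classify_turnover",
    "conserved_fraction",
    "conservation_profile",
]


@dataclass
class Chain:
    """One co-linear alignment chain (plus-strand source and target).

    ``src_starts[i]:src_ends[i]`` on the source chromosome aligns base-
    for-base to ``tgt_starts[i]:...`` on the target chromosome.
    """

    source_chrom: str
    target_chrom: str
    src_starts: np.ndarray
    src_ends: np.ndarray
    tgt_starts: np.ndarray
    chain_id: int = 0

    def covered_bases(self, start: int, end: int) -> int:
        """Bases of [start, end) lying inside aligned blocks."""
        lo = np.minimum(np.maximum(self.src_starts, start), end)
        hi = np.minimum(np.maximum(self.src_ends, start), end)
        return int(np.maximum(hi - lo, 0).sum())

    def map_base(self, pos: int) -> int | None:
        """Target image of one source base, or None if in a gap."""
        i = int(np.searchsorted(self.src_starts, pos, side="right")) - 1
        if i >= 0 and pos < self.src_ends[i]:
            return int(self.tgt_starts[i] + (pos - self.src_starts[i]))
        return None


@dataclass
class AlignmentMap:
    """Ordered collection of chains between two genomes."""

    chains: list[Chain] = field(default_factory=list)

    def for_chrom(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.source_chrom == chrom]


@dataclass
class MappedInterval:
    chrom: str
    start: int
    end: int
    status: str  # "mapped" | "unmapped"
    target_chrom: str | None = None
    target_start: int | None = None
    target_end: int | None = None
    mapped_fraction: float = 0.0


def parse_chain_file(path) -> AlignmentMap:
    """Parse a UCSC chain file (plus-strand alignments only).

    Header: ``chain score tName tSize tStrand tStart tEnd qName qSize
    qStrand qStart qEnd id``; data lines are ``size dt dq`` triples with a
    bare ``size`` terminating each chain. Here the *target* (t) side of
    the file is the source genome and the *query* (q) side the genome
    mapped onto, matching liftover semantics.
    """
    chains: list[Chain] = []
    header = None
    blocks: list[tuple[int, int, int]] = []

    def finish():
        nonlocal header, blocks
        if header is None:
            return
        (t_name, t_start, q_name, q_start, chain_id) = header
        src_starts, src_ends, tgt_starts = [], [], []
        s, q = t_start, q_start
        for size, dt, dq in blocks:
            src_starts.append(s)
            src_ends.append(s + size)
            tgt_starts.append(q)
            s += size + dt
            q += size + dq
        chains.append(
            Chain(
                t_name,
                q_name,
                np.asarray(src_starts, dtype=np.int64),
                np.asarray(src_ends, dtype=np.int64),
                np.asarray(tgt_starts, dtype=np.int64),
                chain_id,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                f = line.split()
                if len(f) != 13:
                    raise ValueError(f"line {lineno}: malformed chain header")
                if f[4] != "+" or f[9] != "+":
                    raise ValueError(
                        f"line {lineno}: only plus-strand chains are supported"
                    )
                header = (f[2], int(f[5]), f[7], int(f[10]), int(f[12]))
            else:
                f = line.split()
                if header is None or len(f) not in (1, 3):
                    raise ValueError(f"line {lineno}: malformed chain data line")
                size = int(f[0])
                if size <= 0:
                    raise ValueError(f"line {lineno}: zero-length aligned block")
                dt = int(f[1]) if len(f) == 3 else 0
                dq = int(f[2]) if len(f) == 3 else 0
                blocks.append((size, dt, dq))
    finish()
    return AlignmentMap(chains)


def invert_alignment(amap: AlignmentMap) -> AlignmentMap:
    """Swap source and target genomes (blocks are 1:1, so exact)."""
    inv = []
    for c in amap.chains:
        lengths = c.src_ends - c.src_starts
        order = np.argsort(c.tgt_starts, kind="stable")
        inv.append(
            Chain(
                c.target_chrom,
                c.source_chrom,
                c.tgt_starts[order],
                (c.tgt_starts + lengths)[order],
                c.src_starts[order],
                c.chain_id,
            )
        )
    return AlignmentMap(inv)


def map_intervals(
    intervals: pd.DataFrame,
    amap: AlignmentMap,
    min_match: float = 0.1,
) -> list[MappedInterval]:
    """Project intervals onto the other genome through the alignment.

    An interval maps iff at least ``min_match`` of its bases fall inside
    aligned blocks of a single best chain (the chain covering the most of
    its bases; ties broken by chain order in the file). The target
    interval spans from the image of its first aligned base to the image
    of its last, inclusive. The default ``min_match=0.1`` follows
    cross-species liftover practice, where large parts of an interval
    routinely fall into alignment gaps.
    """
    if not 0 < min_match <= 1:
        raise ValueError("min_match must be in (0, 1]")
    by_chrom: dict[str, list[Chain]] = {}
    for c in amap.chains:
        by_chrom.setdefault(c.source_chrom, []).append(c)

    out: list[MappedInterval] = []
    for row in intervals.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        length = end - start
        best, best_cov = None, 0
        for c in by_chrom.get(chrom, []):
            cov = c.covered_bases(start, end)
            if cov > best_cov:
                best, best_cov = c, cov
        frac = best_cov / length if length else 0.0
        if best is None or frac < min_match:
            out.append(MappedInterval(chrom, start, end, "unmapped", mapped_fraction=frac))
            continue
        # first/last aligned base within the interval
        lo = np.minimum(np.maximum(best.src_starts, start), end)
        hi = np.minimum(np.maximum(best.src_ends, start), end)
        hit = np.nonzero(hi - lo > 0)[0]
        first = int(lo[hit[0]])
        last = int(hi[hit[-1]]) - 1
        t_first = best.map_base(first)
        t_last = best.map_base(last)
        out.append(
            MappedInterval(
                chrom,
                start,
                end,
                "mapped",
                target_chrom=best.target_chrom,
                target_start=t_first,
                target_end=t_last + 1,
                mapped_fraction=frac,
            )
        )
    return out


def conserved_fraction(n_overlapping: int, n_nonoverlapping: int) -> float:
    """Percent of sites present in both genomes that are conserved for binding.

    Unmappable sites are excluded upstream: the denominator counts only
    sites whose sequence exists in both genomes.
    """
    total = n_overlapping + n_nonoverlapping
    if total == 0:
        return 0.0
    return 100.0 * n_overlapping / total


def classify_turnover(
    mapped: list[MappedInterval],
    target_consensus_peaks: pd.DataFrame,
) -> dict:
    """Partition projected sites into unmappable / non-overlapping / overlapping.

    A projected site counts as *overlapping* (conserved for binding) when
    its target-genome image shares >= 1 bp with any consensus peak of the
    target species. Returns counts plus the conserved fraction in percent.
    """
    peaks = target_consensus_peaks.sort_values(["chrom", "start"])
    by_chrom = {
        chrom: (
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
        )
        for chrom, grp in peaks.groupby("chrom")
    }
    n_unmap = n_nonover = n_over = 0
    overlapping_flags = []
    for m in mapped:
        if m.status != "mapped":
            n_unmap += 1
            overlapping_flags.append(None)
            continue
        starts, ends = by_chrom.get(m.target_chrom, (np.array([]), np.array([])))
        # any peak with start < m.target_end and end > m.target_start
        i = np.searchsorted(starts, m.target_end, side="left")
        hit = bool((ends[:i] > m.target_start).any()) if i else False
        if hit:
            n_over += 1
        else:
            n_nonover += 1
        overlapping_flags.append(hit)
    return {
        "unmappable": n_unmap,
        "mapped_nonoverlapping": n_nonover,
        "mapped_overlapping": n_over,
        "conserved_fraction_pct": conserved_fraction(n_over, n_nonover),
        "overlapping_flags": overlapping_flags,
    }


def conservation_profile(
    sites: pd.DataFrame,
    track: pd.DataFrame,
    flank: int = 2500,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean conservation score per bp offset around site centers.

    ``track`` is bedGraph-like (chrom, start, end, value). Each site
    contributes its window [center - flank, center + flank]; windows
    running past a chromosome end (when ``chrom_sizes`` is given) or below
    zero are dropped. Bases with no track segment are *excluded* from the
    mean at that offset, not treated as zero — conservation tracks are
    sparse and zero-imputation would bias profiles downward.

    Returns a frame (offset, mean, n) with NaN mean where n == 0.
    """
    if sites.empty:
        raise ValueError("empty site set")
    seg = {
        chrom: (
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
            grp["value"].to_numpy(dtype=float),
        )
        for chrom, grp in track.sort_values(["chrom", "start"]).groupby("chrom")
    }
    width = 2 * flank + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=np.int64)
    offsets = np.arange(-flank, flank + 1)
    for row in sites.itertuples(index=False):
        center = int(row.start) + (int(row.end) - int(row.start)) // 2
        lo, hi = center - flank, center + flank
        if lo < 0:
            continue
        if chrom_sizes is not None and hi >= chrom_sizes.get(row.chrom, np.inf):
            continue
        starts, ends, vals = seg.get(row.chrom, (np.array([]), np.array([]), np.array([])))
        pos = center + offsets
        if starts.size == 0:
            continue
        idx = np.searchsorted(starts, pos, side="right") - 1
        valid = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        total[valid] += vals[idx[valid]]
        count[valid] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean": mean, "n": count})
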