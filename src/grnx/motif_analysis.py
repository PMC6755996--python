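"""Consensus-motif scanning and genomic-feature enrichment of peak sets.

The canonical p53 response element (p53RE) is two decameric half sites,
RRRCWWGYYY, here modelled with no spacer between the half sites — the
dominant canonical arrangement. E2F (TTSSSSS) and CHR (TTYGAA) elements,
the short promoter motifs bound by DREAM-associated machinery, use the
same machinery. Each IUPAC consensus is expanded into a position weight
matrix: permitted bases at a position get count 1, non-permitted bases a
pseudocount, columns are normalised and scored as log-odds against a
uniform background. A window is a hit when its log-odds score reaches a
fixed fraction of the matrix's maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotifModel",
    "p53re_model",
    "e2f_model",
    "chr_model",
    "scan_sequence",
    "fraction_peaks_with_motif",
    "genome_wide_motif_count",
    "feature_enrichment",
    "FEATURE_PRIORITY",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """Log-odds scoring matrix derived from an IUPAC consensus."""

    name: str
    consensus: str
    threshold: float = 0.85  # fraction of the maximum log-odds score
    pseudocount: float = 0.25
    logodds: np.ndarray = field(init=False, repr=False)  # (5, width); row 4 = N
    max_score: float = field(init=False)

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        width = len(self.consensus)
        probs = np.empty((4, width))
        for j, sym in enumerate(self.consensus.upper()):
            allowed = IUPAC[sym]
            col = np.array(
                [1.0 if b in allowed else self.pseudocount for b in _BASES]
            )
            probs[:, j] = col / col.sum()
        lo = np.log2(probs / 0.25)
        # N scores as background (log-odds 0) at every position
        self.logodds = np.vstack([lo, np.zeros((1, width))])
        self.max_score = float(lo.max(axis=0).sum())

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def score_cutoff(self) -> float:
        return self.threshold * self.max_score


def p53re_model(threshold: float = 0.85) -> MotifModel:
    """Full-site p53RE: two RRRCWWGYYY half sites, zero spacer."""
    return MotifModel("p53RE", "RRRCWWGYYY" * 2, threshold)


def e2f_model(threshold: float = 0.85) -> MotifModel:
    return MotifModel("E2F", "TTSSSSS", threshold)


def chr_model(threshold: float = 0.85) -> MotifModel:
    return MotifModel("CHR", "TTYGAA", threshold)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)  # anything unexpected scores as N
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    return code[arr]


def _scan_strand(codes: np.ndarray, model: MotifModel) -> np.ndarray:
    """Log-odds score at every window start position."""
    w = model.width
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return model.logodds[windows, np.arange(w)].sum(axis=1)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_sequence(
    seq: str, model: MotifModel, chrom: str = ".", offset: int = 0
) -> pd.DataFrame:
    """All motif hits on both strands of ``seq``.

    Returns a BED6-like frame (chrom, start, end, name, score, strand) in
    coordinates of the forward strand, shifted by ``offset``. Overlapping
    hits on opposite strands are reported separately.
    """
    if len(seq) < model.width:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
    rows = []
    fwd = _scan_strand(_encode(seq), model)
    cut = model.score_cutoff
    for i in np.nonzero(fwd >= cut)[0]:
        rows.append((chrom, offset + int(i), offset + int(i) + model.width,
                     model.name, float(fwd[i]), "+"))
    rev = _scan_strand(_encode(reverse_complement(seq)), model)
    L = len(seq)
    for i in np.nonzero(rev >= cut)[0]:
        start = L - int(i) - model.width
        rows.append((chrom, offset + start, offset + start + model.width,
                     model.name, float(rev[i]), "-"))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return out.sort_values(["start", "strand"], ignore_index=True)


def fraction_peaks_with_motif(
    consensus_peaks: pd.DataFrame,
    genome: dict[str, str],
    model: MotifModel,
) -> tuple[float, int]:
    """Fraction and count of peaks containing at least one motif hit.

    ``genome`` maps chromosome name to sequence (a ``pyfaidx.Fasta``
    works too via ``str()`` on slices).
    """
    if consensus_peaks.empty:
        raise ValueError("empty peak set")
    n_with = 0
    for row in consensus_peaks.itertuples(index=False):
        seq = genome[row.chrom]
        clen = len(seq)
        if row.end > clen or row.start < 0:
            raise ValueError(
                f"peak {row.chrom}:{row.start}-{row.end} outside contig (len {clen})"
            )
        sub = str(seq[row.start : row.end])
        if not scan_sequence(sub, model).empty:
            n_with += 1
    return n_with / len(consensus_peaks), n_with


def genome_wide_motif_count(genome: dict[str, str], model: MotifModel) -> int:
    """Total motif hits over both strands of every contig."""
    total = 0
    for chrom in genome:
        total += len(scan_sequence(str(genome[chrom][:]), model, chrom))
    return total


#: midpoint assignment priority, highest first
FEATURE_PRIORITY = [
    "promoter_1kb",
    "promoter_1to5kb",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "distal_intergenic",
]


def feature_enrichment(
    peaks: pd.DataFrame,
    features: pd.DataFrame,
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Observed vs expected genomic-feature distribution of peak midpoints.

    ``features`` is BED-like (chrom, start, end, feature) with feature
    names from :data:`FEATURE_PRIORITY`. Overlaps are resolved by
    priority (promoters win over UTRs, exons over introns, ...); genome
    not covered by any feature counts as distal intergenic. The expected
    fraction of a feature is its share of the genome after priority
    resolution, so observed and expected fractions each sum to 1.
    Enrichment = observed / expected; reported as NaN where a feature
    covers zero bp.
    """
    prio = {f: i for i, f in enumerate(FEATURE_PRIORITY)}
    unknown = set(features["feature"].unique()) - set(prio)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    n_classes = len(FEATURE_PRIORITY)
    distal = n_classes - 1

    genome_bp = 0
    class_bp = np.zeros(n_classes, dtype=np.int64)
    observed = np.zeros(n_classes, dtype=np.int64)
    for chrom, size in chrom_sizes.items():
        lab = np.full(size, distal, dtype=np.int8)
        fc = features[features["chrom"] == chrom]
        # paint lowest priority first so higher priority overwrites
        for f in reversed(FEATURE_PRIORITY[:-1]):
            for row in fc[fc["feature"] == f].itertuples(index=False):
                lab[max(row.start, 0) : min(row.end, size)] = prio[f]
        genome_bp += size
        class_bp += np.bincount(lab, minlength=n_classes)
        pk = peaks[peaks["chrom"] == chrom]
        if not pk.empty:
            mids = pk["start"].to_numpy(np.int64) + (
                pk["end"].to_numpy(np.int64) - pk["start"].to_numpy(np.int64)
            ) // 2
            if (mids < 0).any() or (mids >= size).any():
                raise ValueError(f"peak midpoint outside {chrom}")
            observed += np.bincount(lab[mids], minlength=n_classes)

    n_peaks = observed.sum()
    if n_peaks == 0:
        raise ValueError("no peaks on annotated chromosomes")
    obs_frac = observed / n_peaks
    exp_frac = class_bp / genome_bp
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(exp_frac > 0, obs_frac / exp_frac, np.nan)
    return pd.DataFrame(
        {
            "feature": FEATURE_PRIORITY,
            "observed_n": observed,
            "observed_fraction": obs_frac,
            "expected_fraction": exp_frac,
            "enrichment": enr,
        }
    )
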