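"""Two-species synthetic test universe with known ground truth.

Emulates the ingredients of a cross-species TF-network meta-analysis
without any downloads: for two species (A and B, single-chromosome
genomes) it fabricates

* many noisy differential-expression datasets with planted up/down
  regulation per gene,
* p53 and E2F4/DREAM ChIP peak sets with per-dataset dropout placed at
  true binding sites near target TSSs,
* an orthology table dominated by one-to-one pairs,
* a co-linear block alignment between the two genomes (UCSC chain),
* a per-base conservation track elevated inside alignable blocks,
* genome sequences with concrete p53RE / E2F / CHR motif instances
  embedded at the planted binding sites,

together with a ground-truth record of every planted regulation class,
binding site and conserved element, so each pipeline stage can be scored
against truth.

Layout: each gene lives in a 6 kb cassette with the TSS at its center;
cassettes are separated by filler, so neighbouring promoter windows never
overlap. A cassette or filler segment is either *aligned* (identical
sequence, one chain block) or species-private. Cassettes of pairs whose
regulation class is conserved are always aligned, which makes their
planted binding sites mappable between genomes; other segments are
aligned with probability ``conserved_block_fraction``.

Noise model: a truly regulated gene carries an effect size
|log2FC| = 0.5 + Gamma(shape 2, scale 0.5) in every dataset, and crosses
the significance threshold (adj. p <= 0.05) with probability
``detection_sensitivity`` — so sensitivity alone governs detection.
Unregulated genes get log2FC ~ Normal(0, 0.2) and a null p-value; a
spurious significant call in a random direction is forced with
probability ``false_call_rate``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_conservation import AlignmentMap, Chain

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_scenario",
    "write_fixture_bundle",
]

REGULATION_CLASSES = [
    "conserved_up",
    "conserved_down",
    "A_up_only",
    "B_up_only",
    "A_down_only",
    "B_down_only",
    "opposite",
    "unregulated",
]

CASSETTE = 6000  # bp per gene cassette, TSS at the center
_SITE_MAX_OFFSET_P53 = 2000
_SITE_MAX_OFFSET_E2F4 = 300


@dataclass
class ScenarioConfig:
    """Tunable parameters of the synthetic universe (all rates in [0,1])."""

    n_genes_per_species: int = 120
    frac_one_to_one: float = 0.9
    regulation_class_probs: dict = field(
        default_factory=lambda: {
            "conserved_up": 0.10,
            "conserved_down": 0.10,
            "A_up_only": 0.06,
            "B_up_only": 0.06,
            "A_down_only": 0.04,
            "B_down_only": 0.04,
            "opposite": 0.02,
            "unregulated": 0.58,
        }
    )
    n_expression_datasets_per_species: int = 15
    detection_sensitivity: float = 0.9
    false_call_rate: float = 0.02
    n_chip_datasets: dict = field(
        default_factory=lambda: {
            "A": {"p53": 9, "E2F4_DREAM": 7},
            "B": {"p53": 28, "E2F4_DREAM": 9},
        }
    )
    peak_dropout: float = 0.2
    noise_peaks_per_dataset: int = 3
    genome_length: int = 2_000_000
    conserved_block_fraction: float = 0.6
    rng_seed: int = 0

    def validate(self) -> None:
        probs = self.regulation_class_probs
        if set(probs) != set(REGULATION_CLASSES):
            raise ValueError(
                f"regulation_class_probs must cover exactly {REGULATION_CLASSES}"
            )
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ValueError("class probabilities must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("regulation_class_probs must sum to 1")
        for name in ("frac_one_to_one", "detection_sensitivity",
                     "false_call_rate", "peak_dropout",
                     "conserved_block_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes_per_species", "n_expression_datasets_per_species",
                     "genome_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for sp, d in self.n_chip_datasets.items():
            for factor, n in d.items():
                if n < 1:
                    raise ValueError(f"n_chip_datasets[{sp}][{factor}] must be >= 1")
        if self.genome_length < self.n_genes_per_species * (CASSETTE + 4000):
            raise ValueError(
                "genome_length too small for gene count: need >= "
                f"{self.n_genes_per_species * (CASSETTE + 4000)} bp"
            )


@dataclass
class GroundTruth:
    """What was planted: regulation classes, directions and binding sites."""

    genes: pd.DataFrame  # gene_id, species, chrom, tss, strand, reg_class,
    #                      direction, direct_target, dream_target, ortholog_partner
    sites: pd.DataFrame  # site_id, species, factor, chrom, start, end,
    #                      gene_id, conserved, motif_embedded
    pairs: pd.DataFrame  # gene_A, gene_B, reg_class
    class_counts: dict = field(default_factory=dict)


@dataclass
class Scenario:
    config: ScenarioConfig
    expression: dict  # species -> {dataset_id -> DataFrame}
    expression_config: pd.DataFrame
    chip: dict  # species -> {factor -> {dataset_id -> DataFrame}}
    chip_config: pd.DataFrame
    orthology: pd.DataFrame
    annotation: dict  # species -> genes DataFrame
    features: dict  # species -> BED-like feature DataFrame
    alignment: AlignmentMap  # A -> B
    conservation: dict  # species -> bedGraph DataFrame
    genomes: dict  # species -> str
    truth: GroundTruth

    @property
    def chrom(self) -> dict:
        return {"A": "chrA", "B": "chrB"}


# ---------------------------------------------------------------------------
# genome layout


def _directions(reg_class: str, opposite_a_up: bool) -> tuple[str, str]:
    """Per-species regulation direction ('up'/'down'/'none') of a pair."""
    table = {
        "conserved_up": ("up", "up"),
        "conserved_down": ("down", "down"),
        "A_up_only": ("up", "none"),
        "B_up_only": ("none", "up"),
        "A_down_only": ("down", "none"),
        "B_down_only": ("none", "down"),
        "unregulated": ("none", "none"),
    }
    if reg_class == "opposite":
        return ("up", "down") if opposite_a_up else ("down", "up")
    return table[reg_class]


def _sample_consensus(consensus: str, rng: np.random.Generator) -> str:
    from .motif_analysis import IUPAC

    return "".join(rng.choice(list(IUPAC[s])) for s in consensus)


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full two-species universe. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_genes_per_species
    n_pairs = int(round(config.frac_one_to_one * n))
    n_single = n - n_pairs

    # regulation class per pair (multinomial draw, recorded in truth)
    class_names = REGULATION_CLASSES
    p = np.array([config.regulation_class_probs[c] for c in class_names])
    pair_classes = rng.choice(class_names, size=n_pairs, p=p / p.sum())
    opposite_a_up = rng.random(n_pairs) < 0.5

    # slots: pairs plus species-private genes, shuffled along the genome
    slots: list[tuple[str, int]] = [("pair", i) for i in range(n_pairs)]
    slots += [("A", i) for i in range(n_single)]
    slots += [("B", i) for i in range(n_single)]
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    n_cassettes = len(slots)
    mean_filler = max(
        4000.0, (config.genome_length - n * CASSETTE) / (n_cassettes + 1)
    )

    seq: dict[str, list[str]] = {"A": [], "B": []}
    pos = {"A": 0, "B": 0}
    aligned_blocks: list[tuple[int, int, int]] = []  # (a_start, b_start, length)
    aligned_intervals: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}

    def emit_filler():
        length = int(mean_filler * rng.uniform(0.5, 1.5))
        if rng.random() < config.conserved_block_fraction:
            s = _random_seq(rng, length)
            aligned_blocks.append((pos["A"], pos["B"], length))
            for sp in "AB":
                aligned_intervals[sp].append((pos[sp], pos[sp] + length))
                seq[sp].append(s)
                pos[sp] += length
        else:
            for sp in "AB":
                ln = int(mean_filler * rng.uniform(0.5, 1.5))
                seq[sp].append(_random_seq(rng, ln))
                pos[sp] += ln

    gene_rows = []  # gene_id, species, tss, strand, reg_class, direction, partner
    pair_rows = []

    emit_filler()
    for kind, idx in slots:
        if kind == "pair":
            reg_class = str(pair_classes[idx])
            dir_a, dir_b = _directions(reg_class, bool(opposite_a_up[idx]))
            gid_a, gid_b = f"geneA{idx:04d}", f"geneB{idx:04d}"
            conserved_cassette = reg_class in ("conserved_up", "conserved_down") or (
                rng.random() < config.conserved_block_fraction
            )
            strand_a = str(rng.choice(["+", "-"]))
            strand_b = strand_a if conserved_cassette else str(rng.choice(["+", "-"]))
            if conserved_cassette:
                s = _random_seq(rng, CASSETTE)
                aligned_blocks.append((pos["A"], pos["B"], CASSETTE))
                for sp in "AB":
                    aligned_intervals[sp].append((pos[sp], pos[sp] + CASSETTE))
            tss = {}
            for sp, gid, d, strand in (
                ("A", gid_a, dir_a, strand_a),
                ("B", gid_b, dir_b, strand_b),
            ):
                if not conserved_cassette:
                    s = _random_seq(rng, CASSETTE)
                seq[sp].append(s)
                tss[sp] = pos[sp] + CASSETTE // 2
                pos[sp] += CASSETTE
                gene_rows.append(
                    (gid, sp, tss[sp], strand, reg_class, d,
                     gid_b if sp == "A" else gid_a, conserved_cassette)
                )
            pair_rows.append((gid_a, gid_b, reg_class))
        else:
            sp, i = kind, idx
            gid = f"gene{sp}x{i:04d}"
            strand = str(rng.choice(["+", "-"]))
            seq[sp].append(_random_seq(rng, CASSETTE))
            tss_sp = pos[sp] + CASSETTE // 2
            pos[sp] += CASSETTE
            gene_rows.append((gid, sp, tss_sp, strand, "unregulated", "none", "", False))
        emit_filler()

    chrom = {"A": "chrA", "B": "chrB"}
    genome_len = {sp: pos[sp] for sp in "AB"}

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "species", "tss", "strand", "reg_class",
                 "direction", "ortholog_partner", "aligned_cassette"],
    )
    genes["chrom"] = genes["species"].map(chrom)

    # ------------------------------------------------------------------
    # true binding sites (p53 for up-regulated genes, E2F4 for down)
    site_rows = []
    site_counter = 0
    pair_site_offsets: dict[str, tuple[int, int]] = {}
    for g in genes.itertuples(index=False):
        if g.direction == "none":
            continue
        factor = "p53" if g.direction == "up" else "E2F4_DREAM"
        max_off = _SITE_MAX_OFFSET_P53 if factor == "p53" else _SITE_MAX_OFFSET_E2F4
        conserved = g.reg_class in ("conserved_up", "conserved_down")
        key = g.ortholog_partner if g.species == "B" else g.gene_id
        if conserved and key in pair_site_offsets:
            off, width = pair_site_offsets[key]
        else:
            if factor == "p53":
                width = int(rng.integers(200, 401))
            else:
                width = int(rng.integers(150, 251))
            off = int(rng.integers(-max_off, max_off + 1))
            if conserved:
                pair_site_offsets[key] = (off, width)
        center = g.tss + off
        start, end = center - width // 2, center - width // 2 + width
        site_rows.append(
            (f"site{site_counter:05d}", g.species, factor, chrom[g.species],
             start, end, g.gene_id, conserved, True)
        )
        site_counter += 1
    sites = pd.DataFrame(
        site_rows,
        columns=["site_id", "species", "factor", "chrom", "start", "end",
                 "gene_id", "conserved", "motif_embedded"],
    )

    # embed motif instances; conserved pair sites share the instance
    genome_arr = {
        sp: np.frombuffer("".join(seq[sp]).encode("ascii"), dtype=np.uint8).copy()
        for sp in "AB"
    }
    gene_key = dict(zip(genes["gene_id"], genes["ortholog_partner"]))
    pair_motif: dict[str, str] = {}
    for s in sites.itertuples(index=False):
        # conserved pairs keyed by the A-side gene so both embed one instance
        key = gene_key[s.gene_id] if s.species == "B" else s.gene_id
        if s.factor == "p53":
            consensus = "RRRCWWGYYY" * 2
        else:
            consensus = "TTSSSSS" + "TTYGAA"  # E2F element followed by CHR
        if s.conserved and key in pair_motif:
            instance = pair_motif[key]
        else:
            instance = _sample_consensus(consensus, rng)
            if s.conserved:
                pair_motif[key] = instance
        center = s.start + (s.end - s.start) // 2
        at = center - len(instance) // 2
        genome_arr[s.species][at : at + len(instance)] = np.frombuffer(
            instance.encode("ascii"), dtype=np.uint8
        )

    genomes = {sp: genome_arr[sp].tobytes().decode("ascii") for sp in "AB"}

    # ------------------------------------------------------------------
    # chain A -> B from the aligned block list
    aligned_blocks.sort()
    chain = Chain(
        chrom["A"],
        chrom["B"],
        np.array([b[0] for b in aligned_blocks], dtype=np.int64),
        np.array([b[0] + b[2] for b in aligned_blocks], dtype=np.int64),
        np.array([b[1] for b in aligned_blocks], dtype=np.int64),
        chain_id=1,
    )
    alignment = AlignmentMap([chain])

    # ------------------------------------------------------------------
    # expression datasets
    expression: dict[str, dict[str, pd.DataFrame]] = {"A": {}, "B": {}}
    expr_cfg_rows = []
    n_ds = config.n_expression_datasets_per_species
    for sp in "AB":
        sp_genes = genes[genes["species"] == sp]
        directions = sp_genes["direction"].to_numpy()
        m = len(sp_genes)
        sign = np.where(directions == "up", 1.0, np.where(directions == "down", -1.0, 0.0))
        regulated = sign != 0
        for d in range(n_ds):
            dataset_id = f"{sp}_expr{d:02d}"
            study_id = f"{sp}_estudy{d // 2:02d}"
            expr_cfg_rows.append((dataset_id, study_id, sp, 0.5, 0.05))
            effect = sign * (0.5 + rng.gamma(2.0, 0.5, size=m))
            lfc = np.where(regulated, effect, rng.normal(0.0, 0.2, size=m))
            detected = rng.random(m) < config.detection_sensitivity
            adj_p = np.where(
                regulated & detected,
                rng.uniform(0.0, 0.05, size=m),
                rng.uniform(0.051, 1.0, size=m),
            )
            # forced spurious calls on unregulated genes
            flip = (~regulated) & (rng.random(m) < config.false_call_rate)
            flip_sign = rng.choice([-1.0, 1.0], size=m)
            lfc = np.where(flip, flip_sign * (0.5 + rng.gamma(2.0, 0.5, size=m)), lfc)
            adj_p = np.where(flip, rng.uniform(0.0, 0.05, size=m), adj_p)
            # un-flipped unregulated genes must never cross both thresholds
            leak = (~regulated) & ~flip & (np.abs(lfc) >= 0.5) & (adj_p <= 0.05)
            adj_p = np.where(leak, rng.uniform(0.06, 1.0, size=m), adj_p)
            expression[sp][dataset_id] = pd.DataFrame(
                {
                    "gene_id": sp_genes["gene_id"].to_numpy(),
                    "log2fc": np.round(lfc, 6),
                    "adj_p": np.round(adj_p, 8),
                }
            )
    expression_config = pd.DataFrame(
        expr_cfg_rows, columns=["dataset_id", "study_id", "species", "lfc_min", "p_max"]
    )

    # ------------------------------------------------------------------
    # ChIP peak sets with per-dataset dropout + jitter + background noise
    chip: dict[str, dict[str, dict[str, pd.DataFrame]]] = {"A": {}, "B": {}}
    chip_cfg_rows = []
    for sp in "AB":
        for factor, n_sets in config.n_chip_datasets[sp].items():
            chip[sp][factor] = {}
            fsites = sites[(sites["species"] == sp) & (sites["factor"] == factor)]
            for d in range(n_sets):
                dataset_id = f"{sp}_{factor}_chip{d:02d}"
                study_id = f"{sp}_{factor}_cstudy{d // 2:02d}"
                chip_cfg_rows.append((dataset_id, study_id, factor, sp))
                keep = rng.random(len(fsites)) >= config.peak_dropout
                kept = fsites[keep]
                jl = rng.integers(0, 31, size=len(kept))
                jr = rng.integers(0, 31, size=len(kept))
                rows = pd.DataFrame(
                    {
                        "chrom": kept["chrom"].to_numpy(),
                        "start": np.maximum(kept["start"].to_numpy() - jl, 0),
                        "end": kept["end"].to_numpy() + jr,
                    }
                )
                n_noise = config.noise_peaks_per_dataset
                if n_noise:
                    ns = rng.integers(0, genome_len[sp] - 400, size=n_noise)
                    noise = pd.DataFrame(
                        {"chrom": chrom[sp], "start": ns, "end": ns + 300}
                    )
                    rows = pd.concat([rows, noise], ignore_index=True)
                chip[sp][factor][dataset_id] = rows.sort_values(
                    ["start"], ignore_index=True
                )
    chip_config = pd.DataFrame(
        chip_cfg_rows, columns=["dataset_id", "study_id", "factor", "species"]
    )

    # ------------------------------------------------------------------
    # orthology: one2one pairs plus a couple of one2many rows
    orth_rows = [(a, b, "ortholog_one2one") for a, b, _ in pair_rows]
    singles_a = [g for g in genes[genes["species"] == "A"]["gene_id"] if "x" in g]
    singles_b = [g for g in genes[genes["species"] == "B"]["gene_id"] if "x" in g]
    if singles_a and len(singles_b) >= 2:
        orth_rows.append((singles_a[0], singles_b[0], "ortholog_one2many"))
        orth_rows.append((singles_a[0], singles_b[1], "ortholog_one2many"))
    orthology = pd.DataFrame(orth_rows, columns=["gene_A", "gene_B", "homology_type"])

    # ------------------------------------------------------------------
    # annotation + genomic features per species
    annotation = {}
    features = {}
    for sp in "AB":
        sp_genes = genes[genes["species"] == sp]
        annotation[sp] = sp_genes[["gene_id", "chrom", "tss", "strand"]].reset_index(
            drop=True
        )
        feat_rows = []
        for g in sp_genes.itertuples(index=False):
            sgn = 1 if g.strand == "+" else -1

            def iv(a, b):
                lo, hi = sorted((g.tss + sgn * a, g.tss + sgn * b))
                return max(lo, 0), min(hi, genome_len[sp])

            for (a, b), name in (
                ((-1000, 0), "promoter_1kb"),
                ((-5000, -1000), "promoter_1to5kb"),
                ((0, 200), "utr5"),
                ((200, 700), "exon"),
                ((700, 2400), "intron"),
                ((2400, 2700), "exon"),
                ((2700, 2900), "utr3"),
            ):
                lo, hi = iv(a, b)
                if hi > lo:
                    feat_rows.append((chrom[sp], lo, hi, name))
        features[sp] = (
            pd.DataFrame(feat_rows, columns=["chrom", "start", "end", "feature"])
            .sort_values(["start"], ignore_index=True)
        )

    # ------------------------------------------------------------------
    # conservation tracks: elevated in aligned blocks, peaked at conserved sites
    conservation = {}
    for sp in "AB":
        ivs = sorted(aligned_intervals[sp])
        cons_sites = sites[(sites["species"] == sp) & sites["conserved"]]
        site_spans = list(zip(cons_sites["start"], cons_sites["end"]))
        segs = []
        cursor = 0
        for lo, hi in ivs + [(genome_len[sp], genome_len[sp])]:
            if cursor < lo:  # unaligned stretch
                for s0 in range(cursor, lo, 500):
                    e0 = min(s0 + 500, lo)
                    segs.append((s0, e0, round(rng.uniform(0.0, 0.3), 4)))
            for s0 in range(lo, hi, 500):
                e0 = min(s0 + 500, hi)
                hot = any(a < e0 and b > s0 for a, b in site_spans)
                val = rng.uniform(0.85, 1.0) if hot else rng.uniform(0.4, 0.9)
                segs.append((s0, e0, round(val, 4)))
            cursor = max(cursor, hi)
        conservation[sp] = pd.DataFrame(
            [(chrom[sp], s, e, v) for s, e, v in segs],
            columns=["chrom", "start", "end", "value"],
        )

    genes_out = genes.copy()
    genes_out["direct_target"] = (genes_out["direction"] == "up")
    genes_out["dream_target"] = (genes_out["direction"] == "down")
    truth = GroundTruth(
        genes=genes_out[
            ["gene_id", "species", "chrom", "tss", "strand", "reg_class",
             "direction", "direct_target", "dream_target", "ortholog_partner",
             "aligned_cassette"]
        ].reset_index(drop=True),
        sites=sites,
        pairs=pd.DataFrame(pair_rows, columns=["gene_A", "gene_B", "reg_class"]),
        class_counts={
            str(k): int(v) for k, v in pd.Series(pair_classes).value_counts().items()
        },
    )

    return Scenario(
        config=config,
        expression=expression,
        expression_config=expression_config,
        chip=chip,
        chip_config=chip_config,
        orthology=orthology,
        annotation=annotation,
        features=features,
        alignment=alignment,
        conservation=conservation,
        genomes=genomes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization


def _chain_text(amap: AlignmentMap, src_len: int, tgt_len: int) -> str:
    lines = []
    for c in amap.chains:
        t0, t1 = int(c.src_starts[0]), int(c.src_ends[-1])
        lengths = c.src_ends - c.src_starts
        q0 = int(c.tgt_starts[0])
        q1 = int(c.tgt_starts[-1] + lengths[-1])
        lines.append(
            f"chain 1000 {c.source_chrom} {src_len} + {t0} {t1} "
            f"{c.target_chrom} {tgt_len} + {q0} {q1} {c.chain_id}"
        )
        for i in range(len(lengths)):
            if i + 1 < len(lengths):
                dt = int(c.src_starts[i + 1] - c.src_ends[i])
                dq = int(c.tgt_starts[i + 1] - (c.tgt_starts[i] + lengths[i]))
                lines.append(f"{lengths[i]} {dt} {dq}")
            else:
                lines.append(f"{lengths[i]}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_fixture_bundle(scenario: Scenario, out_dir) -> pd.DataFrame:
    """Write every scenario artifact in its external format, plus a manifest.

    Returns the manifest (path, role, format, sha256). Identical scenarios
    produce byte-identical files.
    """
    from pathlib import Path

    out = Path(out_dir)
    entries: list[tuple[str, str, str]] = []

    def save(relpath: str, text: str, role: str, fmt: str):
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        entries.append((relpath, role, fmt))

    def tsv(df: pd.DataFrame) -> str:
        return df.to_csv(sep="\t", index=False)

    for sp in "AB":
        for dataset_id, df in scenario.expression[sp].items():
            save(f"expression/{sp}/{dataset_id}.tsv", tsv(df),
                 "differential expression", "tsv")
        for factor, sets in scenario.chip[sp].items():
            for dataset_id, df in sets.items():
                bed = df.to_csv(sep="\t", index=False, header=False)
                save(f"chip/{sp}/{factor}/{dataset_id}.bed", bed, "chip peaks", "bed")
        save(f"annotation/{sp}_genes.tsv", tsv(scenario.annotation[sp]),
             "gene annotation", "tsv")
        save(f"annotation/{sp}_features.bed",
             scenario.features[sp].to_csv(sep="\t", index=False, header=False),
             "genomic features", "bed")
        save(f"conservation/{sp}.bedGraph",
             scenario.conservation[sp].to_csv(sep="\t", index=False, header=False),
             "conservation track", "bedgraph")
        g = scenario.genomes[sp]
        chrom = scenario.chrom[sp]
        fa = f">{chrom}\n" + "\n".join(
            g[i : i + 80] for i in range(0, len(g), 80)
        ) + "\n"
        save(f"genomes/{sp}.fa", fa, "genome sequence", "fasta")
    save("expression_datasets.tsv", tsv(scenario.expression_config),
         "expression dataset config", "tsv")
    save("chip_datasets.tsv", tsv(scenario.chip_config), "chip dataset config", "tsv")
    save("orthology.tsv", tsv(scenario.orthology), "orthology table", "tsv")
    save(
        "alignment_A_to_B.chain",
        _chain_text(
            scenario.alignment,
            len(scenario.genomes["A"]),
            len(scenario.genomes["B"]),
        ),
        "pairwise alignment",
        "chain",
    )
    save("ground_truth_genes.tsv", tsv(scenario.truth.genes), "ground truth", "tsv")
    save("ground_truth_sites.tsv", tsv(scenario.truth.sites), "ground truth", "tsv")

    rows = []
    for relpath, role, fmt in entries:
        digest = hashlib.sha256((out / relpath).read_bytes()).hexdigest()
        rows.append((relpath, role, fmt, digest))
    manifest = pd.DataFrame(rows, columns=["path", "role", "format", "sha256"])
    (out / "manifest.tsv").write_text(tsv(manifest))
    return manifest
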