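"""End-to-end pipeline: files in, report bundle out.

Reads a fixture-bundle-style input directory (per-dataset expression TSVs,
per-dataset ChIP BEDs, gene annotation, orthology table, chain alignment,
conservation tracks, genomes), runs every stage in dependency order —
expression scoring, binding scoring and consensus peaks, direct-target and
DREAM-candidate calling, ortholog pairing and divergence classification,
cross-genome site mapping and turnover, conservation profiles, motif and
feature analysis, over-representation — and writes one TSV per stage plus
a plain-text summary. Reruns with identical config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding_conservation import (
    classify_turnover,
    conservation_profile,
    invert_alignment,
    map_intervals,
    parse_chain_file,
)
from .binding_score import (
    assign_peaks_to_tss,
    build_consensus_peaks,
    consensus_to_frame,
    tss_binding_hits,
)
from .expression_score import calls_from_tables, compute_expression_scores
from .functional_enrichment import enrich, read_gmt
from .motif_analysis import (
    feature_enrichment,
    fraction_peaks_with_motif,
    genome_wide_motif_count,
    p53re_model,
)
from .ortholog_comparison import (
    build_ortholog_pairs,
    classify_divergence,
    correlate_scores,
    intersect_direct_targets,
)
from .target_calling import call_direct_targets, call_dream_candidates

__all__ = ["PipelineConfig", "run_pipeline", "pair_site_conservation"]

SPECIES = ("A", "B")
FACTORS = ("p53", "E2F4_DREAM")


@dataclass
class PipelineConfig:
    """Every input path and threshold of the analysis, with defaults.

    ``chip_min`` scales with each species' ChIP compendium size (3-of-9
    style for A, 5-of-28 style for B); ``min_support`` defines the
    high-confidence consensus peak sets per species and factor.
    """

    input_dir: str = "."
    out_dir: str = "report"
    gmt: str | None = None
    lfc_min: float = 0.5
    p_max: float = 0.05
    min_present: int = 3
    window_p53: int = 5000
    window_e2f4: int = 1000
    es_min: int = 5
    chip_min: dict = field(default_factory=lambda: {"A": 3, "B": 5})
    dream_es_max: int = -5
    dream_chip_min: int = 3
    diff_min: int = 8
    other_support_max: int = 3
    min_support: dict = field(
        default_factory=lambda: {
            "A": {"p53": 4, "E2F4_DREAM": 4},
            "B": {"p53": 5, "E2F4_DREAM": 4},
        }
    )
    min_match: float = 0.1
    flank: int = 2500
    motif_threshold: float = 0.85
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash over analysis parameters only: where files live does not
        change what the pipeline computes."""
        params = asdict(self)
        params.pop("input_dir")
        params.pop("out_dir")
        text = yaml.safe_dump(params, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _read_fasta(path) -> dict[str, str]:
    genomes: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genomes[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        genomes[name] = "".join(chunks)
    return genomes


def pair_site_conservation(
    pairs: pd.DataFrame,
    consensus_a: pd.DataFrame,
    consensus_b: pd.DataFrame,
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
    alignment,
    window: int = 5000,
    min_match: float = 0.1,
) -> pd.DataFrame:
    """Per pair: does a TSS-proximal site of A map onto one of B?

    For each ortholog pair, takes species A's consensus peaks with
    midpoint within ``window`` of the A gene's TSS, projects them through
    the alignment, and asks whether any projection overlaps (>= 1 bp) a
    consensus peak of B that is itself TSS-proximal to the B gene.
    """
    tss_a = dict(zip(annotation_a["gene_id"], annotation_a["tss"]))
    tss_b = dict(zip(annotation_b["gene_id"], annotation_b["tss"]))
    mids_a = consensus_a["start"] + (consensus_a["end"] - consensus_a["start"]) // 2
    mids_b = consensus_b["start"] + (consensus_b["end"] - consensus_b["start"]) // 2
    rows = []
    for pr in pairs.itertuples(index=False):
        ta, tb = tss_a.get(pr.gene_A), tss_b.get(pr.gene_B)
        conserved = False
        if ta is not None and tb is not None:
            near_a = consensus_a[(mids_a - ta).abs() <= window]
            near_b = consensus_b[(mids_b - tb).abs() <= window]
            if not near_a.empty and not near_b.empty:
                for m in map_intervals(near_a, alignment, min_match=min_match):
                    if m.status != "mapped":
                        continue
                    hit = (
                        (near_b["chrom"] == m.target_chrom)
                        & (near_b["start"] < m.target_end)
                        & (near_b["end"] > m.target_start)
                    )
                    if hit.any():
                        conserved = True
                        break
        rows.append((pr.gene_A, pr.gene_B, conserved))
    return pd.DataFrame(rows, columns=["gene_A", "gene_B", "conserved_site"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the result tables and writes the report."""
    ind = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log: list[str] = []

    def emit(name: str, df: pd.DataFrame):
        results[name] = df
        buf = io.StringIO()
        buf.write(f"# grnx {__version__} config={config.config_hash}\n")
        df.to_csv(buf, sep="\t", index=False)
        (out / f"{name}.tsv").write_text(buf.getvalue())
        log.append(f"{name}: {len(df)} rows")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # stage 1: expression scores ---------------------------------------
    expr_cfg = pd.read_csv(ind / "expression_datasets.tsv", sep="\t")
    expr_calls, expr_scores = {}, {}
    for sp in SPECIES:
        def _expr(sp=sp):
            tables = {}
            for _, row in expr_cfg[expr_cfg["species"] == sp].iterrows():
                path = ind / "expression" / sp / f"{row['dataset_id']}.tsv"
                tables[row["dataset_id"]] = pd.read_csv(path, sep="\t")
            calls = calls_from_tables(tables, expr_cfg[expr_cfg["species"] == sp])
            scores = compute_expression_scores(calls, min_present=config.min_present)
            return calls, scores

        expr_calls[sp], expr_scores[sp] = stage(f"expression[{sp}]", _expr)
        emit(f"expression_scores_{sp}", expr_scores[sp])

    # stage 2: binding scores + consensus peaks ------------------------
    chip_cfg = pd.read_csv(ind / "chip_datasets.tsv", sep="\t")
    annotation = {
        sp: pd.read_csv(ind / "annotation" / f"{sp}_genes.tsv", sep="\t")
        for sp in SPECIES
    }
    binding_scores: dict = {sp: {} for sp in SPECIES}
    binding_hits: dict = {sp: {} for sp in SPECIES}
    consensus: dict = {sp: {} for sp in SPECIES}
    for sp in SPECIES:
        for factor in FACTORS:
            def _bind(sp=sp, factor=factor):
                sel = chip_cfg[
                    (chip_cfg["species"] == sp) & (chip_cfg["factor"] == factor)
                ]
                sets = {}
                for _, row in sel.iterrows():
                    path = ind / "chip" / sp / factor / f"{row['dataset_id']}.bed"
                    sets[row["dataset_id"]] = pd.read_csv(
                        path, sep="\t", header=None, names=["chrom", "start", "end"]
                    )
                pooled = pd.concat(
                    [df.assign(dataset_id=d) for d, df in sets.items()],
                    ignore_index=True,
                )
                window = config.window_p53 if factor == "p53" else config.window_e2f4
                scores = assign_peaks_to_tss(pooled, annotation[sp], window)
                hits = tss_binding_hits(pooled, annotation[sp], window)
                cons = consensus_to_frame(
                    build_consensus_peaks(sets, config.min_support[sp][factor])
                )
                return scores, hits, cons

            (
                binding_scores[sp][factor],
                binding_hits[sp][factor],
                consensus[sp][factor],
            ) = stage(f"binding[{sp},{factor}]", _bind)
            emit(f"binding_scores_{sp}_{factor}", binding_scores[sp][factor])
            emit(f"consensus_peaks_{sp}_{factor}", consensus[sp][factor])

    # stage 3: target calling ------------------------------------------
    targets, dream = {}, {}
    for sp in SPECIES:
        targets[sp] = stage(
            f"targets[{sp}]",
            lambda sp=sp: call_direct_targets(
                expr_scores[sp],
                binding_scores[sp]["p53"],
                expr_calls[sp],
                binding_hits[sp]["p53"],
                chip_cfg,
                es_min=config.es_min,
                chip_min=config.chip_min[sp],
            ),
        )
        dream[sp] = stage(
            f"dream[{sp}]",
            lambda sp=sp: call_dream_candidates(
                expr_scores[sp],
                binding_scores[sp]["E2F4_DREAM"],
                es_max=config.dream_es_max,
                chip_min=config.dream_chip_min,
            ),
        )
        emit(f"direct_targets_{sp}", targets[sp])
        emit(f"dream_candidates_{sp}", dream[sp])

    # stage 4: ortholog comparison -------------------------------------
    orthology = pd.read_csv(ind / "orthology.tsv", sep="\t")
    pairs = stage(
        "orthologs",
        lambda: build_ortholog_pairs(orthology, expr_scores["A"], expr_scores["B"]),
    )
    emit("ortholog_pairs", pairs)
    corr_rows = []
    for direction in ("up", "down"):
        for ref in ("A", "B"):
            try:
                rho = correlate_scores(pairs, direction, ref)
            except ValueError:
                rho = float("nan")
            corr_rows.append((direction, ref, rho))
    emit("score_correlations", pd.DataFrame(
        corr_rows, columns=["direction", "reference", "spearman_rho"]))
    divergence = classify_divergence(
        pairs,
        es_min=config.es_min,
        diff_min=config.diff_min,
        other_support_max=config.other_support_max,
    )
    emit("divergence", divergence)

    # stage 5: cross-genome mapping + turnover + conservation ----------
    amap = stage(
        "alignment", lambda: parse_chain_file(ind / "alignment_A_to_B.chain")
    )
    rev = invert_alignment(amap)
    turnover_rows = []
    for factor in FACTORS:
        mapped_ab = map_intervals(consensus["A"][factor], amap, config.min_match)
        t_ab = classify_turnover(mapped_ab, consensus["B"][factor])
        mapped_ba = map_intervals(consensus["B"][factor], rev, config.min_match)
        t_ba = classify_turnover(mapped_ba, consensus["A"][factor])
        for tag, t in ((f"{factor}_A_to_B", t_ab), (f"{factor}_B_to_A", t_ba)):
            turnover_rows.append(
                (tag, t["unmappable"], t["mapped_nonoverlapping"],
                 t["mapped_overlapping"], t["conserved_fraction_pct"])
            )
    emit("turnover", pd.DataFrame(
        turnover_rows,
        columns=["comparison", "unmappable", "mapped_nonoverlapping",
                 "mapped_overlapping", "conserved_fraction_pct"]))

    for sp in SPECIES:
        track = pd.read_csv(
            ind / "conservation" / f"{sp}.bedGraph", sep="\t", header=None,
            names=["chrom", "start", "end", "value"],
        )
        prof = stage(
            f"profile[{sp}]",
            lambda sp=sp, track=track: conservation_profile(
                consensus[sp]["p53"], track, flank=config.flank
            ),
        )
        emit(f"conservation_profile_{sp}", prof)

    # conserved-site annotation for the common-target intersection
    site_cons = stage(
        "site_conservation",
        lambda: pair_site_conservation(
            pairs, consensus["A"]["p53"], consensus["B"]["p53"],
            annotation["A"], annotation["B"], amap,
            window=config.window_p53, min_match=config.min_match,
        ),
    )
    common = intersect_direct_targets(pairs, targets["A"], targets["B"], site_cons)
    emit("common_direct_targets", common)

    # stage 6: motifs + genomic features -------------------------------
    model = p53re_model(config.motif_threshold)
    motif_rows = []
    features = {}
    feat_tables = {}
    for sp in SPECIES:
        genome = _read_fasta(ind / "genomes" / f"{sp}.fa")
        frac, count = stage(
            f"motif[{sp}]",
            lambda sp=sp, genome=genome: fraction_peaks_with_motif(
                consensus[sp]["p53"], genome, model
            ),
        )
        total = genome_wide_motif_count(genome, model)
        motif_rows.append((sp, len(consensus[sp]["p53"]), count, 100 * frac, total))
        features[sp] = pd.read_csv(
            ind / "annotation" / f"{sp}_features.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "feature"],
        )
        sizes = {c: len(s) for c, s in genome.items()}
        feat_tables[sp] = stage(
            f"features[{sp}]",
            lambda sp=sp, sizes=sizes: feature_enrichment(
                consensus[sp]["p53"], features[sp], sizes
            ),
        )
        emit(f"feature_enrichment_{sp}", feat_tables[sp])
    emit("motif_content", pd.DataFrame(
        motif_rows,
        columns=["species", "n_peaks", "n_with_p53re", "pct_with_p53re",
                 "genome_wide_p53re"]))

    # stage 7: over-representation of the common target set ------------
    def _enrich():
        universe = set(pairs["gene_A"])
        query = set(common["gene_A"])
        if config.gmt:
            annotations = read_gmt(config.gmt)
        else:
            # fall back to score-derived gene sets over the pair universe
            annotations = {
                "up_in_A": set(pairs.loc[pairs["score_A"] >= config.es_min, "gene_A"]),
                "down_in_A": set(pairs.loc[pairs["score_A"] <= -config.es_min, "gene_A"]),
                "up_in_B": set(pairs.loc[pairs["score_B"] >= config.es_min, "gene_A"]),
                "down_in_B": set(pairs.loc[pairs["score_B"] <= -config.es_min, "gene_A"]),
            }
        return enrich(query, annotations, universe)

    emit("term_enrichment", stage("enrichment", _enrich))

    # report bundle ----------------------------------------------------
    (out / "config.yaml").write_text(config.to_yaml())
    summary = "\n".join(
        [f"grnx {__version__} pipeline report", f"config hash: {config.config_hash}", ""]
        + log
    ) + "\n"
    (out / "summary.txt").write_text(summary)
    results["summary"] = summary
    return results
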