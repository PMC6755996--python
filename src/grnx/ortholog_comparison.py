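"""Cross-species comparison of expression scores over one-to-one orthologs.

Only one-to-one ortholog pairs where both genes carry a computed
expression score enter the comparison. Scores are correlated by direction
(Spearman on the up- or down-regulated subset of either reference
species), pairs are classified into divergence categories (regulated in
one species with little or no support in the other), and per-species
direct-target calls are intersected into the common core of genes under
direct control in both species, annotated by whether the underlying
binding site is shared or species-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

__all__ = [
    "build_ortholog_pairs",
    "correlate_scores",
    "classify_divergence",
    "intersect_direct_targets",
    "load_common_target_reference",
]

ONE_TO_ONE = "ortholog_one2one"


def build_ortholog_pairs(
    orthology_table: pd.DataFrame,
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
) -> pd.DataFrame:
    """Pair one-to-one orthologs that are scored in both species.

    ``orthology_table`` needs columns gene_A, gene_B, homology_type; only
    rows with homology type ``ortholog_one2one`` are kept, and among those
    only pairs where both genes appear in their species' score table.

    Returns a frame with columns gene_A, gene_B, score_A, score_B,
    n_up_A, n_down_A, n_up_B, n_down_B.

    Raises
    ------
    ValueError
        If a gene occurs in more than one one-to-one row (not one-to-one).
    """
    oto = orthology_table[orthology_table["homology_type"] == ONE_TO_ONE]
    if oto["gene_A"].duplicated().any() or oto["gene_B"].duplicated().any():
        raise ValueError("a gene occurs in more than one one-to-one ortholog row")
    cols = ["gene_id", "score", "n_up", "n_down"]
    pairs = (
        oto[["gene_A", "gene_B"]]
        .merge(
            scores_a[cols].rename(
                columns={"gene_id": "gene_A", "score": "score_A", "n_up": "n_up_A", "n_down": "n_down_A"}
            ),
            on="gene_A",
            how="inner",
        )
        .merge(
            scores_b[cols].rename(
                columns={"gene_id": "gene_B", "score": "score_B", "n_up": "n_up_B", "n_down": "n_down_B"}
            ),
            on="gene_B",
            how="inner",
        )
        .reset_index(drop=True)
    )
    return pairs


def correlate_scores(
    pairs: pd.DataFrame, direction: str, reference: str
) -> float:
    """Spearman correlation of the two species' scores, by direction.

    The pair set is restricted by the *reference* species' score sign:
    ``direction='up'`` keeps pairs with reference score > 0, ``'down'``
    keeps reference score < 0. Reporting both reference orientations gives
    two correlation values per direction. Ties get average ranks
    (standard Spearman).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if reference not in ("A", "B"):
        raise ValueError("reference must be 'A' or 'B'")
    ref = pairs[f"score_{reference}"]
    sub = pairs[ref > 0] if direction == "up" else pairs[ref < 0]
    if len(sub) < 3:
        raise ValueError(
            f"need >= 3 qualifying pairs for Spearman, got {len(sub)}"
        )
    if sub["score_A"].nunique() == 1 or sub["score_B"].nunique() == 1:
        return float("nan")  # rank correlation undefined for constant input
    rho = stats.spearmanr(sub["score_A"], sub["score_B"]).statistic
    return float(rho)


@dataclass(frozen=True)
class DivergenceThresholds:
    es_min: int = 5
    diff_min: int = 8
    other_support_max: int = 3  # regulation "supported" means >= this many datasets


def classify_divergence(
    pairs: pd.DataFrame,
    es_min: int = 5,
    diff_min: int = 8,
    other_support_max: int = 3,
) -> pd.DataFrame:
    """Tag ortholog pairs whose regulation diverges between species.

    A pair is tagged ``A_up_only`` when species A's score reaches
    ``es_min``, the two scores differ by at least ``diff_min``, and fewer
    than ``other_support_max`` datasets call the gene up in species B
    (the same-direction dataset count, not the net score — a gene up in 3
    and down in 3 datasets is not unsupported). The other three ``*_only``
    tags are symmetric. Tags are per direction, so one pair may carry two
    (up in one species, down in the other).

    ``common_up`` / ``common_down`` mark pairs reaching ``es_min`` (resp.
    ``-es_min``) in both species; they are mutually exclusive with the
    corresponding ``*_only`` tags by construction.

    Returns the input frame plus one boolean column per tag and
    ``passes_filter`` (any ``*_only`` tag set).
    """
    out = pairs.copy()
    diff_ok = (out["score_A"] - out["score_B"]).abs() >= diff_min

    out["A_up_only"] = (
        (out["score_A"] >= es_min) & diff_ok & (out["n_up_B"] < other_support_max)
    )
    out["B_up_only"] = (
        (out["score_B"] >= es_min) & diff_ok & (out["n_up_A"] < other_support_max)
    )
    out["A_down_only"] = (
        (out["score_A"] <= -es_min) & diff_ok & (out["n_down_B"] < other_support_max)
    )
    out["B_down_only"] = (
        (out["score_B"] <= -es_min) & diff_ok & (out["n_down_A"] < other_support_max)
    )
    out["common_up"] = (out["score_A"] >= es_min) & (out["score_B"] >= es_min)
    out["common_down"] = (out["score_A"] <= -es_min) & (out["score_B"] <= -es_min)
    out["passes_filter"] = (
        out["A_up_only"] | out["B_up_only"] | out["A_down_only"] | out["B_down_only"]
    )
    return out


def intersect_direct_targets(
    pairs: pd.DataFrame,
    targets_a: pd.DataFrame,
    targets_b: pd.DataFrame,
    site_conservation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Common direct targets of both species, with site-conservation labels.

    Parameters
    ----------
    pairs
        Output of :func:`build_ortholog_pairs`.
    targets_a, targets_b
        Per-species direct-target tables (gene_id, is_direct_target).
    site_conservation
        Optional frame gene_A, conserved_site (bool): whether any
        TSS-proximal consensus peak of species A maps onto a TSS-proximal
        consensus peak of species B for that pair (computed by the
        binding-conservation stage). Pairs bound only at non-overlapping
        sites in the two genomes are labelled species-specific.

    Returns
    -------
    Rows of ``pairs`` where both genes are direct targets, plus a
    ``conserved_site`` column when ``site_conservation`` is given.
    """
    ta = dict(zip(targets_a["gene_id"], targets_a["is_direct_target"]))
    tb = dict(zip(targets_b["gene_id"], targets_b["is_direct_target"]))
    both = pairs[
        pairs["gene_A"].map(ta).fillna(False).astype(bool)
        & pairs["gene_B"].map(tb).fillna(False).astype(bool)
    ].copy()
    if site_conservation is not None:
        cons = dict(zip(site_conservation["gene_A"], site_conservation["conserved_site"]))
        both["conserved_site"] = (
            both["gene_A"].map(cons).fillna(False).astype(bool)
        )
    return both.reset_index(drop=True)


def load_common_target_reference() -> pd.DataFrame:
    """Curated core set of direct p53 target genes shared by mouse and human.

    Ships with the package: 86 genes under direct p53 control in both
    species, each flagged by whether the supporting binding site is
    conserved (shared, mappable between the genomes) or species-specific.
    """
    with resources.files("grnx").joinpath("data/common_direct_targets.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["conserved_site"] = df["conserved_site"].astype(bool)
    return df
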