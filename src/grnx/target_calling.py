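"""Direct-target and DREAM-candidate calling.

A gene is a *direct* p53 target when up-regulation and TSS-proximal p53
binding are each supported by enough independent datasets — and, to guard
against a single study dominating either line of evidence, when the
supporting datasets span at least two distinct studies on both sides.
Down-regulated genes bound by E2F4 near the TSS are candidates for
indirect repression through the DREAM complex (p53 -> p21 -> DREAM).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["call_direct_targets", "call_dream_candidates"]


def _supporting_studies(
    calls: pd.DataFrame, verdict_col: str, want: str
) -> pd.Series:
    """Distinct study count per gene among rows with the wanted verdict."""
    sel = calls[calls[verdict_col] == want]
    return sel.groupby("gene_id")["study_id"].nunique()


def call_direct_targets(
    expr_scores: pd.DataFrame,
    binding_scores: pd.DataFrame,
    expr_calls: pd.DataFrame,
    binding_hits: pd.DataFrame,
    dataset_config: pd.DataFrame,
    es_min: int = 5,
    chip_min: int = 3,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Joint expression + binding direct-target call.

    Parameters
    ----------
    expr_scores
        Output of :func:`grnx.expression_score.compute_expression_scores`.
    binding_scores
        Frame gene_id, n_datasets_bound for the activating factor.
    expr_calls
        Tidy per-dataset calls (gene_id, dataset_id, study_id, verdict);
        used for the two-study rule on the expression side.
    binding_hits
        Frame gene_id, dataset_id with one row per (gene, ChIP dataset
        with a TSS-proximal peak); used for the two-study rule on the
        binding side.
    dataset_config
        Frame mapping every dataset_id to a study_id; a binding dataset
        missing from it is a configuration error.
    es_min, chip_min
        Minimum expression score and minimum number of binding datasets.
        ``chip_min`` scales with the size of the ChIP compendium (e.g. 3
        of 9 mouse-style, 5 of 28 human-style).
    min_studies
        Both evidence types must come from at least this many distinct
        studies.

    Returns
    -------
    DataFrame with per-criterion booleans and the final call, one row per
    scored gene.
    """
    ds_to_study = dict(
        zip(dataset_config["dataset_id"].astype(str), dataset_config["study_id"].astype(str))
    )
    missing = set(binding_hits["dataset_id"].astype(str)) - set(ds_to_study)
    if missing:
        raise ValueError(f"datasets without study mapping: {sorted(missing)}")

    out = expr_scores[["gene_id", "score"]].merge(
        binding_scores[["gene_id", "n_datasets_bound"]], on="gene_id", how="left"
    )
    out["n_datasets_bound"] = out["n_datasets_bound"].fillna(0).astype(int)

    up_studies = _supporting_studies(expr_calls, "verdict", "up")
    out["expression_studies"] = (
        out["gene_id"].map(up_studies).fillna(0).astype(int)
    )

    bh = binding_hits.copy()
    bh["study_id"] = bh["dataset_id"].astype(str).map(ds_to_study)
    bind_studies = bh.groupby("gene_id")["study_id"].nunique()
    out["binding_studies"] = out["gene_id"].map(bind_studies).fillna(0).astype(int)

    out["pass_expression"] = out["score"] >= es_min
    out["pass_binding"] = out["n_datasets_bound"] >= chip_min
    out["pass_studies"] = (out["expression_studies"] >= min_studies) & (
        out["binding_studies"] >= min_studies
    )
    out["is_direct_target"] = (
        out["pass_expression"] & out["pass_binding"] & out["pass_studies"]
    )
    return out


def call_dream_candidates(
    expr_scores: pd.DataFrame,
    e2f4_binding_scores: pd.DataFrame,
    es_max: int = -5,
    chip_min: int = 3,
) -> pd.DataFrame:
    """Down-regulated genes with TSS-proximal E2F4/DREAM binding.

    Thresholds mirror the direct-target call symmetrically (score at or
    below ``es_max``, binding in at least ``chip_min`` datasets within the
    1 kb E2F4 window used upstream).
    """
    out = expr_scores[["gene_id", "score"]].merge(
        e2f4_binding_scores[["gene_id", "n_datasets_bound"]], on="gene_id", how="left"
    )
    out["n_datasets_bound"] = out["n_datasets_bound"].fillna(0).astype(int)
    out["is_dream_candidate"] = (out["score"] <= es_max) & (
        out["n_datasets_bound"] >= chip_min
    )
    return out
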