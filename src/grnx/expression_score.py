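"""Per-gene expression scores from many differential-expression datasets.

A meta-analysis of transcription-factor perturbation experiments rarely
rests on a single study: each dataset calls a partially different set of
genes up- or down-regulated. The *expression score* synthesizes them into
one signed integer per gene,

    score = (# datasets calling the gene up) - (# datasets calling it down),

so that genes consistently induced across many independent experiments end
up with large positive scores and consistently repressed genes with large
negative scores. The score doubles as a confidence ranking: leave-one-out
concordance shows that the more datasets agree on a gene, the more likely a
held-out dataset recovers the same call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "UP",
    "DOWN",
    "NS",
    "ABSENT",
    "DatasetCall",
    "call_regulation",
    "call_dataset",
    "compute_expression_scores",
    "score_group_histogram",
    "leave_one_out_concordance",
]

UP = "up"
DOWN = "down"
NS = "ns"
ABSENT = "absent"

#: default significance thresholds, inclusive on both sides
DEFAULT_LFC_MIN = 0.5
DEFAULT_P_MAX = 0.05


@dataclass(frozen=True)
class DatasetCall:
    """One gene's regulation verdict in one dataset."""

    gene_id: str
    dataset_id: str
    study_id: str
    verdict: str
    log2fc: float
    adj_p: float


def call_regulation(
    log2fc: float,
    adj_p: float,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> str:
    """Classify a single measurement as ``up``, ``down`` or ``ns``.

    Thresholds are inclusive: ``log2fc >= lfc_min`` (resp. ``<= -lfc_min``)
    together with ``adj_p <= p_max`` makes a call.

    Raises
    ------
    ValueError
        If either input is non-finite or ``adj_p`` lies outside [0, 1].
    """
    if not (math.isfinite(log2fc) and math.isfinite(adj_p)):
        raise ValueError(f"non-finite input: log2fc={log2fc}, adj_p={adj_p}")
    if not 0.0 <= adj_p <= 1.0:
        raise ValueError(f"adj_p must be in [0, 1], got {adj_p}")
    if adj_p <= p_max:
        if log2fc >= lfc_min:
            return UP
        if log2fc <= -lfc_min:
            return DOWN
    return NS


def call_dataset(
    table: pd.DataFrame,
    dataset_id: str,
    study_id: str | None = None,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Vectorised :func:`call_regulation` over one dataset table.

    ``table`` needs columns ``gene_id``, ``log2fc``, ``adj_p``. Returns a
    calls frame with columns gene_id, dataset_id, study_id, verdict,
    log2fc, adj_p. A gene absent from ``table`` is simply absent from the
    result ("present" means having a row, whatever the verdict).
    """
    lfc = table["log2fc"].to_numpy(dtype=float)
    p = table["adj_p"].to_numpy(dtype=float)
    if not (np.isfinite(lfc).all() and np.isfinite(p).all()):
        raise ValueError(f"dataset {dataset_id}: non-finite log2fc or adj_p")
    if ((p < 0) | (p > 1)).any():
        raise ValueError(f"dataset {dataset_id}: adj_p outside [0, 1]")
    sig = p <= p_max
    verdict = np.where(
        sig & (lfc >= lfc_min), UP, np.where(sig & (lfc <= -lfc_min), DOWN, NS)
    )
    return pd.DataFrame(
        {
            "gene_id": table["gene_id"].to_numpy(),
            "dataset_id": dataset_id,
            "study_id": study_id if study_id is not None else dataset_id,
            "verdict": verdict,
            "log2fc": lfc,
            "adj_p": p,
        }
    )


def calls_from_tables(
    tables: Mapping[str, pd.DataFrame],
    dataset_config: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build a tidy calls frame from per-dataset tables.

    ``dataset_config`` optionally carries per-dataset threshold overrides
    (columns dataset_id, study_id, lfc_min, p_max); some studies use
    deviating thresholds to conform to their original analysis settings.
    """
    cfg: dict[str, tuple[str, float, float]] = {}
    if dataset_config is not None:
        for row in dataset_config.itertuples(index=False):
            lfc_min = getattr(row, "lfc_min", DEFAULT_LFC_MIN)
            p_max = getattr(row, "p_max", DEFAULT_P_MAX)
            if pd.isna(lfc_min):
                lfc_min = DEFAULT_LFC_MIN
            if pd.isna(p_max):
                p_max = DEFAULT_P_MAX
            cfg[str(row.dataset_id)] = (str(row.study_id), float(lfc_min), float(p_max))
    frames = []
    for dataset_id, table in tables.items():
        study_id, lfc_min, p_max = cfg.get(
            dataset_id, (dataset_id, DEFAULT_LFC_MIN, DEFAULT_P_MAX)
        )
        frames.append(call_dataset(table, dataset_id, study_id, lfc_min, p_max))
    if not frames:
        return pd.DataFrame(
            columns=["gene_id", "dataset_id", "study_id", "verdict", "log2fc", "adj_p"]
        )
    return pd.concat(frames, ignore_index=True)


def compute_expression_scores(
    calls: pd.DataFrame | Iterable[DatasetCall],
    min_present: int = 3,
) -> pd.DataFrame:
    """Aggregate per-dataset calls into per-gene expression scores.

    Parameters
    ----------
    calls
        Tidy frame with columns gene_id, dataset_id, verdict (``absent``
        rows, if present, are dropped first), or an iterable of
        :class:`DatasetCall`.
    min_present
        Genes measured in fewer than this many datasets are excluded; a
        gene seen only once or twice carries too little evidence to rank.

    Returns
    -------
    DataFrame with columns gene_id, n_up, n_down, n_present, score,
    sorted by gene_id.
    """
    if not isinstance(calls, pd.DataFrame):
        calls = pd.DataFrame([c.__dict__ for c in calls])
    calls = calls[calls["verdict"] != ABSENT]
    if calls.duplicated(subset=["gene_id", "dataset_id"]).any():
        dups = calls[calls.duplicated(subset=["gene_id", "dataset_id"], keep=False)]
        pair = dups.iloc[0]
        raise ValueError(
            f"duplicate (gene, dataset) rows, e.g. ({pair['gene_id']}, {pair['dataset_id']})"
        )
    grouped = calls.groupby("gene_id", sort=True)["verdict"]
    out = grouped.agg(
        n_up=lambda v: int((v == UP).sum()),
        n_down=lambda v: int((v == DOWN).sum()),
        n_present="size",
    ).reset_index()
    out = out[out["n_present"] >= min_present].reset_index(drop=True)
    out["score"] = out["n_up"] - out["n_down"]
    return out


def score_group_histogram(
    scores: pd.DataFrame, merge_min_size: int = 0
) -> dict[int, int]:
    """Histogram of genes per integer score group.

    With ``merge_min_size > 0``, extreme groups smaller than it are merged
    into the adjacent group nearer zero (a presentation choice for
    near-empty tail groups; off by default and gene-count preserving).
    """
    counts = scores["score"].value_counts().sort_index()
    hist = {int(s): int(n) for s, n in counts.items()}
    if merge_min_size > 0:
        for s in sorted([k for k in hist if k < 0]):  # most negative first
            if s < 0 and hist.get(s, 0) < merge_min_size and hist.get(s, 0) > 0:
                hist[s + 1] = hist.get(s + 1, 0) + hist.pop(s)
        for s in sorted([k for k in hist if k > 0], reverse=True):
            if s > 0 and hist.get(s, 0) < merge_min_size and hist.get(s, 0) > 0:
                hist[s - 1] = hist.get(s - 1, 0) + hist.pop(s)
    return dict(sorted(hist.items()))


def leave_one_out_concordance(calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-validate datasets against the consensus of the others.

    For each dataset D and each score level s of the remaining datasets,
    reports the fraction of D's up-calls among genes whose
    remaining-score is s (and symmetrically for down-calls at level -s).
    On coherent data the recovery fraction rises with |s|: the more of
    the other datasets agree, the likelier the held-out dataset calls the
    gene the same way.

    Returns a frame with columns dataset_id, direction, remaining_score,
    n_genes, n_recovered, recovery.
    """
    dataset_ids = calls["dataset_id"].unique()
    if len(dataset_ids) < 3:
        raise ValueError("leave-one-out requires at least 3 datasets")
    rows = []
    for held in dataset_ids:
        rest = compute_expression_scores(
            calls[calls["dataset_id"] != held], min_present=1
        )
        held_calls = calls[calls["dataset_id"] == held][["gene_id", "verdict"]]
        merged = rest.merge(held_calls, on="gene_id", how="inner")
        for direction, sign in ((UP, 1), (DOWN, -1)):
            for s, grp in merged.groupby(sign * merged["score"]):
                if s < 0:
                    continue
                rec = int((grp["verdict"] == direction).sum())
                rows.append(
                    {
                        "dataset_id": held,
                        "direction": direction,
                        "remaining_score": int(s),
                        "n_genes": len(grp),
                        "n_recovered": rec,
                        "recovery": rec / len(grp),
                    }
                )
    return pd.DataFrame(rows)
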