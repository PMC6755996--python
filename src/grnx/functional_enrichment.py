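"""Gene-set over-representation analysis (hypergeometric / BH-FDR).

Generic stand-in for gene-ontology style enrichment of called target
sets: for each annotation term, the upper-tail hypergeometric probability
of drawing at least the observed overlap when sampling the query from the
gene universe, corrected across terms by Benjamini-Hochberg. The universe
defaults to all scored genes of the species, the standard choice for
over-representation analysis of a score-derived gene list.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["enrich", "read_gmt"]


def read_gmt(path) -> dict[str, set[str]]:
    """Parse GMT gene sets: term <tab> description <tab> gene1 <tab> ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def enrich(
    query_genes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` per term.

    For a universe of N genes, a term with K members and a query of n
    genes overlapping the term in k, the p-value is P(X >= k) with
    X ~ Hypergeom(N, K, n). FDR is Benjamini-Hochberg across all tested
    terms; rows are sorted by (FDR, p).

    Annotation members outside the universe are ignored; the query must
    be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe, e.g. {sorted(stray)[:3]}")
    N, n = len(universe), len(query)
    rows = []
    for term, members in annotations.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & query)
        # sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["fdr", "p"], ignore_index=True)
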