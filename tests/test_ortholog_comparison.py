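import numpy as np
import pandas as pd
import pytest

from grnx.expression_score import compute_expression_scores
from grnx.ortholog_comparison import (
    build_ortholog_pairs,
    classify_divergence,
    correlate_scores,
    intersect_direct_targets,
    load_common_target_reference,
)

from conftest import expression_calls


def scores_frame(ids, scores):
    return pd.DataFrame(
        {
            "gene_id": ids,
            "score": scores,
            "n_up": [max(s, 0) for s in scores],
            "n_down": [max(-s, 0) for s in scores],
        }
    )


def test_one_to_many_rows_and_unscored_genes_excluded():
    orth = pd.DataFrame(
        {
            "gene_A": ["a1", "a2", "a3", "a4"],
            "gene_B": ["b1", "b2", "b3", "b4"],
            "homology_type": ["ortholog_one2one", "ortholog_one2many",
                              "ortholog_one2one", "ortholog_one2one"],
        }
    )
    sa = scores_frame(["a1", "a2", "a3", "a4"], [1, 2, 3, 4])
    sb = scores_frame(["b1", "b2", "b3"], [1, 2, 3])  # b4 unscored
    pairs = build_ortholog_pairs(orth, sa, sb)
    assert sorted(pairs["gene_A"]) == ["a1", "a3"]


def test_gene_in_two_one_to_one_rows_is_an_error():
    orth = pd.DataFrame(
        {
            "gene_A": ["a1", "a1"],
            "gene_B": ["b1", "b2"],
            "homology_type": ["ortholog_one2one"] * 2,
        }
    )
    sa = scores_frame(["a1"], [1])
    sb = scores_frame(["b1", "b2"], [1, 2])
    with pytest.raises(ValueError, match="one-to-one"):
        build_ortholog_pairs(orth, sa, sb)


def test_pair_count_matches_brute_force_filter(default_scenario):
    sa = compute_expression_scores(expression_calls(default_scenario, "A"))
    sb = compute_expression_scores(expression_calls(default_scenario, "B"))
    pairs = build_ortholog_pairs(default_scenario.orthology, sa, sb)
    expected = 0
    scored_a, scored_b = set(sa["gene_id"]), set(sb["gene_id"])
    for r in default_scenario.orthology.itertuples(index=False):
        if (
            r.homology_type == "ortholog_one2one"
            and r.gene_A in scored_a
            and r.gene_B in scored_b
        ):
            expected += 1
    assert len(pairs) == expected


def _pairs(score_a, score_b, **kw):
    n = len(score_a)
    df = pd.DataFrame(
        {
            "gene_A": [f"a{i}" for i in range(n)],
            "gene_B": [f"b{i}" for i in range(n)],
            "score_A": score_a,
            "score_B": score_b,
            "n_up_A": [max(s, 0) for s in score_a],
            "n_down_A": [max(-s, 0) for s in score_a],
            "n_up_B": [max(s, 0) for s in score_b],
            "n_down_B": [max(-s, 0) for s in score_b],
        }
    )
    for k, v in kw.items():
        df[k] = v
    return df


def test_identical_scores_give_perfect_correlation():
    pairs = _pairs([1, 2, 3, 4], [1, 2, 3, 4])
    assert correlate_scores(pairs, "up", "A") == pytest.approx(1.0)


def test_reversed_ranks_give_perfect_anticorrelation():
    pairs = _pairs([1, 2, 3, 4], [4, 3, 2, 1])
    assert correlate_scores(pairs, "up", "A") == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(42)
    a = rng.integers(-15, 16, size=50)
    b = a + rng.integers(-5, 6, size=50)
    pairs = _pairs(list(a), list(b))
    for direction, ref in (("up", "A"), ("down", "A"), ("up", "B"), ("down", "B")):
        rho = correlate_scores(pairs, direction, ref)
        sub = pairs[pairs[f"score_{ref}"] > 0] if direction == "up" else pairs[
            pairs[f"score_{ref}"] < 0
        ]
        ra = pd.Series(sub["score_A"]).rank(method="average")
        rb = pd.Series(sub["score_B"]).rank(method="average")
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


def test_too_few_qualifying_pairs_is_an_error():
    pairs = _pairs([1, 2, -3, -4], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="3 qualifying"):
        correlate_scores(pairs, "up", "A")


def test_up_in_one_species_only_is_tagged():
    # strong up-regulation in one species, flat in the other
    pairs = _pairs([0], [16], n_up_A=[0], n_down_A=[0])
    out = classify_divergence(pairs)
    row = out.iloc[0]
    assert row["B_up_only"] and row["passes_filter"]
    assert not (row["A_up_only"] or row["common_up"])


def test_opposite_regulation_carries_two_tags():
    # down in A, up in B: both divergence directions tagged on one pair
    pairs = _pairs([-18], [15])
    out = classify_divergence(pairs).iloc[0]
    assert out["A_down_only"] and out["B_up_only"]
    assert not (out["common_up"] or out["common_down"])


def test_subthreshold_pairs_carry_no_tags():
    out = classify_divergence(_pairs([4], [4])).iloc[0]
    assert not out[
        ["A_up_only", "B_up_only", "A_down_only", "B_down_only",
         "common_up", "common_down", "passes_filter"]
    ].any()


def test_same_direction_support_blocks_divergence_tag():
    # score difference is large but 3 datasets still call the gene up in B
    pairs = _pairs([16], [3], n_up_B=[3])
    assert not classify_divergence(pairs).iloc[0]["A_up_only"]


def test_divergence_is_antisymmetric_under_species_swap(default_scenario):
    sa = compute_expression_scores(expression_calls(default_scenario, "A"))
    sb = compute_expression_scores(expression_calls(default_scenario, "B"))
    pairs = build_ortholog_pairs(default_scenario.orthology, sa, sb)
    fwd = classify_divergence(pairs)
    swapped = pairs.rename(
        columns={
            "gene_A": "gene_B", "gene_B": "gene_A",
            "score_A": "score_B", "score_B": "score_A",
            "n_up_A": "n_up_B", "n_up_B": "n_up_A",
            "n_down_A": "n_down_B", "n_down_B": "n_down_A",
        }
    )
    rev = classify_divergence(swapped)
    assert fwd["A_up_only"].equals(rev["B_up_only"])
    assert fwd["B_down_only"].equals(rev["A_down_only"])
    assert fwd["common_up"].equals(rev["common_up"])


def test_divergence_recovers_planted_species_specific_classes(default_scenario):
    sa = compute_expression_scores(expression_calls(default_scenario, "A"))
    sb = compute_expression_scores(expression_calls(default_scenario, "B"))
    pairs = build_ortholog_pairs(default_scenario.orthology, sa, sb)
    div = classify_divergence(pairs)
    truth = default_scenario.truth.pairs.set_index("gene_A")["reg_class"]
    called = set(div.loc[div["passes_filter"], "gene_A"])
    specific = {"A_up_only", "B_up_only", "A_down_only", "B_down_only", "opposite"}
    planted = {g for g, c in truth.items() if c in specific}
    tp = len(called & planted)
    assert tp / len(called) >= 0.9  # precision
    assert tp / len(planted) >= 0.9  # recall


def test_intersection_with_site_conservation_annotation():
    pairs = _pairs([10, 10, 10], [10, 10, 2])
    targets_a = pd.DataFrame(
        {"gene_id": ["a0", "a1", "a2"], "is_direct_target": [True, True, True]}
    )
    targets_b = pd.DataFrame(
        {"gene_id": ["b0", "b1", "b2"], "is_direct_target": [True, True, False]}
    )
    cons = pd.DataFrame({"gene_A": ["a0", "a1"], "conserved_site": [True, False]})
    out = intersect_direct_targets(pairs, targets_a, targets_b, cons)
    assert list(out["gene_A"]) == ["a0", "a1"]
    # pair bound only at non-overlapping sites is annotated species-specific
    assert list(out["conserved_site"]) == [True, False]


def test_reference_common_target_set_partition():
    ref = load_common_target_reference()
    assert len(ref) == 86
    assert int(ref["conserved_site"].sum()) == 58
    assert int((~ref["conserved_site"]).sum()) == 28
    assert round(100 * ref["conserved_site"].mean()) == 67
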