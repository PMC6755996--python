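import numpy as np
import pandas as pd
import pytest

from grnx.binding_conservation import (
    AlignmentMap,
    Chain,
    classify_turnover,
    conservation_profile,
    conserved_fraction,
    invert_alignment,
    map_intervals,
    parse_chain_file,
)


def simple_chain(blocks, src="chrA", tgt="chrB", chain_id=1):
    """blocks: list of (src_start, src_end, tgt_start)."""
    return Chain(
        src,
        tgt,
        np.array([b[0] for b in blocks], dtype=np.int64),
        np.array([b[1] for b in blocks], dtype=np.int64),
        np.array([b[2] for b in blocks], dtype=np.int64),
        chain_id,
    )


def intervals(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_identity_map_returns_intervals_unchanged():
    amap = AlignmentMap([simple_chain([(0, 10000, 0)])])
    ivs = intervals([("chrA", 100, 300), ("chrA", 5000, 5050)])
    for m, (_, s, e) in zip(map_intervals(ivs, amap), ivs.itertuples(index=False)):
        assert m.status == "mapped"
        assert (m.target_start, m.target_end) == (m.start, m.end)
        assert m.mapped_fraction == 1.0


def test_interval_inside_source_gap_is_unmapped():
    amap = AlignmentMap([simple_chain([(0, 100, 0), (500, 600, 200)])])
    (m,) = map_intervals(intervals([("chrA", 200, 400)]), amap)
    assert m.status == "unmapped"
    assert m.mapped_fraction == 0.0


def test_min_match_fraction_gates_mapping():
    # 100 bp interval with 5 aligned bases: below 0.1, above 0.04
    amap = AlignmentMap([simple_chain([(0, 105, 0)])])
    ivs = intervals([("chrA", 100, 200)])
    (m,) = map_intervals(ivs, amap, min_match=0.1)
    assert m.status == "unmapped"
    (m,) = map_intervals(ivs, amap, min_match=0.04)
    assert m.status == "mapped"
    assert m.mapped_fraction == pytest.approx(0.05)


def test_best_chain_wins_and_ties_break_by_order():
    big = simple_chain([(0, 80, 1000)], chain_id=1)
    small = simple_chain([(0, 40, 5000)], chain_id=2)
    (m,) = map_intervals(intervals([("chrA", 0, 80)]), AlignmentMap([small, big]))
    assert m.target_start == 1000  # chain covering more bases wins
    twin = simple_chain([(0, 80, 9000)], chain_id=3)
    (m,) = map_intervals(intervals([("chrA", 0, 80)]), AlignmentMap([big, twin]))
    assert m.target_start == 1000  # tie: first chain in file order


def per_base_oracle(chain, start, end):
    """Brute-force per-base image of [start, end) through one chain."""
    images = []
    for pos in range(start, end):
        img = chain.map_base(pos)
        if img is not None:
            images.append(img)
    return images


def test_mapping_agrees_with_per_base_oracle(default_scenario):
    amap = default_scenario.alignment
    rng = np.random.default_rng(5)
    starts = rng.integers(0, len(default_scenario.genomes["A"]) - 500, size=60)
    ivs = intervals([("chrA", int(s), int(s + rng.integers(50, 500))) for s in starts])
    chain = amap.chains[0]
    for m in map_intervals(ivs, amap, min_match=0.1):
        images = per_base_oracle(chain, m.start, m.end)
        frac = len(images) / (m.end - m.start)
        assert m.mapped_fraction == pytest.approx(frac)
        if frac >= 0.1:
            assert m.status == "mapped"
            assert m.target_start == min(images)
            assert m.target_end == max(images) + 1
        else:
            assert m.status == "unmapped"


def test_round_trip_through_gap_free_chain():
    amap = AlignmentMap([simple_chain([(0, 10000, 3000)])])
    ivs = intervals([("chrA", 120, 450)])
    (m,) = map_intervals(ivs, amap)
    back = intervals([(m.target_chrom, m.target_start, m.target_end)])
    (r,) = map_intervals(back, invert_alignment(amap))
    assert (r.target_start, r.target_end) == (120, 450)


def test_chain_parse_round_trip(default_bundle):
    amap = parse_chain_file(default_bundle / "alignment_A_to_B.chain")
    assert len(amap.chains) == 1
    c = amap.chains[0]
    assert (c.source_chrom, c.target_chrom) == ("chrA", "chrB")
    assert (np.diff(c.src_starts) > 0).all()
    assert (c.src_ends > c.src_starts).all()


def test_malformed_chain_reports_line_number(tmp_path):
    bad = tmp_path / "bad.chain"
    bad.write_text("chain 1 chrA 100 + 0 50 chrB 100 - 0 50 1\n50\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_chain_file(bad)
    bad.write_text("chain 1 chrA 100 + 0 50 chrB 100 + 0 50 1\n0 1 1\n")
    with pytest.raises(ValueError, match="line 2"):
        parse_chain_file(bad)


def test_turnover_counts_partition_input():
    amap = AlignmentMap([simple_chain([(0, 1000, 0)])])
    ivs = intervals(
        [("chrA", 0, 100), ("chrA", 200, 300), ("chrA", 5000, 5100)]  # last unmappable
    )
    mapped = map_intervals(ivs, amap)
    peaks = pd.DataFrame({"chrom": ["chrB"], "start": [50], "end": [80]})
    t = classify_turnover(mapped, peaks)
    assert t["unmappable"] + t["mapped_nonoverlapping"] + t["mapped_overlapping"] == 3
    assert t["mapped_overlapping"] == 1
    assert t["conserved_fraction_pct"] == pytest.approx(50.0)


def test_no_overlap_gives_zero_conserved_fraction():
    assert conserved_fraction(0, 10) == 0.0
    assert conserved_fraction(0, 0) == 0.0


def test_turnover_invariant_under_input_shuffle(default_scenario):
    from grnx.binding_score import build_consensus_peaks, consensus_to_frame

    cons_a = consensus_to_frame(
        build_consensus_peaks(default_scenario.chip["A"]["p53"], 4)
    )
    cons_b = consensus_to_frame(
        build_consensus_peaks(default_scenario.chip["B"]["p53"], 5)
    )
    mapped = map_intervals(cons_a, default_scenario.alignment)
    t1 = classify_turnover(mapped, cons_b)
    t2 = classify_turnover(list(reversed(mapped)), cons_b)
    for k in ("unmappable", "mapped_nonoverlapping", "mapped_overlapping"):
        assert t1[k] == t2[k]


def test_profile_of_constant_track_is_constant():
    sites = intervals([("chrA", 1000, 1200), ("chrA", 3000, 3100)])
    track = pd.DataFrame(
        {"chrom": ["chrA"], "start": [0], "end": [10000], "value": [0.7]}
    )
    prof = conservation_profile(sites, track, flank=100)
    assert (prof["n"] == 2).all()
    assert prof["mean"].to_numpy() == pytest.approx(np.full(201, 0.7))


def test_single_site_profile_equals_track_slice():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 1, size=40).round(3)
    track = pd.DataFrame(
        {
            "chrom": "chrA",
            "start": np.arange(40) * 10,
            "end": (np.arange(40) + 1) * 10,
            "value": vals,
        }
    )
    sites = intervals([("chrA", 190, 210)])  # center 200
    prof = conservation_profile(sites, track, flank=50)
    expected = [vals[(200 + off) // 10] for off in range(-50, 51)]
    assert prof["mean"].to_numpy() == pytest.approx(np.array(expected))


def test_missing_track_positions_are_excluded_not_zero():
    track = pd.DataFrame(
        {"chrom": ["chrA"], "start": [95], "end": [105], "value": [1.0]}
    )
    sites = intervals([("chrA", 90, 110)])  # center 100
    prof = conservation_profile(sites, track, flank=10)
    inside = prof[(prof["offset"] >= -5) & (prof["offset"] < 5)]
    outside = prof[prof["offset"] > 5]
    assert (inside["mean"] == 1.0).all()
    assert (outside["n"] == 0).all()
    assert outside["mean"].isna().all()


def test_empty_site_set_is_an_error():
    track = pd.DataFrame({"chrom": [], "start": [], "end": [], "value": []})
    with pytest.raises(ValueError, match="empty"):
        conservation_profile(intervals([]), track)


def test_conserved_sites_show_elevated_profile_center(default_scenario):
    """Planted conserved elements carry higher conservation at the center
    than at the window edges, and than non-conserved sites do."""
    sites = default_scenario.truth.sites
    track = default_scenario.conservation["A"]
    cons = sites[(sites["species"] == "A") & sites["conserved"]]
    prof = conservation_profile(cons[["chrom", "start", "end"]], track, flank=2500)
    center = prof.loc[prof["offset"].abs() <= 100, "mean"].mean()
    edge = prof.loc[prof["offset"].abs() >= 2400, "mean"].mean()
    assert center > edge
    noncons = sites[(sites["species"] == "A") & ~sites["conserved"]]
    prof_nc = conservation_profile(noncons[["chrom", "start", "end"]], track, flank=2500)
    center_nc = prof_nc.loc[prof_nc["offset"].abs() <= 100, "mean"].mean()
    assert center > center_nc
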