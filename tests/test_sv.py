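"""Discordant-pair extraction, clustering, refinement, annotation, merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbpanel.panel import TargetRegion, RegionClass, load_panel
from nbpanel.sv import (
    BreakpointCall,
    CallerCall,
    ClipEvent,
    DiscordantCluster,
    DiscordantPair,
    FragmentModel,
    MergeParams,
    OrientationClass,
    Resolution,
    SvError,
    call_svs,
    classify_tert_rearrangement,
    cluster_discordant,
    detect_partial_deletion,
    extract_discordant,
    fit_fragment_model,
    merge_sv_callsets,
    refine_breakpoint,
)

SEQ = "A" * 100
QUAL = "I" * 100


def proper_pair_rows(qname, chrom, pos1, tlen):
    """An inward-facing proper pair with the given outer distance."""
    mate1 = pos1 + tlen - 100
    return [
        (qname, 99, chrom, pos1, 60, "100M", "=", mate1, tlen, SEQ, QUAL),
        (qname, 147, chrom, mate1, 60, "100M", "=", pos1, -tlen, SEQ, QUAL),
    ]


# --- fragment model ---------------------------------------------------------

def test_constant_distances_give_zero_sd(sam_factory):
    rows = []
    for i in range(120):
        rows += proper_pair_rows(f"r{i}", "chr1", 1000 + i, 250)
    model = fit_fragment_model(sam_factory(rows))
    assert model.mean == 250
    assert model.sd == 0
    assert model.cutoff == 250


def test_normal_distances_recover_closed_form_cutoff(sam_factory):
    rng = np.random.default_rng(77)
    rows = []
    for i, d in enumerate(rng.normal(250, 25, size=500)):
        rows += proper_pair_rows(f"r{i}", "chr1", 1000 + 3 * i, int(round(d)))
    model = fit_fragment_model(sam_factory(rows))
    assert model.cutoff == pytest.approx(325, abs=12)


def test_too_few_pairs_raise(sam_factory):
    rows = proper_pair_rows("only", "chr1", 1000, 250)
    with pytest.raises(SvError, match="too few"):
        fit_fragment_model(sam_factory(rows))


# --- discordance definition -------------------------------------------------

MODEL = FragmentModel(mean=250.0, sd=25.0)  # cutoff 325


def test_mates_on_different_contigs_are_discordant(sam_factory):
    rows = [
        ("t0", 97, "chr1", 1000, 60, "100M", "chr2", 5000, 0, SEQ, QUAL),
        ("t0", 145, "chr2", 5000, 60, "100M", "chr1", 1000, 0, SEQ, QUAL),
    ]
    pairs = extract_discordant(sam_factory(rows), MODEL)
    assert len(pairs) == 1
    assert pairs[0].orientation is OrientationClass.TRANSLOCATION


def test_distance_below_cutoff_is_concordant(sam_factory):
    pairs = extract_discordant(
        sam_factory(proper_pair_rows("p0", "chr1", 1000, 300)), MODEL
    )
    assert pairs == []


def test_distance_above_cutoff_is_discordant(sam_factory):
    pairs = extract_discordant(
        sam_factory(proper_pair_rows("p0", "chr1", 1000, 10_000)), MODEL
    )
    assert len(pairs) == 1
    assert pairs[0].orientation is OrientationClass.DEL_LIKE
    assert pairs[0].distance == 10_000


def test_outward_orientation_is_discordant_even_when_close(sam_factory):
    # leftmost mate reverse, rightmost forward: dup-like orientation
    rows = [
        ("d0", 81, "chr1", 1000, 60, "100M", "=", 1200, 300, SEQ, QUAL),
        ("d0", 161, "chr1", 1200, 60, "100M", "=", 1000, -300, SEQ, QUAL),
    ]
    pairs = extract_discordant(sam_factory(rows), MODEL)
    assert len(pairs) == 1
    assert pairs[0].orientation is OrientationClass.DUP_LIKE


# --- clustering -------------------------------------------------------------

def _pair(pos_a, pos_b, name, orientation=OrientationClass.TRANSLOCATION,
          chrom_a="chr1", chrom_b="chr2", distance=-1):
    return DiscordantPair(chrom_a, pos_a, "+", chrom_b, pos_b, "-",
                          distance, orientation, name)


def test_tight_pairs_form_one_cluster():
    pairs = [_pair(1000 + i * 10, 5000 + i * 10, f"p{i}") for i in range(5)]
    clusters = cluster_discordant(pairs)
    assert len(clusters) == 1
    assert clusters[0].n_pairs == 5


def test_support_filter_drops_small_clusters():
    pairs = [_pair(1000, 5000, "a"), _pair(11_000, 15_000, "b")]
    assert cluster_discordant(pairs, min_support=3) == []


def test_chained_pairs_link_transitively():
    """Steps of 400 bp chain into one cluster under single linkage."""
    pairs = [_pair(1000 + i * 400, 5000 + i * 400, f"p{i}") for i in range(6)]
    clusters = cluster_discordant(pairs, window=500, min_support=3)
    assert len(clusters) == 1
    assert clusters[0].n_pairs == 6


def test_clustering_matches_bruteforce_linkage_oracle():
    import networkx as nx

    rng = np.random.default_rng(41)
    pairs = [
        _pair(int(rng.integers(0, 6000)), int(rng.integers(0, 6000)), f"p{i}")
        for i in range(40)
    ]
    clusters = cluster_discordant(pairs, window=500, min_support=1)
    got = {frozenset(p.name for p in c.pairs) for c in clusters}

    graph = nx.Graph()
    graph.add_nodes_from(range(len(pairs)))
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            if (
                abs(pairs[i].pos_a - pairs[j].pos_a) <= 500
                and abs(pairs[i].pos_b - pairs[j].pos_b) <= 500
            ):
                graph.add_edge(i, j)
    expected = {
        frozenset(pairs[i].name for i in comp)
        for comp in nx.connected_components(graph)
    }
    assert got == expected


# --- breakpoint refinement --------------------------------------------------

def _cluster(interval_a=(14_800, 14_950), interval_b=(30_000, 30_100)):
    pairs = [
        _pair(interval_a[0], interval_b[0], "p0"),
        _pair(interval_a[1], interval_b[1], "p1"),
        _pair(interval_a[0] + 50, interval_b[0] + 50, "p2"),
    ]
    return DiscordantCluster("chr1", interval_a, "chr2", interval_b,
                             OrientationClass.TRANSLOCATION, pairs)


def test_unanimous_clips_give_base_pair_resolution():
    clips = [ClipEvent("chr1", 15_000, "right") for _ in range(10)]
    call = refine_breakpoint(_cluster(), clips)
    assert call.resolution is Resolution.BASE_PAIR
    assert call.pos_a == 15_001  # 1-based
    assert call.n_clipped_reads == 10


def test_no_clips_fall_back_to_interval_resolution():
    call = refine_breakpoint(_cluster(), [])
    assert call.resolution is Resolution.INTERVAL
    assert call.pos_a == (14_800 + 14_950) // 2 + 1
    assert call.n_clipped_reads == 0


# --- TERT annotation --------------------------------------------------------

TERT = TargetRegion("chr5", 20_000, 22_000, RegionClass.GENE_TARGET, gene="TERT")


def _bp(chrom_a, pos_a, chrom_b="chr9", pos_b=1_000):
    return BreakpointCall(chrom_a, pos_a, chrom_b, pos_b,
                          OrientationClass.TRANSLOCATION, 5, 3,
                          Resolution.BASE_PAIR)


def test_breakpoint_in_gene_body_is_intragenic():
    assert classify_tert_rearrangement(_bp("chr5", 21_000), TERT) == "tert_intragenic"


def test_breakpoint_upstream_of_tss_is_upstream():
    # minus-strand gene: the TSS is the interval end; upstream is to its right
    assert classify_tert_rearrangement(_bp("chr5", 32_001), TERT) == "tert_upstream"
    # a plus-strand gene would have its promoter left of the interval start
    assert (
        classify_tert_rearrangement(_bp("chr5", 10_001), TERT, strand="+")
        == "tert_upstream"
    )


def test_breakpoints_elsewhere_are_other():
    assert classify_tert_rearrangement(_bp("chr2", 21_000), TERT) == "other"
    assert classify_tert_rearrangement(_bp("chr5", 48_001), TERT) == "other"


# --- partial deletions ------------------------------------------------------

def _gene_ratios(ratio_z):
    from nbpanel.cnv import BinRatio
    from nbpanel.panel import Bin

    return [
        BinRatio(
            bin=Bin("chrX", 40_000 + i * 100, 40_100 + i * 100, 0, i),
            depth=1000.0 * r,
            expected=1000.0,
            ratio=r,
            z=z,
        )
        for i, (r, z) in enumerate(ratio_z)
    ]


def test_internal_loss_run_is_partial_deletion():
    ratios = _gene_ratios(
        [(1, 0), (1, 0), (0.5, -8), (0.5, -8), (0.5, -8), (1, 0), (1, 0)]
    )
    call = detect_partial_deletion("ATRX", ratios)
    assert call is not None
    assert call.annotation == "atrx_partial_deletion"
    assert call.confidence == "depth_only"
    assert call.breakpoint.pos_a == 40_201
    assert call.breakpoint.pos_b == 40_500


def test_whole_gene_loss_is_not_partial():
    ratios = _gene_ratios([(0.5, -8)] * 7)
    assert detect_partial_deletion("ATRX", ratios) is None


def test_colocated_breakpoint_upgrades_confidence():
    ratios = _gene_ratios(
        [(1, 0), (1, 0), (0.5, -8), (0.5, -8), (0.5, -8), (1, 0), (1, 0)]
    )
    bp = BreakpointCall("chrX", 40_201, "chrX", 40_500,
                        OrientationClass.DEL_LIKE, 8, 4, Resolution.BASE_PAIR)
    call = detect_partial_deletion("ATRX", ratios, [bp])
    assert call.confidence == "breakpoint_supported"
    assert call.breakpoint is bp


def test_breakpoint_without_depth_signature_is_breakpoint_only():
    ratios = _gene_ratios([(1, 0)] * 7)
    bp = BreakpointCall("chrX", 40_301, "chrX", 40_600,
                        OrientationClass.DEL_LIKE, 8, 4, Resolution.BASE_PAIR)
    call = detect_partial_deletion("ATRX", ratios, [bp])
    assert call is not None
    assert call.confidence == "breakpoint_only"


# --- consensus merging ------------------------------------------------------

def test_two_callers_within_window_collapse_and_survive():
    merged = merge_sv_callsets(
        [
            ("caller1", [CallerCall("chr2", 100, "chr5", 200, "TRA", "caller1")]),
            ("caller2", [CallerCall("chr2", 450, "chr5", 480, "TRA", "caller2")]),
        ]
    )
    assert len(merged) == 1
    assert merged[0].callers == ("caller1", "caller2")


def test_single_caller_call_is_discarded():
    merged = merge_sv_callsets(
        [
            ("caller1", [CallerCall("chr2", 100, "chr5", 200, "TRA", "caller1")]),
            ("caller2", []),
        ]
    )
    assert merged == []


def test_chain_of_three_collapses_under_single_linkage():
    merged = merge_sv_callsets(
        [
            ("c1", [CallerCall("chr2", 100, "chr5", 200, "TRA", "c1")]),
            ("c2", [CallerCall("chr2", 500, "chr5", 600, "TRA", "c2")]),
            ("c3", [CallerCall("chr2", 900, "chr5", 1000, "TRA", "c3")]),
        ]
    )
    assert len(merged) == 1
    assert merged[0].callers == ("c1", "c2", "c3")
    assert merged[0].pos_a == 500  # median


def test_window_zero_keeps_only_coincident_calls():
    a = CallerCall("chr2", 100, "chr5", 200, "TRA", "c1")
    b = CallerCall("chr2", 100, "chr5", 200, "TRA", "c2")
    c = CallerCall("chr2", 101, "chr5", 200, "TRA", "c3")
    merged = merge_sv_callsets(
        [("c1", [a]), ("c2", [b]), ("c3", [c])], MergeParams(window=0)
    )
    assert len(merged) == 1
    assert merged[0].callers == ("c1", "c2")


def test_min_callers_one_discards_nothing():
    calls = [
        ("c1", [CallerCall("chr2", 100, "chr5", 200, "TRA", "c1")]),
        ("c2", [CallerCall("chr7", 100, "chr9", 200, "TRA", "c2")]),
    ]
    merged = merge_sv_callsets(calls, MergeParams(min_callers=1))
    assert len(merged) == 2


def bruteforce_merge(callsets, window, min_callers):
    """Independent oracle: explicit graph + connected components."""
    import itertools

    import networkx as nx

    flat = [c.canonical() for _, cs in callsets for c in cs]
    graph = nx.Graph()
    graph.add_nodes_from(range(len(flat)))
    for i, j in itertools.combinations(range(len(flat)), 2):
        a, b = flat[i], flat[j]
        if (
            a.chrom_a == b.chrom_a
            and a.chrom_b == b.chrom_b
            and a.svtype == b.svtype
            and abs(a.pos_a - b.pos_a) <= window
            and abs(a.pos_b - b.pos_b) <= window
        ):
            graph.add_edge(i, j)
    out = set()
    for comp in nx.connected_components(graph):
        group = [flat[i] for i in comp]
        callers = tuple(sorted({c.caller for c in group}))
        if len(callers) < min_callers:
            continue
        out.add(
            (
                group[0].chrom_a,
                int(np.median([c.pos_a for c in group])),
                group[0].chrom_b,
                int(np.median([c.pos_b for c in group])),
                group[0].svtype,
                callers,
            )
        )
    return out


@st.composite
def random_callsets(draw):
    n_callers = draw(st.integers(2, 4))
    callsets = []
    for ci in range(n_callers):
        n = draw(st.integers(0, 12))
        calls = []
        for _ in range(n):
            chrom_a, chrom_b = draw(
                st.sampled_from([("chr1", "chr1"), ("chr1", "chr2")])
            )
            calls.append(
                CallerCall(
                    chrom_a,
                    draw(st.integers(1, 4000)),
                    chrom_b,
                    draw(st.integers(1, 4000)),
                    draw(st.sampled_from(["TRA", "DEL"])),
                    f"c{ci}",
                )
            )
        callsets.append((f"c{ci}", calls))
    return callsets


@settings(max_examples=60, derandomize=True, deadline=None)
@given(random_callsets(), st.sampled_from([0, 100, 500]), st.sampled_from([1, 2]))
def test_merge_equals_bruteforce_oracle(callsets, window, min_callers):
    merged = merge_sv_callsets(
        callsets, MergeParams(window=window, min_callers=min_callers)
    )
    got = {
        (m.chrom_a, m.pos_a, m.chrom_b, m.pos_b, m.svtype, m.callers)
        for m in merged
    }
    assert got == bruteforce_merge(callsets, window, min_callers)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(random_callsets(), st.randoms(use_true_random=False))
def test_merge_invariant_to_input_order(callsets, rnd):
    baseline = merge_sv_callsets(callsets)
    shuffled = [(name, list(calls)) for name, calls in callsets]
    rnd.shuffle(shuffled)
    for _, calls in shuffled:
        rnd.shuffle(calls)
    assert merge_sv_callsets(shuffled) == baseline


# --- end-to-end recovery ----------------------------------------------------

def test_simulated_rearrangements_recovered_to_base_pair(sv_world):
    """Translocation and intragenic deletion: recall 1.0, breakpoints +-10 bp."""
    calls = call_svs(sv_world["variant"].sam_path, sv_world["panel"])
    truth = sv_world["variant"].truth["sv"]
    assert len(calls) == len(truth) == 2
    for t in truth:
        matches = [
            c
            for c in calls
            if c.breakpoint.chrom_a == t["chrom_a"]
            and c.breakpoint.chrom_b == t["chrom_b"]
            and abs(c.breakpoint.pos_a - 1 - t["pos_a"]) <= 10
            and abs(c.breakpoint.pos_b - 1 - t["pos_b"]) <= 10
        ]
        assert len(matches) == 1
        assert matches[0].breakpoint.resolution is Resolution.BASE_PAIR
    tert = [c for c in calls if "TERT" in c.genes]
    assert tert and tert[0].annotation == "tert_intragenic"


def test_variant_free_sample_yields_no_sv_calls(sv_world):
    assert call_svs(sv_world["clean"].sam_path, sv_world["panel"]) == []
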