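"""Pileup semantics, calling thresholds, flags and detection power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from nbpanel import load_panel
from nbpanel.simulate import SimConfig, SnvSpec, simulate_dataset
from nbpanel.snv import (
    DEFAULT_HOTSPOTS,
    Pileup,
    SnvCall,
    SnvError,
    SnvParams,
    annotate_hotspots,
    call_snvs,
    detection_probability,
    flag_possible_germline,
    pileup,
)

from conftest import SNV_BED, SNV_CONTIGS, SNV_REF_SEED, SNV_SITE


# --- pileup -----------------------------------------------------------------

def _ref_for(panel_bed="chr1\t1000\t1100\tG\n", base="A"):
    return {"chr1": base * 101_000}


def read_row(qname, pos1, seq, cigar=None, mapq=60, qual=None):
    cigar = cigar or f"{len(seq)}M"
    qual = qual or "I" * len(seq)
    return (qname, 0, "chr1", pos1, mapq, cigar, "*", 0, 0, seq, qual)


def test_pileup_counts_mixed_bases(sam_factory):
    panel = load_panel("chr1\t1000\t1100\tG\n")
    rows = [read_row(f"a{i}", 1001, "A" * 100) for i in range(90)]
    rows += [read_row(f"g{i}", 1001, "G" + "A" * 99) for i in range(10)]
    columns = pileup(sam_factory(rows), _ref_for(), panel)
    first = [c for c in columns if c.pos == 1001][0]
    assert first.counts == (90, 0, 10, 0)
    assert first.depth == 100


def test_soft_clipped_portion_not_counted(sam_factory):
    panel = load_panel("chr1\t1000\t1100\tG\n")
    rows = [read_row("r0", 1001, "A" * 70 + "G" * 30, cigar="70M30S")]
    columns = pileup(sam_factory(rows), _ref_for(), panel)
    assert max(c.pos for c in columns) == 1070  # clip never reaches base 71+
    assert all(c.counts[2] == 0 for c in columns)  # no G counted


def test_low_base_quality_excluded_and_recorded(sam_factory):
    panel = load_panel("chr1\t1000\t1100\tG\n")
    qual = "#" + "I" * 99  # first base Q2
    rows = [read_row("r0", 1001, "A" * 100, qual=qual)]
    columns = pileup(sam_factory(rows), _ref_for(), panel)
    assert [c for c in columns if c.pos == 1001] == [] or (
        [c for c in columns if c.pos == 1001][0].depth == 0
    )


def test_simulated_vaf_recovered_within_binomial_ci(snv_world):
    res = snv_world["result"]
    columns = pileup(res.sam_path, res.reference_path, snv_world["panel"])
    site = [c for c in columns if c.pos == SNV_SITE + 1][0]
    alt_idx = "ACGT".index(snv_world["alt"])
    vaf_hat = site.counts[alt_idx] / site.depth
    ci = 3 * math.sqrt(0.105 * 0.895 / site.depth)
    assert abs(vaf_hat - 0.105) < ci


# --- calling thresholds -----------------------------------------------------

def _pileup(depth, alt_count, ref="A", alt="G"):
    counts = [0, 0, 0, 0]
    counts["ACGT".index(ref)] = depth - alt_count
    counts["ACGT".index(alt)] = alt_count
    return Pileup("chr1", 1001, ref, tuple(counts), gene="ALK")


def test_shallow_depth_yields_no_call():
    assert call_snvs([_pileup(45, 20)]) == []


def test_deep_subclonal_site_is_called_and_flagged():
    calls = call_snvs([_pileup(1000, 105)])
    assert len(calls) == 1
    assert calls[0].vaf == pytest.approx(0.105)
    assert calls[0].subclonal is True


def test_too_few_alt_reads_yield_no_call():
    assert call_snvs([_pileup(1000, 4)]) == []


def test_vaf_below_floor_yields_no_call():
    assert call_snvs([_pileup(1000, 30)]) == []  # vaf 0.03 < 0.05


# --- annotation and flags ---------------------------------------------------

def _call(vaf, gene="ALK"):
    depth = 1000
    return SnvCall("chr2", 100, "A", "G", int(round(vaf * depth)), depth,
                   vaf, gene=gene)


@pytest.mark.parametrize("change", ["F1174L", "R1275Q"])
def test_alk_hotspots_flagged_tier1(change):
    annotated = annotate_hotspots(_call(0.4), protein_change=change)
    assert annotated.hotspot_tier1 is True
    assert annotated.protein_change == change


def test_unlisted_variant_not_flagged():
    annotated = annotate_hotspots(_call(0.4), protein_change="A1200V")
    assert annotated.hotspot_tier1 is False


def test_unknown_gene_leaves_call_unchanged():
    call = _call(0.4, gene=None)
    assert annotate_hotspots(call, protein_change="F1174L") == call


@pytest.mark.parametrize(
    "vaf, flagged", [(0.50, True), (0.105, False), (0.97, True), (0.30, False)]
)
def test_germline_band_flagging(vaf, flagged):
    assert flag_possible_germline(_call(vaf)).possible_germline is flagged


def test_population_site_forces_germline_flag():
    call = _call(0.105)
    flagged = flag_possible_germline(
        call, population_sites={("chr2", 100, "G")}
    )
    assert flagged.possible_germline is True


# --- detection power --------------------------------------------------------

def bruteforce_tail(f, c, k):
    """Independent oracle: explicit pmf summation."""
    return sum(
        math.comb(c, i) * f**i * (1 - f) ** (c - i) for i in range(k, c + 1)
    )


def test_detection_probability_examples():
    assert detection_probability(0.5, 1, 1) == pytest.approx(0.5)
    assert detection_probability(0.0, 100, 1) == 0.0
    assert detection_probability(0.105, 45, 3) == pytest.approx(
        bruteforce_tail(0.105, 45, 3), abs=1e-12
    )


def test_detection_probability_matches_pmf_sum_on_grid():
    for f in (0.01, 0.105, 0.25, 0.5, 0.9):
        for c in (10, 45, 200):
            for k in (1, 3, 10):
                assert detection_probability(f, c, k) == pytest.approx(
                    bruteforce_tail(f, c, k), abs=1e-9
                )


@settings(max_examples=80, derandomize=True)
@given(
    st.floats(0.01, 0.99),
    st.integers(1, 300),
    st.integers(1, 20),
)
def test_detection_probability_monotone(f, c, k):
    p = detection_probability(f, c, k)
    assert detection_probability(min(f + 0.05, 1.0), c, k) >= p - 1e-12
    assert detection_probability(f, c + 10, k) >= p - 1e-12
    assert detection_probability(f, c, k + 1) <= p + 1e-12


@pytest.mark.parametrize("f,c,k", [(-0.1, 45, 3), (0.1, 0, 3), (0.1, 45, 0)])
def test_detection_probability_rejects_bad_ranges(f, c, k):
    with pytest.raises(SnvError):
        detection_probability(f, c, k)


# --- statistical behavior on simulations ------------------------------------

def test_vaf_estimates_unbiased_across_many_sites(tmp_path):
    """Mean VAF error across >= 50 sites stays within the binomial SE."""
    from nbpanel.simulate import make_reference

    panel = load_panel("chr2\t10000\t14000\tALK\n")
    contigs = [("chr2", 30_000)]
    probe = SimConfig(contigs=contigs, panel=panel, seed=0, reference_seed=71)
    ref = make_reference(probe)["chr2"]
    flip = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rng = np.random.default_rng(72)
    sites = []
    for i in range(50):
        pos = 10_040 + i * 79
        vaf = float(rng.uniform(0.08, 0.5))
        sites.append(SnvSpec("chr2", pos, flip[ref[pos]], round(vaf, 3)))
    cfg = SimConfig(
        contigs=contigs, panel=panel, mean_depth=400.0,
        on_target_fraction=1.0, seed=73, reference_seed=71, snv_truth=sites,
    )
    res = simulate_dataset(cfg, tmp_path / "many")
    columns = {c.pos: c for c in pileup(res.sam_path, res.reference_path, panel)}
    errors, variances = [], []
    for s in sites:
        col = columns[s.pos + 1]
        alt_idx = "ACGT".index(s.alt)
        vaf_hat = col.counts[alt_idx] / col.depth
        errors.append(vaf_hat - s.vaf)
        variances.append(s.vaf * (1 - s.vaf) / col.depth)
    se_of_mean = math.sqrt(sum(variances)) / len(sites)
    assert abs(float(np.mean(errors))) < 3 * se_of_mean


def test_no_calls_on_variant_free_data_with_sequencing_errors(tmp_path):
    panel = load_panel("chr2\t10000\t11000\tALK\n")
    cfg = SimConfig(
        contigs=[("chr2", 30_000)], panel=panel, mean_depth=1000.0,
        on_target_fraction=1.0, seed=74, base_error_rate=0.001,
    )
    res = simulate_dataset(cfg, tmp_path / "err")
    columns = pileup(res.sam_path, res.reference_path, panel)
    assert call_snvs(columns, SnvParams()) == []


def test_low_coverage_miss_rate_matches_binomial_tail(snv_world):
    """At WES-like 45x with k=3, misses follow the binomial tail (500 reps)."""
    panel = snv_world["panel"]
    alt = snv_world["alt"]
    alt_idx = "ACGT".index(alt)
    params = SnvParams(min_depth=1, min_alt_reads=3, min_vaf=0.001)
    misses = 0
    expectation = 0.0
    variance = 0.0
    root = snv_world["root"]
    for i in range(500):
        cfg = SimConfig(
            contigs=SNV_CONTIGS, panel=panel, mean_depth=45.0,
            on_target_fraction=1.0, seed=8000 + i, reference_seed=SNV_REF_SEED,
            snv_truth=[SnvSpec("chr2", SNV_SITE, alt, 0.105)],
        )
        res = simulate_dataset(cfg, root / "rep")
        columns = pileup(res.sam_path, res.reference_path, panel)
        site = [c for c in columns if c.pos == SNV_SITE + 1]
        depth = site[0].depth if site else 0
        called = any(
            c.pos == SNV_SITE + 1 and c.alt == alt
            for c in call_snvs(site, params)
        )
        misses += not called
        p_miss = float(binom.cdf(2, depth, 0.105)) if depth else 1.0
        expectation += p_miss
        variance += p_miss * (1 - p_miss)
    assert abs(misses - expectation) <= 2 * math.sqrt(variance)
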