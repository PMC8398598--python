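"""Shared fixtures: panels, simulated datasets, and a handcrafted-SAM helper.

Simulated datasets are session-scoped because several test modules (and the
acceptance tests) interrogate the same study conditions: high-depth
(1000x) copy-number recovery against five diploid controls, a
translocation plus intragenic-deletion sample for SV recall, and a
moderate-depth sample for alignment QC.
"""

from __future__ import annotations

import numpy as np
import pytest

from nbpanel import depth_profile, load_panel, make_bins
from nbpanel.cnv import build_control_model
from nbpanel.simulate import (
    CnvSegment,
    SimConfig,
    SnvSpec,
    SvSpec,
    make_reference,
    simulate_dataset,
)

MINI_CONTIGS = [
    ("chr1", 100_000),
    ("chr2", 100_000),
    ("chr5", 60_000),
    ("chr11", 40_000),
    ("chr17", 40_000),
    ("chrX", 60_000),
]


def mini_panel_bed() -> str:
    """Panel fixture: 4 genes, 1p36/11q/17q tiles, 65 reference probes."""
    rows: list[tuple[str, int, int, str]] = [
        ("chr2", 30_000, 31_500, "MYCN"),
        ("chr2", 60_000, 61_500, "ALK"),
        ("chr2", 62_000, 63_500, "ALK"),
        ("chr5", 20_000, 22_000, "TERT"),
        ("chrX", 40_000, 44_000, "ATRX"),
    ]
    for i in range(5):
        rows.append(("chr1", 10_000 + i * 700, 10_600 + i * 700, "1p36"))
    for i in range(4):
        rows.append(("chr11", 10_000 + i * 700, 10_600 + i * 700, "11q"))
    for i in range(4):
        rows.append(("chr17", 10_000 + i * 700, 10_600 + i * 700, "17q"))
    probe_spots = (
        [("chr1", 20_000 + i * 1_200) for i in range(20)]
        + [("chr2", 5_000 + i * 900) for i in range(15)]
        + [("chr5", 30_000 + i * 900) for i in range(10)]
        + [("chr11", 20_000 + i * 900) for i in range(10)]
        + [("chr17", 20_000 + i * 900) for i in range(5)]
        + [("chrX", 10_000 + i * 900) for i in range(5)]
    )
    for chrom, start in probe_spots:
        rows.append((chrom, start, start + 100, "REF"))
    return "".join(f"{c}\t{s}\t{e}\t{label}\n" for c, s, e, label in rows)


@pytest.fixture(scope="session")
def mini_bed() -> str:
    return mini_panel_bed()


@pytest.fixture(scope="session")
def mini_panel(mini_bed):
    return load_panel(mini_bed)


def write_sam(path, contigs, rows) -> str:
    """Write a SAM file from (qname, flag, chrom, pos1, mapq, cigar, rnext,
    pnext1, tlen, seq, qual) tuples."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    lines += [f"@SQ\tSN:{n}\tLN:{length}" for n, length in contigs]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture()
def sam_factory(tmp_path):
    def factory(rows, contigs=(("chr1", 100_000), ("chr2", 100_000))):
        return write_sam(tmp_path / "reads.sam", list(contigs), rows)

    return factory


# --- CNV study conditions ---------------------------------------------------

CNV_CONTIGS = [("chr1", 130_000), ("chr2", 60_000)]
CNV_GRID = [(1, 0.5), (1, 1.0), (3, 0.5), (3, 1.0), (4, 0.5),
            (4, 1.0), (8, 0.5), (8, 1.0), (40, 0.5), (40, 1.0)]
CNV_EVENT = ("chr2", 10_000, 10_600)  # region G00


def cnv_panel_bed() -> str:
    """Compact CNV panel: 12 gene-like regions on chr2 + 65 reference probes."""
    rows = [
        f"chr2\t{10_000 + i * 3_000}\t{10_600 + i * 3_000}\tG{i:02d}\n"
        for i in range(12)
    ]
    rows += [
        f"chr1\t{50_000 + i * 1_000}\t{50_100 + i * 1_000}\tREF\n"
        for i in range(65)
    ]
    return "".join(rows)


def _cnv_config(panel, seed, purity=1.0, cnv_truth=()):
    return SimConfig(
        contigs=CNV_CONTIGS,
        panel=panel,
        mean_depth=1000.0,
        on_target_fraction=1.0,
        emit_sequences=False,
        purity=purity,
        cnv_truth=cnv_truth,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cnv_world(tmp_path_factory):
    """Five diploid controls, a held-out diploid sample, and the CN recovery grid."""
    root = tmp_path_factory.mktemp("cnv")
    panel = load_panel(cnv_panel_bed())
    bins = make_bins(panel, 100)

    controls = []
    for i in range(5):
        res = simulate_dataset(_cnv_config(panel, seed=4100 + i), root / f"c{i}")
        controls.append(depth_profile(res.sam_path, panel))
    model = build_control_model(controls, bins)

    null_res = simulate_dataset(_cnv_config(panel, seed=4200), root / "null")
    null_profile = depth_profile(null_res.sam_path, panel)

    grid = {}
    chrom, start, end = CNV_EVENT
    for j, (cn, purity) in enumerate(CNV_GRID):
        res = simulate_dataset(
            _cnv_config(
                panel,
                seed=4300 + j,
                purity=purity,
                cnv_truth=[CnvSegment(chrom, start, end, cn)],
            ),
            root / f"g{j}",
        )
        grid[(cn, purity)] = depth_profile(res.sam_path, panel)

    return {
        "panel": panel,
        "bins": bins,
        "controls": controls,
        "model": model,
        "null_profile": null_profile,
        "grid": grid,
    }


# --- SV study conditions ----------------------------------------------------

SV_CONTIGS = [("chr2", 100_000), ("chr5", 60_000), ("chrX", 60_000)]
SV_BED = (
    "chr2\t60000\t63000\tALK\n"
    "chr5\t20000\t22000\tTERT\n"
    "chrX\t40000\t44000\tATRX\n"
)
SV_TRANSLOCATION = SvSpec("chr2", 61_500, "chr5", 21_000, "translocation")
SV_ATRX_DEL = SvSpec("chrX", 41_000, "chrX", 42_500, "del")


@pytest.fixture(scope="session")
def sv_world(tmp_path_factory):
    """One sample with a translocation and an intragenic deletion, one without."""
    root = tmp_path_factory.mktemp("sv")
    panel = load_panel(SV_BED)
    variant = simulate_dataset(
        SimConfig(
            contigs=SV_CONTIGS,
            panel=panel,
            mean_depth=500.0,
            on_target_fraction=1.0,
            seed=5100,
            cnv_truth=[CnvSegment("chrX", 41_000, 42_500, 1)],
            sv_truth=[SV_TRANSLOCATION, SV_ATRX_DEL],
        ),
        root / "variant",
    )
    clean = simulate_dataset(
        SimConfig(
            contigs=SV_CONTIGS,
            panel=panel,
            mean_depth=500.0,
            on_target_fraction=1.0,
            seed=5200,
        ),
        root / "clean",
    )
    return {"panel": panel, "variant": variant, "clean": clean}


# --- QC study conditions ----------------------------------------------------

@pytest.fixture(scope="session")
def qc_world(tmp_path_factory, mini_panel):
    """Moderate-depth run on the full mini panel at the default enrichment."""
    root = tmp_path_factory.mktemp("qc")
    res = simulate_dataset(
        SimConfig(
            contigs=MINI_CONTIGS,
            panel=mini_panel,
            mean_depth=150.0,
            on_target_fraction=0.45,
            seed=6100,
        ),
        root / "qc",
    )
    profile = depth_profile(res.sam_path, mini_panel)
    return {"panel": mini_panel, "result": res, "profile": profile}


# --- SNV study conditions ---------------------------------------------------

SNV_BED = "chr2\t10000\t10400\tALK\n"
SNV_CONTIGS = [("chr2", 30_000)]
SNV_SITE = 10_200  # 0-based
SNV_REF_SEED = 7000


def snv_alt_allele() -> str:
    """An alt allele distinct from the fixed reference base at the test site."""
    panel = load_panel(SNV_BED)
    cfg = SimConfig(contigs=SNV_CONTIGS, panel=panel,
                    seed=0, reference_seed=SNV_REF_SEED)
    ref_base = make_reference(cfg)["chr2"][SNV_SITE]
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[ref_base]


@pytest.fixture(scope="session")
def snv_world(tmp_path_factory):
    """A 1000x sample carrying one subclonal SNV at 10.5% allele fraction."""
    root = tmp_path_factory.mktemp("snv")
    panel = load_panel(SNV_BED)
    alt = snv_alt_allele()
    res = simulate_dataset(
        SimConfig(
            contigs=SNV_CONTIGS,
            panel=panel,
            mean_depth=1000.0,
            on_target_fraction=1.0,
            seed=7100,
            reference_seed=SNV_REF_SEED,
            snv_truth=[SnvSpec("chr2", SNV_SITE, alt, 0.105)],
        ),
        root / "deep",
    )
    return {"panel": panel, "alt": alt, "result": res, "root": root}
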