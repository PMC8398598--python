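"""Tumor-only pileup SNV calling with VAF, flags and detection power.

Calling is tumor-only by design: with no matched normal, likely germline
variants (allele fraction near 0.5 or near 1.0) are *flagged*, never hard
filtered, so rare but relevant somatic variants are not silently dropped.
The detection-power helper quantifies when a subclonal variant is expected
to escape a lower-coverage assay: the number of variant-supporting reads at
a site with depth c and allele fraction f is Binomial(c, f), so the chance
of seeing at least k supporting reads is the upper binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta
from scipy.stats import binom

from .panel import Panel


class SnvError(ValueError):
    pass


_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase
_BASES = "ACGT"


@dataclass(frozen=True)
class Pileup:
    """Base counts at one site (1-based position)."""

    chrom: str
    pos: int
    ref: str
    counts: tuple[int, int, int, int]  # A, C, G, T
    n_low_qual: int = 0
    gene: str | None = None

    @property
    def depth(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class SnvParams:
    min_depth: int = 100
    min_alt_reads: int = 10
    min_vaf: float = 0.05
    min_baseq: int = 13
    min_mapq: int = 20
    subclonal_vaf_cut: float = 0.20
    germline_band: tuple[float, float] = (0.40, 0.60)
    germline_high_vaf: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf < 1:
            raise SnvError("min_vaf must be in (0, 1)")
        if self.min_alt_reads < 1:
            raise SnvError("min_alt_reads must be >= 1")


@dataclass(frozen=True)
class SnvCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int
    depth: int
    vaf: float
    gene: str | None = None
    subclonal: bool = False
    possible_germline: bool = False
    hotspot_tier1: bool = False
    protein_change: str | None = None


def _reference_lookup(reference) -> callable:
    """Accept a FASTA path, a pyfaidx.Fasta, or a dict of contig -> str."""
    if isinstance(reference, str):
        fasta = Fasta(reference)
        return lambda chrom, start, end: str(fasta[chrom][start:end])
    if isinstance(reference, Fasta):
        return lambda chrom, start, end: str(reference[chrom][start:end])
    if isinstance(reference, Mapping):
        return lambda chrom, start, end: reference[chrom][start:end]
    raise SnvError("unsupported reference type")


def pileup(
    sam_path: str,
    reference,
    panel: Panel,
    min_mapq: int = 20,
    min_baseq: int = 13,
) -> list[Pileup]:
    """Base counts at every covered target position.

    Only reference-aligned bases (CIGAR M/=/X) with base quality >= the
    floor and MAPQ >= the threshold are counted; soft-clipped tails and
    insertions never contribute.
    """
    lookup = _reference_lookup(reference)
    counts = [np.zeros((r.length, 4), dtype=np.int64) for r in panel.regions]
    lowq = [np.zeros(r.length, dtype=np.int64) for r in panel.regions]
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(panel.regions):
        by_chrom.setdefault(r.chrom, []).append(i)

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        ref_contigs = set(by_chrom)
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
            ):
                continue
            chrom = read.reference_name
            if chrom not in ref_contigs:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            quals = read.query_qualities
            codes = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
            qarr = (
                np.asarray(quals, dtype=np.int16)
                if quals is not None
                else np.full(len(seq), 60, dtype=np.int16)
            )
            qpos = rpos = 0
            rstart = read.reference_start
            cig = read.cigartuples or ()
            for op, ln in cig:
                if op in (0, 7, 8):  # M/=/X
                    bstart, bend = rstart + rpos, rstart + rpos + ln
                    for ri in by_chrom[chrom]:
                        region = panel.regions[ri]
                        lo = max(bstart, region.start)
                        hi = min(bend, region.end)
                        if hi <= lo:
                            continue
                        roff = lo - region.start
                        qoff = qpos + (lo - bstart)
                        sub_codes = codes[qoff:qoff + (hi - lo)]
                        sub_q = qarr[qoff:qoff + (hi - lo)]
                        ok = (sub_codes >= 0) & (sub_q >= min_baseq)
                        pos_idx = np.arange(roff, roff + (hi - lo))
                        np.add.at(
                            counts[ri], (pos_idx[ok], sub_codes[ok]), 1
                        )
                        bad = ~ok
                        if bad.any():
                            np.add.at(lowq[ri], pos_idx[bad], 1)
                    qpos += ln
                    rpos += ln
                elif op in (1, 4):  # I/S consume query
                    qpos += ln
                elif op in (2, 3):  # D/N consume reference
                    rpos += ln

    out: list[Pileup] = []
    for ri, region in enumerate(panel.regions):
        region_counts = counts[ri]
        covered = np.flatnonzero(region_counts.sum(axis=1) > 0)
        if covered.size == 0:
            continue
        refseq = lookup(region.chrom, region.start, region.end).upper()
        for off in covered.tolist():
            out.append(
                Pileup(
                    chrom=region.chrom,
                    pos=region.start + off + 1,
                    ref=refseq[off],
                    counts=tuple(int(x) for x in region_counts[off]),
                    n_low_qual=int(lowq[ri][off]),
                    gene=region.gene,
                )
            )
    return out


def call_snvs(pileups: Iterable[Pileup], params: SnvParams = SnvParams()) -> list[SnvCall]:
    """Threshold-based substitution calling on pileup columns."""
    calls: list[SnvCall] = []
    for p in pileups:
        depth = p.depth
        if depth < params.min_depth or p.ref not in _BASES:
            continue
        ref_idx = _BASES.index(p.ref)
        alt_idx = max(
            (i for i in range(4) if i != ref_idx), key=lambda i: p.counts[i]
        )
        alt_count = p.counts[alt_idx]
        if alt_count < params.min_alt_reads:
            continue
        vaf = alt_count / depth
        if vaf < params.min_vaf:
            continue
        calls.append(
            SnvCall(
                chrom=p.chrom,
                pos=p.pos,
                ref=p.ref,
                alt=_BASES[alt_idx],
                alt_count=alt_count,
                depth=depth,
                vaf=vaf,
                gene=p.gene,
                subclonal=vaf < params.subclonal_vaf_cut,
            )
        )
    return calls


#: Bundled tier-1 hotspot lookup for the recurrently mutated panel genes.
#: Keys are (gene symbol, protein change).  This is a small static stand-in
#: for a full annotation source and is user-extendable.
DEFAULT_HOTSPOTS: dict[tuple[str, str], int] = {
    ("ALK", "F1174L"): 1,
    ("ALK", "F1174V"): 1,
    ("ALK", "R1275Q"): 1,
    ("ALK", "I1171N"): 1,
    ("TP53", "R175H"): 1,
    ("TP53", "R248Q"): 1,
    ("TP53", "R273H"): 1,
}


def annotate_hotspots(
    call: SnvCall,
    protein_change: str | None = None,
    table: Mapping[tuple[str, str], int] = DEFAULT_HOTSPOTS,
) -> SnvCall:
    """Attach a protein change and set the tier-1 hotspot flag when matched."""
    pc = protein_change or call.protein_change
    if call.gene is None or pc is None:
        return call
    tier = table.get((call.gene, pc))
    return replace(
        call, protein_change=pc, hotspot_tier1=(tier == 1)
    )


def flag_possible_germline(
    call: SnvCall,
    params: SnvParams = SnvParams(),
    population_sites: set[tuple[str, int, str]] | None = None,
) -> SnvCall:
    """Heuristic germline suspicion for tumor-only calling.

    Flags allele fractions inside the heterozygous band or above the
    homozygous threshold; a site listed in an optional population-variant
    set is always flagged.
    """
    lo, hi = params.germline_band
    flagged = lo <= call.vaf <= hi or call.vaf >= params.germline_high_vaf
    if population_sites and (call.chrom, call.pos, call.alt) in population_sites:
        flagged = True
    return replace(call, possible_germline=flagged)


def detection_probability(f: float, c: int, k: int) -> float:
    """P(at least k variant reads) with depth c and allele fraction f."""
    if not 0 <= f <= 1:
        raise SnvError("allele fraction must be in [0, 1]")
    if c < 1 or int(c) != c:
        raise SnvError("depth must be a positive integer")
    if k < 1 or int(k) != k:
        raise SnvError("minimum supporting reads must be a positive integer")
    return float(binom.sf(k - 1, int(c), f))


def write_snv_vcf(calls: Sequence[SnvCall],
                  contigs: Sequence[tuple[str, int]], path: str) -> None:
    """VCF 4.2 with AF/DP/AD in FORMAT and flags in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SUBCLONAL,Number=0,Type=Flag,Description="VAF below subclonal cut">',
        '##INFO=<ID=POSSIBLE_GERMLINE,Number=0,Type=Flag,Description="Allele fraction in germline band">',
        '##INFO=<ID=HOTSPOT_TIER1,Number=0,Type=Flag,Description="Tier 1 hotspot">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt depths">',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    ]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR")
    for c in calls:
        info = []
        if c.subclonal:
            info.append("SUBCLONAL")
        if c.possible_germline:
            info.append("POSSIBLE_GERMLINE")
        if c.hotspot_tier1:
            info.append("HOTSPOT_TIER1")
        if c.gene:
            info.append(f"GENE={c.gene}")
        if c.protein_change:
            info.append(f"PCHANGE={c.protein_change}")
        ref_count = c.depth - c.alt_count
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
            f"{';'.join(info) or '.'}\tDP:AD:AF\t"
            f"{c.depth}:{ref_count},{c.alt_count}:{c.vaf:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
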