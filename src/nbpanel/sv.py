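"""Structural-variant detection from discordant pairs and clipped reads.

The caller follows the standard discordant-pair recipe for targeted panels:

* fit a robust fragment-size model (median / MAD) from properly oriented
  same-contig pairs and set the discordance cutoff at mean + 3 sd;
* extract pairs whose mates map to different contigs, farther apart than
  the cutoff, or in non-inward orientation;
* single-linkage cluster pairs whose two anchor positions both lie within a
  window, requiring a minimum number of supporting pairs;
* refine each cluster to base-pair resolution when soft-clipped reads agree
  on a clip coordinate (reads spanning the junction);
* annotate TERT rearrangements (upstream vs intragenic) and partial
  intragenic deletions (internal run of loss bins with neutral flanks);
* merge call sets from multiple callers by collapsing calls whose
  breakpoints both fall within a window and keeping calls supported by a
  minimum number of distinct callers.

Deletion-type clusters additionally require the median mapping distance to
exceed the cutoff by a margin of a few fragment-size standard deviations
before being reported: the extreme right tail of the fragment-length
distribution otherwise produces spurious clusters at high depth.
"""

from __future__ import annotations

import enum
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pysam

from .panel import Panel, TargetRegion
from .qc import PanelIndex


class SvError(ValueError):
    pass


class OrientationClass(enum.Enum):
    DEL_LIKE = "del_like"
    DUP_LIKE = "dup_like"
    INV_LIKE = "inv_like"
    TRANSLOCATION = "translocation"


class Resolution(enum.Enum):
    BASE_PAIR = "base_pair"
    INTERVAL = "interval"


@dataclass(frozen=True)
class FragmentModel:
    mean: float
    sd: float

    @property
    def cutoff(self) -> float:
        """Mapping distance above which a same-contig pair is discordant."""
        return self.mean + 3 * self.sd


@dataclass(frozen=True)
class DiscordantPair:
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    distance: int  # outer distance for same-contig pairs, -1 otherwise
    orientation: OrientationClass
    name: str


@dataclass
class DiscordantCluster:
    chrom_a: str
    interval_a: tuple[int, int]
    chrom_b: str
    interval_b: tuple[int, int]
    orientation: OrientationClass
    pairs: list[DiscordantPair]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def median_distance(self) -> float:
        d = [p.distance for p in self.pairs if p.distance >= 0]
        return float(statistics.median(d)) if d else float("nan")


@dataclass(frozen=True)
class BreakpointCall:
    """A refined junction; positions are 1-based."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    orientation: OrientationClass
    n_discordant_pairs: int
    n_clipped_reads: int
    resolution: Resolution


@dataclass
class SvCall:
    breakpoint: BreakpointCall
    genes: set[str] = field(default_factory=set)
    annotation: str = "other"
    callers: set[str] = field(default_factory=set)
    confidence: str = "discordant_pairs"


@dataclass(frozen=True)
class MergeParams:
    window: int = 500
    min_callers: int = 2

    def __post_init__(self) -> None:
        if self.window < 0:
            raise SvError("window must be >= 0")
        if self.min_callers < 1:
            raise SvError("min_callers must be >= 1")


def fit_fragment_model(sam_path: str, min_pairs: int = 100,
                       min_mapq: int = 20) -> FragmentModel:
    """Robust fragment-size model from proper inward same-contig pairs."""
    sizes: list[int] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or not read.is_read1
                or read.mapping_quality < min_mapq
            ):
                continue
            if read.reference_id != read.next_reference_id:
                continue
            if read.is_reverse == read.mate_is_reverse:
                continue
            tlen = read.template_length
            if tlen == 0:
                continue
            # inward orientation: leftmost mate forward
            if (tlen > 0 and read.is_reverse) or (tlen < 0 and not read.is_reverse):
                continue
            sizes.append(abs(tlen))
    if len(sizes) < min_pairs:
        raise SvError(
            f"too few proper pairs to fit a fragment model "
            f"({len(sizes)} < {min_pairs})"
        )
    arr = np.array(sizes, dtype=float)
    med = float(np.median(arr))
    mad_sd = float(1.4826 * np.median(np.abs(arr - med)))
    return FragmentModel(mean=med, sd=mad_sd)


def _orientation_class(
    chrom_a: str, strand_a: str, chrom_b: str, strand_b: str
) -> OrientationClass:
    if chrom_a != chrom_b:
        return OrientationClass.TRANSLOCATION
    if strand_a == strand_b:
        return OrientationClass.INV_LIKE
    if strand_a == "+":
        return OrientationClass.DEL_LIKE  # inward but too far apart
    return OrientationClass.DUP_LIKE  # outward-facing


def extract_discordant(
    sam_path: str, model: FragmentModel, min_mapq: int = 20
) -> list[DiscordantPair]:
    """Pairs on different contigs, beyond the cutoff, or not inward-facing."""
    out: list[DiscordantPair] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or not read.is_read1
                or read.mapping_quality < min_mapq
            ):
                continue
            chrom_a = read.reference_name
            chrom_b = read.next_reference_name
            pos_a, pos_b = read.reference_start, read.next_reference_start
            strand_a = "-" if read.is_reverse else "+"
            strand_b = "-" if read.mate_is_reverse else "+"
            same = chrom_a == chrom_b
            distance = -1
            discordant = False
            if not same:
                discordant = True
            else:
                tlen = abs(read.template_length)
                distance = tlen if tlen else abs(pos_b - pos_a)
                left_fwd = (pos_a <= pos_b and strand_a == "+") or (
                    pos_b < pos_a and strand_b == "+"
                )
                right_rev = (pos_a <= pos_b and strand_b == "-") or (
                    pos_b < pos_a and strand_a == "-"
                )
                inward = left_fwd and right_rev
                if not inward or distance > model.cutoff:
                    discordant = True
            if not discordant:
                continue
            # canonical breakpoint order
            if (chrom_b, pos_b) < (chrom_a, pos_a):
                chrom_a, chrom_b = chrom_b, chrom_a
                pos_a, pos_b = pos_b, pos_a
                strand_a, strand_b = strand_b, strand_a
            out.append(
                DiscordantPair(
                    chrom_a=chrom_a,
                    pos_a=pos_a,
                    strand_a=strand_a,
                    chrom_b=chrom_b,
                    pos_b=pos_b,
                    strand_b=strand_b,
                    distance=distance,
                    orientation=_orientation_class(
                        chrom_a, strand_a, chrom_b, strand_b
                    ),
                    name=read.query_name,
                )
            )
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_discordant(
    pairs: Sequence[DiscordantPair], window: int = 500, min_support: int = 3
) -> list[DiscordantCluster]:
    """Single-linkage clustering: both anchors within ``window`` of a member."""
    grouped: dict[tuple[str, str, OrientationClass], list[DiscordantPair]] = {}
    for p in pairs:
        grouped.setdefault((p.chrom_a, p.chrom_b, p.orientation), []).append(p)

    clusters: list[DiscordantCluster] = []
    for (chrom_a, chrom_b, orientation), members in grouped.items():
        members.sort(key=lambda p: (p.pos_a, p.pos_b, p.name))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            j = i - 1
            while j >= 0 and members[i].pos_a - members[j].pos_a <= window:
                if abs(members[i].pos_b - members[j].pos_b) <= window:
                    uf.union(i, j)
                j -= 1
        comp: dict[int, list[DiscordantPair]] = defaultdict(list)
        for i, p in enumerate(members):
            comp[uf.find(i)].append(p)
        for group in comp.values():
            if len(group) < min_support:
                continue
            clusters.append(
                DiscordantCluster(
                    chrom_a=chrom_a,
                    interval_a=(min(p.pos_a for p in group),
                                max(p.pos_a for p in group)),
                    chrom_b=chrom_b,
                    interval_b=(min(p.pos_b for p in group),
                                max(p.pos_b for p in group)),
                    orientation=orientation,
                    pairs=group,
                )
            )
    clusters.sort(key=lambda c: (c.chrom_a, c.interval_a, c.chrom_b, c.interval_b))
    return clusters


@dataclass(frozen=True)
class ClipEvent:
    chrom: str
    pos: int  # 0-based junction coordinate implied by the clip
    side: str  # "right": clip follows the aligned bases; "left": precedes


def collect_clips(sam_path: str, min_mapq: int = 20,
                  min_clip: int = 5) -> list[ClipEvent]:
    """Terminal soft-clip coordinates from all usable reads."""
    events: list[ClipEvent] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
                or read.cigartuples is None
            ):
                continue
            cig = read.cigartuples
            if cig[0][0] == 4 and cig[0][1] >= min_clip:
                events.append(
                    ClipEvent(read.reference_name, read.reference_start, "left")
                )
            if cig[-1][0] == 4 and cig[-1][1] >= min_clip:
                events.append(
                    ClipEvent(read.reference_name, read.reference_end, "right")
                )
    return events


def _refine_side(
    chrom: str,
    interval: tuple[int, int],
    clips: Sequence[ClipEvent],
    window: int,
    pad: int,
) -> tuple[int | None, int]:
    lo, hi = interval[0] - window, interval[1] + window + pad
    positions = [c.pos for c in clips if c.chrom == chrom and lo <= c.pos <= hi]
    if not positions:
        return None, 0
    mode, _count = Counter(positions).most_common(1)[0]
    return mode, len(positions)


def refine_breakpoint(
    cluster: DiscordantCluster,
    clips: Sequence[ClipEvent],
    window: int = 500,
    read_length: int = 150,
) -> BreakpointCall:
    """Base-pair resolution where clipped reads agree; interval fallback."""
    pos_a, n_a = _refine_side(
        cluster.chrom_a, cluster.interval_a, clips, window, read_length
    )
    pos_b, n_b = _refine_side(
        cluster.chrom_b, cluster.interval_b, clips, window, read_length
    )
    n_clip = n_a + n_b
    resolution = Resolution.BASE_PAIR if n_clip >= 1 else Resolution.INTERVAL
    if pos_a is None:
        pos_a = (cluster.interval_a[0] + cluster.interval_a[1]) // 2
    if pos_b is None:
        pos_b = (cluster.interval_b[0] + cluster.interval_b[1]) // 2
    return BreakpointCall(
        chrom_a=cluster.chrom_a,
        pos_a=pos_a + 1,
        chrom_b=cluster.chrom_b,
        pos_b=pos_b + 1,
        orientation=cluster.orientation,
        n_discordant_pairs=cluster.n_pairs,
        n_clipped_reads=n_clip,
        resolution=resolution,
    )


def classify_tert_rearrangement(
    bp: BreakpointCall,
    tert_interval: TargetRegion,
    strand: str = "-",
    upstream_window: int = 25_000,
) -> str:
    """``tert_intragenic`` / ``tert_upstream`` / ``other`` for one junction.

    A breakpoint inside the gene body is intragenic (the configuration seen
    in gene-fusion rearrangements such as ALK:TERT); a breakpoint within
    ``upstream_window`` bp 5' of the TSS is upstream (the classic
    regulatory-region rearrangement).  The two classes are never conflated.
    """
    gs, ge = tert_interval.start, tert_interval.end
    ends = [(bp.chrom_a, bp.pos_a - 1), (bp.chrom_b, bp.pos_b - 1)]
    for chrom, pos in ends:
        if chrom == tert_interval.chrom and gs <= pos < ge:
            return "tert_intragenic"
    for chrom, pos in ends:
        if chrom != tert_interval.chrom:
            continue
        if strand == "-" and ge <= pos < ge + upstream_window:
            return "tert_upstream"
        if strand == "+" and gs - upstream_window <= pos < gs:
            return "tert_upstream"
    return "other"


def detect_partial_deletion(
    gene: str,
    ratios: Sequence,  # ordered BinRatio list over the gene's bins
    breakpoints: Sequence[BreakpointCall] = (),
    z_cut: float = 3.0,
    min_run: int = 3,
    window: int = 500,
) -> SvCall | None:
    """Intragenic partial deletion: internal loss run with neutral flanks.

    Returns a depth-supported call (upgraded when a breakpoint co-locates
    with a run edge), a ``breakpoint_only`` record when a junction falls in
    the gene without the depth signature, or ``None``.
    """
    n = len(ratios)
    if n < 6:
        return None
    z = [r.z for r in ratios]
    sig = [v < -z_cut for v in z]

    runs: list[tuple[int, int]] = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, n))

    chrom = ratios[0].bin.chrom
    gene_lo = min(r.bin.start for r in ratios)
    gene_hi = max(r.bin.end for r in ratios)

    def bp_in_gene(bp: BreakpointCall) -> bool:
        for c, p in ((bp.chrom_a, bp.pos_a - 1), (bp.chrom_b, bp.pos_b - 1)):
            if c == chrom and gene_lo - window <= p < gene_hi + window:
                return True
        return False

    gene_bps = [bp for bp in breakpoints if bp_in_gene(bp)]

    for lo, hi in runs:
        if hi - lo < min_run:
            continue
        if lo == 0 and hi == n:
            return None  # whole-gene loss, not partial
        if lo == 0 or hi == n:
            continue  # run touches a gene edge: not internal
        if abs(z[lo - 1]) > z_cut or (hi < n and abs(z[hi]) > z_cut):
            continue  # flanks must be neutral
        edge_lo = ratios[lo].bin.start
        edge_hi = ratios[hi - 1].bin.end
        supported = None
        for bp in gene_bps:
            for _, p in ((bp.chrom_a, bp.pos_a - 1), (bp.chrom_b, bp.pos_b - 1)):
                if abs(p - edge_lo) <= window or abs(p - edge_hi) <= window:
                    supported = bp
                    break
            if supported:
                break
        if supported is not None:
            call_bp = supported
            confidence = "breakpoint_supported"
        else:
            call_bp = BreakpointCall(
                chrom_a=chrom,
                pos_a=edge_lo + 1,
                chrom_b=chrom,
                pos_b=edge_hi,
                orientation=OrientationClass.DEL_LIKE,
                n_discordant_pairs=0,
                n_clipped_reads=0,
                resolution=Resolution.INTERVAL,
            )
            confidence = "depth_only"
        annotation = "atrx_partial_deletion" if gene.upper() == "ATRX" else "other"
        return SvCall(
            breakpoint=call_bp,
            genes={gene},
            annotation=annotation,
            confidence=confidence,
        )

    if gene_bps:
        return SvCall(
            breakpoint=gene_bps[0],
            genes={gene},
            annotation="other",
            confidence="breakpoint_only",
        )
    return None


@dataclass(frozen=True)
class CallerCall:
    """One breakpoint call from one external caller (1-based positions)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    svtype: str
    caller: str

    def canonical(self) -> "CallerCall":
        if (self.chrom_b, self.pos_b) < (self.chrom_a, self.pos_a):
            return CallerCall(
                self.chrom_b, self.pos_b, self.chrom_a, self.pos_a,
                self.svtype, self.caller,
            )
        return self


@dataclass(frozen=True)
class ConsensusSv:
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    svtype: str
    callers: tuple[str, ...]
    n_members: int


def merge_sv_callsets(
    callsets: Sequence[tuple[str, Sequence[CallerCall]]],
    params: MergeParams = MergeParams(),
) -> list[ConsensusSv]:
    """Collapse multi-caller call sets and keep multi-caller-supported calls.

    Calls whose two breakpoints both lie within ``params.window`` of a
    member of the same single-linkage component (and whose types match) are
    collapsed to one consensus call at the per-breakpoint median position
    carrying the union of caller names; components with fewer than
    ``params.min_callers`` distinct callers are discarded.
    """
    calls = [
        c.canonical() if c.caller else replace(c, caller=name).canonical()
        for name, cs in callsets
        for c in (replace(x, caller=x.caller or name) for x in cs)
    ]
    grouped: dict[tuple[str, str, str], list[CallerCall]] = {}
    for c in calls:
        grouped.setdefault((c.chrom_a, c.chrom_b, c.svtype), []).append(c)

    out: list[ConsensusSv] = []
    W = params.window
    for (chrom_a, chrom_b, svtype), members in grouped.items():
        members.sort(key=lambda c: (c.pos_a, c.pos_b, c.caller))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            j = i - 1
            while j >= 0 and members[i].pos_a - members[j].pos_a <= W:
                if abs(members[i].pos_b - members[j].pos_b) <= W:
                    uf.union(i, j)
                j -= 1
        comp: dict[int, list[CallerCall]] = defaultdict(list)
        for i, c in enumerate(members):
            comp[uf.find(i)].append(c)
        for group in comp.values():
            callers = sorted({c.caller for c in group})
            if len(callers) < params.min_callers:
                continue
            out.append(
                ConsensusSv(
                    chrom_a=chrom_a,
                    pos_a=int(np.median([c.pos_a for c in group])),
                    chrom_b=chrom_b,
                    pos_b=int(np.median([c.pos_b for c in group])),
                    svtype=svtype,
                    callers=tuple(callers),
                    n_members=len(group),
                )
            )
    out.sort(key=lambda c: (c.chrom_a, c.pos_a, c.chrom_b, c.pos_b, c.svtype))
    return out


def annotate_genes(bp: BreakpointCall, panel: Panel, pad: int = 0) -> set[str]:
    index = PanelIndex(panel)
    genes: set[str] = set()
    for chrom, pos in ((bp.chrom_a, bp.pos_a - 1), (bp.chrom_b, bp.pos_b - 1)):
        for ri in index.overlapping(chrom, pos - pad, pos + 1 + pad):
            gene = panel.regions[ri].gene
            if gene:
                genes.add(gene)
    return genes


def call_svs(
    sam_path: str,
    panel: Panel,
    window: int = 500,
    min_support: int = 3,
    min_mapq: int = 20,
    del_margin_sds: float = 3.0,
    tert_gene: str = "TERT",
    tert_strand: str = "-",
    upstream_window: int = 25_000,
) -> list[SvCall]:
    """End-to-end discordant-pair SV calling with breakpoint refinement."""
    model = fit_fragment_model(sam_path, min_mapq=min_mapq)
    pairs = extract_discordant(sam_path, model, min_mapq=min_mapq)
    clusters = cluster_discordant(pairs, window=window, min_support=min_support)
    # fragment-length-tail guard for deletion-type clusters
    min_del_distance = model.cutoff + del_margin_sds * model.sd
    clusters = [
        c
        for c in clusters
        if c.orientation is not OrientationClass.DEL_LIKE
        or c.median_distance > min_del_distance
    ]
    clips = collect_clips(sam_path, min_mapq=min_mapq)
    try:
        tert_interval = panel.gene_interval(tert_gene)
    except Exception:
        tert_interval = None

    out: list[SvCall] = []
    for cluster in clusters:
        bp = refine_breakpoint(cluster, clips, window=window)
        genes = annotate_genes(bp, panel, pad=window)
        annotation = "other"
        if tert_interval is not None:
            ann = classify_tert_rearrangement(
                bp, tert_interval, strand=tert_strand,
                upstream_window=upstream_window,
            )
            if ann != "other":
                annotation = ann
        out.append(SvCall(breakpoint=bp, genes=genes, annotation=annotation))
    return out


# --- external call-set I/O --------------------------------------------------

def load_sv_tsv(path: str, default_caller: str = "tsv") -> list[CallerCall]:
    """6-column TSV: chromA, posA, chromB, posB, type, caller (1-based)."""
    out: list[CallerCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chroma"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise SvError(f"SV TSV line {lineno}: expected >= 5 columns")
            caller = parts[5] if len(parts) > 5 else default_caller
            out.append(
                CallerCall(parts[0], int(parts[1]), parts[2], int(parts[3]),
                           parts[4], caller)
            )
    return out


def load_sv_vcf(path: str, caller: str) -> list[CallerCall]:
    """Breakend (BND) records from a VCF; one call per mate pair."""
    out: list[CallerCall] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            if "[" not in alt and "]" not in alt:
                continue
            token = alt.replace("]", "[").split("[")[1]
            mate_chrom, mate_pos = token.rsplit(":", 1)
            a = (rec.chrom, rec.pos)
            b = (mate_chrom, int(mate_pos))
            if b < a:
                continue  # keep one record per junction
            svtype = "BND"
            for key in ("SVCLASS", "SVTYPE"):
                try:
                    value = rec.info.get(key)
                except ValueError:  # key absent from the header
                    value = None
                if value:
                    svtype = value[0] if isinstance(value, tuple) else value
                    break
            out.append(CallerCall(a[0], a[1], b[0], b[1], str(svtype), caller))
    return out


def write_sv_vcf(calls: Sequence[SvCall], contigs: Sequence[tuple[str, int]],
                 path: str) -> None:
    """Write calls as paired BND records (VCF 4.2)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##INFO=<ID=DP_PAIRS,Number=1,Type=Integer,Description="Discordant pairs">',
        '##INFO=<ID=CLIPS,Number=1,Type=Integer,Description="Clipped reads">',
        '##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation">',
        '##INFO=<ID=GENES,Number=.,Type=String,Description="Genes at breakpoints">',
    ]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, call in enumerate(calls):
        bp = call.breakpoint
        ida, idb = f"bnd_{i}_a", f"bnd_{i}_b"
        genes = ",".join(sorted(call.genes)) if call.genes else "."
        info_common = (
            f"SVTYPE=BND;DP_PAIRS={bp.n_discordant_pairs};"
            f"CLIPS={bp.n_clipped_reads};ANN={call.annotation};GENES={genes}"
        )
        alt_a = f"N[{bp.chrom_b}:{bp.pos_b}["
        alt_b = f"N]{bp.chrom_a}:{bp.pos_a}]"
        lines.append(
            f"{bp.chrom_a}\t{bp.pos_a}\t{ida}\tN\t{alt_a}\t.\tPASS\t"
            f"{info_common};MATEID={idb}"
        )
        lines.append(
            f"{bp.chrom_b}\t{bp.pos_b}\t{idb}\tN\t{alt_b}\t.\tPASS\t"
            f"{info_common};MATEID={ida}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
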