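"""Panel definition: target regions, gene annotation and analysis bins.

A hybrid-capture panel is a set of genomic target regions, each belonging to
one of three classes:

* ``gene_target`` -- exonic/genic capture regions carrying a gene symbol;
* ``chromosomal_region`` -- tiles over large chromosomal segments whose gain
  or loss is prognostic (1p36, 11q, 17q in neuroblastoma);
* ``reference_probe`` -- probes scattered over presumed copy-number-neutral
  territory, used to normalize depth for copy-number analysis.

Coordinates are BED-style throughout the package: 0-based, half-open.
1-based coordinates appear only at SAM/VCF I/O boundaries.
"""

from __future__ import annotations

import enum
import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO


class PanelError(ValueError):
    """Raised for malformed panel input or invalid configuration."""


class RegionClass(enum.Enum):
    GENE_TARGET = "gene_target"
    CHROMOSOMAL_REGION = "chromosomal_region"
    REFERENCE_PROBE = "reference_probe"


#: labels recognized as prognostic chromosomal segments rather than genes
CHROMOSOMAL_REGION_LABELS = frozenset({"1P36", "11Q", "17Q"})

_REF_LABEL_RE = re.compile(r"^REF(ERENCE)?([_\-].*)?$", re.IGNORECASE)


@dataclass(frozen=True)
class TargetRegion:
    """One merged capture region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    region_class: RegionClass
    gene: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"region end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.region_class is RegionClass.REFERENCE_PROBE and self.gene:
            raise PanelError("reference probes carry no gene symbol")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        """Human-readable identifier used in calls and reports."""
        if self.gene:
            return self.gene
        if self.label:
            return self.label
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Bin:
    """One analysis bin tiling a parent target region."""

    chrom: str
    start: int
    end: int
    region_index: int
    bin_index: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Panel:
    """An ordered, merged set of target regions."""

    regions: list[TargetRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions, key=lambda r: (r.chrom, r.start, r.end)
        )
        # No two same-class regions may overlap after loading.
        seen: dict[tuple[str, RegionClass], int] = {}
        for r in self.regions:
            key = (r.chrom, r.region_class)
            if key in seen and r.start < seen[key]:
                raise PanelError(
                    f"overlapping {r.region_class.value} regions on {r.chrom} "
                    f"near {r.start}"
                )
            seen[key] = max(seen.get(key, 0), r.end)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions if r.gene}

    @property
    def total_target_bp(self) -> int:
        return sum(r.length for r in self.regions)

    @property
    def contigs(self) -> list[str]:
        out: list[str] = []
        for r in self.regions:
            if r.chrom not in out:
                out.append(r.chrom)
        return out

    def regions_by_class(self, region_class: RegionClass) -> list[TargetRegion]:
        return [r for r in self.regions if r.region_class is region_class]

    def gene_interval(self, gene: str) -> TargetRegion:
        """Span of all regions annotated with ``gene`` (single merged interval)."""
        hits = [r for r in self.regions if r.gene == gene]
        if not hits:
            raise PanelError(f"gene not on panel: {gene}")
        chroms = {r.chrom for r in hits}
        if len(chroms) > 1:
            raise PanelError(f"gene {gene} maps to multiple contigs: {chroms}")
        return TargetRegion(
            chrom=hits[0].chrom,
            start=min(r.start for r in hits),
            end=max(r.end for r in hits),
            region_class=RegionClass.GENE_TARGET,
            gene=gene,
        )


def _classify_label(label: str | None) -> tuple[RegionClass, str | None, str | None]:
    """Map a BED name column to (class, gene, label)."""
    if label is None or label in ("", "."):
        return RegionClass.GENE_TARGET, None, None
    if label.upper() in CHROMOSOMAL_REGION_LABELS:
        return RegionClass.CHROMOSOMAL_REGION, None, label
    if _REF_LABEL_RE.match(label):
        return RegionClass.REFERENCE_PROBE, None, "REF"
    return RegionClass.GENE_TARGET, label, label


def _read_gene_table(gene_table: str | TextIO) -> list[tuple[str, str, int, int]]:
    """Parse a gene annotation TSV with columns gene, chrom, start, end."""
    if isinstance(gene_table, str):
        handle: TextIO = io.StringIO(gene_table) if "\t" in gene_table or "\n" in gene_table else open(gene_table)
    else:
        handle = gene_table
    rows: list[tuple[str, str, int, int]] = []
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise PanelError(f"gene table line {lineno}: expected 4 columns")
        try:
            rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
        except ValueError as exc:
            raise PanelError(f"gene table line {lineno}: {exc}") from exc
    return rows


def load_panel(bed: str | TextIO, gene_table: str | TextIO | None = None) -> Panel:
    """Load a panel from BED text (path, text or file object).

    The optional 4th BED column carries the gene symbol or region label
    (``1p36``/``11q``/``17q`` become chromosomal regions, ``REF``-style labels
    become reference probes, anything else is a gene target).  Overlapping or
    bookended records of the same class are merged.  ``gene_table`` optionally
    assigns gene symbols to unlabeled records by interval overlap.
    """
    if isinstance(bed, str):
        if "\n" in bed or "\t" in bed:
            handle: TextIO = io.StringIO(bed)
        else:
            handle = open(bed)
    else:
        handle = bed

    gene_rows = _read_gene_table(gene_table) if gene_table is not None else []

    raw: list[TargetRegion] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PanelError(f"BED line {lineno}: fewer than 3 columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise PanelError(f"BED line {lineno}: non-integer coordinate") from exc
        if end <= start:
            raise PanelError(f"BED line {lineno}: end <= start")
        label = parts[3] if len(parts) > 3 else None
        region_class, gene, lab = _classify_label(label)
        if gene is None and region_class is RegionClass.GENE_TARGET:
            for g, gchrom, gstart, gend in gene_rows:
                if gchrom == chrom and gstart < end and start < gend:
                    gene, lab = g, g
                    break
        raw.append(
            TargetRegion(chrom=chrom, start=start, end=end,
                         region_class=region_class, gene=gene, label=lab)
        )

    return Panel(regions=_merge_same_class(raw))


def _merge_same_class(regions: Iterable[TargetRegion]) -> list[TargetRegion]:
    """Union overlapping/bookended intervals per (chrom, class)."""
    grouped: dict[tuple[str, RegionClass], list[TargetRegion]] = {}
    for r in regions:
        grouped.setdefault((r.chrom, r.region_class), []).append(r)

    merged: list[TargetRegion] = []
    for (chrom, rclass), group in grouped.items():
        group.sort(key=lambda r: (r.start, r.end))
        cur_start, cur_end = group[0].start, group[0].end
        genes = {group[0].gene} if group[0].gene else set()
        labels = {group[0].label} if group[0].label else set()

        def emit(start: int, end: int, genes: set[str], labels: set[str]) -> None:
            merged.append(
                TargetRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    region_class=rclass,
                    gene=";".join(sorted(genes)) if genes else None,
                    label=";".join(sorted(labels)) if labels else None,
                )
            )

        for r in group[1:]:
            if r.start <= cur_end:
                cur_end = max(cur_end, r.end)
                if r.gene:
                    genes.add(r.gene)
                if r.label:
                    labels.add(r.label)
            else:
                emit(cur_start, cur_end, genes, labels)
                cur_start, cur_end = r.start, r.end
                genes = {r.gene} if r.gene else set()
                labels = {r.label} if r.label else set()
        emit(cur_start, cur_end, genes, labels)

    return merged


def write_panel(panel: Panel) -> str:
    """Serialize a panel back to 4-column BED text (round-trips load_panel)."""
    lines = []
    for r in panel.regions:
        if r.region_class is RegionClass.REFERENCE_PROBE:
            label = r.label or "REF"
        elif r.region_class is RegionClass.CHROMOSOMAL_REGION:
            label = r.label or "."
        else:
            label = r.gene or "."
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{label}")
    return "\n".join(lines) + ("\n" if lines else "")


def make_bins(panel: Panel, bin_size: int = 100) -> list[Bin]:
    """Tile every target region with fixed-size bins (last bin may be short)."""
    if bin_size < 10:
        raise PanelError(f"bin_size must be >= 10, got {bin_size}")
    bins: list[Bin] = []
    for region_index, region in enumerate(panel.regions):
        for bin_index, start in enumerate(range(region.start, region.end, bin_size)):
            bins.append(
                Bin(
                    chrom=region.chrom,
                    start=start,
                    end=min(start + bin_size, region.end),
                    region_index=region_index,
                    bin_index=bin_index,
                )
            )
    return bins


def panel_summary(panel: Panel) -> dict:
    """Counts describing the panel: regions, genes, reference probes, target bp."""
    return {
        "n_regions": len(panel.regions),
        "n_genes": len(panel.genes),
        "n_reference_probes": len(
            panel.regions_by_class(RegionClass.REFERENCE_PROBE)
        ),
        "total_target_bp": panel.total_target_bp,
    }


def summary_json(panel: Panel) -> str:
    return json.dumps(panel_summary(panel), indent=2)
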