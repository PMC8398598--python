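"""Alignment QC over the panel: on-target fraction and depth statistics.

"Uniquely aligned" is operationalized as a MAPQ cutoff (default 20);
secondary, supplementary, unmapped and duplicate-flagged records are always
excluded.  Depth counts reference-aligned bases only (CIGAR M/=/X), so
soft-clipped tails never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .panel import Panel


class QcError(ValueError):
    pass


class PanelIndex:
    """Per-chromosome sorted region intervals for fast overlap lookups."""

    def __init__(self, panel: Panel):
        self.panel = panel
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._max_len: dict[str, int] = {}
        tmp: dict[str, list[tuple[int, int, int]]] = {}
        for i, r in enumerate(panel.regions):
            tmp.setdefault(r.chrom, []).append((r.start, r.end, i))
        for chrom, rows in tmp.items():
            rows.sort()
            starts = np.array([s for s, _, _ in rows], dtype=np.int64)
            ends = np.array([e for _, e, _ in rows], dtype=np.int64)
            idx = np.array([i for _, _, i in rows], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, idx)
            self._max_len[chrom] = int((ends - starts).max())

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Region indices overlapping [start, end) by >= 1 bp."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        lo = int(np.searchsorted(starts, start - self._max_len[chrom]))
        hi = int(np.searchsorted(starts, end))
        return [int(idx[j]) for j in range(lo, hi) if ends[j] > start]

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, _ = entry
        lo = int(np.searchsorted(starts, start - self._max_len[chrom]))
        hi = int(np.searchsorted(starts, end))
        for j in range(lo, hi):
            if ends[j] > start:
                return True
        return False


@dataclass
class DepthProfile:
    """Per-base depth over target territory, plus read accounting."""

    panel: Panel
    region_depths: list[np.ndarray]
    n_unique_reads: int = 0
    n_on_target_reads: int = 0
    skipped_contigs: set[str] = field(default_factory=set)

    def region_mean_depths(self) -> np.ndarray:
        return np.array([d.mean() if d.size else 0.0 for d in self.region_depths])

    def all_depths(self) -> np.ndarray:
        if not self.region_depths:
            return np.array([], dtype=np.int64)
        return np.concatenate(self.region_depths)

    def total_on_target_bases(self) -> int:
        return int(sum(int(d.sum()) for d in self.region_depths))


def _usable(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def on_target_fraction(sam_path: str, panel: Panel, min_mapq: int = 20) -> float:
    """Fraction of uniquely aligned reads overlapping any target by >= 1 bp."""
    index = PanelIndex(panel)
    n_unique = n_on = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if not _usable(read, min_mapq):
                continue
            n_unique += 1
            if index.overlaps_any(
                read.reference_name, read.reference_start, read.reference_end
            ):
                n_on += 1
    if n_unique == 0:
        raise QcError("no uniquely aligned reads; on-target fraction undefined")
    return n_on / n_unique


def depth_profile(sam_path: str, panel: Panel, min_mapq: int = 20) -> DepthProfile:
    """Per-base depth over each target region (M/=/X aligned bases only)."""
    index = PanelIndex(panel)
    depths = [np.zeros(r.length, dtype=np.int64) for r in panel.regions]
    profile = DepthProfile(panel=panel, region_depths=depths)
    contigs = {r.chrom for r in panel.regions}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if not _usable(read, min_mapq):
                continue
            profile.n_unique_reads += 1
            chrom = read.reference_name
            if chrom not in contigs:
                profile.skipped_contigs.add(chrom)
                continue
            on_target = False
            for bstart, bend in read.get_blocks():
                for ri in index.overlapping(chrom, bstart, bend):
                    region = panel.regions[ri]
                    lo = max(bstart, region.start) - region.start
                    hi = min(bend, region.end) - region.start
                    if hi > lo:
                        depths[ri][lo:hi] += 1
                        on_target = True
            if on_target:
                profile.n_on_target_reads += 1
    return profile


def coverage_at_fraction(
    profile: DepthProfile, q: float = 0.95, per_region: bool = False
) -> int:
    """Largest depth v such that >= q of target bases have depth >= v.

    With ``per_region`` the quantile is taken over region mean depths
    instead of individual target bases (a laxer reading of "coverage of a
    fraction of target regions"); the base-level default is the stricter,
    standard metric.
    """
    if not 0 < q <= 1:
        raise QcError("q must be in (0, 1]")
    if per_region:
        depths = np.floor(profile.region_mean_depths()).astype(np.int64)
    else:
        depths = profile.all_depths()
    if depths.size == 0:
        raise QcError("empty depth profile")
    desc = np.sort(depths)[::-1]
    k = int(np.ceil(q * depths.size))
    return int(desc[k - 1])


def qc_summary(profile: DepthProfile, q: float = 0.95) -> dict:
    mean_depths = profile.region_mean_depths()
    return {
        "n_unique_reads": profile.n_unique_reads,
        "n_on_target_reads": profile.n_on_target_reads,
        "on_target_fraction": (
            profile.n_on_target_reads / profile.n_unique_reads
            if profile.n_unique_reads
            else float("nan")
        ),
        "mean_target_depth": float(
            profile.all_depths().mean()) if profile.all_depths().size else 0.0,
        "coverage_at_fraction": (
            coverage_at_fraction(profile, q) if profile.all_depths().size else None
        ),
        "q": q,
        "n_regions": len(profile.panel.regions),
        "min_region_mean_depth": float(mean_depths.min()) if mean_depths.size else 0.0,
        "max_region_mean_depth": float(mean_depths.max()) if mean_depths.size else 0.0,
    }
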