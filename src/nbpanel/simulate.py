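"""Synthetic hybrid-capture alignments with known truth.

The generator emulates what a targeted panel run looks like *after*
alignment: paired-end reads with on-target enrichment, a unimodal fragment
size distribution, copy-number segments (including high-level amplification),
SNVs at configured allele fractions, and rearrangement junctions that produce
discordant pairs and soft-clipped reads.  Reads are emitted pre-placed (the
generator computes positions and CIGARs), so the whole calling stack is
testable without an aligner or downloads.

Generative model
----------------
* Fragment lengths ~ Normal(fragment_mean, fragment_sd), truncated below at
  2 x read_length (mates never overlap, so per-site allele draws stay
  independent across reads).
* On-target fragments are placed uniformly such that they overlap a target
  region; the per-segment sampling rate is scaled by
  (purity * CN + (1 - purity) * 2) / 2 over copy-number segments.
* Off-target fragments are placed uniformly outside target +/- flank, at a
  rate calibrated against the realized on-target *read* count so the
  uniquely-aligned on-target read fraction converges to the configured
  value.
* At an SNV site each *fragment* carries the alternate allele with the
  generative probability returned by :func:`expected_vaf`.
* Each rearrangement junction emits chimeric fragments; reads that straddle
  the junction are written with terminal soft-clips at the junction
  coordinate, reads fully on one side become discordant mates.

Fixed seed gives byte-identical FASTA/SAM/JSON output.
"""

from __future__ import annotations

import json
import os
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import Panel


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class CnvSegment:
    """A total-copy-number segment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise SimulationError("copy number must be a non-negative integer")
        if self.end <= self.start:
            raise SimulationError("CNV segment end must exceed start")


@dataclass(frozen=True)
class SnvSpec:
    """A substitution at ``pos`` (0-based) with tumor-cell allele fraction ``vaf``."""

    chrom: str
    pos: int
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if not 0 < self.vaf <= 1:
            raise SimulationError("vaf must be in (0, 1]")
        if self.alt not in "ACGT":
            raise SimulationError("alt must be one of A/C/G/T")


@dataclass(frozen=True)
class SvSpec:
    """A rearrangement junction joining chrom_a:pos_a (left side) to chrom_b:pos_b.

    ``orientation`` is ``"del"`` (same-contig deletion-type junction) or
    ``"translocation"`` (different contigs); both join the sequence left of
    pos_a to the sequence starting at pos_b, read in the forward direction.
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    orientation: str = "translocation"

    def __post_init__(self) -> None:
        if self.orientation not in ("del", "translocation"):
            raise SimulationError(
                f"unsupported junction orientation: {self.orientation!r}"
            )


@dataclass
class SimConfig:
    """Study conditions for one simulated sample."""

    contigs: list[tuple[str, int]]
    panel: Panel
    mean_depth: float = 1000.0
    on_target_fraction: float = 0.45
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    read_length: int = 100
    purity: float = 1.0
    cnv_truth: Sequence[CnvSegment] = ()
    snv_truth: Sequence[SnvSpec] = ()
    sv_truth: Sequence[SvSpec] = ()
    seed: int = 0
    base_error_rate: float = 0.0
    mapq0_fraction: float = 0.0
    flank: int = 500
    emit_sequences: bool = True
    #: separate seed for the reference sequence, so replicate runs (different
    #: ``seed``) can share one genome; defaults to ``seed``
    reference_seed: int | None = None

    def validate(self) -> None:
        lengths = dict(self.contigs)
        if not 0 < self.on_target_fraction <= 1:
            raise SimulationError("on_target_fraction must be in (0, 1]")
        if not 0 < self.purity <= 1:
            raise SimulationError("purity must be in (0, 1]")
        if self.fragment_mean < 2 * self.read_length:
            raise SimulationError("fragment_mean must be >= 2 * read_length")
        for r in self.panel.regions:
            if r.chrom not in lengths or r.end > lengths[r.chrom]:
                raise SimulationError(f"panel region outside contigs: {r}")
        for sv in self.sv_truth:
            for chrom, pos in ((sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b)):
                if chrom not in lengths or not 0 <= pos < lengths[chrom]:
                    raise SimulationError(
                        f"SV breakpoint outside contigs: {chrom}:{pos}"
                    )
        for snv in self.snv_truth:
            if snv.chrom not in lengths or not 0 <= snv.pos < lengths[snv.chrom]:
                raise SimulationError(f"SNV outside contigs: {snv}")
        for seg in self.cnv_truth:
            if seg.chrom not in lengths or seg.end > lengths[seg.chrom]:
                raise SimulationError(f"CNV segment outside contigs: {seg}")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_reference(config: SimConfig) -> dict[str, str]:
    """Deterministic random reference sequences for the configured contigs."""
    ref_seed = config.reference_seed if config.reference_seed is not None else config.seed
    rng = np.random.default_rng([ref_seed, 1])
    out = {}
    for name, length in config.contigs:
        seq = _BASES[rng.integers(0, 4, size=length)]
        out[name] = seq.tobytes().decode()
    return out


def local_copy_number(config: SimConfig, chrom: str, pos: int) -> int:
    for seg in config.cnv_truth:
        if seg.chrom == chrom and seg.start <= pos < seg.end:
            return seg.copy_number
    return 2


def expected_vaf(config: SimConfig, chrom: str, pos: int) -> float:
    """Generative alternate-allele probability at a site.

    The configured ``vaf`` is the allele fraction within tumor cells; the
    observed fraction in a bulk sample is diluted by normal (diploid) cells
    and concentrated by local copy number:

        p_alt = purity * vaf * CN / (purity * CN + (1 - purity) * 2)

    Sites with no configured SNV return 0.0; sites outside the contigs raise.
    """
    lengths = dict(config.contigs)
    if chrom not in lengths or not 0 <= pos < lengths[chrom]:
        raise SimulationError(f"site not covered by configuration: {chrom}:{pos}")
    for snv in config.snv_truth:
        if snv.chrom == chrom and snv.pos == pos:
            cn = local_copy_number(config, chrom, pos)
            denom = config.purity * cn + (1 - config.purity) * 2
            if denom == 0:
                return 0.0
            return config.purity * snv.vaf * cn / denom
    return 0.0


def _rate_segments(config: SimConfig) -> list[tuple[str, int, int, float]]:
    """Split target regions at CNV boundaries; attach a depth multiplier."""
    segments: list[tuple[str, int, int, float]] = []
    for region in config.panel.regions:
        cuts = {region.start, region.end}
        for seg in config.cnv_truth:
            if seg.chrom == region.chrom:
                for p in (seg.start, seg.end):
                    if region.start < p < region.end:
                        cuts.add(p)
        edges = sorted(cuts)
        for s, e in zip(edges[:-1], edges[1:]):
            cn = local_copy_number(config, region.chrom, s)
            mult = (config.purity * cn + (1 - config.purity) * 2) / 2.0
            segments.append((region.chrom, s, e, mult))
    return segments


def _offtarget_space(config: SimConfig) -> list[tuple[str, int, int]]:
    """Intervals outside target +/- flank, flattened across contigs."""
    lengths = dict(config.contigs)
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for r in config.panel.regions:
        by_chrom[r.chrom].append(
            (max(0, r.start - config.flank),
             min(lengths[r.chrom], r.end + config.flank))
        )
    out: list[tuple[str, int, int]] = []
    for chrom, length in config.contigs:
        iv = sorted(by_chrom[chrom])
        merged: list[tuple[int, int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        prev = 0
        for s, e in merged:
            if s > prev:
                out.append((chrom, prev, s))
            prev = e
        if prev < length:
            out.append((chrom, prev, length))
    return out


class _TargetIndex:
    """Merged target intervals per contig, for read-overlap checks."""

    def __init__(self, panel: Panel):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in panel.regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, iv in by_chrom.items():
            iv.sort()
            merged = [list(iv[0])]
            for s, e in iv[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self.ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlap_mask(self, chrom: str, read_starts: np.ndarray,
                     read_length: int) -> np.ndarray:
        """Boolean mask: read [start, start + read_length) overlaps a target."""
        if chrom not in self.starts:
            return np.zeros(read_starts.shape, dtype=bool)
        idx = np.searchsorted(self.starts[chrom], read_starts + read_length,
                              side="left")
        mask = idx > 0
        prev_end = np.where(mask, self.ends[chrom][np.maximum(idx - 1, 0)], 0)
        return mask & (prev_end > read_starts)


class _SnvIndex:
    """Per-chrom sorted SNV positions with generative alt probabilities."""

    def __init__(self, config: SimConfig):
        self.by_chrom: dict[str, tuple[list[int], list[str], list[float]]] = {}
        for snv in sorted(config.snv_truth, key=lambda s: (s.chrom, s.pos)):
            pos, alts, probs = self.by_chrom.setdefault(snv.chrom, ([], [], []))
            pos.append(snv.pos)
            alts.append(snv.alt)
            probs.append(expected_vaf(config, snv.chrom, snv.pos))

    def in_range(self, chrom: str, start: int, end: int):
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return ()
        pos, alts, probs = entry
        lo = bisect_left(pos, start)
        hi = bisect_right(pos, end - 1)
        if lo == hi:
            return ()
        return tuple(zip(pos[lo:hi], alts[lo:hi], probs[lo:hi]))


def _truncated_lengths(rng: np.random.Generator, n: int,
                       config: SimConfig) -> np.ndarray:
    lens = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n))
    return np.clip(lens, 2 * config.read_length, None).astype(np.int64)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    out = list(seq)
    for pos in rng.integers(0, len(seq), size=n_err):
        cur = out[pos]
        choices = [b for b in "ACGT" if b != cur]
        out[pos] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def simulate_reads(config: SimConfig):
    """Generate reference and aligned read records.

    Returns ``(reference, records, truth)``: ``reference`` maps contig name
    to sequence; ``records`` is a coordinate-sorted list of
    ``(tid, pos, sam_line)`` tuples; ``truth`` is the realized truth dict.
    """
    config.validate()
    reference = make_reference(config)
    for snv in config.snv_truth:
        if reference[snv.chrom][snv.pos] == snv.alt:
            raise SimulationError(
                f"SNV alt equals the reference base at {snv.chrom}:{snv.pos}; "
                "the variant would be invisible"
            )
    rng = np.random.default_rng([config.seed, 2])
    snv_index = _SnvIndex(config)
    target_index = _TargetIndex(config.panel)
    lengths = dict(config.contigs)
    tid_of = {name: i for i, (name, _) in enumerate(config.contigs)}
    R = config.read_length
    Fm = config.fragment_mean
    qual = "I" * R
    err = config.base_error_rate
    emit_seq = config.emit_sequences
    records: list[tuple[int, int, str]] = []
    frag_counter = 0
    n_reads_on = 0  # reads overlapping a target
    n_reads_off_from_target_frags = 0

    def emit_pairs(chrom: str, starts: np.ndarray, lens: np.ndarray,
                   count_on_target: bool) -> None:
        """Emit one proper pair per (start, length); positions are 0-based."""
        nonlocal frag_counter, n_reads_on, n_reads_off_from_target_frags
        n = starts.size
        if n == 0:
            return
        tid = tid_of[chrom]
        ref = reference[chrom]
        clen = lengths[chrom]
        starts = np.clip(starts, 0, np.maximum(clen - lens, 0))
        p2 = starts + lens - R
        if count_on_target:
            on1 = target_index.overlap_mask(chrom, starts, R)
            on2 = target_index.overlap_mask(chrom, p2, R)
            n_on = int(on1.sum()) + int(on2.sum())
            n_reads_on += n_on
            n_reads_off_from_target_frags += 2 * n - n_on
        if config.mapq0_fraction > 0:
            mapqs = np.where(rng.random(n) < config.mapq0_fraction, 0, 60)
        else:
            mapqs = None
        snvs_here = chrom in snv_index.by_chrom
        for i in range(n):
            frag_counter += 1
            s = int(starts[i])
            L = int(lens[i])
            q = f"frag{frag_counter:08d}"
            mq = 60 if mapqs is None else int(mapqs[i])
            pos2 = s + L - R
            if emit_seq:
                seq1 = ref[s:s + R]
                seq2 = ref[pos2:pos2 + R]
                if snvs_here:
                    for spos, alt, p_alt in snv_index.in_range(chrom, s, s + L):
                        if rng.random() < p_alt:
                            off1 = spos - s
                            if 0 <= off1 < R:
                                seq1 = seq1[:off1] + alt + seq1[off1 + 1:]
                            off2 = spos - pos2
                            if 0 <= off2 < R:
                                seq2 = seq2[:off2] + alt + seq2[off2 + 1:]
                if err > 0:
                    seq1 = _apply_errors(seq1, rng, err)
                    seq2 = _apply_errors(seq2, rng, err)
                q1, q2 = qual, qual
            else:
                seq1 = seq2 = "*"
                q1 = q2 = "*"
            records.append((
                tid, s,
                f"{q}\t99\t{chrom}\t{s + 1}\t{mq}\t{R}M\t=\t{pos2 + 1}\t{L}\t{seq1}\t{q1}",
            ))
            records.append((
                tid, pos2,
                f"{q}\t147\t{chrom}\t{pos2 + 1}\t{mq}\t{R}M\t=\t{s + 1}\t{-L}\t{seq2}\t{q2}",
            ))

    # --- on-target fragments, rate scaled by local copy number -------------
    for chrom, s, e, mult in _rate_segments(config):
        seg_len = e - s
        lam = config.mean_depth * mult * (seg_len + Fm - 1) / (2 * R)
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        lens = _truncated_lengths(rng, n, config)
        u = rng.random(n)
        starts = s - lens + 1 + np.floor(u * (seg_len + lens - 1)).astype(np.int64)
        emit_pairs(chrom, starts, lens, count_on_target=True)
    n_on_frags = frag_counter

    # --- off-target fragments, calibrated to the realized read counts ------
    p_on = config.on_target_fraction
    if p_on < 1.0 and n_reads_on > 0:
        spots = _offtarget_space(config)
        sizes = np.array([e - s for _, s, e in spots], dtype=np.int64)
        total_free = int(sizes.sum())
        if total_free > 0:
            target_off_reads = (
                n_reads_on * (1 - p_on) / p_on - n_reads_off_from_target_frags
            )
            n_off = int(rng.poisson(max(target_off_reads, 0.0) / 2.0))
            if n_off > 0:
                cum = np.cumsum(sizes)
                picks = rng.integers(0, total_free, size=n_off)
                lens = _truncated_lengths(rng, n_off, config)
                spot_idx = np.searchsorted(cum, picks, side="right")
                order = np.argsort(spot_idx, kind="stable")
                spot_sorted = spot_idx[order]
                boundaries = np.flatnonzero(np.diff(spot_sorted)) + 1
                for group in np.split(order, boundaries):
                    si = int(spot_idx[group[0]])
                    chrom, s, e = spots[si]
                    offsets = picks[group] - (int(cum[si]) - int(sizes[si]))
                    emit_pairs(chrom, s + offsets, lens[group],
                               count_on_target=False)

    # --- rearrangement junctions -------------------------------------------
    truth_sv: list[dict] = []
    chim_counter = 0
    for sv in config.sv_truth:
        lam = config.purity / 2.0 * config.mean_depth * (Fm - 2) / (2 * R)
        n = int(rng.poisson(lam))
        n_disc = n_clip = 0
        lens = _truncated_lengths(rng, n, config)
        for L in lens.tolist():
            chim_counter += 1
            d, c = _emit_chimeric(
                config, reference, records, rng, sv, int(L), tid_of, chim_counter
            )
            n_disc += d
            n_clip += c
        truth_sv.append(
            {
                "chrom_a": sv.chrom_a,
                "pos_a": sv.pos_a,
                "chrom_b": sv.chrom_b,
                "pos_b": sv.pos_b,
                "orientation": sv.orientation,
                "n_fragments": n,
                "n_discordant_pairs": n_disc,
                "n_clipped_reads": n_clip,
            }
        )

    records.sort()

    truth = {
        "seed": config.seed,
        "purity": config.purity,
        "mean_depth": config.mean_depth,
        "on_target_fraction": config.on_target_fraction,
        "n_on_target_fragments": n_on_frags,
        "n_fragments": frag_counter,
        "n_on_target_reads": n_reads_on,
        "cnv": [
            {
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "copy_number": seg.copy_number,
                "expected_ratio": (config.purity * seg.copy_number
                                   + (1 - config.purity) * 2) / 2.0,
            }
            for seg in config.cnv_truth
        ],
        "snv": [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "alt": s.alt,
                "vaf": s.vaf,
                "expected_vaf": expected_vaf(config, s.chrom, s.pos),
            }
            for s in config.snv_truth
        ],
        "sv": truth_sv,
    }
    return reference, records, truth


def _emit_chimeric(config, reference, records, rng, sv: SvSpec, L: int,
                   tid_of: dict[str, int], serial: int) -> tuple[int, int]:
    """Emit one chimeric read pair for a junction; returns (n_discordant, n_clipped)."""
    R = config.read_length
    qname = f"chim{serial:07d}"
    d = int(rng.integers(1, L))  # bases of the fragment on side A
    ref_a, ref_b = reference[sv.chrom_a], reference[sv.chrom_b]
    b_len = L - d
    if sv.pos_a - d < 0 or sv.pos_b + b_len > len(ref_b):
        return 0, 0  # fragment falls off a contig end; drop it
    n_disc = n_clip = 0
    qual = "I" * R

    # read 1: forward, fragment offsets [0, R)
    if d >= R:
        pos1, cig1 = sv.pos_a - d, f"{R}M"
        seq1 = ref_a[pos1:pos1 + R]
    else:
        pos1, cig1 = sv.pos_a - d, f"{d}M{R - d}S"
        seq1 = (ref_a[pos1:sv.pos_a] + ref_b[sv.pos_b:sv.pos_b + (R - d)])[:R]
        n_clip += 1
    # read 2: reverse, fragment offsets [L - R, L)
    if b_len >= R:
        pos2, cig2 = sv.pos_b + b_len - R, f"{R}M"
        seq2 = ref_b[pos2:pos2 + R]
    else:
        a_tail = d - (L - R)  # clipped bases from side A
        pos2, cig2 = sv.pos_b, f"{a_tail}S{b_len}M"
        seq2 = (ref_a[sv.pos_a - a_tail:sv.pos_a] + ref_b[sv.pos_b:sv.pos_b + b_len])[:R]
        n_clip += 1
    if "S" not in cig1 and "S" not in cig2:
        n_disc = 1
    if not config.emit_sequences:
        seq1 = seq2 = qual1 = qual2 = "*"
    else:
        qual1 = "I" * len(seq1)
        qual2 = "I" * len(seq2)

    same = sv.chrom_a == sv.chrom_b
    rnext1 = "=" if same else sv.chrom_b
    rnext2 = "=" if same else sv.chrom_a
    if same:
        span = (pos2 + R) - pos1
        tlen1, tlen2 = span, -span
    else:
        tlen1 = tlen2 = 0
    # flags: paired + mapped mate; r1 first-in-pair with reverse mate, r2 reverse
    records.append((
        tid_of[sv.chrom_a], pos1,
        f"{qname}\t97\t{sv.chrom_a}\t{pos1 + 1}\t60\t{cig1}\t{rnext1}\t"
        f"{pos2 + 1}\t{tlen1}\t{seq1}\t{qual1}",
    ))
    records.append((
        tid_of[sv.chrom_b], pos2,
        f"{qname}\t145\t{sv.chrom_b}\t{pos2 + 1}\t60\t{cig2}\t{rnext2}\t"
        f"{pos1 + 1}\t{tlen2}\t{seq2}\t{qual2}",
    ))
    return n_disc, n_clip


def _sam_text(config: SimConfig, records: list[tuple[int, int, str]]) -> str:
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in config.contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    lines.extend(line for _, _, line in records)
    return "\n".join(lines) + "\n"


def _fasta_text(reference: dict[str, str], width: int = 60) -> str:
    parts = []
    for name, seq in reference.items():
        parts.append(f">{name}")
        parts.extend(seq[i:i + width] for i in range(0, len(seq), width))
    return "\n".join(parts) + "\n"


@dataclass
class SimResult:
    reference_path: str
    sam_path: str
    truth_path: str
    truth: dict


def simulate_dataset(config: SimConfig, out_dir: str) -> SimResult:
    """Run the generator and write reference FASTA, sorted SAM and truth JSON."""
    reference, records, truth = simulate_reads(config)
    os.makedirs(out_dir, exist_ok=True)
    ref_path = os.path.join(out_dir, "reference.fa")
    sam_path = os.path.join(out_dir, "alignments.sam")
    truth_path = os.path.join(out_dir, "truth.json")
    with open(ref_path, "w") as fh:
        fh.write(_fasta_text(reference))
    with open(sam_path, "w") as fh:
        fh.write(_sam_text(config, records))
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimResult(ref_path, sam_path, truth_path, truth)
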