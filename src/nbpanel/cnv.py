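"""Copy-number calling from binned depth ratios against diploid controls.

The model is deliberately simple and matched to high-depth targeted panels:

1. Technically matched control samples with diploid genomes capture the
   platform's per-bin technical variation.  Each control is library-size
   normalized, then the per-bin expected depth is the across-control median
   and the dispersion a MAD-derived standard deviation, floored at
   sqrt(expected depth) (the Poisson lower bound -- identical controls must
   not produce zero dispersion).
2. A sample is normalized onto the control scale by the median of
   expected/observed ratios over the copy-number reference probe bins (all
   unmasked bins if the panel has no reference probes), then every unmasked
   bin gets a ratio r = observed/expected and a z-score against the control
   dispersion.
3. A gene or chromosomal region is called altered only when a strict
   majority of its bins deviates significantly *in the same direction*
   (|z| > z_cut, common sign); mixed directions yield a no-call.
4. The mean ratio over the significant bins is converted to an absolute
   copy-number estimate given tumor purity:
   CN = (ploidy * r - ploidy * (1 - purity)) / purity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import Bin, Panel, RegionClass
from .qc import DepthProfile


class CnvError(ValueError):
    pass


class Direction(enum.Enum):
    GAIN = "gain"
    LOSS = "loss"


class CnvCategory(enum.Enum):
    AMPLIFICATION = "amplification"
    GAIN = "gain"
    NEUTRAL = "neutral"
    LOSS = "loss"
    DEEP_LOSS = "deep_loss"


@dataclass
class ControlModel:
    """Per-bin expected depth and dispersion learned from diploid controls."""

    bins: list[Bin]
    expected: np.ndarray
    dispersion: np.ndarray
    usable: np.ndarray  # bool mask; low/zero-depth bins are unusable
    n_controls: int


@dataclass(frozen=True)
class BinRatio:
    bin: Bin
    depth: float
    expected: float
    ratio: float
    z: float


@dataclass(frozen=True)
class CnvCall:
    region_name: str
    direction: Direction
    category: CnvCategory
    mean_ratio: float
    copy_number: float
    fraction_significant: float
    n_bins: int


@dataclass(frozen=True)
class NoCall:
    region_name: str
    reason: str
    n_bins: int = 0


def bin_depths(profile: DepthProfile, bins: Sequence[Bin]) -> np.ndarray:
    """Mean per-base depth of each bin."""
    out = np.empty(len(bins), dtype=float)
    for i, b in enumerate(bins):
        region = profile.panel.regions[b.region_index]
        arr = profile.region_depths[b.region_index]
        out[i] = arr[b.start - region.start:b.end - region.start].mean()
    return out


def build_control_model(
    control_profiles: Sequence[DepthProfile],
    bins: Sequence[Bin],
    min_expected: float = 10.0,
) -> ControlModel:
    """Aggregate diploid control depth profiles into an expected-depth model."""
    if not control_profiles:
        raise CnvError("at least one control profile required")
    matrix = np.vstack([bin_depths(p, bins) for p in control_profiles])

    # library-size normalization to the pooled median
    lib = np.array([np.median(row[row > 0]) if (row > 0).any() else 0.0
                    for row in matrix])
    if (lib <= 0).any():
        raise CnvError("control profile with no covered bins")
    pooled = float(np.median(lib))
    matrix = matrix * (pooled / lib)[:, None]

    expected = np.median(matrix, axis=0)
    mad_sd = 1.4826 * np.median(np.abs(matrix - expected), axis=0)
    dispersion = np.maximum(mad_sd, np.sqrt(np.maximum(expected, 0.0)))
    usable = expected >= min_expected
    if not usable.any():
        raise CnvError("no usable bins in control model")
    return ControlModel(
        bins=list(bins),
        expected=expected,
        dispersion=dispersion,
        usable=usable,
        n_controls=len(control_profiles),
    )


def bin_ratios(
    sample: DepthProfile, model: ControlModel, panel: Panel
) -> list[BinRatio]:
    """Per-bin observed/expected ratios and z-scores for one sample."""
    obs = bin_depths(sample, model.bins)
    usable = model.usable & (obs >= 0)
    if not usable.any():
        raise CnvError("no unmasked bins")

    # normalize the sample onto the control scale via reference-probe bins
    ref_mask = np.array(
        [
            panel.regions[b.region_index].region_class is RegionClass.REFERENCE_PROBE
            for b in model.bins
        ]
    )
    norm_mask = usable & ref_mask & (obs > 0)
    if not norm_mask.any():
        norm_mask = usable & (obs > 0)
    scale = float(np.median(model.expected[norm_mask] / obs[norm_mask]))
    obs_norm = obs * scale

    out: list[BinRatio] = []
    for i, b in enumerate(model.bins):
        if not usable[i]:
            continue
        exp = float(model.expected[i])
        out.append(
            BinRatio(
                bin=b,
                depth=float(obs_norm[i]),
                expected=exp,
                ratio=float(obs_norm[i] / exp),
                z=float((obs_norm[i] - exp) / model.dispersion[i]),
            )
        )
    return out


def estimate_copy_number(
    mean_ratio: float, purity: float = 1.0, ploidy: float = 2.0
) -> float:
    """Absolute copy number implied by a depth ratio at a given tumor purity."""
    if not 0 < purity <= 1:
        raise CnvError("purity must be in (0, 1]")
    return max(0.0, (ploidy * mean_ratio - ploidy * (1 - purity)) / purity)


def classify_cnv(cn: float) -> CnvCategory:
    """Diagnostic category from an absolute copy-number estimate."""
    if cn < 0:
        raise CnvError("copy number must be >= 0")
    if cn >= 8:
        return CnvCategory.AMPLIFICATION
    if cn >= 2.5:
        return CnvCategory.GAIN
    if cn <= 0.5:
        return CnvCategory.DEEP_LOSS
    if cn <= 1.5:
        return CnvCategory.LOSS
    return CnvCategory.NEUTRAL


def call_region_cnv(
    region_name: str,
    ratios: Sequence[BinRatio],
    z_cut: float = 3.0,
    majority: float = 0.5,
    purity: float = 1.0,
    min_bins: int = 3,
) -> CnvCall | NoCall:
    """Majority-of-bins rule over one gene or chromosomal region."""
    n = len(ratios)
    if n < min_bins:
        return NoCall(region_name, "insufficient_bins", n_bins=n)
    z = np.array([r.z for r in ratios])
    pos = z > z_cut
    neg = z < -z_cut
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos > 0 and n_neg > 0:
        return NoCall(region_name, "mixed_direction", n_bins=n)
    n_sig = max(n_pos, n_neg)
    if n_sig <= majority * n:
        return NoCall(region_name, "no_majority", n_bins=n)
    sig_mask = pos if n_pos else neg
    mean_ratio = float(np.mean([r.ratio for r, m in zip(ratios, sig_mask) if m]))
    cn = estimate_copy_number(mean_ratio, purity=purity)
    category = classify_cnv(cn)
    direction = Direction.GAIN if n_pos else Direction.LOSS
    return CnvCall(
        region_name=region_name,
        direction=direction,
        category=category,
        mean_ratio=mean_ratio,
        copy_number=cn,
        fraction_significant=n_sig / n,
        n_bins=n,
    )


def call_cnvs(
    sample: DepthProfile,
    model: ControlModel,
    panel: Panel,
    purity: float = 1.0,
    z_cut: float = 3.0,
    majority: float = 0.5,
) -> list[CnvCall | NoCall]:
    """Call every gene and chromosomal region on the panel.

    Bins are grouped by region name, so multi-exon genes and multi-tile
    chromosomal regions are each evaluated as one unit.  Reference probes
    are never called.
    """
    ratios = bin_ratios(sample, model, panel)
    grouped: dict[str, list[BinRatio]] = {}
    for r in ratios:
        region = panel.regions[r.bin.region_index]
        if region.region_class is RegionClass.REFERENCE_PROBE:
            continue
        grouped.setdefault(region.name, []).append(r)
    return [
        call_region_cnv(name, rs, z_cut=z_cut, majority=majority, purity=purity)
        for name, rs in sorted(grouped.items())
    ]


def ratios_tsv(ratios: Sequence[BinRatio]) -> str:
    """Per-bin ratio table (chrom, start, end, depth, expected, ratio, z)."""
    lines = ["chrom\tstart\tend\tdepth\texpected\tratio\tz"]
    for r in ratios:
        lines.append(
            f"{r.bin.chrom}\t{r.bin.start}\t{r.bin.end}\t"
            f"{r.depth:.3f}\t{r.expected:.3f}\t{r.ratio:.4f}\t{r.z:.3f}"
        )
    return "\n".join(lines) + "\n"
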