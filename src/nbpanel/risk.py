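"""Marker aggregation, telomere-maintenance status and risk stratification.

The classification rule is a small truth table over two axes:

* **Telomere maintenance (TMM)** -- any of MYCN amplification, TERT
  rearrangement (upstream or intragenic, reported distinctly), or an ATRX
  alteration (SNV or deletion).  One positive marker gives that marker's
  status; two or more give ``multiple``; none gives ``none``.
* **Pathway hits** -- SNVs or amplifications in RAS/MAPK or p53/MDM2
  pathway gene sets (germline-flagged SNVs are excluded by default).

A tumor with active telomere maintenance *and* a pathway hit is
ultra-high-risk; telomere maintenance alone is high-risk; without a
detected TMM marker the sample is reported ``tmm_negative`` with an
explicit caveat (ALT and telomerase expression are not assessed by a
DNA panel, so TMM-negative is not a low-risk claim).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CnvCall, CnvCategory, NoCall
from .snv import SnvCall
from .sv import SvCall


class RiskError(ValueError):
    pass


class TmmStatus(enum.Enum):
    MYCN_AMPLIFICATION = "mycn_amplification"
    TERT_REARRANGEMENT = "tert_rearrangement"
    ATRX_ALTERATION = "atrx_alteration"
    MULTIPLE = "multiple"
    NONE = "none"


class RiskClass(enum.Enum):
    ULTRA_HIGH_RISK = "ultra_high_risk"
    HIGH_RISK_TMM = "high_risk_tmm"
    TMM_NEGATIVE = "tmm_negative"


#: Default pathway gene sets; user-overridable (e.g., via a TSV).  These are
#: a documented stand-in for a site-specific curation.
DEFAULT_PATHWAY_GENES: dict[str, frozenset[str]] = {
    "RAS_MAPK": frozenset(
        {"ALK", "NRAS", "KRAS", "HRAS", "BRAF", "RAF1", "NF1", "PTPN11", "FGFR1"}
    ),
    "p53_MDM2": frozenset({"TP53", "MDM2", "PPM1D", "CDKN2A"}),
}

TERT_ANNOTATIONS = frozenset({"tert_upstream", "tert_intragenic"})


@dataclass
class TumorProfile:
    """One sample's aggregated marker calls."""

    sample_id: str
    cnv_calls: Sequence[CnvCall | NoCall] = ()
    sv_calls: Sequence[SvCall] = ()
    snv_calls: Sequence[SnvCall] = ()
    timepoint: str = "primary_biopsy"
    material: str = "fresh_frozen"
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.timepoint not in ("primary_biopsy", "post_induction_surgery", "relapse"):
            raise RiskError(f"unknown timepoint: {self.timepoint}")
        if self.material not in ("fresh_frozen", "FFPE"):
            raise RiskError(f"unknown material: {self.material}")
        if not 0 < self.purity <= 1:
            raise RiskError("purity must be in (0, 1]")

    def gene_cnv(self, name: str) -> CnvCall | None:
        for c in self.cnv_calls:
            if isinstance(c, CnvCall) and c.region_name == name:
                return c
        return None


@dataclass(frozen=True)
class RiskCall:
    sample_id: str
    telomere_maintenance: TmmStatus
    tmm_markers: tuple[str, ...]
    pathway_hits: tuple[str, ...]
    risk_class: RiskClass
    caveats: tuple[str, ...] = ()


def _tmm_markers(profile: TumorProfile) -> list[str]:
    markers: list[str] = []
    mycn = profile.gene_cnv("MYCN")
    if mycn is not None and mycn.category is CnvCategory.AMPLIFICATION:
        markers.append("mycn_amplification")
    tert_types = sorted(
        {sv.annotation for sv in profile.sv_calls if sv.annotation in TERT_ANNOTATIONS}
    )
    if tert_types:
        # one TMM marker, but the breakpoint class is reported distinctly
        markers.append("tert_rearrangement:" + "+".join(tert_types))
    atrx_snv = any(c.gene == "ATRX" for c in profile.snv_calls)
    atrx_sv = any(
        sv.annotation == "atrx_partial_deletion"
        or ("ATRX" in sv.genes and sv.confidence != "breakpoint_only")
        for sv in profile.sv_calls
    )
    atrx_cnv = profile.gene_cnv("ATRX")
    atrx_loss = atrx_cnv is not None and atrx_cnv.category in (
        CnvCategory.LOSS,
        CnvCategory.DEEP_LOSS,
    )
    if atrx_snv or atrx_sv or atrx_loss:
        markers.append("atrx_alteration")
    return markers


def telomere_maintenance_status(profile: TumorProfile) -> TmmStatus:
    """TMM status from the sample's marker calls."""
    markers = _tmm_markers(profile)
    if not markers:
        return TmmStatus.NONE
    if len(markers) > 1:
        return TmmStatus.MULTIPLE
    key = markers[0].split(":")[0]
    return TmmStatus(key)


def pathway_hits(
    profile: TumorProfile,
    gene_sets: Mapping[str, frozenset[str]] = DEFAULT_PATHWAY_GENES,
    include_germline: bool = False,
) -> tuple[str, ...]:
    """Pathways with at least one SNV or amplification in their gene set."""
    if not gene_sets:
        raise RiskError("empty pathway gene sets")
    hit: set[str] = set()
    for pathway, genes in gene_sets.items():
        for c in profile.snv_calls:
            if c.gene in genes and (include_germline or not c.possible_germline):
                hit.add(pathway)
                break
        else:
            for c in profile.cnv_calls:
                if (
                    isinstance(c, CnvCall)
                    and c.region_name in genes
                    and c.category is CnvCategory.AMPLIFICATION
                ):
                    hit.add(pathway)
                    break
    return tuple(sorted(hit))


def classify_risk(
    profile: TumorProfile,
    gene_sets: Mapping[str, frozenset[str]] = DEFAULT_PATHWAY_GENES,
    include_germline: bool = False,
) -> RiskCall:
    """Truth table: TMM x pathway hits -> risk class."""
    tmm = telomere_maintenance_status(profile)
    hits = pathway_hits(profile, gene_sets, include_germline=include_germline)
    caveats: list[str] = []
    if tmm is TmmStatus.NONE:
        risk = RiskClass.TMM_NEGATIVE
        caveats.append(
            "ALT and telomerase expression unassessed; tmm_negative is not a "
            "low-risk claim"
        )
    elif hits:
        risk = RiskClass.ULTRA_HIGH_RISK
    else:
        risk = RiskClass.HIGH_RISK_TMM
    return RiskCall(
        sample_id=profile.sample_id,
        telomere_maintenance=tmm,
        tmm_markers=tuple(_tmm_markers(profile)),
        pathway_hits=hits,
        risk_class=risk,
        caveats=tuple(caveats),
    )


# --- FISH comparison --------------------------------------------------------

@dataclass(frozen=True)
class FishResult:
    """A FISH reference result: per-ratio-class cell fractions (percent)."""

    marker: str
    class_fractions: tuple[tuple[str, float], ...]
    overall_call: str | None = None

    def __post_init__(self) -> None:
        if any(frac < 0 for _, frac in self.class_fractions):
            raise RiskError("FISH class fractions must be >= 0")
        if sum(frac for _, frac in self.class_fractions) > 100 + 1e-9:
            raise RiskError("FISH class fractions sum above 100%")


def aggregate_fish_fraction(fish: FishResult) -> float:
    """Total percent of cells carrying the aberration (sum over ratio classes)."""
    return float(sum(frac for _, frac in fish.class_fractions))


# --- cohort concordance -----------------------------------------------------

@dataclass(frozen=True)
class Discordance:
    sample_id: str
    marker: str
    panel_value: bool
    reference_value: bool


@dataclass
class ConcordanceReport:
    counts: dict[str, dict[str, int]]
    discordant: list[Discordance]
    n_samples: int


def concordance(panel_calls: pd.DataFrame, reference_calls: pd.DataFrame) -> ConcordanceReport:
    """Per-marker 2x2 agreement between panel and reference marker tables.

    Both tables are indexed by sample id with one boolean column per
    marker; sample ids must match exactly.
    """
    missing = set(panel_calls.index).symmetric_difference(reference_calls.index)
    if missing:
        raise RiskError(f"sample id mismatch between tables: {sorted(missing)}")
    markers = [m for m in panel_calls.columns if m in reference_calls.columns]
    counts: dict[str, dict[str, int]] = {}
    discordant: list[Discordance] = []
    for marker in markers:
        p = panel_calls[marker].astype(bool)
        r = reference_calls.loc[panel_calls.index, marker].astype(bool)
        counts[marker] = {
            "both_positive": int((p & r).sum()),
            "panel_only": int((p & ~r).sum()),
            "reference_only": int((~p & r).sum()),
            "both_negative": int((~p & ~r).sum()),
        }
        for sample_id in panel_calls.index[p != r]:
            discordant.append(
                Discordance(
                    sample_id=str(sample_id),
                    marker=marker,
                    panel_value=bool(p[sample_id]),
                    reference_value=bool(r[sample_id]),
                )
            )
    return ConcordanceReport(
        counts=counts, discordant=discordant, n_samples=len(panel_calls)
    )


# --- oncoplot-style cohort matrix -------------------------------------------

_RISK_ORDER = {
    RiskClass.ULTRA_HIGH_RISK: 0,
    RiskClass.HIGH_RISK_TMM: 1,
    RiskClass.TMM_NEGATIVE: 2,
}

#: markers always shown as dedicated rows, before per-gene SNV rows
MARKER_ROWS = ("MYCN", "1p36", "11q", "17q", "TERT", "ATRX")


def _profile_cells(profile: TumorProfile) -> dict[str, str]:
    cells: dict[str, str] = {}
    for c in profile.cnv_calls:
        if not isinstance(c, CnvCall):
            continue
        cells[c.region_name] = c.category.value
    for sv in profile.sv_calls:
        if sv.annotation in TERT_ANNOTATIONS:
            cells["TERT"] = "rearrangement"
        if sv.annotation == "atrx_partial_deletion":
            cells["ATRX"] = "partial_deletion"
    for c in profile.snv_calls:
        if c.gene:
            prev = cells.get(c.gene)
            cells[c.gene] = "SNV" if prev in (None, "neutral") else prev + "+SNV"
    return {k: v for k, v in cells.items() if v != "neutral"}


def build_oncoplot_matrix(profiles: Sequence[TumorProfile]) -> pd.DataFrame:
    """Genes x samples categorical matrix, columns sorted by risk then burden."""
    per_sample = {p.sample_id: _profile_cells(p) for p in profiles}
    risk = {p.sample_id: classify_risk(p) for p in profiles}
    gene_rows = sorted(
        {g for cells in per_sample.values() for g in cells} - set(MARKER_ROWS)
    )
    rows = [m for m in MARKER_ROWS] + gene_rows

    def sort_key(sample_id: str):
        burden = len(per_sample[sample_id])
        return (_RISK_ORDER[risk[sample_id].risk_class], -burden, sample_id)

    columns = sorted(per_sample, key=sort_key)
    data = {
        s: [per_sample[s].get(row, "none") for row in rows] for s in columns
    }
    matrix = pd.DataFrame(data, index=rows, columns=columns)
    matrix.index.name = "marker"
    return matrix


def render_oncoplot(matrix: pd.DataFrame, path: str) -> None:
    """Minimal categorical heatmap rendering of the cohort matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    categories = sorted({v for v in matrix.values.ravel()})
    cat_index = {c: i for i, c in enumerate(categories)}
    grid = np.vectorize(cat_index.__getitem__)(matrix.to_numpy()).astype(float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.shape[1]), max(3, 0.4 * matrix.shape[0]))
    )
    im = ax.imshow(grid, aspect="auto", cmap="tab20", vmin=0, vmax=max(len(categories) - 1, 1))
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=im.cmap(im.norm(cat_index[c])))
        for c in categories
    ]
    ax.legend(handles, categories, loc="upper left", bbox_to_anchor=(1.02, 1),
              fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
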