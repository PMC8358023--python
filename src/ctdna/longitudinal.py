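"""Longitudinal average-VAF tracking, clearance, concordance and emergence.

Plasma tumor burden is summarized per patient per timepoint as the
unweighted mean VAF (percent) over that sample's finalized somatic set —
the *average VAF*.  The denominator is the set of mutations detected at
that timepoint, so a sample with nothing detected has average VAF 0; a
patient whose average VAF falls strictly below the 1% cutoff at the first
response evaluation is classified as *cleared*.

Tissue–plasma concordance matches finalized tissue variants against the
plasma somatic set by exact key, then checks whether unmatched tissue
variants are present in the *unfiltered* (post-class, pre-threshold)
plasma calls at sub-threshold VAF — the "rescue" that quantifies how much
sensitivity the 1% cutoff costs.  The symmetric check is applied to
plasma-only variants against unfiltered tissue calls.

Emergent (candidate resistance) mutations are those present in the
finalized plasma set at progression but absent from every earlier plasma
somatic set and from the tissue somatic set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .somatic_filter import SomaticSet
from .variant_io import (
    ClinicalRecord,
    Material,
    TISSUE_MATERIALS,
    VariantCall,
    VariantKey,
    timepoint_rank,
)

log = logging.getLogger(__name__)

__all__ = [
    "TrajectoryPoint",
    "TrajectoryDelta",
    "ConcordanceReport",
    "average_vaf",
    "vaf_trajectory",
    "classify_clearance",
    "detect_emergent",
    "concordance",
    "AnnotatedCall",
    "load_hotspots",
    "load_pathogenicity",
    "annotate",
]

DEFAULT_CLEARANCE_CUTOFF_PCT = 1.0


@dataclass(frozen=True)
class TrajectoryPoint:
    patient_id: str
    timepoint: str
    average_vaf_pct: float
    n_mutations: int
    tumor_size_mm: float | None = None
    #: optional comparator columns (plasma DNA yield based burden proxies)
    cfdna_conc: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.average_vaf_pct <= 100.0:
            raise ValueError("average_vaf_pct must be in [0, 100]")
        if self.n_mutations == 0 and self.average_vaf_pct != 0.0:
            raise ValueError("no mutations implies average VAF 0")

    @property
    def vaf_times_conc(self) -> float | None:
        if self.cfdna_conc is None:
            return None
        return self.average_vaf_pct * self.cfdna_conc


@dataclass(frozen=True)
class TrajectoryDelta:
    """Change from baseline to a follow-up timepoint."""

    patient_id: str
    timepoint: str
    vaf_delta_points: float  # percentage points
    size_delta_pct: float | None  # percent change of the target-lesion size


def average_vaf(somatic: SomaticSet) -> float:
    """Unweighted mean VAF (percent) over a finalized cfDNA somatic set.

    An empty set maps to 0 by convention (nothing detectable in plasma).
    """
    if somatic.material is not None and somatic.material != Material.CFDNA:
        raise ValueError(f"average VAF is a plasma summary; got {somatic.material}")
    if not somatic.calls:
        return 0.0
    return sum(c.vaf_pct for c in somatic.calls) / len(somatic.calls)


def vaf_trajectory(
    somatic_sets: Sequence[SomaticSet],
    clinical: ClinicalRecord | None = None,
) -> tuple[list[TrajectoryPoint], list[TrajectoryDelta]]:
    """Average-VAF trajectory of one patient, ordered by timepoint.

    Deltas are reported against baseline: VAF delta in percentage points,
    tumor-size delta as percent change of the matched target-lesion
    measurement (absent when either measurement is missing).
    """
    if not somatic_sets:
        raise ValueError("need at least one cfDNA somatic set")
    patients = {s.patient_id for s in somatic_sets if s.patient_id is not None}
    if len(patients) > 1:
        raise ValueError(f"trajectory is per-patient; got {sorted(patients)}")
    patient_id = patients.pop() if patients else (clinical.patient_id if clinical else "")
    ordered = sorted(somatic_sets, key=lambda s: timepoint_rank(s.timepoint or "baseline"))
    if ordered[0].timepoint != "baseline":
        raise ValueError("trajectory requires a baseline sample")
    sizes = clinical.tumor_size_mm if clinical else {}
    conc = clinical.cfdna_conc if clinical else None
    points = [
        TrajectoryPoint(
            patient_id=patient_id,
            timepoint=s.timepoint,
            average_vaf_pct=average_vaf(s),
            n_mutations=len(s.calls),
            tumor_size_mm=sizes.get(s.timepoint),
            cfdna_conc=conc if s.timepoint == "baseline" else None,
        )
        for s in ordered
    ]
    base = points[0]
    deltas = []
    for pt in points[1:]:
        size_delta = None
        if base.tumor_size_mm and pt.tumor_size_mm is not None:
            size_delta = 100.0 * (pt.tumor_size_mm - base.tumor_size_mm) / base.tumor_size_mm
        deltas.append(
            TrajectoryDelta(
                patient_id=patient_id,
                timepoint=pt.timepoint,
                vaf_delta_points=pt.average_vaf_pct - base.average_vaf_pct,
                size_delta_pct=size_delta,
            )
        )
    return points, deltas


def classify_clearance(
    points: Sequence[TrajectoryPoint],
    cutoff_pct: float = DEFAULT_CLEARANCE_CUTOFF_PCT,
    first_eval: str = "eval1",
) -> str:
    """Classify plasma clearance at the first response evaluation.

    ``cleared`` iff the first-evaluation average VAF is strictly below the
    cutoff (exactly 1.0% is *not* cleared).  A patient without a
    first-evaluation sample is ``unknown`` and excluded from downstream
    survival comparisons.
    """
    for pt in points:
        if pt.timepoint == first_eval:
            return "cleared" if pt.average_vaf_pct < cutoff_pct else "not_cleared"
    return "unknown"


def detect_emergent(
    pd_set: SomaticSet | None,
    earlier_cfdna_sets: Sequence[SomaticSet],
    tissue_set: SomaticSet | None,
) -> list[VariantCall]:
    """Mutations newly detected in plasma at progression.

    A finalized PD call is emergent iff its key appears in none of the
    patient's earlier plasma somatic sets nor in the tissue somatic set.
    """
    if pd_set is None:
        raise ValueError("no PD plasma sample: emergent detection undefined")
    seen: set[VariantKey] = set()
    for s in earlier_cfdna_sets:
        seen |= s.keys
    if tissue_set is not None:
        seen |= tissue_set.keys
    return [c for c in pd_set.calls if c.key not in seen]


@dataclass(frozen=True)
class ConcordanceReport:
    """Tissue vs plasma variant agreement for one patient."""

    patient_id: str
    n_tissue: int
    n_matched: int
    n_unmatched: int
    n_rescued_subthreshold: int
    n_ctdna_only: int
    n_ctdna_only_subthreshold_in_tissue: int
    patient_covered: bool

    def __post_init__(self) -> None:
        if self.n_matched + self.n_unmatched != self.n_tissue:
            raise ValueError("matched + unmatched must equal tissue total")
        if self.n_rescued_subthreshold > self.n_unmatched:
            raise ValueError("rescued is a subset of unmatched")


def _match_keys(keys: set[VariantKey], other: set[VariantKey], positional: bool) -> set[VariantKey]:
    if not positional:
        return keys & other
    other_pos = {(k.chrom, k.pos) for k in other}
    return {k for k in keys if (k.chrom, k.pos) in other_pos}


def concordance(
    tissue_somatic: SomaticSet,
    cfdna_somatic: SomaticSet,
    cfdna_unfiltered: Sequence[VariantCall],
    tissue_unfiltered: Sequence[VariantCall] = (),
    positional: bool = False,
) -> ConcordanceReport:
    """Tissue–plasma concordance with sub-threshold rescue.

    ``cfdna_unfiltered`` (and optionally ``tissue_unfiltered``) are the
    post-class, pre-threshold call lists: an unmatched tissue variant is
    *rescued* when it appears there with VAF > 0 (i.e. it was observed in
    plasma but failed the cfDNA threshold).  ``positional=True`` matches
    by chrom+pos only, tolerating indel-representation drift.
    """
    for s in (tissue_somatic, cfdna_somatic):
        if (
            tissue_somatic.patient_id is not None
            and cfdna_somatic.patient_id is not None
            and tissue_somatic.patient_id != cfdna_somatic.patient_id
        ):
            raise ValueError("concordance inputs must come from one patient")
    tissue_keys = tissue_somatic.keys
    plasma_keys = cfdna_somatic.keys
    matched = _match_keys(tissue_keys, plasma_keys, positional)
    unmatched = tissue_keys - matched
    plasma_sub = {c.key for c in cfdna_unfiltered if c.vaf > 0} - plasma_keys
    rescued = _match_keys(unmatched, plasma_sub, positional)
    ctdna_only = plasma_keys - _match_keys(plasma_keys, tissue_keys, positional)
    tissue_sub = {c.key for c in tissue_unfiltered if c.vaf > 0} - tissue_keys
    ctdna_only_sub = _match_keys(ctdna_only, tissue_sub, positional)
    return ConcordanceReport(
        patient_id=tissue_somatic.patient_id or cfdna_somatic.patient_id or "",
        n_tissue=len(tissue_keys),
        n_matched=len(matched),
        n_unmatched=len(unmatched),
        n_rescued_subthreshold=len(rescued),
        n_ctdna_only=len(ctdna_only),
        n_ctdna_only_subthreshold_in_tissue=len(ctdna_only_sub),
        patient_covered=(len(unmatched) == 0),
    )


# ---------------------------------------------------------------------------
# Hotspot / pathogenicity annotation (bundled lookup tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedCall:
    call: VariantCall
    hotspot: str  # hotspot label ("KRAS G12V", ...) or "none"
    pathogenicity: str  # pathogenic | likely_pathogenic | uncertain | none

    @property
    def is_hotspot(self) -> bool:
        return self.hotspot != "none"


def _data_path(name: str):
    return resources.files("ctdna.data").joinpath(name)


def load_hotspots(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the (gene, HGVS p.) -> hotspot-label table.

    Covers the canonical RAS/RAF/MEK activating codons (KRAS G12/G13/Q61,
    NRAS G12/G13/Q61, BRAF V600, MAP2K1 K57).  Lookups are total: missing
    entries mean "none".
    """
    src = Path(path).open() if path is not None else _data_path("hotspots.tsv").open()
    table: dict[tuple[str, str], str] = {}
    with src as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[(row["gene"], row["aa_change"])] = row["label"]
    return table


def load_pathogenicity(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the (gene, HGVS c.) -> pathogenicity-class table (offline
    snapshot of database labels for the panel's recurrent alleles)."""
    src = Path(path).open() if path is not None else _data_path("pathogenicity.tsv").open()
    table: dict[tuple[str, str], str] = {}
    with src as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[(row["gene"], row["base_change"])] = row["classification"]
    return table


def annotate(
    call: VariantCall,
    hotspots: Mapping[tuple[str, str], str],
    pathogenicity: Mapping[tuple[str, str], str],
) -> AnnotatedCall:
    """Attach hotspot and pathogenicity labels; unknown entries are "none"."""
    hotspot = "none"
    if call.aa_change is not None:
        hotspot = hotspots.get((call.gene, call.aa_change), "none")
    patho = "none"
    if call.base_change is not None:
        patho = pathogenicity.get((call.gene, call.base_change), "none")
    return AnnotatedCall(call=call, hotspot=hotspot, pathogenicity=patho)
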