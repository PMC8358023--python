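"""The somatic filter cascade for plasma/tissue targeted panel calls.

Stages, in canonical order:

1. functional-class selection — keep missense, stop-gain, stop-loss,
   in-frame deletion and frameshift calls (possibly functional variants);
2. material-specific thresholds — cfDNA: VAF >= 1% and >= 10 variant
   reads; tissue: VAF >= 10% and >= 10 variant reads (boundaries
   inclusive);
3. patient-matched PBMC germline subtraction — PBMC calls at VAF >= 20%
   are germline and removed from the same patient's cfDNA/tissue results;
4. cohort blacklist — PBMC calls below 20% VAF pooled across all PBMC
   samples form a blacklist of recurrent noise / clonal-hematopoiesis
   alleles removed from every sample;
5. optional manual-exclusion hook standing in for interactive review of
   alignments (a no-op unless keys are supplied).

The 20% PBMC boundary is a single comparator: a PBMC call is germline
iff VAF >= 20%, blacklist candidate iff VAF < 20% — never both, never
neither.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variant_io import (
    FunctionalClass,
    Material,
    SampleMeta,
    TISSUE_MATERIALS,
    VariantCall,
    VariantKey,
)

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "Blacklist",
    "SomaticSet",
    "Disposition",
    "filter_functional",
    "filter_thresholds",
    "extract_germline",
    "build_blacklist",
    "finalize_somatic",
    "run_cascade",
    "write_blacklist",
    "read_blacklist",
]

DEFAULT_ALLOWED_CLASSES = frozenset(
    {
        FunctionalClass.MISSENSE,
        FunctionalClass.STOP_GAIN,
        FunctionalClass.STOP_LOSS,
        FunctionalClass.INFRAME_DELETION,
        FunctionalClass.FRAMESHIFT,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade, in percent (converted internally).

    Defaults are the analysis' canonical values: cfDNA calls need at least
    1% VAF and 10 variant reads, tissue calls at least 10% VAF and 10
    variant reads, and PBMC calls at or above 20% VAF are treated as
    germline.
    """

    cfdna_min_vaf_pct: float = 1.0
    cfdna_min_alt_reads: int = 10
    tissue_min_vaf_pct: float = 10.0
    tissue_min_alt_reads: int = 10
    germline_min_vaf_pct: float = 20.0
    allowed_classes: frozenset[FunctionalClass] = DEFAULT_ALLOWED_CLASSES
    #: "cohort" applies the blacklist to every patient; "patient" restricts
    #: it to keys seen in the same patient's PBMC (sensitivity analysis).
    blacklist_scope: str = "cohort"
    #: minimum number of distinct PBMC samples a key must appear in.
    blacklist_min_recurrence: int = 1

    def __post_init__(self) -> None:
        for name in ("cfdna_min_vaf_pct", "tissue_min_vaf_pct", "germline_min_vaf_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cfdna_min_alt_reads <= 0 or self.tissue_min_alt_reads <= 0:
            raise ValueError("minimum read counts must be > 0")
        if not self.allowed_classes:
            raise ValueError("allowed_classes must be non-empty")
        if self.blacklist_scope not in ("cohort", "patient"):
            raise ValueError("blacklist_scope must be 'cohort' or 'patient'")
        if self.blacklist_min_recurrence < 1:
            raise ValueError("blacklist_min_recurrence must be >= 1")


@dataclass
class Blacklist:
    """Cohort-level recurrent-noise / clonal-hematopoiesis variant keys.

    ``provenance`` records, per key, every (sample_id, vaf) PBMC
    observation below the germline threshold that contributed.
    """

    entries: set[VariantKey] = field(default_factory=set)
    provenance: dict[VariantKey, list[tuple[str, float]]] = field(default_factory=dict)
    #: per key, the patients whose PBMC contributed (for patient scoping).
    patients: dict[VariantKey, set[str]] = field(default_factory=dict)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


class Disposition:
    KEPT = "kept"
    CLASS = "dropped:class"
    THRESHOLD = "dropped:threshold"
    GERMLINE = "dropped:germline"
    BLACKLIST = "dropped:blacklist"
    MANUAL = "dropped:manual"


@dataclass
class SomaticSet:
    """Finalized somatic calls of one sample plus the full cascade log."""

    sample_id: str
    calls: list[VariantCall]
    cascade_log: list[tuple[VariantCall, str]]
    patient_id: str | None = None
    material: Material | None = None
    timepoint: str | None = None

    @property
    def keys(self) -> set[VariantKey]:
        return {c.key for c in self.calls}

    def disposition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, disp in self.cascade_log:
            counts[disp] = counts.get(disp, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Cascade stages
# ---------------------------------------------------------------------------

def filter_functional(
    calls: Sequence[VariantCall], config: FilterConfig | None = None
) -> list[VariantCall]:
    """Keep only calls in the allowed functional classes, order preserved."""
    config = config or FilterConfig()
    return [c for c in calls if c.functional_class in config.allowed_classes]


def _passes_threshold(call: VariantCall, min_vaf_pct: float, min_alt: int) -> bool:
    if call.depth:
        # exact comparison on counts: alt/depth >= pct/100 without the
        # float rounding that 100*(alt/depth) can introduce at boundaries
        vaf_ok = 100.0 * call.alt_reads >= min_vaf_pct * call.depth - 1e-9
    else:
        vaf_ok = call.vaf_pct >= min_vaf_pct - 1e-9
    if not vaf_ok:
        return False
    if call.alt_reads is None:
        # Report-style input without read support: the read-count criterion
        # cannot be evaluated and is waived (the VAF criterion still applies).
        log.warning("%s: no read counts; read-count threshold waived", call.key)
        return True
    return call.alt_reads >= min_alt


def filter_thresholds(
    calls: Sequence[VariantCall], material: Material, config: FilterConfig | None = None
) -> list[VariantCall]:
    """Apply the material-specific VAF / variant-read thresholds.

    PBMC calls must not be passed here — they follow the germline /
    blacklist path instead.
    """
    config = config or FilterConfig()
    if material == Material.PBMC:
        raise ValueError("PBMC calls take the germline/blacklist path, not thresholds")
    if material == Material.CFDNA:
        min_vaf, min_alt = config.cfdna_min_vaf_pct, config.cfdna_min_alt_reads
    elif material in TISSUE_MATERIALS:
        min_vaf, min_alt = config.tissue_min_vaf_pct, config.tissue_min_alt_reads
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unsupported material {material}")
    return [c for c in calls if _passes_threshold(c, min_vaf, min_alt)]


def _check_pbmc(calls: Sequence[VariantCall], samples: Mapping[str, SampleMeta] | None) -> None:
    if samples is None:
        return
    for call in calls:
        meta = samples.get(call.sample_id)
        if meta is not None and meta.material != Material.PBMC:
            raise ValueError(f"call {call.key} is from {meta.material}, not PBMC")


def extract_germline(
    pbmc_calls: Sequence[VariantCall],
    config: FilterConfig | None = None,
    samples: Mapping[str, SampleMeta] | None = None,
) -> set[VariantKey]:
    """Germline keys of one patient: PBMC calls with VAF >= 20%.

    Heterozygous and homozygous germline variants sit near 50% and 100%
    VAF in PBMC; everything at or above the threshold is subtracted from
    the same patient's cfDNA and tissue results.
    """
    config = config or FilterConfig()
    _check_pbmc(pbmc_calls, samples)
    if samples is not None:
        patients = {samples[c.sample_id].patient_id for c in pbmc_calls if c.sample_id in samples}
        if len(patients) > 1:
            raise ValueError(f"germline extraction is patient-local; got {sorted(patients)}")
    return {c.key for c in pbmc_calls if c.vaf_pct >= config.germline_min_vaf_pct}


def build_blacklist(
    pbmc_calls_cohort: Sequence[VariantCall],
    config: FilterConfig | None = None,
    samples: Mapping[str, SampleMeta] | None = None,
) -> Blacklist:
    """Pool sub-threshold PBMC calls across the whole cohort into a blacklist.

    Every distinct key seen below the germline threshold in any PBMC
    sample enters, with provenance.  ``blacklist_min_recurrence`` > 1
    requires the key in that many distinct PBMC samples.
    """
    config = config or FilterConfig()
    _check_pbmc(pbmc_calls_cohort, samples)
    bl = Blacklist()
    for call in pbmc_calls_cohort:
        if call.vaf_pct >= config.germline_min_vaf_pct:
            continue
        bl.provenance.setdefault(call.key, []).append((call.sample_id, call.vaf))
        if samples is not None and call.sample_id in samples:
            bl.patients.setdefault(call.key, set()).add(samples[call.sample_id].patient_id)
    for key, prov in bl.provenance.items():
        if len({sid for sid, _ in prov}) >= config.blacklist_min_recurrence:
            bl.entries.add(key)
    return bl


def finalize_somatic(
    calls: Sequence[VariantCall],
    germline_keys: set[VariantKey],
    blacklist: Blacklist | None,
    config: FilterConfig | None = None,
    *,
    sample: SampleMeta | None = None,
    manual_exclusions: Iterable[VariantKey] = (),
    prior_log: Sequence[tuple[VariantCall, str]] = (),
) -> SomaticSet:
    """Subtract germline, blacklist and manual-exclusion keys.

    Germline removal is applied before the blacklist, so a key matching
    both is logged as ``dropped:germline``.  ``manual_exclusions`` is the
    hook standing in for interactive alignment review; it defaults to the
    empty set (a no-op).
    """
    config = config or FilterConfig()
    manual = set(manual_exclusions)
    kept: list[VariantCall] = []
    cascade_log: list[tuple[VariantCall, str]] = list(prior_log)
    for call in calls:
        if call.key in germline_keys:
            cascade_log.append((call, Disposition.GERMLINE))
            continue
        if blacklist is not None and call.key in blacklist.entries:
            if config.blacklist_scope == "patient" and sample is not None:
                contributors = blacklist.patients.get(call.key, set())
                if sample.patient_id not in contributors:
                    pass  # out of scope: fall through to the remaining rules
                else:
                    cascade_log.append((call, Disposition.BLACKLIST))
                    continue
            else:
                cascade_log.append((call, Disposition.BLACKLIST))
                continue
        if call.key in manual:
            cascade_log.append((call, Disposition.MANUAL))
            continue
        kept.append(call)
        cascade_log.append((call, Disposition.KEPT))
    return SomaticSet(
        sample_id=sample.sample_id if sample else (calls[0].sample_id if calls else ""),
        calls=kept,
        cascade_log=cascade_log,
        patient_id=sample.patient_id if sample else None,
        material=sample.material if sample else None,
        timepoint=sample.timepoint if sample else None,
    )


def run_cascade(
    calls: Sequence[VariantCall],
    sample: SampleMeta,
    config: FilterConfig | None = None,
    germline_keys: set[VariantKey] | None = None,
    blacklist: Blacklist | None = None,
    manual_exclusions: Iterable[VariantKey] = (),
) -> SomaticSet:
    """Run the full cascade (class -> threshold -> germline -> blacklist)
    on one cfDNA or tissue sample, logging a disposition per input call.

    A patient without a PBMC sample passes ``germline_keys=None``: the
    subtraction is skipped with a logged warning rather than failing.
    """
    config = config or FilterConfig()
    if sample.material == Material.PBMC:
        raise ValueError("run_cascade takes cfDNA/tissue samples; PBMC feeds the blacklist")
    if germline_keys is None:
        log.warning(
            "patient %s has no PBMC germline set; germline subtraction skipped",
            sample.patient_id,
        )
        germline_keys = set()
    prior: list[tuple[VariantCall, str]] = []
    stage1: list[VariantCall] = []
    for call in calls:
        if call.functional_class in config.allowed_classes:
            stage1.append(call)
        else:
            prior.append((call, Disposition.CLASS))
    stage2: list[VariantCall] = []
    passed = set(map(id, filter_thresholds(stage1, sample.material, config)))
    for call in stage1:
        if id(call) in passed:
            stage2.append(call)
        else:
            prior.append((call, Disposition.THRESHOLD))
    return finalize_somatic(
        stage2,
        germline_keys,
        blacklist,
        config,
        sample=sample,
        manual_exclusions=manual_exclusions,
        prior_log=prior,
    )


# ---------------------------------------------------------------------------
# Blacklist serialization (TSV: chrom, pos, ref, alt, n_samples, max_vaf)
# ---------------------------------------------------------------------------

def write_blacklist(blacklist: Blacklist, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "n_samples", "max_vaf"])
        for key in sorted(blacklist.entries):
            prov = blacklist.provenance.get(key, [])
            n_samples = len({sid for sid, _ in prov})
            max_vaf = max((v for _, v in prov), default=0.0)
            writer.writerow([key.chrom, key.pos, key.ref, key.alt, n_samples, f"{max_vaf:.6g}"])


def read_blacklist(path: str | Path) -> Blacklist:
    bl = Blacklist()
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            bl.entries.add(VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]))
    return bl
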