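"""Data model and readers/writers for variant calls, sample sheets and clinical tables.

The in-memory model mirrors what a targeted-panel ctDNA study works with:
one :class:`VariantCall` per observed ALT allele per sample, keyed by a
:class:`VariantKey` (chrom, 1-based pos, ref, alt).  VAF is stored as a
fraction in [0, 1]; thresholds elsewhere in the package are expressed in
percent and converted at the configuration boundary.

Two tabular dialects are supported:

* VCF 4.2 with per-sample ``DP``/``AD`` FORMAT fields (read via pysam);
* a flat TSV with columns
  ``Chr  Start  End  Ref  Alt  Functional  Gene  Base change  AA change  VAF (%)``
  plus optional ``Depth``, ``Alt reads`` and ``Sample`` columns.

Alleles are taken at face value (no reference genome required) and are
expected to follow the VCF left-anchored convention for indels; anchorless
ANNOVAR-style ``-`` alleles are rejected with an explicit error.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

__all__ = [
    "FunctionalClass",
    "Material",
    "TISSUE_MATERIALS",
    "PanelDef",
    "PANEL_V2_GENES",
    "PANEL_V3_GENES",
    "get_panel",
    "VariantKey",
    "VariantCall",
    "SampleMeta",
    "ClinicalRecord",
    "timepoint_rank",
    "VariantIOError",
    "read_vcf",
    "write_vcf",
    "read_variant_table",
    "write_variant_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_clinical",
    "write_clinical",
    "check_referential_integrity",
    "apply_panel",
]


class VariantIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


class FunctionalClass(str, enum.Enum):
    """Canonical functional consequence classes retained by the analysis."""

    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    INFRAME_DELETION = "inframe_deletion"
    FRAMESHIFT = "frameshift"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: SnpEff/SO-style annotation strings mapped onto the canonical enum.
_FUNCTIONAL_ALIASES: dict[str, FunctionalClass] = {
    "missense": FunctionalClass.MISSENSE,
    "missense_variant": FunctionalClass.MISSENSE,
    "stop_gain": FunctionalClass.STOP_GAIN,
    "stop_gained": FunctionalClass.STOP_GAIN,
    "stopgain": FunctionalClass.STOP_GAIN,
    "stop_loss": FunctionalClass.STOP_LOSS,
    "stop_lost": FunctionalClass.STOP_LOSS,
    "stoploss": FunctionalClass.STOP_LOSS,
    "inframe_deletion": FunctionalClass.INFRAME_DELETION,
    "in-frame_deletion": FunctionalClass.INFRAME_DELETION,
    "disruptive_inframe_deletion": FunctionalClass.INFRAME_DELETION,
    "frameshift": FunctionalClass.FRAMESHIFT,
    "frameshift_variant": FunctionalClass.FRAMESHIFT,
    "other": FunctionalClass.OTHER,
}


def parse_functional(token: str) -> FunctionalClass:
    """Map an annotation string onto the canonical class.

    Unknown strings map to ``other`` with a logged warning rather than
    failing: downstream filtering drops them anyway.
    """
    norm = token.strip().lower().replace(" ", "_")
    try:
        return _FUNCTIONAL_ALIASES[norm]
    except KeyError:
        log.warning("unknown functional class %r mapped to 'other'", token)
        return FunctionalClass.OTHER


class Material(str, enum.Enum):
    CFDNA = "cfDNA"
    TISSUE_FFPE = "tissue_FFPE"
    TISSUE_FROZEN = "tissue_frozen"
    PBMC = "PBMC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


TISSUE_MATERIALS = frozenset({Material.TISSUE_FFPE, Material.TISSUE_FROZEN})

PANEL_V2_GENES: tuple[str, ...] = (
    "APC", "TP53", "KRAS", "PIK3CA", "BRAF", "EGFR",
    "ERBB2", "ERBB3", "FGFR1", "NRAS", "HRAS",
)
PANEL_V3_GENES: tuple[str, ...] = PANEL_V2_GENES + (
    "IRS1", "MAP2K1", "MET", "PDGFRB", "PTEN",
)


@dataclass(frozen=True)
class PanelDef:
    """A targeted panel version and its ordered gene list."""

    version: str
    genes: tuple[str, ...]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


_PANELS = {
    "v2": PanelDef("v2", PANEL_V2_GENES),
    "v3": PanelDef("v3", PANEL_V3_GENES),
}


def get_panel(version: str) -> PanelDef:
    try:
        return _PANELS[version]
    except KeyError:
        raise VariantIOError(f"unknown panel version {version!r}; expected one of {sorted(_PANELS)}")


_VALID_TIMEPOINT_PREFIX = "eval"


def timepoint_rank(timepoint: str) -> int:
    """Ordering rank of a timepoint label: baseline < eval1 < eval2 < ... < PD."""
    if timepoint == "baseline":
        return 0
    if timepoint == "PD":
        return 10_000
    if timepoint.startswith(_VALID_TIMEPOINT_PREFIX):
        suffix = timepoint[len(_VALID_TIMEPOINT_PREFIX):]
        if suffix.isdigit() and int(suffix) >= 1:
            return int(suffix)
    raise VariantIOError(f"unknown timepoint label {timepoint!r}")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of an allele: chromosome, 1-based position, ref and alt strings.

    Chromosome labels are opaque and compared exactly ("12" != "chr12");
    use :meth:`normalized` to strip a "chr" prefix when mixing conventions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "-" in (self.ref, self.alt):
            raise ValueError(
                "anchorless '-' alleles are not supported; supply VCF-style "
                "left-anchored ref/alt"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")

    def normalized(self, strip_chr: bool = True) -> "VariantKey":
        chrom = self.chrom
        if strip_chr and chrom.lower().startswith("chr"):
            chrom = chrom[3:]
        return replace(self, chrom=chrom)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class VariantCall:
    """One observed allele in one sample, with read support.

    ``depth`` and ``alt_reads`` refer to deduplicated (UMI-collapsed) read
    families when barcode information was available upstream; VCF input is
    taken as already deduplicated.  They may be absent for calls ingested
    from report-style tables that only print a VAF.
    """

    key: VariantKey
    gene: str
    functional_class: FunctionalClass
    sample_id: str
    vaf: float
    depth: int | None = None
    alt_reads: int | None = None
    base_change: str | None = None
    aa_change: str | None = None

    _VAF_TOL = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if (self.depth is None) != (self.alt_reads is None):
            raise ValueError("depth and alt_reads must be supplied together")
        if self.depth is not None:
            if not 0 <= self.alt_reads <= self.depth:
                raise ValueError(
                    f"require 0 <= alt_reads <= depth, got {self.alt_reads}/{self.depth}"
                )
            if self.depth > 0:
                implied = self.alt_reads / self.depth
                if abs(self.vaf - implied) > self._VAF_TOL:
                    raise ValueError(
                        f"vaf {self.vaf} inconsistent with alt_reads/depth {implied}"
                    )

    @property
    def vaf_pct(self) -> float:
        return 100.0 * self.vaf


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    material: Material
    timepoint: str
    panel_version: str = "v3"

    def __post_init__(self) -> None:
        timepoint_rank(self.timepoint)  # validates the label
        get_panel(self.panel_version)

    @property
    def panel(self) -> PanelDef:
        return get_panel(self.panel_version)


_RESPONSES = ("PR", "SD", "PD", "NE")


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotations used by the outcome analyses."""

    patient_id: str
    best_response: str
    pfs_months: float
    pfs_event: bool
    tumor_size_mm: dict[str, float] = field(default_factory=dict)
    cea_ng_ml: float | None = None
    cfdna_conc: float | None = None
    met_sites: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.best_response not in _RESPONSES:
            raise ValueError(f"best_response must be one of {_RESPONSES}")
        if self.pfs_months < 0:
            raise ValueError("pfs_months must be >= 0")
        for tp, size in self.tumor_size_mm.items():
            timepoint_rank(tp)
            if size < 0:
                raise ValueError(f"tumor size at {tp} must be >= 0")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample: SampleMeta) -> list[VariantCall]:
    """Read per-ALT variant calls for one sample from a VCF 4.2 file.

    Requires a per-sample ``AD`` FORMAT field (ref plus one count per ALT);
    total depth is taken from ``DP`` when present, else from ``sum(AD)``.
    Multi-allelic records are split into one call per ALT allele.  Gene and
    functional annotations are read from the ``GENE``/``FCLASS`` INFO fields
    (and ``CDNA``/``PAA`` for HGVS strings) when present.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantIOError(f"{path}: malformed VCF: {exc}") from exc
    calls: list[VariantCall] = []
    with vf:
        if sample.sample_id in list(vf.header.samples):
            sample_col = sample.sample_id
        elif len(list(vf.header.samples)) == 1:
            sample_col = list(vf.header.samples)[0]
        else:
            raise VariantIOError(
                f"{path}: sample {sample.sample_id!r} not present and file is multi-sample"
            )
        info_ids = set(vf.header.info.keys())
        for rec in vf:
            where = f"{path}:{rec.chrom}:{rec.pos}"
            fmt = rec.samples[sample_col]
            if "AD" not in fmt or fmt["AD"] is None or fmt["AD"][0] is None:
                raise VariantIOError(f"{where}: record lacks the AD depth annotation")
            ad = list(fmt["AD"])
            alts = rec.alts or ()
            if len(ad) != len(alts) + 1:
                raise VariantIOError(
                    f"{where}: AD has {len(ad)} values for {len(alts)} ALT alleles"
                )
            depth = fmt.get("DP")
            if depth is None:
                depth = sum(ad)
            gene = rec.info.get("GENE", "") if "GENE" in info_ids else ""
            fclass = rec.info.get("FCLASS", "other") if "FCLASS" in info_ids else "other"
            cdna = (rec.info.get("CDNA") or None) if "CDNA" in info_ids else None
            paa = (rec.info.get("PAA") or None) if "PAA" in info_ids else None
            for alt, alt_reads in zip(alts, ad[1:]):
                if alt_reads > depth:
                    raise VariantIOError(f"{where}: AD {alt_reads} exceeds depth {depth}")
                vaf = alt_reads / depth if depth > 0 else 0.0
                try:
                    key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                except ValueError as exc:
                    raise VariantIOError(f"{where}: {exc}") from exc
                calls.append(
                    VariantCall(
                        key=key,
                        gene=str(gene),
                        functional_class=parse_functional(str(fclass)),
                        sample_id=sample.sample_id,
                        vaf=vaf,
                        depth=int(depth),
                        alt_reads=int(alt_reads),
                        base_change=cdna,
                        aa_change=paa,
                    )
                )
    return calls


_VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">',
    '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">',
    '##INFO=<ID=CDNA,Number=1,Type=String,Description="HGVS c. notation">',
    '##INFO=<ID=PAA,Number=1,Type=String,Description="HGVS p. notation">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Deduplicated depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Deduplicated allelic depths">',
)


def write_vcf(calls: Sequence[VariantCall], path: str | Path, sample_id: str | None = None) -> None:
    """Write single-sample calls as an uncompressed VCF 4.2 file.

    Every call must carry ``depth``/``alt_reads``; calls are written one
    record per ALT (no multi-allelic merging) sorted by position.
    """
    path = Path(path)
    if calls:
        sample_ids = {c.sample_id for c in calls}
        if len(sample_ids) > 1:
            raise VariantIOError(f"write_vcf expects one sample, got {sorted(sample_ids)}")
        sample_id = sample_id or next(iter(sample_ids))
    sample_id = sample_id or "SAMPLE"
    contigs = sorted({c.key.chrom for c in calls})
    with path.open("w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for call in sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.key.alt)):
            if call.depth is None:
                raise VariantIOError(f"{call.key}: cannot write VCF without depth/alt_reads")
            info = [f"GENE={call.gene}", f"FCLASS={call.functional_class.value}"]
            if call.base_change:
                info.append(f"CDNA={call.base_change}")
            if call.aa_change:
                info.append(f"PAA={call.aa_change}")
            ref_reads = call.depth - call.alt_reads
            fh.write(
                f"{call.key.chrom}\t{call.key.pos}\t.\t{call.key.ref}\t{call.key.alt}"
                f"\t.\tPASS\t{';'.join(info)}\tDP:AD\t{call.depth}:{ref_reads},{call.alt_reads}\n"
            )


# ---------------------------------------------------------------------------
# Flat variant table (report-style TSV)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = (
    "Chr", "Start", "End", "Ref", "Alt", "Functional", "Gene",
    "Base change", "AA change", "VAF (%)",
)


def _sniff_delimiter(path: Path) -> str:
    with path.open() as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_variant_table(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read calls from the flat report dialect (TSV or CSV).

    ``VAF (%)`` is converted to a fraction; ``End`` is ignored (redundant
    with ``Start`` + ``Ref``).  ``Depth``/``Alt reads`` columns are used
    when present; otherwise read support is recorded as unknown.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    calls: list[VariantCall] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in _TABLE_COLUMNS if c not in header]
        if missing:
            raise VariantIOError(f"{path}: missing columns {missing}")
        has_reads = "Depth" in header and "Alt reads" in header
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:line {lineno}"
            try:
                vaf_pct = float(row["VAF (%)"])
            except (TypeError, ValueError) as exc:
                raise VariantIOError(f"{where}: non-numeric VAF {row.get('VAF (%)')!r}") from exc
            depth = alt_reads = None
            if has_reads and row["Depth"] not in (None, "", "NA"):
                depth = int(row["Depth"])
                alt_reads = int(row["Alt reads"])
            try:
                key = VariantKey(row["Chr"], int(row["Start"]), row["Ref"], row["Alt"])
            except ValueError as exc:
                raise VariantIOError(f"{where}: {exc}") from exc
            vaf = vaf_pct / 100.0
            if depth is not None and depth > 0:
                vaf = alt_reads / depth  # authoritative over the printed percent
            calls.append(
                VariantCall(
                    key=key,
                    gene=row["Gene"],
                    functional_class=parse_functional(row["Functional"]),
                    sample_id=sample_id or row.get("Sample") or "",
                    vaf=vaf,
                    depth=depth,
                    alt_reads=alt_reads,
                    base_change=(row["Base change"] or None),
                    aa_change=(row["AA change"] or None),
                )
            )
    return calls


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls in the flat TSV dialect (lossless round-trip with
    :func:`read_variant_table` when read support is present)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_TABLE_COLUMNS) + ["Depth", "Alt reads", "Sample"])
        for call in calls:
            k = call.key
            end = k.pos + max(len(k.ref), 1) - 1
            writer.writerow(
                [
                    k.chrom, k.pos, end, k.ref, k.alt,
                    call.functional_class.value, call.gene,
                    call.base_change or "", call.aa_change or "",
                    f"{call.vaf_pct:.6g}",
                    call.depth if call.depth is not None else "",
                    call.alt_reads if call.alt_reads is not None else "",
                    call.sample_id,
                ]
            )


# ---------------------------------------------------------------------------
# Sample sheet & clinical table
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the CSV sample sheet (sample_id,patient_id,material,timepoint,panel_version)."""
    path = Path(path)
    samples: list[SampleMeta] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "patient_id", "material", "timepoint", "panel_version"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise VariantIOError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["sample_id"]
            if sid in seen:
                raise VariantIOError(f"{path}:line {lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                material = Material(row["material"])
            except ValueError as exc:
                raise VariantIOError(
                    f"{path}:line {lineno}: unknown material {row['material']!r}"
                ) from exc
            try:
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        patient_id=row["patient_id"],
                        material=material,
                        timepoint=row["timepoint"],
                        panel_version=row["panel_version"],
                    )
                )
            except (ValueError, VariantIOError) as exc:
                raise VariantIOError(f"{path}:line {lineno}: {exc}") from exc
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "patient_id", "material", "timepoint", "panel_version"])
        for s in samples:
            writer.writerow([s.sample_id, s.patient_id, s.material.value, s.timepoint, s.panel_version])


_CLINICAL_FIXED = ("patient_id", "best_response", "pfs_months", "pfs_event",
                   "cea_ng_ml", "cfdna_conc", "met_sites")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the per-patient clinical CSV.

    Target-lesion sizes are wide columns named ``size_<timepoint>`` (mm);
    metastatic sites are a ``;``-separated token list.
    """
    path = Path(path)
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _CLINICAL_FIXED if c not in header]
        if missing:
            raise VariantIOError(f"{path}: missing columns {missing}")
        size_cols = [c for c in header if c.startswith("size_")]
        for lineno, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if pid in seen:
                raise VariantIOError(f"{path}:line {lineno}: duplicate patient_id {pid!r}")
            seen.add(pid)
            sizes = {
                c[len("size_"):]: float(row[c])
                for c in size_cols
                if row[c] not in (None, "", "NA")
            }
            def _opt(colval: str) -> float | None:
                return None if colval in (None, "", "NA") else float(colval)
            try:
                records.append(
                    ClinicalRecord(
                        patient_id=pid,
                        best_response=row["best_response"],
                        pfs_months=float(row["pfs_months"]),
                        pfs_event=row["pfs_event"].strip().lower() in ("1", "true", "yes"),
                        tumor_size_mm=sizes,
                        cea_ng_ml=_opt(row["cea_ng_ml"]),
                        cfdna_conc=_opt(row["cfdna_conc"]),
                        met_sites=frozenset(t for t in row["met_sites"].split(";") if t),
                    )
                )
            except ValueError as exc:
                raise VariantIOError(f"{path}:line {lineno}: {exc}") from exc
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    timepoints = sorted({tp for r in records for tp in r.tumor_size_mm}, key=timepoint_rank)
    size_cols = [f"size_{tp}" for tp in timepoints]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(_CLINICAL_FIXED) + size_cols)
        for r in records:
            row = [
                r.patient_id, r.best_response, f"{r.pfs_months:.6g}",
                int(r.pfs_event),
                "" if r.cea_ng_ml is None else f"{r.cea_ng_ml:.6g}",
                "" if r.cfdna_conc is None else f"{r.cfdna_conc:.6g}",
                ";".join(sorted(r.met_sites)),
            ]
            for tp in timepoints:
                size = r.tumor_size_mm.get(tp)
                row.append("" if size is None else f"{size:.6g}")
            writer.writerow(row)


def check_referential_integrity(
    samples: Sequence[SampleMeta], clinical: Sequence[ClinicalRecord]
) -> None:
    """Every sample's patient must exist in the clinical table."""
    known = {r.patient_id for r in clinical}
    orphans = sorted({s.patient_id for s in samples} - known)
    if orphans:
        raise VariantIOError(f"samples reference unknown patients: {orphans}")


def apply_panel(
    calls: Sequence[VariantCall], panel: PanelDef
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Split calls into (in-panel, flagged off-panel).

    Off-panel calls are excluded from every downstream count; they are
    returned (not discarded silently) so callers can log them.
    """
    kept, flagged = [], []
    for call in calls:
        (kept if call.gene in panel else flagged).append(call)
    if flagged:
        log.warning("%d calls in genes outside panel %s flagged", len(flagged), panel.version)
    return kept, flagged
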