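"""Synthetic cohort generator with ground truth.

Generates full study-shaped cohorts — per-sample variant calls for
plasma (cfDNA), tumor tissue and PBMC, a sample sheet and a clinical
table — together with a :class:`TruthSet` recording what was planted, so
every pipeline stage can be tested end-to-end without external data.

The generator emulates the statistical structure a targeted-panel ctDNA
study of a treated metastatic cohort exhibits:

* ~90% of patients have detectable baseline plasma mutations, averaging
  ~2.7 mutations per mutation-positive patient, with per-gene weights
  matching the typical APC/TP53-dominated colorectal spectrum;
* per-variant read support is binomially sampled at targeted-panel depth
  (~2000x), so detection near the 1%/10-read cutoff behaves like real
  data;
* germline heterozygous/homozygous variants near 50%/100% VAF appear in
  PBMC, plasma and tissue; low-VAF clonal-hematopoiesis variants appear
  in PBMC and plasma only;
* baseline plasma burden (average VAF) is co-generated with tumor size
  through a shedding coefficient, inducing a positive correlation
  (~0.6 at defaults);
* follow-up VAFs track treatment response, with a planted plasma
  clearance label per patient (the generator leaves a detection margin
  around the 1% clearance cutoff so the label is recoverable);
* at progression, new resistance-pathway mutations (RAS/MAPK-weighted)
  emerge in plasma;
* progression-free survival is exponential with clearance-group-specific
  medians (11.9 vs 5.5 months) under administrative censoring.

Each patient draws from a deterministic substream keyed by (seed,
patient index), so patient ``i`` is reproducible independent of cohort
size, and the same seed yields byte-identical output files.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .read_dedup import TaggedRead
from .variant_io import (
    ClinicalRecord,
    FunctionalClass,
    Material,
    SampleMeta,
    VariantCall,
    VariantKey,
    get_panel,
    write_clinical,
    write_sample_sheet,
    write_variant_table,
)

__all__ = [
    "SimParams",
    "TruthSet",
    "PatientTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_umi_reads",
    "UmiSimTruth",
]

_BASES = ("A", "C", "G", "T")

#: per-gene weights of baseline somatic mutations (colorectal,
#: EGFR-pathway panel); follow-up/emergent draws reweight toward RAS/MAPK.
_BASELINE_GENE_WEIGHTS = {
    "APC": 111, "TP53": 71, "ERBB2": 13, "KRAS": 7, "PIK3CA": 6, "PTEN": 6,
    "MET": 4, "PDGFRB": 3, "BRAF": 3, "NRAS": 2, "ERBB3": 2, "MAP2K1": 1,
    "EGFR": 1,
}
_EMERGENT_GENE_WEIGHTS = {
    "APC": 10, "TP53": 9, "ERBB2": 8, "KRAS": 5, "PIK3CA": 5, "MAP2K1": 4,
    "ERBB3": 3, "MET": 3, "PDGFRB": 2, "EGFR": 2, "PTEN": 1, "NRAS": 1,
    "HRAS": 1,
}
_FCLASS_WEIGHTS = {
    FunctionalClass.MISSENSE: 0.62,
    FunctionalClass.STOP_GAIN: 0.14,
    FunctionalClass.FRAMESHIFT: 0.14,
    FunctionalClass.INFRAME_DELETION: 0.05,
    FunctionalClass.STOP_LOSS: 0.05,
}

#: catalog of recurrent resistance alleles (real panel coordinates and
#: HGVS labels) drawn on for a fraction of emergent mutations, so hotspot
#: and pathogenicity annotation are exercised end-to-end.
_RESISTANCE_CATALOG = (
    ("KRAS", "12", 25398284, "C", "A", "c.35G>T", "p.Gly12Val"),
    ("KRAS", "12", 25398284, "C", "T", "c.35G>A", "p.Gly12Asp"),
    ("KRAS", "12", 25398285, "C", "A", "c.34G>T", "p.Gly12Cys"),
    ("KRAS", "12", 25380275, "T", "G", "c.183A>C", "p.Gln61His"),
    ("NRAS", "1", 115256530, "T", "C", "c.182A>G", "p.Gln61Arg"),
    ("MAP2K1", "15", 66727455, "G", "T", "c.171G>T", "p.Lys57Asn"),
    ("MAP2K1", "15", 66727454, "A", "C", "c.170A>C", "p.Lys57Thr"),
    ("TP53", "17", 7577548, "C", "T", "c.733G>A", "p.Gly245Ser"),
    ("APC", "5", 112175639, "C", "T", "c.4348C>T", "p.Arg1450*"),
    ("APC", "5", 112177901, "C", "T", "c.6610C>T", "p.Arg2204*"),
    ("PTEN", "10", 89711900, "G", "A", "c.518G>A", "p.Arg173His"),
)
_CATALOG_POSITIONS = {(g[1], g[2]) for g in _RESISTANCE_CATALOG}

#: modulus of the per-patient position stratification: patient i draws
#: only positions congruent to i mod this, guaranteeing cross-patient
#: key uniqueness without cohort-level coordination.
_POS_STRIDE = 512


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the study-shaped conditions."""

    n_patients: int = 93
    panel_version: str = "v3"
    seed: int = 0
    depth_mean: float = 2000.0
    #: fraction of patients shedding essentially no ctDNA at baseline
    dropout: float = 0.097
    #: baseline somatic count per patient = 1 + Poisson(this)
    somatic_extra_mean: float = 1.74
    #: per-patient plasma shedding scale: lognormal, coupled to tumor size
    vaf_scale_median: float = 0.149  # tuned so cohort mean average VAF ~ 23%
    shedding_coef: float = 0.70
    patient_sigma: float = 0.6
    variant_sigma: float = 0.5
    #: fraction of somatic variants nearly absent from the tissue sample
    tissue_suppressed_rate: float = 0.10
    #: tissue-enriched variants shed at sub-threshold plasma VAF
    tissue_extra_zero_prob: float = 0.84
    tissue_extra_mean: float = 3.4  # 1 + Poisson(mean-1) when present
    germline_het: int = 3
    germline_hom: int = 1
    ch_mean: float = 0.35
    ch_vaf_range: tuple[float, float] = (0.01, 0.15)
    noise_mean: float = 1.0
    noise_vaf_range: tuple[float, float] = (0.0005, 0.003)
    response_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.75, "SD": 0.207, "PD": 0.043}
    )
    clearance_by_response: Mapping[str, float] = field(
        default_factory=lambda: {"PR": 0.82, "SD": 0.55, "PD": 0.10}
    )
    eval1_rate: float = 0.99
    eval2_rate: float = 0.60
    pd_sample_rate: float = 0.58
    tissue_rate: float = 0.71
    emergent_mean: float = 1.15
    pfs_median_cleared: float = 11.9
    pfs_median_not_cleared: float = 5.5
    censor_range: tuple[float, float] = (15.0, 36.0)
    caller_min_alt: int = 3

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_patients > _POS_STRIDE:
            raise ValueError(f"n_patients must be <= {_POS_STRIDE}")
        for name in ("dropout", "tissue_suppressed_rate", "tissue_extra_zero_prob",
                     "eval1_rate", "eval2_rate", "pd_sample_rate", "tissue_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.response_probs.values()) - 1.0) > 1e-6:
            raise ValueError("response_probs must sum to 1")
        if self.depth_mean <= 0 or self.emergent_mean < 0:
            raise ValueError("invalid rate parameter")
        needed = self.germline_het + self.germline_hom
        panel = get_panel(self.panel_version)
        if needed > 20 * len(panel.genes):
            raise ValueError("germline count exceeds available panel positions")


def _load_gene_intervals() -> dict[str, tuple[str, int, int]]:
    table: dict[str, tuple[str, int, int]] = {}
    with resources.files("ctdna.data").joinpath("panel_genes.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["gene"]] = (row["chrom"], int(row["start"]), int(row["end"]))
    return table


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------

def _key_dict(key: VariantKey) -> dict:
    return {"chrom": key.chrom, "pos": key.pos, "ref": key.ref, "alt": key.alt}


def key_from_dict(d: Mapping) -> VariantKey:
    return VariantKey(d["chrom"], int(d["pos"]), d["ref"], d["alt"])


@dataclass
class PatientTruth:
    patient_id: str
    dropout: bool
    response: str
    clearance_label: str  # cleared | not_cleared | unknown
    pfs_months: float
    pfs_event: bool
    timepoints: list[str]
    has_tissue: bool
    somatic: list[dict]  # key, gene, tissue_vaf|None, tissue_suppressed, plasma_vaf{tp}
    tissue_extra: list[dict]  # key, gene, tissue_vaf, plasma_vaf (scalar)
    germline: list[dict]  # key, gene, vaf
    ch: list[dict]  # key, gene, vaf
    emergent: list[dict]  # key, gene, vaf

    def somatic_keys(self) -> set[VariantKey]:
        return {key_from_dict(v["key"]) for v in self.somatic}

    def germline_keys(self) -> set[VariantKey]:
        return {key_from_dict(v["key"]) for v in self.germline}

    def ch_keys(self) -> set[VariantKey]:
        return {key_from_dict(v["key"]) for v in self.ch}

    def emergent_keys(self) -> set[VariantKey]:
        return {key_from_dict(v["key"]) for v in self.emergent}


@dataclass
class TruthSet:
    seed: int
    patients: dict[str, PatientTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "patients": {pid: asdict(pt) for pid, pt in sorted(self.patients.items())},
        }
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with Path(path).open() as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            patients={pid: PatientTruth(**d) for pid, d in payload["patients"].items()},
        )


@dataclass
class SimulatedCohort:
    params: SimParams
    samples: list[SampleMeta]
    calls: dict[str, list[VariantCall]]  # sample_id -> calls
    clinical: list[ClinicalRecord]
    truth: TruthSet

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit calls.tsv, sample_sheet.csv, clinical.csv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "calls": outdir / "calls.tsv",
            "sample_sheet": outdir / "sample_sheet.csv",
            "clinical": outdir / "clinical.csv",
            "truth": outdir / "truth.json",
        }
        all_calls = [c for sid in sorted(self.calls) for c in self.calls[sid]]
        write_variant_table(all_calls, paths["calls"])
        write_sample_sheet(self.samples, paths["sample_sheet"])
        write_clinical(self.clinical, paths["clinical"])
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Per-patient generation machinery
# ---------------------------------------------------------------------------

class _PositionAllocator:
    """Draws panel positions unique across the whole cohort.

    Patient ``i`` only ever receives positions congruent to ``i`` modulo a
    fixed stride within each gene interval, so two patients can never
    collide and patient streams stay independent of cohort size.
    Positions of the fixed resistance catalog are excluded.
    """

    def __init__(self, intervals: Mapping[str, tuple[str, int, int]], patient_index: int):
        self._intervals = intervals
        self._residue = patient_index % _POS_STRIDE
        self._used: set[tuple[str, int]] = set()
        self._taken_per_gene: dict[str, int] = {}

    def _slots(self, gene: str) -> int:
        chrom, start, end = self._intervals[gene]
        return (end - start - _POS_STRIDE) // _POS_STRIDE

    def draw(self, rng: np.random.Generator, gene: str) -> tuple[str, str, int]:
        """Return (gene, chrom, pos); falls back to a gene with free slots
        when the requested gene's stratum is exhausted (small genes hold
        only a handful of positions per patient)."""
        candidates = [gene] + sorted(g for g in self._intervals if g != gene)
        for g in candidates:
            if self._taken_per_gene.get(g, 0) >= max(self._slots(g) - 1, 0):
                continue
            chrom, start, _ = self._intervals[g]
            n_slots = self._slots(g)
            for _ in range(1000):
                pos = start + self._residue + _POS_STRIDE * int(rng.integers(0, n_slots))
                if (chrom, pos) in self._used or (chrom, pos) in _CATALOG_POSITIONS:
                    continue
                self._used.add((chrom, pos))
                self._taken_per_gene[g] = self._taken_per_gene.get(g, 0) + 1
                return g, chrom, pos
        raise RuntimeError("panel position space exhausted")


def _draw_alleles(rng: np.random.Generator, fclass: FunctionalClass) -> tuple[str, str]:
    anchor = _BASES[rng.integers(4)]
    if fclass in (FunctionalClass.FRAMESHIFT, FunctionalClass.INFRAME_DELETION):
        n_del = 3 if fclass is FunctionalClass.INFRAME_DELETION else int(rng.integers(1, 3))
        ref = anchor + "".join(_BASES[rng.integers(4)] for _ in range(n_del))
        return ref, anchor
    alt = _BASES[rng.integers(4)]
    while alt == anchor:
        alt = _BASES[rng.integers(4)]
    return anchor, alt


def _weighted_choice(rng: np.random.Generator, weights: Mapping, allowed: set | None = None):
    items = [(k, w) for k, w in weights.items() if allowed is None or k in allowed]
    keys = [k for k, _ in items]
    w = np.array([v for _, v in items], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def _emit_call(
    rng: np.random.Generator,
    sample_id: str,
    key: VariantKey,
    gene: str,
    fclass: FunctionalClass,
    true_vaf: float,
    params: SimParams,
    base_change: str | None = None,
    aa_change: str | None = None,
) -> VariantCall | None:
    """Binomial read sampling at panel depth; None when the caller would
    not report the allele (fewer than ``caller_min_alt`` supporting reads)."""
    depth = int(rng.poisson(params.depth_mean))
    if depth == 0:
        return None
    alt_reads = int(rng.binomial(depth, min(max(true_vaf, 0.0), 1.0)))
    if alt_reads < params.caller_min_alt:
        return None
    return VariantCall(
        key=key,
        gene=gene,
        functional_class=fclass,
        sample_id=sample_id,
        vaf=alt_reads / depth,
        depth=depth,
        alt_reads=alt_reads,
        base_change=base_change,
        aa_change=aa_change,
    )


def _simulate_patient(
    index: int, params: SimParams, intervals: Mapping[str, tuple[str, int, int]]
) -> tuple[list[SampleMeta], dict[str, list[VariantCall]], ClinicalRecord, PatientTruth]:
    rng = np.random.default_rng([params.seed, index])
    pid = f"P{index + 1:03d}"
    panel = get_panel(params.panel_version)
    genes = set(panel.genes)
    alloc = _PositionAllocator(intervals, index)

    dropout = bool(rng.random() < params.dropout)
    responses = sorted(params.response_probs)
    probs = np.array([params.response_probs[r] for r in responses])
    response = responses[int(rng.choice(len(responses), p=probs / probs.sum()))]

    timepoints = ["baseline"]
    if rng.random() < params.eval1_rate:
        timepoints.append("eval1")
        if rng.random() < params.eval2_rate:
            timepoints.append("eval2")
    if rng.random() < params.pd_sample_rate:
        timepoints.append("PD")
    has_tissue = bool(rng.random() < params.tissue_rate)

    # --- tumor size and plasma shedding scale (coupled) -------------------
    log_size = rng.normal(math.log(35.0), 0.4)
    baseline_size = float(np.exp(log_size))
    z_size = (log_size - math.log(35.0)) / 0.4
    ln_scale = (
        math.log(params.vaf_scale_median)
        + params.shedding_coef * z_size
        + rng.normal(0.0, params.patient_sigma)
    )
    scale = float(np.exp(ln_scale))
    if dropout:
        scale *= 0.01  # essentially no shedding: nothing passes the 1% cutoff

    # --- baseline somatic variants ----------------------------------------
    n_somatic = 1 + int(rng.poisson(params.somatic_extra_mean))
    somatic: list[dict] = []
    for _ in range(n_somatic):
        gene = _weighted_choice(rng, _BASELINE_GENE_WEIGHTS, genes)
        fclass = _weighted_choice(rng, _FCLASS_WEIGHTS)
        gene, chrom, pos = alloc.draw(rng, gene)
        ref, alt = _draw_alleles(rng, fclass)
        key = VariantKey(chrom, pos, ref, alt)
        vaf0 = float(np.clip(scale * rng.lognormal(0.0, params.variant_sigma), 1e-4, 0.95))
        if dropout:
            # non-shedders stay clearly below the cutoff at all timepoints
            vaf0 = min(vaf0, 0.004)
        if not dropout and 0.004 < vaf0 < 0.025:
            # detection margin: keep clonal baseline VAFs clear of the
            # 1%/10-read boundary so planted detectability is unambiguous
            # at panel depth (dropout patients stay sub-threshold).
            vaf0 += 0.021
        tissue_suppressed = bool(rng.random() < params.tissue_suppressed_rate)
        tissue_vaf = (
            float(rng.uniform(0.0006, 0.004))
            if tissue_suppressed
            else float(rng.uniform(0.15, 0.60))
        )
        somatic.append(
            {
                "key": _key_dict(key),
                "gene": gene,
                "fclass": fclass.value,
                "tissue_vaf": tissue_vaf,
                "tissue_suppressed": tissue_suppressed,
                "plasma_vaf": {"baseline": vaf0},
            }
        )

    # --- clearance label and follow-up plasma VAFs ------------------------
    if "eval1" not in timepoints:
        clearance = "unknown"
    elif dropout:
        clearance = "cleared"
    else:
        clearance = (
            "cleared"
            if rng.random() < params.clearance_by_response[response]
            else "not_cleared"
        )
    # the generator leaves a margin around the 1% cutoff (residual disease
    # well below, persistent disease well above) so labels are recoverable
    # at panel depth.
    if "eval1" in timepoints:
        rebound_scale = float(rng.uniform(0.3, 1.6))
        for v in somatic:
            base = v["plasma_vaf"]["baseline"]
            if dropout or clearance == "cleared":
                v["plasma_vaf"]["eval1"] = float(rng.uniform(0.0002, 0.002))
            else:
                v["plasma_vaf"]["eval1"] = float(
                    np.clip(max(base * rebound_scale, 0.025), 0.025, 0.95)
                )
        if "eval2" in timepoints:
            for v in somatic:
                drift = float(rng.uniform(0.5, 1.5))
                e2 = v["plasma_vaf"]["eval1"] * drift
                if dropout or clearance == "cleared":
                    e2 = min(e2, 0.004)
                v["plasma_vaf"]["eval2"] = float(np.clip(e2, 1e-5, 0.95))
    if "PD" in timepoints:
        for v in somatic:
            pd_vaf = v["plasma_vaf"]["baseline"] * float(rng.uniform(0.7, 1.6))
            if dropout:
                pd_vaf = min(pd_vaf, 0.004)
            v["plasma_vaf"]["PD"] = float(np.clip(pd_vaf, 1e-5, 0.95))

    # --- tissue-enriched variants shed below the plasma cutoff ------------
    tissue_extra: list[dict] = []
    if has_tissue and rng.random() > params.tissue_extra_zero_prob:
        n_extra = 1 + int(rng.poisson(params.tissue_extra_mean - 1.0))
        for _ in range(n_extra):
            gene = _weighted_choice(rng, _BASELINE_GENE_WEIGHTS, genes)
            fclass = _weighted_choice(rng, _FCLASS_WEIGHTS)
            gene, chrom, pos = alloc.draw(rng, gene)
            ref, alt = _draw_alleles(rng, fclass)
            tissue_extra.append(
                {
                    "key": _key_dict(VariantKey(chrom, pos, ref, alt)),
                    "gene": gene,
                    "fclass": fclass.value,
                    "tissue_vaf": float(rng.uniform(0.15, 0.60)),
                    "plasma_vaf": float(rng.uniform(0.0022, 0.003)),
                }
            )

    # --- germline and clonal hematopoiesis --------------------------------
    germline: list[dict] = []
    for j in range(params.germline_het + params.germline_hom):
        gene = panel.genes[int(rng.integers(len(panel.genes)))]
        gene, chrom, pos = alloc.draw(rng, gene)
        ref, alt = _draw_alleles(rng, FunctionalClass.MISSENSE)
        hom = j >= params.germline_het
        vaf = (
            float(np.clip(rng.normal(0.995, 0.003), 0.97, 1.0))
            if hom
            else float(np.clip(rng.normal(0.5, 0.02), 0.35, 0.65))
        )
        germline.append(
            {"key": _key_dict(VariantKey(chrom, pos, ref, alt)), "gene": gene, "vaf": vaf}
        )
    ch: list[dict] = []
    for _ in range(int(rng.poisson(params.ch_mean))):
        gene = panel.genes[int(rng.integers(len(panel.genes)))]
        gene, chrom, pos = alloc.draw(rng, gene)
        ref, alt = _draw_alleles(rng, FunctionalClass.MISSENSE)
        ch.append(
            {
                "key": _key_dict(VariantKey(chrom, pos, ref, alt)),
                "gene": gene,
                "vaf": float(rng.uniform(*params.ch_vaf_range)),
            }
        )

    # --- emergent resistance mutations at PD -------------------------------
    emergent: list[dict] = []
    if "PD" in timepoints and not dropout:
        existing = {(v["key"]["chrom"], v["key"]["pos"]) for v in somatic + tissue_extra}
        for _ in range(int(rng.poisson(params.emergent_mean))):
            if rng.random() < 0.25:
                g, chrom, pos, ref, alt, cdna, paa = _RESISTANCE_CATALOG[
                    int(rng.integers(len(_RESISTANCE_CATALOG)))
                ]
                if g not in genes or (chrom, pos) in existing:
                    continue
                entry = {
                    "key": _key_dict(VariantKey(chrom, pos, ref, alt)),
                    "gene": g,
                    "fclass": (
                        FunctionalClass.STOP_GAIN if paa.endswith("*") else FunctionalClass.MISSENSE
                    ).value,
                    "base_change": cdna,
                    "aa_change": paa,
                }
            else:
                gene = _weighted_choice(rng, _EMERGENT_GENE_WEIGHTS, genes)
                fclass = _weighted_choice(rng, _FCLASS_WEIGHTS)
                gene, chrom, pos = alloc.draw(rng, gene)
                ref, alt = _draw_alleles(rng, fclass)
                entry = {
                    "key": _key_dict(VariantKey(chrom, pos, ref, alt)),
                    "gene": gene,
                    "fclass": fclass.value,
                    "base_change": None,
                    "aa_change": None,
                }
            if (entry["key"]["chrom"], entry["key"]["pos"]) in existing:
                continue
            existing.add((entry["key"]["chrom"], entry["key"]["pos"]))
            entry["vaf"] = float(np.clip(rng.lognormal(math.log(0.03), 0.8), 0.015, 0.40))
            emergent.append(entry)

    # --- survival ----------------------------------------------------------
    cleared_like = clearance in ("cleared", "unknown")
    median = params.pfs_median_cleared if cleared_like else params.pfs_median_not_cleared
    t_event = float(rng.exponential(median / math.log(2.0)))
    censor = float(rng.uniform(*params.censor_range))
    pfs_months = min(t_event, censor)
    pfs_event = t_event <= censor

    # --- clinical record ----------------------------------------------------
    sizes = {"baseline": round(baseline_size, 1)}
    factors = {"PR": (0.40, 0.70), "SD": (0.80, 1.15), "PD": (1.20, 1.60)}
    last = baseline_size
    if "eval1" in timepoints:
        last = baseline_size * float(rng.uniform(*factors[response]))
        sizes["eval1"] = round(last, 1)
    if "eval2" in timepoints:
        last = last * float(rng.uniform(0.9, 1.2))
        sizes["eval2"] = round(last, 1)
    if "PD" in timepoints:
        sizes["PD"] = round(last * float(rng.uniform(1.2, 1.5)), 1)
    positive_expected = not dropout
    cea = float(rng.lognormal(math.log(35.8 if positive_expected else 4.6), 1.1))
    cfdna_conc = float(rng.lognormal(math.log(10.0), 0.8))
    met_sites = set()
    if rng.random() < (0.82 if positive_expected else 0.40):
        met_sites.add("liver")
    for site, p_site in (("lung", 0.23), ("peritoneum", 0.22), ("lymph_node", 0.29), ("other", 0.10)):
        if rng.random() < p_site:
            met_sites.add(site)
    if not met_sites:
        met_sites.add("other")
    clinical = ClinicalRecord(
        patient_id=pid,
        best_response=response,
        pfs_months=round(pfs_months, 2),
        pfs_event=pfs_event,
        tumor_size_mm=sizes,
        cea_ng_ml=round(cea, 1),
        cfdna_conc=round(cfdna_conc, 2),
        met_sites=frozenset(met_sites),
    )

    # --- emit per-sample observed calls -------------------------------------
    samples: list[SampleMeta] = []
    calls: dict[str, list[VariantCall]] = {}

    def _add_sample(sid: str, material: Material, timepoint: str) -> None:
        samples.append(
            SampleMeta(
                sample_id=sid,
                patient_id=pid,
                material=material,
                timepoint=timepoint,
                panel_version=params.panel_version,
            )
        )
        calls[sid] = []

    def _noise_calls(rng: np.random.Generator, sid: str, plasma: bool) -> list[VariantCall]:
        out = []
        for _ in range(int(rng.poisson(params.noise_mean))):
            gene = panel.genes[int(rng.integers(len(panel.genes)))]
            gene, chrom, pos = alloc.draw(rng, gene)
            ref, alt = _draw_alleles(rng, FunctionalClass.MISSENSE)
            call = _emit_call(
                rng, sid, VariantKey(chrom, pos, ref, alt), gene,
                FunctionalClass.MISSENSE, float(rng.uniform(*params.noise_vaf_range)), params,
            )
            if call:
                out.append(call)
        if plasma:
            # synonymous/non-functional calls at appreciable VAF exercise
            # the functional-class stage of the cascade.
            for _ in range(int(rng.poisson(0.5))):
                gene = panel.genes[int(rng.integers(len(panel.genes)))]
                gene, chrom, pos = alloc.draw(rng, gene)
                ref, alt = _draw_alleles(rng, FunctionalClass.OTHER)
                call = _emit_call(
                    rng, sid, VariantKey(chrom, pos, ref, alt), gene,
                    FunctionalClass.OTHER, float(rng.uniform(0.01, 0.10)), params,
                )
                if call:
                    out.append(call)
        return out

    # PBMC
    sid = f"{pid}_PBMC"
    _add_sample(sid, Material.PBMC, "baseline")
    for v in germline + ch:
        call = _emit_call(
            rng, sid, key_from_dict(v["key"]), v["gene"], FunctionalClass.MISSENSE,
            v["vaf"], params,
        )
        if call:
            calls[sid].append(call)
    calls[sid].extend(_noise_calls(rng, sid, plasma=False))

    # plasma timepoints
    for tp in timepoints:
        sid = f"{pid}_cf_{tp}"
        _add_sample(sid, Material.CFDNA, tp)
        for v in somatic:
            vaf = v["plasma_vaf"].get(tp)
            if vaf is None:
                continue
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"],
                FunctionalClass(v["fclass"]), vaf, params,
            )
            if call:
                calls[sid].append(call)
        for v in tissue_extra:
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"],
                FunctionalClass(v["fclass"]), v["plasma_vaf"], params,
            )
            if call:
                calls[sid].append(call)
        if tp == "PD":
            for v in emergent:
                call = _emit_call(
                    rng, sid, key_from_dict(v["key"]), v["gene"],
                    FunctionalClass(v["fclass"]), v["vaf"], params,
                    base_change=v.get("base_change"), aa_change=v.get("aa_change"),
                )
                if call:
                    calls[sid].append(call)
        for v in germline:
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"], FunctionalClass.MISSENSE,
                v["vaf"], params,
            )
            if call:
                calls[sid].append(call)
        for v in ch:
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"], FunctionalClass.MISSENSE,
                v["vaf"], params,
            )
            if call:
                calls[sid].append(call)
        calls[sid].extend(_noise_calls(rng, sid, plasma=True))

    # tissue
    if has_tissue:
        material = Material.TISSUE_FROZEN if rng.random() < 0.30 else Material.TISSUE_FFPE
        sid = f"{pid}_tissue"
        _add_sample(sid, material, "baseline")
        for v in somatic + tissue_extra:
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"],
                FunctionalClass(v["fclass"]), v["tissue_vaf"], params,
            )
            if call:
                calls[sid].append(call)
        for v in germline:
            call = _emit_call(
                rng, sid, key_from_dict(v["key"]), v["gene"], FunctionalClass.MISSENSE,
                v["vaf"], params,
            )
            if call:
                calls[sid].append(call)
        calls[sid].extend(_noise_calls(rng, sid, plasma=False))

    truth = PatientTruth(
        patient_id=pid,
        dropout=dropout,
        response=response,
        clearance_label=clearance,
        pfs_months=clinical.pfs_months,
        pfs_event=pfs_event,
        timepoints=timepoints,
        has_tissue=has_tissue,
        somatic=somatic,
        tissue_extra=tissue_extra,
        germline=germline,
        ch=ch,
        emergent=emergent,
    )
    return samples, calls, clinical, truth


def simulate_cohort(params: SimParams | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort with ground truth."""
    params = params or SimParams()
    intervals = _load_gene_intervals()
    samples: list[SampleMeta] = []
    calls: dict[str, list[VariantCall]] = {}
    clinical: list[ClinicalRecord] = []
    patients: dict[str, PatientTruth] = {}
    for i in range(params.n_patients):
        s, c, clin, truth = _simulate_patient(i, params, intervals)
        samples.extend(s)
        calls.update(c)
        clinical.append(clin)
        patients[truth.patient_id] = truth
    return SimulatedCohort(
        params=params,
        samples=samples,
        calls=calls,
        clinical=clinical,
        truth=TruthSet(seed=params.seed, patients=patients),
    )


# ---------------------------------------------------------------------------
# UMI read simulation (feeds the dedup module's tests and CLI demos)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UmiSimTruth:
    n_molecules: int
    n_alt_molecules: int
    true_vaf: float

    @property
    def molecule_vaf(self) -> float:
        return self.n_alt_molecules / self.n_molecules if self.n_molecules else 0.0


def simulate_umi_reads(
    locus: VariantKey,
    depth: int,
    dup_rate: float,
    error_rate: float,
    true_vaf: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[TaggedRead], UmiSimTruth]:
    """Simulate ``depth`` tagged reads over a known family structure.

    ``dup_rate`` is the duplicated fraction of reads: the number of source
    molecules is ``max(1, round(depth * (1 - dup_rate)))`` (0 -> every
    read its own molecule; 1 -> all reads copies of a single molecule).
    Each molecule carries the ALT allele with probability ``true_vaf``;
    each read copy is independently corrupted to a random other base with
    probability ``error_rate``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= dup_rate <= 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_molecules = max(1, round(depth * (1.0 - dup_rate)))
    # distribute reads over molecules, each molecule getting >= 1 read
    extra = rng.multinomial(depth - n_molecules, np.full(n_molecules, 1.0 / n_molecules))
    copies = 1 + extra
    umis: set[str] = set()
    while len(umis) < n_molecules:
        umis.add("".join(_BASES[b] for b in rng.integers(0, 4, size=10)))
    umi_list = sorted(umis)
    rng.shuffle(umi_list)
    reads: list[TaggedRead] = []
    n_alt = 0
    alleles = (locus.ref, locus.alt)
    for mol in range(n_molecules):
        is_alt = rng.random() < true_vaf
        n_alt += is_alt
        true_allele = alleles[int(is_alt)]
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(int(copies[mol])):
            allele = true_allele
            if rng.random() < error_rate:
                others = [b for b in _BASES if b != true_allele]
                allele = others[int(rng.integers(len(others)))]
            reads.append(
                TaggedRead(
                    umi=umi_list[mol],
                    chrom=locus.chrom,
                    start=locus.pos,
                    strand=strand,
                    allele=allele,
                    locus=locus,
                )
            )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, UmiSimTruth(n_molecules=n_molecules, n_alt_molecules=int(n_alt), true_vaf=true_vaf)
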