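"""End-to-end orchestration: cohort in, consolidated report out.

``run_pipeline`` drives the canonical analysis over a cohort directory
(``calls.tsv`` + ``sample_sheet.csv`` + ``clinical.csv``, as written by
the synthetic generator or assembled from real exports):

1. pool PBMC calls — per-patient germline sets, cohort blacklist;
2. run the somatic filter cascade on every cfDNA/tissue sample;
3. per-patient average-VAF trajectories and clearance classification;
4. tissue–plasma concordance with sub-threshold rescue;
5. emergent mutations at progression;
6. cohort statistics: per-gene frequency tables (baseline and emergent),
   clearance- and hotspot-stratified survival, burden/size correlations
   and detection associations.

All thresholds live in :class:`RunConfig` with the canonical values as
defaults, so the zero-flag invocation reproduces the standard analysis.
The run is deterministic: the same config and seed produce a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import cohort_stats as cs
from . import longitudinal as lg
from .somatic_filter import (
    Blacklist,
    FilterConfig,
    SomaticSet,
    build_blacklist,
    extract_germline,
    filter_functional,
    run_cascade,
    write_blacklist,
)
from .synthetic import SimParams, simulate_cohort
from .variant_io import (
    ClinicalRecord,
    Material,
    SampleMeta,
    TISSUE_MATERIALS,
    VariantCall,
    apply_panel,
    check_referential_integrity,
    read_clinical,
    read_sample_sheet,
    read_variant_table,
    timepoint_rank,
    write_variant_table,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_cohort", "CohortData"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and offending sample/patient."""


@dataclass
class RunConfig:
    out_dir: str = "ctdna_run"
    #: directory with calls.tsv / sample_sheet.csv / clinical.csv; when
    #: None, a synthetic cohort is generated under out_dir/cohort.
    input_dir: str | None = None
    seed: int = 0
    n_patients: int = 93
    filter: FilterConfig = field(default_factory=FilterConfig)
    clearance_cutoff_pct: float = lg.DEFAULT_CLEARANCE_CUTOFF_PCT
    first_eval: str = "eval1"
    run_stats: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["filter"]["allowed_classes"] = sorted(
            c.value for c in self.filter.allowed_classes
        )
        with Path(path).open("w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        from .variant_io import FunctionalClass

        with Path(path).open() as fh:
            payload = json.load(fh)
        fdict = payload.pop("filter", {})
        if "allowed_classes" in fdict:
            fdict["allowed_classes"] = frozenset(
                FunctionalClass(c) for c in fdict["allowed_classes"]
            )
        return cls(filter=FilterConfig(**fdict), **payload)


@dataclass
class CohortData:
    samples: list[SampleMeta]
    calls: dict[str, list[VariantCall]]
    clinical: list[ClinicalRecord]


def load_cohort(input_dir: str | Path) -> CohortData:
    """Load a cohort directory and validate referential integrity."""
    input_dir = Path(input_dir)
    samples = read_sample_sheet(input_dir / "sample_sheet.csv")
    clinical = read_clinical(input_dir / "clinical.csv")
    check_referential_integrity(samples, clinical)
    all_calls = read_variant_table(input_dir / "calls.tsv")
    known = {s.sample_id for s in samples}
    calls: dict[str, list[VariantCall]] = {s.sample_id: [] for s in samples}
    for call in all_calls:
        if call.sample_id not in known:
            raise PipelineError(f"stage=load: call for unknown sample {call.sample_id!r}")
        calls[call.sample_id].append(call)
    return CohortData(samples=samples, calls=calls, clinical=clinical)


def _round(x: float | None, nd: int = 6) -> float | None:
    return None if x is None else round(float(x), nd)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis; returns the report (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    if config.input_dir is None:
        cohort_dir = out_dir / "cohort"
        sim = simulate_cohort(SimParams(n_patients=config.n_patients, seed=config.seed))
        sim.write(cohort_dir)
        data = CohortData(samples=sim.samples, calls=sim.calls, clinical=sim.clinical)
        manifest.extend(str(cohort_dir / n) for n in
                        ("calls.tsv", "sample_sheet.csv", "clinical.csv", "truth.json"))
    else:
        data = load_cohort(config.input_dir)

    by_patient: dict[str, list[SampleMeta]] = {}
    for s in data.samples:
        by_patient.setdefault(s.patient_id, []).append(s)
    clin_by_patient = {c.patient_id: c for c in data.clinical}

    # ----- stage: germline / blacklist ------------------------------------
    germline_by_patient: dict[str, set] = {}
    pbmc_pool: list[VariantCall] = []
    sample_meta = {s.sample_id: s for s in data.samples}
    for pid, plist in sorted(by_patient.items()):
        pbmc = [s for s in plist if s.material == Material.PBMC]
        for s in pbmc:
            gated, _ = apply_panel(data.calls[s.sample_id], s.panel)
            pbmc_pool.extend(gated)
            germline_by_patient.setdefault(pid, set()).update(
                extract_germline(gated, config.filter)
            )
    blacklist = build_blacklist(pbmc_pool, config.filter, samples=sample_meta)

    # ----- stage: per-sample filter cascade -------------------------------
    somatic: dict[str, SomaticSet] = {}
    unfiltered: dict[str, list[VariantCall]] = {}  # post-class, pre-threshold
    for s in sorted(data.samples, key=lambda s: s.sample_id):
        if s.material == Material.PBMC:
            continue
        try:
            gated, _ = apply_panel(data.calls[s.sample_id], s.panel)
            unfiltered[s.sample_id] = filter_functional(gated, config.filter)
            somatic[s.sample_id] = run_cascade(
                gated, s, config.filter,
                germline_keys=germline_by_patient.get(s.patient_id),
                blacklist=blacklist,
            )
        except Exception as exc:  # pragma: no cover - defensive rewrap
            raise PipelineError(f"stage=filter sample={s.sample_id}: {exc}") from exc

    def _cfdna_sets(pid: str) -> list[SomaticSet]:
        sets = [
            somatic[s.sample_id]
            for s in by_patient[pid]
            if s.material == Material.CFDNA and s.sample_id in somatic
        ]
        return sorted(sets, key=lambda ss: timepoint_rank(ss.timepoint))

    def _tissue_set(pid: str) -> SomaticSet | None:
        for s in by_patient[pid]:
            if s.material in TISSUE_MATERIALS and s.sample_id in somatic:
                return somatic[s.sample_id]
        return None

    # ----- stage: trajectories & clearance --------------------------------
    trajectories: dict[str, list[lg.TrajectoryPoint]] = {}
    deltas: dict[str, list[lg.TrajectoryDelta]] = {}
    clearance: dict[str, str] = {}
    for pid in sorted(by_patient):
        sets = _cfdna_sets(pid)
        if not sets or sets[0].timepoint != "baseline":
            continue
        try:
            points, ds = lg.vaf_trajectory(sets, clin_by_patient.get(pid))
        except Exception as exc:
            raise PipelineError(f"stage=track patient={pid}: {exc}") from exc
        trajectories[pid] = points
        deltas[pid] = ds
        clearance[pid] = lg.classify_clearance(
            points, config.clearance_cutoff_pct, config.first_eval
        )

    # ----- stage: concordance ---------------------------------------------
    concordance_reports: dict[str, lg.ConcordanceReport] = {}
    for pid in sorted(by_patient):
        tissue = _tissue_set(pid)
        sets = _cfdna_sets(pid)
        baseline = next((s for s in sets if s.timepoint == "baseline"), None)
        if tissue is None or baseline is None:
            continue
        tissue_sample = tissue.sample_id
        concordance_reports[pid] = lg.concordance(
            tissue, baseline,
            cfdna_unfiltered=unfiltered.get(baseline.sample_id, []),
            tissue_unfiltered=unfiltered.get(tissue_sample, []),
        )

    # ----- stage: emergent mutations at PD --------------------------------
    emergent: dict[str, list[VariantCall]] = {}
    for pid in sorted(by_patient):
        sets = _cfdna_sets(pid)
        pd_set = next((s for s in sets if s.timepoint == "PD"), None)
        if pd_set is None:
            continue
        earlier = [s for s in sets if timepoint_rank(s.timepoint) < timepoint_rank("PD")]
        emergent[pid] = lg.detect_emergent(pd_set, earlier, _tissue_set(pid))

    report: dict[str, Any] = {
        "n_patients": len(by_patient),
        "n_samples": len(data.samples),
        "clearance_labels": dict(sorted(clearance.items())),
        "blacklist_size": len(blacklist),
    }

    # ----- stage: cohort statistics ---------------------------------------
    baseline_sets = [
        next(s for s in _cfdna_sets(pid) if s.timepoint == "baseline")
        for pid in sorted(by_patient)
        if any(s.timepoint == "baseline" for s in _cfdna_sets(pid))
    ]
    freq = cs.summarize_frequencies(baseline_sets, cohort_size=len(baseline_sets))
    report["frequency_baseline"] = {
        "table": freq.table.to_dict(orient="records"),
        "total_mutations": freq.total_mutations,
        "n_patients_positive": freq.n_patients_positive,
        "fraction_positive": _round(freq.fraction_positive),
        "mean_mutations_per_positive": _round(freq.mean_mutations_per_positive),
    }

    emergent_sets = [
        SomaticSet(
            sample_id=f"{pid}_emergent", calls=list(calls), cascade_log=[],
            patient_id=pid, material=Material.CFDNA, timepoint="PD",
        )
        for pid, calls in sorted(emergent.items())
    ]
    if emergent_sets:
        efreq = cs.summarize_frequencies(emergent_sets, cohort_size=len(emergent_sets))
        report["frequency_emergent"] = {
            "table": efreq.table.to_dict(orient="records"),
            "total_mutations": efreq.total_mutations,
            "n_patients_with_pd_sample": len(emergent_sets),
        }

    if concordance_reports:
        n_tissue = sum(r.n_tissue for r in concordance_reports.values())
        n_matched = sum(r.n_matched for r in concordance_reports.values())
        n_unmatched = sum(r.n_unmatched for r in concordance_reports.values())
        n_rescued = sum(r.n_rescued_subthreshold for r in concordance_reports.values())
        n_only = sum(r.n_ctdna_only for r in concordance_reports.values())
        n_only_sub = sum(
            r.n_ctdna_only_subthreshold_in_tissue for r in concordance_reports.values()
        )
        covered = sum(r.patient_covered for r in concordance_reports.values())
        report["concordance"] = {
            "n_patients_compared": len(concordance_reports),
            "n_tissue_variants": n_tissue,
            "n_matched": n_matched,
            "matched_pct": _round(100.0 * n_matched / n_tissue if n_tissue else 0.0, 1),
            "n_unmatched": n_unmatched,
            "n_rescued_subthreshold": n_rescued,
            "rescued_pct_of_unmatched": _round(
                100.0 * n_rescued / n_unmatched if n_unmatched else 0.0, 1
            ),
            "n_ctdna_only": n_only,
            "ctdna_only_subthreshold_in_tissue_pct": _round(
                100.0 * n_only_sub / n_only if n_only else 0.0, 1
            ),
            "patients_covered_pct": _round(
                100.0 * covered / len(concordance_reports), 1
            ),
        }

    if config.run_stats:
        report["stats"] = _cohort_statistics(
            by_patient, clin_by_patient, trajectories, deltas, clearance, baseline_sets
        )

    # ----- artifacts --------------------------------------------------------
    write_blacklist(blacklist, out_dir / "blacklist.tsv")
    manifest.append(str(out_dir / "blacklist.tsv"))
    somatic_calls = [c for sid in sorted(somatic) for c in somatic[sid].calls]
    write_variant_table(somatic_calls, out_dir / "somatic_calls.tsv")
    manifest.append(str(out_dir / "somatic_calls.tsv"))
    _write_trajectories(trajectories, deltas, clearance, out_dir / "trajectories.tsv")
    manifest.append(str(out_dir / "trajectories.tsv"))
    emergent_calls = [c for pid in sorted(emergent) for c in emergent[pid]]
    write_variant_table(emergent_calls, out_dir / "emergent_calls.tsv")
    manifest.append(str(out_dir / "emergent_calls.tsv"))
    report["manifest"] = sorted(manifest + [str(out_dir / "report.json")])
    with (out_dir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _write_trajectories(trajectories, deltas, clearance, path: Path) -> None:
    import csv as _csv

    with path.open("w", newline="") as fh:
        w = _csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["patient_id", "timepoint", "average_vaf_pct", "n_mutations",
             "tumor_size_mm", "vaf_delta_points", "size_delta_pct", "clearance"]
        )
        for pid in sorted(trajectories):
            dmap = {d.timepoint: d for d in deltas.get(pid, [])}
            for pt in trajectories[pid]:
                d = dmap.get(pt.timepoint)
                w.writerow(
                    [
                        pid, pt.timepoint, f"{pt.average_vaf_pct:.4f}", pt.n_mutations,
                        "" if pt.tumor_size_mm is None else f"{pt.tumor_size_mm:.6g}",
                        "" if d is None else f"{d.vaf_delta_points:.4f}",
                        "" if d is None or d.size_delta_pct is None else f"{d.size_delta_pct:.4f}",
                        clearance.get(pid, "unknown"),
                    ]
                )


def _survival_comparison(groups: Mapping[str, list[tuple[float, bool]]]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for label, tv in sorted(groups.items()):
        if not tv:
            continue
        km = cs.km_estimate([t for t, _ in tv], [e for _, e in tv])
        out[label] = {"n": km.n, "n_events": km.n_events, "median_pfs_months": _round(km.median, 3)}
    labels = [l for l in sorted(groups) if groups[l]]
    if len(labels) == 2:
        a, b = (groups[l] for l in labels)
        if any(e for _, e in a) or any(e for _, e in b):
            stat, p = cs.logrank_test(
                [t for t, _ in a], [e for _, e in a], [t for t, _ in b], [e for _, e in b]
            )
            out["logrank"] = {"statistic": _round(stat), "p": _round(p, 8)}
    return out


def _cohort_statistics(
    by_patient, clin_by_patient, trajectories, deltas, clearance, baseline_sets
) -> dict[str, Any]:
    stats_report: dict[str, Any] = {}
    hotspots = lg.load_hotspots()
    pathogenicity = lg.load_pathogenicity()
    baseline_by_pid = {s.patient_id: s for s in baseline_sets}

    # overall survival summary
    all_tv = [
        (c.pfs_months, c.pfs_event) for c in clin_by_patient.values()
    ]
    if all_tv:
        km = cs.km_estimate([t for t, _ in all_tv], [e for _, e in all_tv])
        stats_report["pfs_overall"] = {
            "n": km.n, "n_events": km.n_events, "median_pfs_months": _round(km.median, 3)
        }

    # clearance-stratified PFS
    groups: dict[str, list[tuple[float, bool]]] = {"cleared": [], "not_cleared": []}
    for pid, label in clearance.items():
        clin = clin_by_patient.get(pid)
        if clin is None or label == "unknown":
            continue
        groups[label].append((clin.pfs_months, clin.pfs_event))
    stats_report["pfs_by_clearance"] = _survival_comparison(groups)

    # RAS/RAF hotspot stratification from baseline plasma mutations
    hot_groups: dict[str, list[tuple[float, bool]]] = {"hotspot": [], "wild_type": []}
    for pid, sset in sorted(baseline_by_pid.items()):
        clin = clin_by_patient.get(pid)
        if clin is None:
            continue
        carrier = any(
            lg.annotate(c, hotspots, pathogenicity).is_hotspot and c.gene in ("KRAS", "NRAS")
            for c in sset.calls
        )
        hot_groups["hotspot" if carrier else "wild_type"].append(
            (clin.pfs_months, clin.pfs_event)
        )
    stats_report["pfs_by_ras_hotspot"] = _survival_comparison(hot_groups)

    # baseline burden vs tumor size (mutation-positive patients)
    xs, ys = [], []
    for pid, points in sorted(trajectories.items()):
        base = points[0]
        if base.n_mutations > 0 and base.tumor_size_mm is not None:
            xs.append(base.average_vaf_pct)
            ys.append(base.tumor_size_mm)
    if len(xs) >= 3:
        r, p = cs.correlate(xs, ys, "pearson")
        stats_report["baseline_vaf_vs_tumor_size"] = {
            "pearson_r": _round(r), "p": _round(p, 8), "n": len(xs)
        }

    # change in burden vs change in size at first evaluation
    dx, dy = [], []
    for pid, ds in sorted(deltas.items()):
        for d in ds:
            if d.timepoint == "eval1" and d.size_delta_pct is not None:
                dx.append(d.vaf_delta_points)
                dy.append(d.size_delta_pct)
    if len(dx) >= 3:
        r, p = cs.correlate(dx, dy, "pearson")
        stats_report["delta_vaf_vs_delta_size_eval1"] = {
            "pearson_r": _round(r), "p": _round(p, 8), "n": len(dx)
        }

    # detection vs liver metastasis, and burden markers by detection status
    det_liver = [[0, 0], [0, 0]]
    size_pos, size_neg, cea_pos, cea_neg = [], [], [], []
    for pid, sset in sorted(baseline_by_pid.items()):
        clin = clin_by_patient.get(pid)
        if clin is None:
            continue
        positive = bool(sset.calls)
        liver = "liver" in clin.met_sites
        det_liver[0 if liver else 1][0 if positive else 1] += 1
        base_size = clin.tumor_size_mm.get("baseline")
        if base_size is not None:
            (size_pos if positive else size_neg).append(base_size)
        if clin.cea_ng_ml is not None:
            (cea_pos if positive else cea_neg).append(clin.cea_ng_ml)
    if sum(map(sum, det_liver)) > 0:
        try:
            assoc = cs.assoc_2x2(det_liver)
            stats_report["detection_vs_liver_metastasis"] = {
                "table": det_liver, "p": _round(assoc.p, 8), "test_used": assoc.test_used
            }
        except ValueError:
            pass
    if size_pos and size_neg:
        u, p = cs.mann_whitney(size_pos, size_neg)
        stats_report["tumor_size_by_detection"] = {"U": u, "p": _round(p, 8)}
    if cea_pos and cea_neg:
        u, p = cs.mann_whitney(cea_pos, cea_neg)
        stats_report["cea_by_detection"] = {"U": u, "p": _round(p, 8)}
    return stats_report
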