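"""The filter cascade: class, thresholds, germline, blacklist."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_call
from ctdna.somatic_filter import (
    Disposition,
    FilterConfig,
    build_blacklist,
    extract_germline,
    filter_functional,
    filter_thresholds,
    finalize_somatic,
    run_cascade,
    read_blacklist,
    write_blacklist,
)
from ctdna.synthetic import SimParams, simulate_cohort
from ctdna.variant_io import FunctionalClass, Material, SampleMeta, VariantKey


class TestFunctionalStage:
    def test_allowed_classes_kept_others_dropped(self):
        calls = [
            make_call(pos=100, fclass=FunctionalClass.MISSENSE),
            make_call(pos=200, fclass=FunctionalClass.OTHER),
            make_call(pos=300, fclass=FunctionalClass.FRAMESHIFT, ref="CT", alt="C"),
        ]
        kept = filter_functional(calls)
        assert [c.key.pos for c in kept] == [100, 300]

    def test_mixed_list_dispositions_logged(self, cfdna_sample):
        classes = [
            FunctionalClass.MISSENSE, FunctionalClass.OTHER, FunctionalClass.STOP_GAIN,
            FunctionalClass.OTHER, FunctionalClass.STOP_LOSS, FunctionalClass.OTHER,
            FunctionalClass.INFRAME_DELETION, FunctionalClass.OTHER,
            FunctionalClass.OTHER, FunctionalClass.OTHER,
        ]
        calls = [
            make_call(
                pos=100 + i,
                fclass=f,
                ref="CTA" if f is FunctionalClass.INFRAME_DELETION else "C",
                alt="C" if f is FunctionalClass.INFRAME_DELETION else "A",
            )
            for i, f in enumerate(classes)
        ]
        sset = run_cascade(calls, cfdna_sample)
        assert len(sset.calls) == 4
        counts = sset.disposition_counts()
        assert counts[Disposition.CLASS] == 6
        assert counts[Disposition.KEPT] == 4
        assert sum(counts.values()) == len(calls)


class TestThresholdStage:
    def test_cfdna_boundaries_inclusive(self, config):
        keep = make_call(depth=1000, alt_reads=10, vaf=0.01)  # exactly 1%, 10 reads
        assert filter_thresholds([keep], Material.CFDNA, config) == [keep]

    def test_cfdna_reported_call_retained(self, config):
        call = make_call(depth=2011, alt_reads=35)  # 1.74%
        assert filter_thresholds([call], Material.CFDNA, config) == [call]

    def test_below_either_criterion_dropped(self, config):
        low_vaf = make_call(depth=10000, alt_reads=90, vaf=0.009)
        assert filter_thresholds([low_vaf], Material.CFDNA, config) == []
        few_reads = make_call(depth=500, alt_reads=9, vaf=0.018)
        assert filter_thresholds([few_reads], Material.CFDNA, config) == []

    def test_tissue_ten_percent_rule(self, config):
        ok = make_call(depth=2000, alt_reads=200, vaf=0.10)
        near = make_call(pos=999, depth=2020, alt_reads=200)  # 9.9%
        assert filter_thresholds([ok, near], Material.TISSUE_FFPE, config) == [ok]

    def test_pbmc_rejected(self, config):
        with pytest.raises(ValueError, match="PBMC"):
            filter_thresholds([make_call()], Material.PBMC, config)


class TestGermlineAndBlacklist:
    def test_twenty_percent_boundary_partition(self, config):
        vafs = [0.999, 0.501, 0.20, 0.19, 0.03]
        calls = [
            make_call(pos=100 + i, depth=1000, alt_reads=int(1000 * v), vaf=None)
            for i, v in enumerate(vafs)
        ]
        germ = extract_germline(calls, config)
        bl = build_blacklist(calls, config)
        assert len(germ) == 3  # >= 20% including the boundary
        assert len(bl.entries) == 2
        assert not germ & bl.entries
        assert germ | bl.entries == {c.key for c in calls}

    def test_blacklist_provenance_across_patients(self, config):
        calls = [
            make_call(sample_id=s, depth=1000, alt_reads=20, vaf=None)
            for s in ("B1", "B2", "B3")
        ]
        bl = build_blacklist(calls, config)
        assert len(bl.entries) == 1
        (prov,) = bl.provenance.values()
        assert len(prov) == 3

    def test_min_recurrence_option(self):
        config = FilterConfig(blacklist_min_recurrence=2)
        singleton = make_call(pos=100, sample_id="B1", depth=1000, alt_reads=20, vaf=None)
        recurrent = [
            make_call(pos=200, sample_id=s, depth=1000, alt_reads=20, vaf=None)
            for s in ("B1", "B2")
        ]
        bl = build_blacklist([singleton] + recurrent, config)
        assert bl.entries == {recurrent[0].key}

    def test_empty_pool_valid(self, config):
        assert len(build_blacklist([], config)) == 0

    def test_blacklist_round_trip(self, tmp_path, config):
        calls = [make_call(pos=100 + i, depth=1000, alt_reads=20, vaf=None) for i in range(4)]
        bl = build_blacklist(calls, config)
        write_blacklist(bl, tmp_path / "bl.tsv")
        assert read_blacklist(tmp_path / "bl.tsv").entries == bl.entries


class TestFinalize:
    def test_germline_applied_before_blacklist(self, cfdna_sample, config):
        call = make_call()
        bl = build_blacklist(
            [make_call(sample_id="B9", depth=1000, alt_reads=20, vaf=None)], config
        )
        sset = finalize_somatic([call], {call.key}, bl, config, sample=cfdna_sample)
        assert sset.cascade_log[-1][1] == Disposition.GERMLINE

    def test_blacklist_only_match(self, cfdna_sample, config):
        call = make_call()
        bl = build_blacklist(
            [make_call(sample_id="B9", depth=1000, alt_reads=20, vaf=None)], config
        )
        sset = finalize_somatic([call], set(), bl, config, sample=cfdna_sample)
        assert sset.calls == [] and sset.cascade_log[-1][1] == Disposition.BLACKLIST

    def test_manual_exclusion_hook(self, cfdna_sample, config):
        call = make_call()
        sset = finalize_somatic(
            [call], set(), None, config, sample=cfdna_sample, manual_exclusions=[call.key]
        )
        assert sset.cascade_log[-1][1] == Disposition.MANUAL

    def test_missing_pbmc_does_not_crash(self, cfdna_sample, config):
        sset = run_cascade([make_call()], cfdna_sample, config, germline_keys=None)
        assert len(sset.calls) == 1


# ---------------------------------------------------------------------------
# Brute-force oracle and cascade properties
# ---------------------------------------------------------------------------

ALLOWED = {
    FunctionalClass.MISSENSE, FunctionalClass.STOP_GAIN, FunctionalClass.STOP_LOSS,
    FunctionalClass.INFRAME_DELETION, FunctionalClass.FRAMESHIFT,
}


def brute_force_filter(calls, material, germline_keys, blacklist_keys):
    """Independent one-pass reference filter (kept deliberately naive)."""
    if material == Material.CFDNA:
        min_vaf, min_alt = 0.01, 10
    else:
        min_vaf, min_alt = 0.10, 10
    kept = []
    for c in calls:
        if c.functional_class not in ALLOWED:
            continue
        vaf_ok = (
            100 * c.alt_reads >= 100 * min_vaf * c.depth - 1e-9
            if c.depth
            else c.vaf >= min_vaf - 1e-11
        )
        if not vaf_ok or (c.alt_reads is not None and c.alt_reads < min_alt):
            continue
        if c.key in germline_keys or c.key in blacklist_keys:
            continue
        kept.append(c)
    return kept


def random_calls(rng, n, sample_id="S1"):
    calls = []
    for i in range(n):
        depth = int(rng.integers(50, 3000))
        alt = int(rng.integers(0, depth // 3 + 1))
        calls.append(
            make_call(
                pos=int(rng.integers(1, 500)),
                alt="A",
                ref="C",
                fclass=list(FunctionalClass)[int(rng.integers(6))],
                sample_id=sample_id,
                depth=depth,
                alt_reads=alt,
                vaf=None,
            )
        )
    return calls


@pytest.mark.parametrize("material", [Material.CFDNA, Material.TISSUE_FFPE])
@pytest.mark.parametrize("seed", range(6))
def test_cascade_equals_brute_force_on_random_input(material, seed, config):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(0, 101))
    calls = random_calls(rng, n)
    germ = {c.key for c in calls[::7]}
    bl_calls = [
        make_call(pos=int(p), sample_id="B1", depth=1000, alt_reads=30, vaf=None)
        for p in rng.integers(1, 500, size=10)
    ]
    bl = build_blacklist(bl_calls, config)
    sample = SampleMeta("S1", "P1", material, "baseline", "v3")
    sset = run_cascade(calls, sample, config, germline_keys=germ, blacklist=bl)
    expected = brute_force_filter(calls, material, germ, bl.entries)
    assert sset.calls == expected
    assert len(sset.cascade_log) == len(calls)


def test_cascade_idempotent_on_its_own_output(config, cfdna_sample):
    rng = np.random.default_rng(42)
    calls = random_calls(rng, 80)
    germ = {c.key for c in calls[::9]}
    first = run_cascade(calls, cfdna_sample, config, germline_keys=germ)
    second = run_cascade(first.calls, cfdna_sample, config, germline_keys=germ)
    assert second.calls == first.calls


def test_no_kept_call_violates_thresholds(config, cfdna_sample, tissue_sample):
    rng = np.random.default_rng(7)
    calls = random_calls(rng, 100)
    for sample, min_vaf in ((cfdna_sample, 0.01), (tissue_sample, 0.10)):
        sset = run_cascade(calls, sample, config)
        assert all(c.vaf >= min_vaf and c.alt_reads >= 10 for c in sset.calls)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(vaf_milli=st.integers(0, 1000))
def test_pbmc_call_is_germline_xor_blacklist_candidate(vaf_milli):
    """Every PBMC VAF in [0, 1] routes to exactly one of the two pools."""
    config = FilterConfig()
    vaf = vaf_milli / 1000.0
    call = make_call(depth=1000, alt_reads=vaf_milli, vaf=None, sample_id="B1")
    germ = extract_germline([call], config)
    bl = build_blacklist([call], config)
    assert (call.key in germ) != (call.key in bl.entries)


def test_planted_clonal_hematopoiesis_recovered_exactly(config):
    """Cohort-simulator oracle: PBMC pools route germline vs blacklist
    exactly as planted (no noise calls in this check)."""
    params = SimParams(n_patients=60, seed=21, noise_mean=0.0, ch_mean=0.6)
    cohort = simulate_cohort(params)
    pool = [
        c
        for s in cohort.samples
        if s.material == Material.PBMC
        for c in cohort.calls[s.sample_id]
    ]
    bl = build_blacklist(pool, config)
    planted_ch = set()
    for pt in cohort.truth.patients.values():
        planted_ch |= pt.ch_keys()
    assert bl.entries == planted_ch
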