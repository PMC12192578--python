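"""Consensus variant filter: normalization, merging, criteria I-V,
significance exclusion, and brute-force oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfpipe import simulate as sim
from cfpipe.consensus import (
    Candidate,
    CallerVariant,
    FilterParams,
    SiteAnnotation,
    annotations_from_frames,
    apply_criteria,
    filter_callset,
    merge_callers,
    normalize_variant,
    read_caller_vcf,
    write_caller_vcf,
)

PASSING = SiteAnnotation(germline_alt_reads=0, max_pop_af=0.0,
                         significance="uncertain_significance")


def make_candidate(n_callers=3, depth=147, alt_reads=12):
    return Candidate(
        key=("7", 100, "C", "T"),
        supporting_callers=tuple(f"caller{i}" for i in range(n_callers)),
        depth=depth,
        alt_reads=alt_reads,
    )


class TestNormalizeVariant:
    def test_snv_unchanged(self):
        assert normalize_variant("7", 100, "C", "T") == ("7", 100, "C", "T")

    def test_shared_suffix_trimmed(self):
        assert normalize_variant("7", 100, "CA", "TA") == ("7", 100, "C", "T")

    def test_minimal_deletion_kept(self):
        assert normalize_variant("7", 100, "AC", "A") == ("7", 100, "AC", "A")

    def test_prefix_trim_advances_position(self):
        assert normalize_variant("7", 100, "AT", "AG") == ("7", 101, "T", "G")

    @given(
        pos=st.integers(1, 10**6),
        core_ref=st.text("ACGT", min_size=1, max_size=3),
        core_alt=st.text("ACGT", min_size=1, max_size=3),
        prefix=st.text("ACGT", max_size=3),
        suffix=st.text("ACGT", max_size=3),
    )
    @settings(max_examples=200, deadline=None)
    def test_padding_never_changes_the_key(self, pos, core_ref, core_alt, prefix, suffix):
        if core_ref == core_alt:
            return
        if core_ref[-1] == core_alt[-1] or core_ref[0] == core_alt[0]:
            return  # core itself must already be minimal
        base = normalize_variant("1", pos + len(prefix), core_ref, core_alt)
        padded = normalize_variant(
            "1", pos, prefix + core_ref + suffix, prefix + core_alt + suffix
        )
        assert padded == base

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant("7", 100, "", "T")


class TestMergeCallers:
    def test_counts_from_deepest_caller(self):
        callsets = {
            "a": [CallerVariant("a", "7", 100, "C", "T", 120, 10)],
            "b": [CallerVariant("b", "7", 100, "C", "T", 200, 14)],
        }
        (cand,) = merge_callers(callsets)
        assert cand.supporting_callers == ("a", "b")
        assert (cand.depth, cand.alt_reads) == (200, 14)

    def test_caller_counts(self):
        v = ("7", 100, "C", "T")
        callsets = {
            c: [CallerVariant(c, *v, 100, 10)] for c in ("m", "v", "s", "k")
        }
        callsets["m"].append(CallerVariant("m", "8", 5, "A", "G", 100, 10))
        merged = {c.key: c for c in merge_callers(callsets)}
        assert len(merged[("7", 100, "C", "T")].supporting_callers) == 4
        assert len(merged[("8", 5, "A", "G")].supporting_callers) == 1

    def test_equivalent_representations_merge(self):
        callsets = {
            "a": [CallerVariant("a", "7", 100, "CA", "TA", 100, 10)],
            "b": [CallerVariant("b", "7", 100, "C", "T", 90, 9)],
        }
        (cand,) = merge_callers(callsets)
        assert cand.key == ("7", 100, "C", "T")
        assert len(cand.supporting_callers) == 2


class TestApplyCriteria:
    def test_deep_callset_example_passes(self):
        res = apply_criteria(
            make_candidate(n_callers=2, depth=147, alt_reads=12), PASSING
        )
        assert res.verdict == "pass" and res.failure_reasons == ()

    def test_seven_alt_reads_fails_iv(self):
        res = apply_criteria(make_candidate(alt_reads=7, depth=100), PASSING)
        assert res.verdict == "fail" and res.failure_reasons == ("IV",)

    def test_likely_benign_fails_significance(self):
        annot = SiteAnnotation(0, 0.0, "likely_benign")
        res = apply_criteria(make_candidate(), annot)
        assert res.failure_reasons == ("significance",)

    def test_germline_support_fails_iv(self):
        annot = SiteAnnotation(germline_alt_reads=3, max_pop_af=0.0,
                               significance="uncertain_significance")
        res = apply_criteria(make_candidate(), annot)
        assert res.failure_reasons == ("IV",)

    def test_pop_af_threshold_is_strict(self):
        at_limit = SiteAnnotation(0, 1e-4, "uncertain_significance")
        assert apply_criteria(make_candidate(), at_limit).failure_reasons == ("V",)
        below = SiteAnnotation(0, 0.99e-4, "uncertain_significance")
        assert apply_criteria(make_candidate(), below).verdict == "pass"

    def test_missing_annotation_fails_v(self):
        res = apply_criteria(make_candidate(), None)
        assert res.failure_reasons == ("V",)

    def test_every_violation_listed(self):
        annot = SiteAnnotation(2, 0.01, "benign")
        res = apply_criteria(
            Candidate(("1", 1, "A", "T"), ("only",), depth=8, alt_reads=0), annot
        )
        assert res.failure_reasons == ("I", "II", "III", "IV", "V", "significance")


def brute_force_filter(callsets, annotations, params):
    """Oracle: re-evaluate the six predicates from the raw caller records."""
    by_key = {}
    for caller, records in callsets.items():
        for v in records:
            by_key.setdefault((v.chrom, v.pos, v.ref, v.alt), {})[caller] = v
    passing = set()
    for key, records in by_key.items():
        best = max(records.values(), key=lambda v: (v.depth, v.caller))
        annot = annotations.get(key)
        sig = (annot.significance.lower().replace("_", " ") if annot else "")
        ok = (
            len(records) >= params.min_callers
            and best.depth >= params.min_depth
            and best.alt_reads / best.depth >= params.min_vaf
            and best.alt_reads >= params.min_alt_reads
            and (annot is not None and annot.germline_alt_reads <= params.max_germline_alt)
            and (annot is not None and annot.max_pop_af < params.max_pop_af)
            and sig not in ("benign", "likely benign")
        )
        if ok:
            passing.add(key)
    return passing


def random_callset_spec(rng):
    variants = []
    used = set()
    for _ in range(rng.integers(3, 12)):
        site = (str(rng.integers(1, 23)), int(rng.integers(1, 10**8)))
        if site in used:
            continue
        used.add(site)
        variants.append(
            sim.TrueVariant(site[0], site[1], "C", "T", float(rng.uniform(0.02, 0.3)))
        )
    return sim.CallsetSpec(
        true_variants=variants,
        depth=int(rng.integers(30, 300)),
        sensitivities={c: float(rng.uniform(0.5, 1.0))
                       for c in ("m2", "vd", "vs", "s2")},
        fp_per_caller=int(rng.integers(0, 5)),
        germline_contaminants=int(rng.integers(0, 4)),
    )


class TestFilterCallset:
    def test_empty_input(self):
        passing, audit = filter_callset({"a": [], "b": []}, {})
        assert passing == [] and audit.empty

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spec = random_callset_spec(rng)
        bundle = sim.gen_callsets(spec, seed=seed)
        annotations = annotations_from_frames(bundle.annotations, bundle.germline)
        params = FilterParams()
        passing, audit = filter_callset(bundle.callsets, annotations, params)
        expected = brute_force_filter(bundle.callsets, annotations, params)
        assert {r.key for r in passing} == expected
        # audit holds every candidate, and pass <=> no failed criterion
        crit_cols = [c for c in audit.columns if c.startswith("crit_")]
        assert (audit[crit_cols].all(axis=1) == (audit["verdict"] == "pass")).all()

    def test_conjunction_is_candidate_local(self):
        bundle = sim.gen_callsets(sim.CallsetSpec(), seed=9)
        annotations = annotations_from_frames(bundle.annotations, bundle.germline)
        full, _ = filter_callset(bundle.callsets, annotations)
        # drop one candidate from every caller: others' verdicts unchanged
        drop = bundle.truth.iloc[0]
        trimmed = {
            c: [v for v in vs if (v.chrom, v.pos) != (drop.chrom, drop.pos)]
            for c, vs in bundle.callsets.items()
        }
        partial, _ = filter_callset(trimmed, annotations)
        kept = {r.key for r in full} - {(drop.chrom, drop.pos, drop.ref, drop.alt)}
        assert {r.key for r in partial} == kept

    @pytest.mark.parametrize(
        "tighter",
        [
            {"min_callers": 3},
            {"min_depth": 100},
            {"min_vaf": 0.10},
            {"min_alt_reads": 15},
            {"max_pop_af": 1e-6},
        ],
    )
    def test_tightening_never_grows_passing_set(self, tighter):
        bundle = sim.gen_callsets(sim.CallsetSpec(), seed=13)
        annotations = annotations_from_frames(bundle.annotations, bundle.germline)
        base, _ = filter_callset(bundle.callsets, annotations, FilterParams())
        tight, _ = filter_callset(
            bundle.callsets, annotations, FilterParams(**tighter)
        )
        assert {r.key for r in tight} <= {r.key for r in base}

    def test_output_sorted_by_position(self):
        bundle = sim.gen_callsets(sim.CallsetSpec(), seed=2)
        annotations = annotations_from_frames(bundle.annotations, bundle.germline)
        passing, audit = filter_callset(bundle.callsets, annotations)
        keys = [(r.key[0], r.key[1]) for r in passing]
        assert keys == sorted(keys)


class TestVcfIO:
    def test_round_trip(self, tmp_path):
        variants = [
            CallerVariant("m2", "7", 100, "C", "T", 150, 12),
            CallerVariant("m2", "X", 5000, "G", "A", 80, 40),
        ]
        path = tmp_path / "m2.vcf"
        write_caller_vcf(variants, path, sample="m2")
        back = read_caller_vcf(path, "m2")
        assert sorted(back, key=lambda v: v.chrom) == sorted(
            variants, key=lambda v: v.chrom
        )

    def test_generated_bundle_round_trips(self, tmp_path):
        bundle = sim.gen_callsets(sim.CallsetSpec(), seed=6)
        paths = bundle.write(tmp_path)
        for caller, path in paths["vcf"].items():
            back = read_caller_vcf(path, caller)
            key = lambda v: (v.chrom, v.pos, v.ref, v.alt)
            assert sorted(back, key=key) == sorted(bundle.callsets[caller], key=key)
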