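"""Filter predicates, built-in profiles, and the cascade."""

import dataclasses
import random

import pytest
from hypothesis import given, settings, strategies as st

from _naive import naive_retained_keys
from conftest import score_cohort

from tmbkit.filters import (
    DriverPolicy,
    FilterProfile,
    Preservation,
    QualityPolicy,
    RunContext,
    apply_profile,
    builtin_profile,
    class_pass,
    germline_flag,
    recurrence_flag,
    vaf_depth_pass,
)
from tmbkit.simulate import SimConfig, simulate_cohort
from tmbkit.variants import (
    AnnotatedVariant,
    Caller,
    Consequence,
    FunctionalAnnotation,
    RegionClass,
    VariantCall,
    VariantKey,
)


def mkvar(pos=100, vaf=0.3, depth=500, pass_flag=True, region=RegionClass.EXONIC,
          consequence=Consequence.MISSENSE, afs=None, cosmic=False, sample="S1"):
    key = VariantKey("1", pos, "A", "T")
    return AnnotatedVariant(
        call=VariantCall(key=key, vaf=vaf, depth=depth, caller=Caller.VARSCAN2,
                         pass_flag=pass_flag, sample_id=sample),
        annotation=FunctionalAnnotation(
            region_class=region, consequence=consequence,
            population_afs=afs or {}, cosmic_hit=cosmic,
        ),
    )


class TestBuiltinProfiles:
    def test_ic_parameterization(self, ic_profile):
        p = ic_profile
        assert p.min_vaf_by_preservation[Preservation.FFPE] == 0.10
        assert p.min_vaf_by_preservation[Preservation.FROZEN] == 0.05
        assert p.min_depth == 100
        assert p.maf_cutoff == 0.001
        assert set(p.germline_dbs) == {"1000g", "gnomad", "exac"}
        assert p.quality_policy is QualityPolicy.INTRA_RUN_RECURRENCE
        assert p.recurrence_threshold == 0.15
        assert p.driver_policy is DriverPolicy.INCLUDE_COSMIC
        assert p.panel_size_mb == 1.6
        assert not p.class_policy[Consequence.SYNONYMOUS]
        assert not p.class_policy[Consequence.SPLICE_SITE]
        assert p.class_policy[Consequence.MISSENSE]
        assert p.class_policy[Consequence.FRAMESHIFT_INDEL]

    def test_fo_parameterization(self, fo_profile):
        p = fo_profile
        assert p.min_vaf_by_preservation[Preservation.FFPE] == 0.05
        assert p.min_vaf_by_preservation[Preservation.FROZEN] == 0.05
        assert p.driver_policy is DriverPolicy.EXCLUDE_COSMIC
        assert "gnomad" not in p.germline_dbs
        assert set(p.germline_dbs) == {"1000g", "exac"}
        assert p.quality_policy is QualityPolicy.REQUIRE_PASS
        assert p.class_policy[Consequence.SYNONYMOUS]
        assert p.class_policy[Consequence.SPLICE_SITE]

    def test_profiles_differ_exactly_where_documented(self, ic_profile, fo_profile):
        differing = {
            f.name
            for f in dataclasses.fields(FilterProfile)
            if getattr(ic_profile, f.name) != getattr(fo_profile, f.name)
        }
        assert differing == {
            "name", "min_vaf_by_preservation", "germline_dbs",
            "quality_policy", "class_policy", "driver_policy",
        }

    def test_unknown_name_lists_builtins(self):
        with pytest.raises(ValueError, match="IC"):
            builtin_profile("XYZ")

    def test_yaml_round_trip(self, tmp_path, ic_profile):
        ic_profile.to_yaml(tmp_path / "p.yaml")
        loaded = FilterProfile.from_yaml(tmp_path / "p.yaml")
        assert loaded == ic_profile


class TestGermlineFlag:
    def test_af_above_cutoff_removed(self, ic_profile):
        ann = mkvar(afs={"gnomad": 0.002}).annotation
        assert germline_flag(ann, ic_profile) is True

    def test_af_exactly_at_cutoff_kept(self, ic_profile):
        # the bound is strict: "higher than 0.1%"
        ann = mkvar(afs={"gnomad": 0.001}).annotation
        assert germline_flag(ann, ic_profile) is False

    def test_absent_afs_never_trigger(self, ic_profile):
        assert germline_flag(mkvar().annotation, ic_profile) is False

    def test_unconfigured_database_ignored(self, fo_profile):
        # FO's database list has no gnomAD: a gnomAD-only polymorphism stays
        ann = mkvar(afs={"gnomad": 0.3}).annotation
        assert germline_flag(ann, fo_profile) is False


class TestRecurrenceFlag:
    def run_ctx(self, count, total, key):
        return RunContext("r1", total, {key: count})

    @pytest.mark.parametrize("count,total,expected", [
        (4, 20, True),   # 20% > 15%
        (3, 20, False),  # exactly 15%: strict bound
        (1, 1, True),    # degenerate single-sample run
        (0, 10, False),
    ])
    def test_threshold(self, ic_profile, count, total, expected):
        key = VariantKey("1", 5, "C", "T")
        assert recurrence_flag(key, self.run_ctx(count, total, key), ic_profile) is expected

    def test_empty_run_errors(self, ic_profile):
        key = VariantKey("1", 5, "C", "T")
        with pytest.raises(ValueError):
            recurrence_flag(key, RunContext("r1", 0, {}), ic_profile)

    def test_presence_exceeding_run_size_rejected(self):
        key = VariantKey("1", 5, "C", "T")
        with pytest.raises(ValueError):
            RunContext("r1", 2, {key: 3})


class TestVafDepthPass:
    @pytest.mark.parametrize("pres,vaf,depth,expected", [
        ("FFPE", 0.09, 500, False),   # below the FFPE 10% bound
        ("frozen", 0.09, 500, True),  # above the frozen 5% bound
        ("FFPE", 0.50, 100, False),   # depth not strictly above 100
        ("FFPE", 0.10, 500, False),   # VAF exactly at bound: strict
        ("frozen", 0.051, 101, True),
    ])
    def test_strict_bounds(self, ic_profile, pres, vaf, depth, expected):
        call = mkvar(vaf=vaf, depth=depth).call
        assert vaf_depth_pass(call, pres, ic_profile) is expected

    def test_nonstrict_mode(self, ic_profile):
        lax = dataclasses.replace(ic_profile, strict=False)
        call = mkvar(vaf=0.10, depth=100).call
        assert vaf_depth_pass(call, "FFPE", lax) is True


class TestClassPass:
    def test_synonymous_profile_dependent(self, ic_profile, fo_profile):
        ann = mkvar(consequence=Consequence.SYNONYMOUS).annotation
        assert class_pass(ann, ic_profile) is False
        assert class_pass(ann, fo_profile) is True

    def test_cosmic_driver_removed_only_under_fo(self, ic_profile, fo_profile):
        ann = mkvar(cosmic=True).annotation
        assert class_pass(ann, fo_profile) is False
        assert class_pass(ann, ic_profile) is True

    def test_unknown_consequence_conservatively_excluded(self, ic_profile, fo_profile):
        ann = mkvar(consequence=Consequence.UNKNOWN).annotation
        assert class_pass(ann, ic_profile) is False
        assert class_pass(ann, fo_profile) is False

    @pytest.mark.parametrize("region", [
        RegionClass.INTRONIC, RegionClass.UTR, RegionClass.INTERGENIC,
        RegionClass.OTHER_NONCODING, RegionClass.UNKNOWN,
    ])
    def test_noncoding_regions_excluded_everywhere(self, ic_profile, fo_profile, region):
        ann = mkvar(region=region).annotation
        assert class_pass(ann, ic_profile) is False
        assert class_pass(ann, fo_profile) is False

    def test_splice_site_profile_dependent(self, ic_profile, fo_profile):
        ann = mkvar(region=RegionClass.SPLICING,
                    consequence=Consequence.SPLICE_SITE).annotation
        assert class_pass(ann, ic_profile) is False
        assert class_pass(ann, fo_profile) is True


class TestApplyProfile:
    def test_empty_input(self, ic_profile):
        report = apply_profile([], "FFPE", RunContext("r", 5, {}), ic_profile)
        assert report.n_retained == 0
        assert sum(report.attrition.values()) == 0

    def test_single_stage_attrition(self, fo_profile):
        # ten variants failing only the germline filter
        variants = [
            mkvar(pos=100 + i, afs={"1000g": 0.01}) for i in range(10)
        ]
        report = apply_profile(variants, "FFPE", None, fo_profile)
        assert report.n_retained == 0
        assert report.attrition["germline"] == 10
        assert sum(report.attrition.values()) == 10

    def test_attrition_partitions_removals(self, default_cohort, ic_profile):
        sid = next(iter(default_cohort.variants))
        report = apply_profile(
            default_cohort.variants[sid],
            default_cohort.metas[sid].preservation,
            default_cohort.run_of(sid), ic_profile,
        )
        assert report.n_input - report.n_retained == sum(report.attrition.values())

    def test_external_germline_hook(self, fo_profile):
        v = mkvar(pos=100)
        verdicts = {v.key: True}
        report = apply_profile([v], "FFPE", None, fo_profile,
                               external_germline=verdicts)
        assert report.n_retained == 0
        assert report.attrition["germline"] == 1

    def test_missing_run_context_rejected(self, ic_profile):
        with pytest.raises(ValueError, match="RunContext"):
            apply_profile([mkvar()], "FFPE", None, ic_profile)

    @pytest.mark.parametrize("profile_name", ["IC", "FO"])
    def test_matches_naive_reference_on_synthetic_samples(
        self, default_cohort, profile_name
    ):
        profile = builtin_profile(profile_name)
        for sid, variants in default_cohort.variants.items():
            run = default_cohort.run_of(sid)
            pres = default_cohort.metas[sid].preservation
            report = apply_profile(variants, pres, run, profile)
            got = {v.key for v in report.retained_variants()}
            expected = naive_retained_keys(variants, pres, run, profile)
            assert got == expected

    def test_retention_invariant_to_input_order(self, default_cohort, ic_profile):
        sid = next(iter(default_cohort.variants))
        variants = list(default_cohort.variants[sid])
        run = default_cohort.run_of(sid)
        pres = default_cohort.metas[sid].preservation
        base = {v.key for v in
                apply_profile(variants, pres, run, ic_profile).retained_variants()}
        rng = random.Random(5)
        for _ in range(3):
            shuffled = variants[:]
            rng.shuffle(shuffled)
            got = {v.key for v in
                   apply_profile(shuffled, pres, run, ic_profile).retained_variants()}
            assert got == base


class TestMonotonicity:
    @given(
        min_vaf=st.floats(min_value=0.01, max_value=0.5),
        min_depth=st.integers(min_value=50, max_value=2000),
        bump_vaf=st.floats(min_value=0.0, max_value=0.3),
        bump_depth=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_tightening_thresholds_never_gains_variants(
        self, min_vaf, min_depth, bump_vaf, bump_depth
    ):
        cohort = simulate_cohort(SimConfig(seed=55, n_samples=2, samples_per_run=2))
        sid = "S001"
        variants = cohort.variants[sid]
        run = cohort.run_of(sid)
        pres = cohort.metas[sid].preservation
        base_profile = dataclasses.replace(
            builtin_profile("IC"),
            min_vaf_by_preservation={
                Preservation.FFPE: min_vaf, Preservation.FROZEN: min_vaf,
            },
            min_depth=min_depth,
        )
        tight = dataclasses.replace(
            base_profile,
            min_vaf_by_preservation={
                Preservation.FFPE: min(min_vaf + bump_vaf, 0.99),
                Preservation.FROZEN: min(min_vaf + bump_vaf, 0.99),
            },
            min_depth=min_depth + bump_depth,
        )
        n_base = apply_profile(variants, pres, run, base_profile).n_retained
        n_tight = apply_profile(variants, pres, run, tight).n_retained
        assert n_tight <= n_base

    def test_adding_germline_database_never_gains(self, default_cohort, fo_profile):
        wider = dataclasses.replace(
            fo_profile, germline_dbs=fo_profile.germline_dbs + ["gnomad"]
        )
        for r_narrow, r_wide in zip(
            score_cohort(default_cohort, fo_profile),
            score_cohort(default_cohort, wider),
        ):
            assert r_wide.n_retained <= r_narrow.n_retained
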