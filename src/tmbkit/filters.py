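"""Variant-filter cascade and the two built-in algorithm profiles.

Each filter is an independent, pure predicate over one variant (given a
fixed run context), so the retained set is invariant to evaluation order.
The two built-ins mirror the published parameterizations:

``IC``
    Intra-run recurrence quality filter (variants seen in more than 15%
    of samples of the same sequencing run are systematic artifacts);
    germline removal by population MAF > 0.1% in 1000 Genomes, gnomAD or
    ExAC; keeps missense, nonsense and indels (COSMIC membership
    ignored); excludes synonymous, splice-site and non-coding variants;
    VAF > 5% for frozen tumors and > 10% for FFPE tumors; depth > 100X.

``FO``
    Caller PASS tag as the quality filter; germline removal by MAF >
    0.1% in 1000 Genomes or ExAC (an external somatic/germline-zygosity
    verdict can be plugged in per variant); keeps synonymous,
    splice-site, missense, nonsense and indels but removes COSMIC-listed
    drivers and non-coding variants; VAF > 5% for both preservations;
    depth > 100X.

All threshold comparisons are strict (``>``), following the "higher
than" convention; set ``strict=False`` on a profile for ``>=`` semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .variants import (
    AnnotatedVariant,
    Consequence,
    FunctionalAnnotation,
    RegionClass,
    VariantCall,
    VariantKey,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Preservation",
    "QualityPolicy",
    "DriverPolicy",
    "FilterProfile",
    "RunContext",
    "VariantVerdict",
    "FilterReport",
    "FILTER_STAGES",
    "builtin_profile",
    "quality_pass",
    "germline_flag",
    "recurrence_flag",
    "vaf_depth_pass",
    "class_pass",
    "apply_profile",
    "build_run_context",
]


class Preservation(str, Enum):
    FFPE = "FFPE"
    FROZEN = "frozen"


class QualityPolicy(str, Enum):
    REQUIRE_PASS = "require_pass"
    INTRA_RUN_RECURRENCE = "intra_run_recurrence"
    BOTH = "both"
    NONE = "none"


class DriverPolicy(str, Enum):
    INCLUDE_COSMIC = "include_cosmic"
    EXCLUDE_COSMIC = "exclude_cosmic"


#: Reporting order of the cascade stages (retention itself is
#: order-independent; attrition is attributed to the first failing stage
#: in this order).
FILTER_STAGES = ("quality", "recurrence", "germline", "class_driver", "vaf_depth")


@dataclass
class FilterProfile:
    """Complete parameterization of one TMB algorithm."""

    name: str
    min_vaf_by_preservation: dict[Preservation, float]
    min_depth: int
    maf_cutoff: float
    germline_dbs: list[str]
    quality_policy: QualityPolicy
    recurrence_threshold: float
    class_policy: dict[Consequence, bool]
    driver_policy: DriverPolicy
    panel_size_mb: float
    strict: bool = True

    def __post_init__(self) -> None:
        self.min_vaf_by_preservation = {
            Preservation(k): float(v) for k, v in self.min_vaf_by_preservation.items()
        }
        self.quality_policy = QualityPolicy(self.quality_policy)
        self.driver_policy = DriverPolicy(self.driver_policy)
        self.class_policy = {Consequence(k): bool(v) for k, v in self.class_policy.items()}
        for p in Preservation:
            if p not in self.min_vaf_by_preservation:
                raise ValueError(f"min_vaf_by_preservation missing {p.value}")
        for v in self.min_vaf_by_preservation.values():
            if not 0.0 < v < 1.0:
                raise ValueError(f"min_vaf out of (0,1): {v}")
        if not 0.0 < self.maf_cutoff < 1.0:
            raise ValueError(f"maf_cutoff out of (0,1): {self.maf_cutoff}")
        if not 0.0 < self.recurrence_threshold <= 1.0:
            raise ValueError(
                f"recurrence_threshold out of (0,1]: {self.recurrence_threshold}"
            )
        if self.panel_size_mb <= 0:
            raise ValueError(f"panel_size_mb must be > 0: {self.panel_size_mb}")
        missing = [c for c in Consequence if c not in self.class_policy]
        if missing:
            raise ValueError(f"class_policy missing consequences: {missing}")

    def _gt(self, value: float, bound: float) -> bool:
        return value > bound if self.strict else value >= bound

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "min_vaf_by_preservation": {
                k.value: v for k, v in self.min_vaf_by_preservation.items()
            },
            "min_depth": self.min_depth,
            "maf_cutoff": self.maf_cutoff,
            "germline_dbs": list(self.germline_dbs),
            "quality_policy": self.quality_policy.value,
            "recurrence_threshold": self.recurrence_threshold,
            "class_policy": {k.value: v for k, v in self.class_policy.items()},
            "driver_policy": self.driver_policy.value,
            "panel_size_mb": self.panel_size_mb,
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FilterProfile":
        return cls(**dict(data))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def builtin_profile(name: str) -> FilterProfile:
    """Return one of the built-in profiles, ``"IC"`` or ``"FO"``."""
    if name == "IC":
        return FilterProfile(
            name="IC",
            min_vaf_by_preservation={Preservation.FFPE: 0.10, Preservation.FROZEN: 0.05},
            min_depth=100,
            maf_cutoff=0.001,
            germline_dbs=["1000g", "gnomad", "exac"],
            quality_policy=QualityPolicy.INTRA_RUN_RECURRENCE,
            recurrence_threshold=0.15,
            class_policy={
                Consequence.SYNONYMOUS: False,
                Consequence.MISSENSE: True,
                Consequence.NONSENSE: True,
                Consequence.FRAMESHIFT_INDEL: True,
                Consequence.INFRAME_INDEL: True,
                Consequence.SPLICE_SITE: False,
                Consequence.UNKNOWN: False,
            },
            driver_policy=DriverPolicy.INCLUDE_COSMIC,
            panel_size_mb=1.6,
        )
    if name == "FO":
        return FilterProfile(
            name="FO",
            min_vaf_by_preservation={Preservation.FFPE: 0.05, Preservation.FROZEN: 0.05},
            min_depth=100,
            maf_cutoff=0.001,
            germline_dbs=["1000g", "exac"],
            quality_policy=QualityPolicy.REQUIRE_PASS,
            recurrence_threshold=0.15,
            class_policy={
                Consequence.SYNONYMOUS: True,
                Consequence.MISSENSE: True,
                Consequence.NONSENSE: True,
                Consequence.FRAMESHIFT_INDEL: True,
                Consequence.INFRAME_INDEL: True,
                Consequence.SPLICE_SITE: True,
                Consequence.UNKNOWN: False,
            },
            driver_policy=DriverPolicy.EXCLUDE_COSMIC,
            panel_size_mb=1.6,
        )
    raise ValueError(f"unknown profile {name!r}; built-ins are: ['IC', 'FO']")


@dataclass
class RunContext:
    """Per-sequencing-run variant presence, for the recurrence filter."""

    run_id: str
    sample_count: int
    variant_presence: Mapping[VariantKey, int]

    def __post_init__(self) -> None:
        if self.sample_count < 0:
            raise ValueError("sample_count must be >= 0")
        over = [k for k, c in self.variant_presence.items() if c > self.sample_count]
        if over:
            raise ValueError(
                f"presence count exceeds sample_count for {len(over)} key(s)"
            )


def build_run_context(
    run_id: str, variants_by_sample: Mapping[str, Sequence[AnnotatedVariant]]
) -> RunContext:
    """Count, per variant key, how many samples of the run carry it.

    Presence is counted among raw parsed variants (before any filter).
    """
    presence: dict[VariantKey, int] = {}
    for sample_variants in variants_by_sample.values():
        for key in {v.key for v in sample_variants}:
            presence[key] = presence.get(key, 0) + 1
    return RunContext(
        run_id=run_id, sample_count=len(variants_by_sample), variant_presence=presence
    )


# --- predicates -------------------------------------------------------------


def quality_pass(call: VariantCall, profile: FilterProfile) -> bool:
    """Caller-quality stage: PASS tag required when the policy says so."""
    if profile.quality_policy in (QualityPolicy.REQUIRE_PASS, QualityPolicy.BOTH):
        return call.pass_flag
    return True


def germline_flag(annotation: FunctionalAnnotation, profile: FilterProfile) -> bool:
    """True when the variant is a population polymorphism to remove.

    Triggers iff any configured database reports an allele frequency
    strictly above the MAF cutoff; a database with no entry for the
    variant never triggers removal.
    """
    if not profile.germline_dbs:
        raise ValueError("profile has no germline databases configured")
    for db in profile.germline_dbs:
        af = annotation.population_afs.get(db)
        if af is not None and profile._gt(af, profile.maf_cutoff):
            return True
    return False


def recurrence_flag(key: VariantKey, run: RunContext, profile: FilterProfile) -> bool:
    """True when the variant recurs in more than ``recurrence_threshold``
    of the run's samples (a systematic artifact)."""
    if run.sample_count == 0:
        raise ValueError(f"run {run.run_id!r} has zero samples")
    frac = run.variant_presence.get(key, 0) / run.sample_count
    return profile._gt(frac, profile.recurrence_threshold)


def vaf_depth_pass(
    call: VariantCall, preservation: Preservation | str, profile: FilterProfile
) -> bool:
    """VAF above the preservation-specific bound and depth above 100X
    (both strict)."""
    min_vaf = profile.min_vaf_by_preservation[Preservation(preservation)]
    return profile._gt(call.vaf, min_vaf) and profile._gt(call.depth, profile.min_depth)


def class_pass(annotation: FunctionalAnnotation, profile: FilterProfile) -> bool:
    """Consequence-class and driver policy in one retention decision.

    Non-coding variants (region outside exonic/splicing) are excluded by
    every profile; under ``exclude_cosmic`` a COSMIC-listed variant is
    removed regardless of class; under ``include_cosmic`` COSMIC
    membership is ignored.
    """
    if profile.driver_policy is DriverPolicy.EXCLUDE_COSMIC and annotation.cosmic_hit:
        return False
    if annotation.region_class not in (RegionClass.EXONIC, RegionClass.SPLICING):
        return False
    return profile.class_policy[annotation.consequence]


# --- cascade ----------------------------------------------------------------


@dataclass(frozen=True)
class VariantVerdict:
    variant: AnnotatedVariant
    stage_pass: Mapping[str, bool]  # keyed by FILTER_STAGES
    retained: bool
    first_failing: Optional[str]  # stage label, None when retained


@dataclass
class FilterReport:
    sample_id: str
    profile_name: str
    verdicts: list[VariantVerdict]
    attrition: dict[str, int]  # first-failure counts per stage

    @property
    def n_input(self) -> int:
        return len(self.verdicts)

    @property
    def n_retained(self) -> int:
        return sum(v.retained for v in self.verdicts)

    def retained_variants(self) -> list[AnnotatedVariant]:
        return [v.variant for v in self.verdicts if v.retained]


def apply_profile(
    variants: Sequence[AnnotatedVariant],
    preservation: Preservation | str,
    run: Optional[RunContext],
    profile: FilterProfile,
    external_germline: Optional[Mapping[VariantKey, bool]] = None,
) -> FilterReport:
    """Evaluate every filter on every variant and assemble the report.

    Parameters
    ----------
    variants
        All parsed variants of one sample.
    preservation
        The sample's preservation (FFPE or frozen); selects the VAF bound.
    run
        Run context; required when the profile's quality policy involves
        intra-run recurrence.
    external_germline
        Optional per-variant germline verdicts from an external
        somatic/germline classifier (e.g. a zygosity-model call); a key
        mapped to True is removed at the germline stage in addition to
        the database MAF rule.

    Every predicate is evaluated for every variant (the report carries
    the full truth table); ``retained`` is their conjunction, so the
    outcome does not depend on stage order. Attrition attributes each
    removed variant to its first failing stage in :data:`FILTER_STAGES`
    order.
    """
    preservation = Preservation(preservation)
    use_recurrence = profile.quality_policy in (
        QualityPolicy.INTRA_RUN_RECURRENCE, QualityPolicy.BOTH,
    )
    if use_recurrence and run is None:
        raise ValueError(
            f"profile {profile.name!r} requires a RunContext for the "
            "intra-run recurrence filter"
        )
    if use_recurrence and 0 < run.sample_count < 7:
        # 15% of 7 samples ~ one sample: below this, any variant shared by
        # two samples is removed as recurrent
        logger.warning(
            "run %s has only %d sample(s); the recurrence filter removes any "
            "variant shared by 2+ samples at threshold %.2f",
            run.run_id, run.sample_count, profile.recurrence_threshold,
        )
    verdicts: list[VariantVerdict] = []
    attrition = {stage: 0 for stage in FILTER_STAGES}
    for v in variants:
        stage_pass = {
            "quality": quality_pass(v.call, profile),
            "recurrence": (not recurrence_flag(v.key, run, profile))
            if use_recurrence else True,
            "germline": not (
                germline_flag(v.annotation, profile)
                or bool(external_germline and external_germline.get(v.key, False))
            ),
            "class_driver": class_pass(v.annotation, profile),
            "vaf_depth": vaf_depth_pass(v.call, preservation, profile),
        }
        retained = all(stage_pass.values())
        first_failing = None
        if not retained:
            first_failing = next(s for s in FILTER_STAGES if not stage_pass[s])
            attrition[first_failing] += 1
        verdicts.append(
            VariantVerdict(
                variant=v, stage_pass=stage_pass,
                retained=retained, first_failing=first_failing,
            )
        )
    return FilterReport(
        sample_id=variants[0].call.sample_id if variants else "",
        profile_name=profile.name,
        verdicts=verdicts,
        attrition=attrition,
    )
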