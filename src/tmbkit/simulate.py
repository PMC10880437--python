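"""Synthetic annotated-VCF cohorts with known ground truth.

The generator emulates the statistical structure of targeted-panel
somatic calling on clinical tumor samples, so every pipeline stage can
be tested without external data:

* **True somatic variants** at a controllable per-Mb density (lognormal
  across samples, Poisson within), with a consequence-class mixture and
  clonal VAFs drawn well above the filter cutoffs.
* **Germline leakage** carrying population-database allele frequencies
  drawn from a two-point mixture straddling the 0.1% MAF bound, so the
  strict-inequality edge case is always exercised. A configurable slice
  is common only in gnomAD, separating database lists that do and do
  not include it.
* **FFPE deamination artifacts** (C>T / G>A) at low VAF. High-quality
  FFPE places almost all artifact VAF mass below 10%; low-quality FFPE
  has a heavier tail above 10%, so its sweep plateaus later or never.
  Frozen samples receive no deamination artifacts.
* **Run-recurrent artifacts** injected into more than the recurrence
  threshold's fraction of samples within a sequencing run.

Coordinates live on a single pseudo-contig because filtering never
consults a reference sequence. Depths are drawn high enough that the
coverage filter is inert unless ``low_depth_fraction`` is raised.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CurationFeatures
from .filters import Preservation, RunContext, build_run_context
from .tmb import MsiStatus, PoleStatus, QCMetrics, SampleMeta, TMBResult
from .variants import (
    AnnotatedVariant,
    Annotator,
    Caller,
    Consequence,
    FunctionalAnnotation,
    RegionClass,
    VariantCall,
    VariantKey,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SampleTruth",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_curation_features",
    "evaluate_against_truth",
]

#: Consequence-class mixture keys; "noncoding" stands for any region
#: outside exonic/splicing.
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "synonymous": 0.22,
    "missense": 0.48,
    "nonsense": 0.05,
    "frameshift_indel": 0.06,
    "inframe_indel": 0.03,
    "splice_site": 0.04,
    "noncoding": 0.12,
}

#: Classes counted by the stricter (non-synonymous coding) policy.
COUNTABLE_CLASSES = ("missense", "nonsense", "frameshift_indel", "inframe_indel")

_TUMOR_TYPES = (
    "breast", "colorectal", "sarcoma", "ovarian", "CNS", "lung",
    "endometrial", "lymphoma",
)

_RECURRENT_POSITION_BLOCK = 10_000  # reserved low positions, per-run spaced


@dataclass
class SimConfig:
    """Generative parameters of one synthetic cohort.

    The defaults describe a routine mixed FFPE/frozen panel cohort:
    ~8 countable somatic mutations per Mb on a 1.6 Mb footprint, clonal
    somatic VAFs (Beta(6,10) truncated below 12%, i.e. adequate tumor
    purity), ~30 leaked germline polymorphisms per sample of which 85%
    are common enough to be removed by database MAF, 25 deamination
    artifacts per Mb on high-quality FFPE with VAF ~ Beta(1.5, 28)
    (mass concentrated below 10%), and three systematic artifact sites
    per sequencing run recurring in 30% of its samples.
    """

    seed: int = 0
    n_samples: int = 32
    ffpe_fraction: float = 0.5
    samples_per_run: int = 16
    panel_size_mb: float = 1.6
    caller: Caller = Caller.VARSCAN2
    annotator: Annotator = Annotator.ANNOVAR

    # somatic content
    somatic_density_mean: float = 8.0  # countable variants per Mb
    somatic_density_sigma: float = 0.4  # lognormal spread across samples
    class_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    somatic_vaf_beta: tuple[float, float] = (6.0, 10.0)
    somatic_vaf_min: float = 0.12  # truncation; keeps true clones above cutoffs
    cosmic_hit_rate: float = 0.05  # fraction of countable somatic in COSMIC

    # hypermutator labels
    msi_fraction: float = 0.0
    msi_density_multiplier: float = 5.0
    pole_fraction: float = 0.0
    pole_density_multiplier: float = 8.0
    #: hypermutators whose routine MSI/POLE status reads MSS/WT but whose
    #: curation evidence (MSIsensor score, MMR variants, signatures) is
    #: positive — the cases biological curation exists to reclassify
    hidden_msi_fraction: float = 0.0

    # germline leakage
    germline_leak_rate: float = 30.0  # expected per sample
    germline_common_fraction: float = 0.85  # AF above the 0.1% bound
    germline_gnomad_only_fraction: float = 0.15  # of common: AF high only in gnomAD
    germline_boundary_fraction: float = 0.25  # of rare: AF exactly 0.001

    # FFPE deamination artifacts
    ffpe_artifact_rate_high: float = 25.0  # per Mb, high-quality FFPE
    ffpe_artifact_rate_low: float = 120.0  # per Mb, low-quality FFPE
    artifact_vaf_beta_high: tuple[float, float] = (1.5, 28.0)
    artifact_vaf_beta_low: tuple[float, float] = (1.5, 9.0)
    ffpe_low_quality_fraction: float = 0.0
    artifact_nonpass_fraction: float = 0.3  # artifacts lacking the caller PASS tag

    # run-recurrent artifacts
    recurrent_sites_per_run: int = 3
    recurrent_sample_fraction: float = 0.30
    recurrent_vaf_range: tuple[float, float] = (0.06, 0.25)

    # depth / QC
    depth_median: float = 1500.0
    depth_sigma: float = 0.35
    low_depth_fraction: float = 0.0  # records drawn below the 100X bound
    qc_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.caller = Caller(self.caller)
        self.annotator = Annotator(self.annotator)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.samples_per_run < 1:
            raise ValueError("samples_per_run must be >= 1")
        if not 0.0 <= self.ffpe_fraction <= 1.0:
            raise ValueError("ffpe_fraction out of [0,1]")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mixture must sum to 1, got {total}")
        unknown = set(self.class_mixture) - set(DEFAULT_CLASS_MIXTURE)
        if unknown:
            raise ValueError(f"unknown class_mixture keys: {sorted(unknown)}")
        for name in (
            "somatic_density_mean", "germline_leak_rate",
            "ffpe_artifact_rate_high", "ffpe_artifact_rate_low",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.recurrent_sites_per_run > 0 and not (
            0.0 < self.recurrent_sample_fraction <= 1.0
        ):
            raise ValueError("recurrent_sample_fraction out of (0,1]")
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["caller"] = self.caller.value
        d["annotator"] = self.annotator.value
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for k, v in list(data.items()):
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls(**data)


@dataclass
class SampleTruth:
    """True composition of one synthetic sample."""

    somatic: list[tuple[VariantKey, str]]  # (key, class label)
    germline: list[tuple[VariantKey, dict[str, float]]]  # (key, true AFs)
    artifacts: list[tuple[VariantKey, str]]  # (key, mechanism)
    true_countable: int  # somatic variants of a countable class
    true_density: float  # true_countable / panel_size_mb
    hypermutator: str = "none"  # none | msi | pole | hidden_msi

    def label_of(self, key: VariantKey) -> str:
        for k, _ in self.somatic:
            if k == key:
                return "somatic"
        for k, _ in self.germline:
            if k == key:
                return "germline"
        for k, mech in self.artifacts:
            if k == key:
                return mech
        raise KeyError(key)


@dataclass
class GroundTruth:
    samples: dict[str, SampleTruth]
    labels: dict[tuple[str, VariantKey], str]  # (sample_id, key) -> label


@dataclass
class SimulatedCohort:
    config: SimConfig
    variants: dict[str, list[AnnotatedVariant]]
    metas: dict[str, SampleMeta]
    qc: dict[str, QCMetrics]
    runs: dict[str, RunContext]
    truth: GroundTruth

    def run_of(self, sample_id: str) -> RunContext:
        return self.runs[self.metas[sample_id].run_id]


def _draw_class(rng: np.random.Generator, mixture: Mapping[str, float]) -> str:
    names = list(mixture)
    return names[rng.choice(len(names), p=np.array([mixture[n] for n in names]))]


def _class_to_annotation(label: str) -> tuple[RegionClass, Consequence]:
    if label == "noncoding":
        return RegionClass.INTRONIC, Consequence.UNKNOWN
    if label == "splice_site":
        return RegionClass.SPLICING, Consequence.SPLICE_SITE
    return RegionClass.EXONIC, Consequence(label)


_BASES = np.array(list("ACGT"))


def _alleles(rng: np.random.Generator, label: str) -> tuple[str, str]:
    if label == "frameshift_indel":
        ref = str(rng.choice(_BASES))
        if rng.random() < 0.5:
            return ref, ref + "".join(rng.choice(_BASES, 1))
        return ref + "".join(rng.choice(_BASES, 2)), ref
    if label == "inframe_indel":
        ref = str(rng.choice(_BASES))
        return ref, ref + "".join(rng.choice(_BASES, 3))
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice(_BASES[_BASES != ref]))
    return ref, alt


def _depth(rng: np.random.Generator, cfg: SimConfig) -> int:
    if cfg.low_depth_fraction > 0 and rng.random() < cfg.low_depth_fraction:
        return int(rng.integers(20, 100))
    d = rng.lognormal(math.log(cfg.depth_median), cfg.depth_sigma)
    return int(min(max(d, 150), 100_000))


def _beta_trunc(
    rng: np.random.Generator, a: float, b: float, lo: float = 0.0, hi: float = 1.0
) -> float:
    for _ in range(1000):
        v = rng.beta(a, b)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(rng.beta(a, b), lo), hi))


def _germline_afs(rng: np.random.Generator, cfg: SimConfig) -> dict[str, float]:
    """Two-point AF mixture around the 0.1% bound, over the three
    standard databases."""
    dbs = ("1000g", "exac", "gnomad")
    if rng.random() < cfg.germline_common_fraction:
        af = float(np.exp(rng.uniform(math.log(0.002), math.log(0.5))))
        af = round(af, 6)
        if rng.random() < cfg.germline_gnomad_only_fraction:
            # common in gnomAD only: removed by lists that include it
            out = {"gnomad": af}
            if rng.random() < 0.5:
                out["1000g"] = round(float(rng.uniform(1e-5, 9e-4)), 6)
            return out
        return {db: af for db in dbs if rng.random() < 0.9} or {"1000g": af}
    if rng.random() < cfg.germline_boundary_fraction:
        af = 0.001  # exactly at the strict bound: must be kept
    else:
        af = round(float(rng.uniform(1e-5, 9e-4)), 6)
    return {db: af for db in dbs if rng.random() < 0.7}


def simulate_cohort(
    config: SimConfig, out_dir: Optional[str | Path] = None
) -> SimulatedCohort:
    """Generate a cohort; deterministic given the config (incl. seed).

    When ``out_dir`` is given, also writes one VCF per sample, a
    ``metadata.tsv`` manifest (with QC metrics), a ``truth.tsv`` label
    table and a ``sim_config.yaml`` echo of the parameters.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    panel_bp = int(cfg.panel_size_mb * 1e6)
    if panel_bp <= _RECURRENT_POSITION_BLOCK * 2:
        raise ValueError("panel too small for position layout")

    n_runs = math.ceil(cfg.n_samples / cfg.samples_per_run)
    sample_ids = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    run_ids = [f"run{r + 1}" for r in range(n_runs)]
    run_of = {
        sid: run_ids[i // cfg.samples_per_run] for i, sid in enumerate(sample_ids)
    }

    n_ffpe = int(round(cfg.ffpe_fraction * cfg.n_samples))
    preservations = [Preservation.FFPE] * n_ffpe + [Preservation.FROZEN] * (
        cfg.n_samples - n_ffpe
    )
    rng.shuffle(preservations)

    # plan run-recurrent artifact sites
    recurrent_plan: dict[str, list[tuple[VariantKey, float]]] = {s: [] for s in sample_ids}
    for r_idx, run_id in enumerate(run_ids):
        members = [s for s in sample_ids if run_of[s] == run_id]
        for j in range(cfg.recurrent_sites_per_run):
            pos = 1 + r_idx * (_RECURRENT_POSITION_BLOCK // max(n_runs, 1)) + j * 17
            key = VariantKey("1", pos, "C", "T")
            n_carriers = max(
                2, math.ceil(cfg.recurrent_sample_fraction * len(members))
            ) if len(members) > 1 else 1
            n_carriers = min(n_carriers, len(members))
            carriers = rng.choice(len(members), size=n_carriers, replace=False)
            vaf = round(float(rng.uniform(*cfg.recurrent_vaf_range)), 6)
            for c in carriers:
                recurrent_plan[members[c]].append((key, vaf))

    variants: dict[str, list[AnnotatedVariant]] = {}
    metas: dict[str, SampleMeta] = {}
    qc: dict[str, QCMetrics] = {}
    truths: dict[str, SampleTruth] = {}
    labels: dict[tuple[str, VariantKey], str] = {}
    countable_share = sum(cfg.class_mixture.get(c, 0.0) for c in COUNTABLE_CLASSES)
    if countable_share <= 0:
        raise ValueError("class_mixture has no countable mass")

    for sid, pres in zip(sample_ids, preservations):
        is_msi = rng.random() < cfg.msi_fraction
        is_pole = (not is_msi) and rng.random() < cfg.pole_fraction
        is_hidden_msi = (
            not is_msi and not is_pole and rng.random() < cfg.hidden_msi_fraction
        )
        dna_quality = None
        if pres is Preservation.FFPE:
            dna_quality = (
                "low" if rng.random() < cfg.ffpe_low_quality_fraction else "high"
            )

        density = cfg.somatic_density_mean * float(
            rng.lognormal(-0.5 * cfg.somatic_density_sigma**2, cfg.somatic_density_sigma)
        )
        if is_msi or is_hidden_msi:
            density *= cfg.msi_density_multiplier
        elif is_pole:
            density *= cfg.pole_density_multiplier
        n_somatic = int(rng.poisson(density * cfg.panel_size_mb / countable_share))
        n_germline = int(rng.poisson(cfg.germline_leak_rate))
        if pres is Preservation.FFPE:
            rate = (
                cfg.ffpe_artifact_rate_low
                if dna_quality == "low"
                else cfg.ffpe_artifact_rate_high
            )
            n_artifact = int(rng.poisson(rate * cfg.panel_size_mb))
            beta = (
                cfg.artifact_vaf_beta_low
                if dna_quality == "low"
                else cfg.artifact_vaf_beta_high
            )
        else:
            n_artifact, beta = 0, cfg.artifact_vaf_beta_high

        n_private = n_somatic + n_germline + n_artifact
        positions = rng.choice(
            panel_bp - _RECURRENT_POSITION_BLOCK, size=n_private, replace=False
        ) + _RECURRENT_POSITION_BLOCK + 1
        pos_iter = iter(int(p) for p in positions)

        recs: list[AnnotatedVariant] = []
        somatic_truth: list[tuple[VariantKey, str]] = []
        germline_truth: list[tuple[VariantKey, dict[str, float]]] = []
        artifact_truth: list[tuple[VariantKey, str]] = []

        a, b = cfg.somatic_vaf_beta
        for _ in range(n_somatic):
            label = _draw_class(rng, cfg.class_mixture)
            region, cons = _class_to_annotation(label)
            ref, alt = _alleles(rng, label)
            key = VariantKey("1", next(pos_iter), ref, alt)
            vaf = round(_beta_trunc(rng, a, b, lo=cfg.somatic_vaf_min), 6)
            cosmic = label in COUNTABLE_CLASSES and rng.random() < cfg.cosmic_hit_rate
            recs.append(
                AnnotatedVariant(
                    call=VariantCall(
                        key=key, vaf=vaf, depth=_depth(rng, cfg),
                        caller=cfg.caller, pass_flag=True, sample_id=sid,
                    ),
                    annotation=FunctionalAnnotation(
                        region_class=region, consequence=cons,
                        gene=f"GENE{rng.integers(1, 600)}",
                        cosmic_hit=cosmic, annotator=cfg.annotator,
                    ),
                )
            )
            somatic_truth.append((key, label))

        for _ in range(n_germline):
            label = _draw_class(rng, cfg.class_mixture)
            region, cons = _class_to_annotation(label)
            ref, alt = _alleles(rng, label)
            key = VariantKey("1", next(pos_iter), ref, alt)
            afs = _germline_afs(rng, cfg)
            vaf = 1.0 if rng.random() < 0.1 else round(
                float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7)), 6
            )
            recs.append(
                AnnotatedVariant(
                    call=VariantCall(
                        key=key, vaf=vaf, depth=_depth(rng, cfg),
                        caller=cfg.caller, pass_flag=True, sample_id=sid,
                    ),
                    annotation=FunctionalAnnotation(
                        region_class=region, consequence=cons,
                        gene=f"GENE{rng.integers(1, 600)}",
                        population_afs=afs, annotator=cfg.annotator,
                    ),
                )
            )
            germline_truth.append((key, afs))

        aa, ab = beta
        for _ in range(n_artifact):
            label = _draw_class(rng, cfg.class_mixture)
            region, cons = _class_to_annotation(label)
            # deamination: C>T (or G>A on the reverse strand)
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
            key = VariantKey("1", next(pos_iter), ref, alt)
            vaf = round(max(_beta_trunc(rng, aa, ab), 0.005), 6)
            pass_flag = rng.random() >= cfg.artifact_nonpass_fraction
            recs.append(
                AnnotatedVariant(
                    call=VariantCall(
                        key=key, vaf=vaf, depth=_depth(rng, cfg),
                        caller=cfg.caller, pass_flag=pass_flag, sample_id=sid,
                    ),
                    annotation=FunctionalAnnotation(
                        region_class=region, consequence=cons,
                        gene=f"GENE{rng.integers(1, 600)}",
                        annotator=cfg.annotator,
                    ),
                )
            )
            artifact_truth.append((key, "artifact_ffpe"))

        for key, vaf in recurrent_plan[sid]:
            recs.append(
                AnnotatedVariant(
                    call=VariantCall(
                        key=key, vaf=vaf, depth=_depth(rng, cfg),
                        caller=cfg.caller, pass_flag=True, sample_id=sid,
                    ),
                    annotation=FunctionalAnnotation(
                        region_class=RegionClass.EXONIC,
                        consequence=Consequence.MISSENSE,
                        gene="GENE999", annotator=cfg.annotator,
                    ),
                )
            )
            artifact_truth.append((key, "artifact_recurrent"))

        n_countable = sum(1 for _, lab in somatic_truth if lab in COUNTABLE_CLASSES)
        truths[sid] = SampleTruth(
            somatic=somatic_truth,
            germline=germline_truth,
            artifacts=artifact_truth,
            true_countable=n_countable,
            true_density=n_countable / cfg.panel_size_mb,
            hypermutator=(
                "msi" if is_msi else "pole" if is_pole
                else "hidden_msi" if is_hidden_msi else "none"
            ),
        )
        for k, _ in somatic_truth:
            labels[(sid, k)] = "somatic"
        for k, _ in germline_truth:
            labels[(sid, k)] = "germline"
        for k, mech in artifact_truth:
            labels[(sid, k)] = mech

        variants[sid] = recs
        metas[sid] = SampleMeta(
            sample_id=sid,
            preservation=pres,
            run_id=run_of[sid],
            tumor_type=str(rng.choice(_TUMOR_TYPES)),
            msi_status=MsiStatus.MSI if is_msi else MsiStatus.MSS,
            pole_status=PoleStatus.MUTATED if is_pole else PoleStatus.WT,
            dna_quality=dna_quality,
        )
        if rng.random() < cfg.qc_fail_fraction:
            if rng.random() < 0.5:
                m = QCMetrics(int(rng.uniform(5e6, 1.9e7)), round(float(rng.uniform(0.4, 0.9)), 4))
            else:
                m = QCMetrics(int(rng.uniform(3e7, 9e7)), round(float(rng.uniform(0.01, 0.14)), 4))
        else:
            m = QCMetrics(int(rng.uniform(3e7, 9e7)), round(float(rng.uniform(0.4, 0.95)), 4))
        qc[sid] = m

    runs = {
        run_id: build_run_context(
            run_id, {s: variants[s] for s in sample_ids if run_of[s] == run_id}
        )
        for run_id in run_ids
    }

    cohort = SimulatedCohort(
        config=cfg, variants=variants, metas=metas, qc=qc, runs=runs,
        truth=GroundTruth(samples=truths, labels=labels),
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SimulatedCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_dir = out_dir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    meta_rows = []
    for sid, recs in cohort.variants.items():
        path = vcf_dir / f"{sid}.vcf"
        if recs:
            write_vcf(recs, path, annotator=cohort.config.annotator)
        else:
            path.write_text("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        m, q = cohort.metas[sid], cohort.qc[sid]
        meta_rows.append(
            {
                "sample_id": sid,
                "vcf": str(path.relative_to(out_dir)),
                "caller": cohort.config.caller.value,
                "annotator": cohort.config.annotator.value,
                "preservation": m.preservation.value,
                "run_id": m.run_id,
                "tumor_type": m.tumor_type,
                "msi_status": m.msi_status.value,
                "pole_status": m.pole_status.value,
                "dna_quality": m.dna_quality or "",
                "total_reads": q.total_reads,
                "frac_captured_ge_1000x": q.frac_captured_ge_1000x,
            }
        )
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    truth_rows = []
    for sid, st in cohort.truth.samples.items():
        for key, label in st.somatic:
            truth_rows.append((sid, key, "somatic", label))
        for key, afs in st.germline:
            truth_rows.append((sid, key, "germline", ";".join(f"{d}={a}" for d, a in afs.items())))
        for key, mech in st.artifacts:
            truth_rows.append((sid, key, mech, ""))
    pd.DataFrame(
        [
            {
                "sample_id": sid, "chrom": k.chrom, "pos": k.pos,
                "ref": k.ref, "alt": k.alt, "label": lab, "detail": det,
            }
            for sid, k, lab, det in truth_rows
        ]
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    cohort.config.to_yaml(out_dir / "sim_config.yaml")


def simulate_curation_features(
    cohort: SimulatedCohort, seed_offset: int = 1
) -> dict[str, CurationFeatures]:
    """Curation evidence consistent with the cohort's hypermutator labels.

    MSI samples — including hidden hypermutators whose routine status
    reads MSS — receive an MSIsensor score above 10% and usually a
    pathogenic mismatch-repair variant and MSI signature; POLE-mutated
    samples a proofreading-domain call; a small slice of the rest carry
    an APOBEC signature or a pathogenic DNA-damage-repair candidate hit.
    """
    rng = np.random.default_rng(cohort.config.seed + seed_offset)
    out: dict[str, CurationFeatures] = {}
    for sid, meta in cohort.metas.items():
        hyper = cohort.truth.samples[sid].hypermutator
        if meta.msi_status is MsiStatus.MSI or hyper == "hidden_msi":
            feats = CurationFeatures(
                sample_id=sid,
                msi_sensor_score=round(float(rng.uniform(12, 40)), 2),
                mmr_pathogenic_variant=bool(rng.random() < 0.7),
                msi_signature=bool(rng.random() < 0.8),
            )
        elif meta.pole_status is PoleStatus.MUTATED:
            feats = CurationFeatures(
                sample_id=sid,
                msi_sensor_score=round(float(rng.uniform(0, 5)), 2),
                pole_proofreading_mut=True,
            )
        else:
            hits: list[tuple[str, float, bool]] = []
            if rng.random() < 0.3:
                hits.append(
                    ("TP53", round(float(rng.uniform(0.15, 0.6)), 3), True)
                )
            if rng.random() < 0.1:
                hits.append(("PTEN", round(float(rng.uniform(0.02, 0.09)), 3), True))
            feats = CurationFeatures(
                sample_id=sid,
                msi_sensor_score=round(float(rng.uniform(0, 5)), 2),
                apobec_signature=bool(rng.random() < 0.08),
                ddr_candidate_hits=tuple(hits),
            )
        out[sid] = feats
    return out


def evaluate_against_truth(
    results: Sequence[TMBResult], truth: GroundTruth
) -> pd.DataFrame:
    """Label-join retained variants with ground truth.

    Returns one row per sample: absolute TMB error against the true
    countable density, artifact leak-through count, germline
    leak-through count, and true-somatic loss (countable-class somatic
    variants that the filters removed).
    """
    rows = []
    for r in results:
        if r.sample_id not in truth.samples:
            raise KeyError(f"sample {r.sample_id!r} not present in ground truth")
        st = truth.samples[r.sample_id]
        retained_keys = {v.key for v in r.report.retained_variants()}
        countable_somatic = {
            k for k, lab in st.somatic if lab in COUNTABLE_CLASSES
        }
        artifact_keys = {k for k, _ in st.artifacts}
        germline_keys = {k for k, _ in st.germline}
        rows.append(
            {
                "sample_id": r.sample_id,
                "profile": r.profile_name,
                "tmb": r.tmb,
                "true_density": st.true_density,
                "abs_error": abs(r.tmb - st.true_density),
                "artifact_leak": len(retained_keys & artifact_keys),
                "germline_leak": len(retained_keys & germline_keys),
                "somatic_loss": len(countable_somatic - retained_keys),
            }
        )
    return pd.DataFrame(rows)
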