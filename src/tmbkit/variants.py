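"""Variant containers and VCF input/output.

Reads somatic VCFs produced by Mutect2 or VarScan2 and annotated with
either ANNOVAR or snpEff, and normalizes them into a single in-memory
representation (:class:`AnnotatedVariant`) that the filter engine consumes.

Conventions enforced here:

* VAF is always a fraction in [0, 1]; VarScan2's percent-string ``FREQ``
  is converted on read.
* Multi-allelic records are split into one record per alternate allele
  before anything downstream sees them.
* Chromosome labels are normalized by stripping a leading ``chr``.
* Population allele frequencies are rounded to 9 decimals to undo the
  float32 quantization htslib applies to Float INFO fields; the germline
  filter's strict comparison at the 0.1% bound depends on this.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "Caller",
    "Annotator",
    "RegionClass",
    "Consequence",
    "VariantKey",
    "VariantCall",
    "FunctionalAnnotation",
    "AnnotatedVariant",
    "AnnotationConfig",
    "VcfParseError",
    "parse_varscan_freq",
    "parse_annotation",
    "read_vcf",
    "write_vcf",
]


class Caller(str, Enum):
    MUTECT2 = "mutect2"
    VARSCAN2 = "varscan2"


class Annotator(str, Enum):
    ANNOVAR = "annovar"
    SNPEFF = "snpeff"


class RegionClass(str, Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    INTRONIC = "intronic"
    UTR = "UTR"
    INTERGENIC = "intergenic"
    OTHER_NONCODING = "other_noncoding"
    UNKNOWN = "unknown"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    UNKNOWN = "unknown"


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele at one site.

    Multi-allelic VCF records are split before keying, so ``alt`` is
    always a single allele. Used verbatim (no left-alignment) because
    intra-run recurrence matching operates within one pipeline's own
    output.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "," in self.alt:
            raise ValueError(f"alt must be a single allele, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r})")


@dataclass(frozen=True)
class VariantCall:
    key: VariantKey
    vaf: float
    depth: int
    caller: Caller
    pass_flag: bool
    sample_id: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")


@dataclass(frozen=True)
class FunctionalAnnotation:
    region_class: RegionClass = RegionClass.UNKNOWN
    consequence: Consequence = Consequence.UNKNOWN
    gene: str = ""
    population_afs: Mapping[str, float] = field(default_factory=dict)
    cosmic_hit: bool = False
    pathogenic_flag: Optional[bool] = None
    annotator: Annotator = Annotator.ANNOVAR

    def __post_init__(self) -> None:
        for db, af in self.population_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"population AF for {db} out of [0,1]: {af}")


@dataclass(frozen=True)
class AnnotatedVariant:
    call: VariantCall
    annotation: FunctionalAnnotation

    @property
    def key(self) -> VariantKey:
        return self.call.key


class VcfParseError(ValueError):
    pass


# --- annotation term tables (frozen) ---------------------------------------

#: ANNOVAR Func.refGene -> region class. Values not listed map to unknown.
ANNOVAR_REGION_TERMS: dict[str, RegionClass] = {
    "exonic": RegionClass.EXONIC,
    "exonic;splicing": RegionClass.SPLICING,
    "splicing": RegionClass.SPLICING,
    "intronic": RegionClass.INTRONIC,
    "UTR3": RegionClass.UTR,
    "UTR5": RegionClass.UTR,
    "UTR5;UTR3": RegionClass.UTR,
    "intergenic": RegionClass.INTERGENIC,
    "upstream": RegionClass.OTHER_NONCODING,
    "downstream": RegionClass.OTHER_NONCODING,
    "upstream;downstream": RegionClass.OTHER_NONCODING,
    "ncRNA_exonic": RegionClass.OTHER_NONCODING,
    "ncRNA_intronic": RegionClass.OTHER_NONCODING,
    "ncRNA_splicing": RegionClass.OTHER_NONCODING,
    "ncRNA_UTR3": RegionClass.OTHER_NONCODING,
    "ncRNA_UTR5": RegionClass.OTHER_NONCODING,
}

#: ANNOVAR ExonicFunc.refGene -> consequence (underscores or spaces accepted).
ANNOVAR_CONSEQUENCE_TERMS: dict[str, Consequence] = {
    "synonymous SNV": Consequence.SYNONYMOUS,
    "nonsynonymous SNV": Consequence.MISSENSE,
    "stopgain": Consequence.NONSENSE,
    "stoploss": Consequence.NONSENSE,
    "frameshift insertion": Consequence.FRAMESHIFT_INDEL,
    "frameshift deletion": Consequence.FRAMESHIFT_INDEL,
    "frameshift substitution": Consequence.FRAMESHIFT_INDEL,
    "nonframeshift insertion": Consequence.INFRAME_INDEL,
    "nonframeshift deletion": Consequence.INFRAME_INDEL,
    "nonframeshift substitution": Consequence.INFRAME_INDEL,
}

#: snpEff effect term -> (region class, consequence). First matching term
#: of the ANN annotation wins (snpEff orders by putative impact). Splice
#: donor/acceptor terms denote the 2 intronic bases flanking each exon,
#: matching the splice-site definition used by the filters.
SNPEFF_EFFECT_TERMS: dict[str, tuple[RegionClass, Consequence]] = {
    "synonymous_variant": (RegionClass.EXONIC, Consequence.SYNONYMOUS),
    "stop_retained_variant": (RegionClass.EXONIC, Consequence.SYNONYMOUS),
    "missense_variant": (RegionClass.EXONIC, Consequence.MISSENSE),
    "stop_gained": (RegionClass.EXONIC, Consequence.NONSENSE),
    "stop_lost": (RegionClass.EXONIC, Consequence.NONSENSE),
    "start_lost": (RegionClass.EXONIC, Consequence.NONSENSE),
    "frameshift_variant": (RegionClass.EXONIC, Consequence.FRAMESHIFT_INDEL),
    "inframe_insertion": (RegionClass.EXONIC, Consequence.INFRAME_INDEL),
    "inframe_deletion": (RegionClass.EXONIC, Consequence.INFRAME_INDEL),
    "disruptive_inframe_insertion": (RegionClass.EXONIC, Consequence.INFRAME_INDEL),
    "disruptive_inframe_deletion": (RegionClass.EXONIC, Consequence.INFRAME_INDEL),
    "splice_acceptor_variant": (RegionClass.SPLICING, Consequence.SPLICE_SITE),
    "splice_donor_variant": (RegionClass.SPLICING, Consequence.SPLICE_SITE),
    "splice_region_variant": (RegionClass.INTRONIC, Consequence.UNKNOWN),
    "intron_variant": (RegionClass.INTRONIC, Consequence.UNKNOWN),
    "5_prime_UTR_variant": (RegionClass.UTR, Consequence.UNKNOWN),
    "3_prime_UTR_variant": (RegionClass.UTR, Consequence.UNKNOWN),
    "5_prime_UTR_premature_start_codon_gain_variant": (RegionClass.UTR, Consequence.UNKNOWN),
    "intergenic_region": (RegionClass.INTERGENIC, Consequence.UNKNOWN),
    "upstream_gene_variant": (RegionClass.OTHER_NONCODING, Consequence.UNKNOWN),
    "downstream_gene_variant": (RegionClass.OTHER_NONCODING, Consequence.UNKNOWN),
    "non_coding_transcript_variant": (RegionClass.OTHER_NONCODING, Consequence.UNKNOWN),
    "non_coding_transcript_exon_variant": (RegionClass.OTHER_NONCODING, Consequence.UNKNOWN),
}


@dataclass(frozen=True)
class AnnotationConfig:
    """INFO key names used when parsing annotations.

    Defaults follow ANNOVAR's refGene output and its canonical database
    column names. ``population_af_keys`` maps an internal database name
    (the names the filter profiles refer to) onto the INFO key carrying
    its allele frequency; the same keys are looked up for snpEff-annotated
    files, where population frequencies come from companion INFO fields
    rather than the ANN block.
    """

    region_key: str = "Func.refGene"
    consequence_key: str = "ExonicFunc.refGene"
    gene_key: str = "Gene.refGene"
    population_af_keys: Mapping[str, str] = field(
        default_factory=lambda: {
            "1000g": "1000g2015aug_all",
            "exac": "ExAC_ALL",
            "gnomad": "gnomAD_genome_ALL",
        }
    )
    cosmic_key: str = "cosmic86"
    pathogenic_key: str = "CLNSIG"
    snpeff_ann_key: str = "ANN"


DEFAULT_ANNOTATION_CONFIG = AnnotationConfig()

_FREQ_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*%\s*$")


def parse_varscan_freq(freq_field: str) -> float:
    """Convert VarScan2's percent-string ``FREQ`` to a fraction in [0, 1].

    >>> parse_varscan_freq("12.5%")
    0.125
    """
    m = _FREQ_RE.match(freq_field)
    if not m:
        raise VcfParseError(f"unparsable VarScan2 FREQ field: {freq_field!r}")
    value = float(m.group(1)) / 100.0
    if not 0.0 <= value <= 1.0:
        raise VcfParseError(f"FREQ outside [0,100]%: {freq_field!r}")
    return value


def _scalar(value):
    """INFO values declared Number=A/./1 may arrive as 1-tuples."""
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _as_str(value) -> Optional[str]:
    v = _scalar(value)
    if v is None:
        return None
    if isinstance(v, bytes):
        v = v.decode()
    return str(v)


def parse_annotation(
    info: Mapping[str, object],
    annotator: Annotator,
    config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG,
    alt: Optional[str] = None,
) -> FunctionalAnnotation:
    """Normalize an ANNOVAR or snpEff INFO payload.

    Unmappable terms become ``unknown`` (never silently coding). A record
    with no annotation block at all is classified unknown/unknown; callers
    count these via the reader's warning counter.
    """
    annotator = Annotator(annotator)
    region = RegionClass.UNKNOWN
    consequence = Consequence.UNKNOWN
    gene = ""

    if annotator is Annotator.ANNOVAR:
        region_term = _as_str(info.get(config.region_key))
        if region_term is not None:
            region = ANNOVAR_REGION_TERMS.get(
                region_term.replace("\\x3b", ";"), RegionClass.UNKNOWN
            )
        cons_term = _as_str(info.get(config.consequence_key))
        if cons_term is not None and cons_term != ".":
            cons_term = cons_term.replace("_", " ").replace("\\x3b", ";")
            consequence = ANNOVAR_CONSEQUENCE_TERMS.get(cons_term, Consequence.UNKNOWN)
        # any variant in the splicing region (2 bp into the intron) is a
        # splice-site event regardless of the exonic-consequence column
        if region is RegionClass.SPLICING:
            consequence = Consequence.SPLICE_SITE
        gene = _as_str(info.get(config.gene_key)) or ""
    else:
        ann = info.get(config.snpeff_ann_key)
        entries: list[str] = []
        if ann is not None:
            if isinstance(ann, (tuple, list)):
                entries = [str(e) for e in ann]
            else:
                entries = str(ann).split(",")
        chosen = None
        for entry in entries:
            fields = entry.split("|")
            if alt is not None and fields and fields[0] not in ("", alt):
                continue
            chosen = fields
            break
        if chosen is None and entries:
            chosen = entries[0].split("|")
        if chosen and len(chosen) > 1:
            for term in chosen[1].split("&"):
                if term in SNPEFF_EFFECT_TERMS:
                    region, consequence = SNPEFF_EFFECT_TERMS[term]
                    break
            if len(chosen) > 3:
                gene = chosen[3]

    afs: dict[str, float] = {}
    for db, key in config.population_af_keys.items():
        raw = _scalar(info.get(key))
        if raw is None:
            continue
        if isinstance(raw, (bytes, str)):
            raw = _as_str(raw)
            if raw in (".", ""):
                continue
        try:
            af = round(float(raw), 9)  # undo float32 INFO quantization
        except (TypeError, ValueError):
            continue
        afs[db] = min(max(af, 0.0), 1.0)

    cosmic_raw = _as_str(info.get(config.cosmic_key))
    cosmic_hit = cosmic_raw is not None and cosmic_raw not in (".", "")

    patho_raw = _as_str(info.get(config.pathogenic_key))
    pathogenic: Optional[bool] = None
    if patho_raw is not None and patho_raw not in (".", ""):
        pathogenic = "pathogenic" in patho_raw.lower()

    return FunctionalAnnotation(
        region_class=region,
        consequence=consequence,
        gene=gene,
        population_afs=afs,
        cosmic_hit=cosmic_hit,
        pathogenic_flag=pathogenic,
        annotator=annotator,
    )


def _detect_annotator(header: pysam.VariantHeader, config: AnnotationConfig) -> Annotator:
    if config.snpeff_ann_key in header.info:
        return Annotator.SNPEFF
    return Annotator.ANNOVAR


def _mutect2_vaf_depth(sample, alt_index: int) -> tuple[float, int]:
    """VAF from AD (allele-specific, robust to multi-allelic splitting),
    falling back to the AF tag; depth from summed AD, falling back to DP."""
    ad = sample.get("AD")
    if ad is not None and not all(a is None for a in ad):
        ad = [a or 0 for a in ad]
        total = sum(ad)
        ref_alt = ad[0] + ad[alt_index]
        vaf = ad[alt_index] / ref_alt if ref_alt > 0 else 0.0
        return vaf, int(total)
    af = sample.get("AF")
    if isinstance(af, (tuple, list)):
        af = af[alt_index - 1] if len(af) >= alt_index else None
    dp = sample.get("DP")
    if af is None or dp is None:
        raise VcfParseError("Mutect2 record lacks both AD and AF/DP")
    return float(af), int(dp)


def _varscan_vaf_depth(sample) -> tuple[float, int]:
    freq = sample.get("FREQ")
    if freq is None:
        raise VcfParseError("VarScan2 record lacks FREQ")
    if isinstance(freq, (tuple, list)):
        freq = freq[0]
    if isinstance(freq, bytes):
        freq = freq.decode()
    vaf = parse_varscan_freq(str(freq))
    dp = sample.get("DP")
    if dp is None:
        raise VcfParseError("VarScan2 record lacks DP")
    return vaf, int(dp)


def read_vcf(
    path: str | Path,
    caller: Caller | str,
    tumor_sample: Optional[str] = None,
    annotator: Annotator | str | None = None,
    config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG,
    sample_id: Optional[str] = None,
) -> list[AnnotatedVariant]:
    """Read an annotated somatic VCF into a list of :class:`AnnotatedVariant`.

    Parameters
    ----------
    path
        VCF 4.2 file (plain or bgzipped).
    caller
        ``mutect2`` or ``varscan2``; selects the genotype-field dialect
        used to extract VAF and depth.
    tumor_sample
        Genotype column to read. May be omitted for single-sample VCFs;
        for multi-sample files it is mandatory and a missing name raises
        with the available columns listed.
    annotator
        ``annovar`` or ``snpeff``; auto-detected from the header
        (presence of the ANN INFO field) when omitted.
    sample_id
        Identifier stored on each record; defaults to the genotype
        column name.

    Records whose VAF/depth fields cannot be parsed are dropped and
    counted in a single warning; malformed files raise.
    """
    caller = Caller(caller)
    path = str(path)
    # ANNOVAR's canonical INFO keys (e.g. "1000g2015aug_all") are not
    # valid htslib tag names; suppress the harmless header warning.
    verbosity = pysam.set_verbosity(0)
    try:
        vcf = pysam.VariantFile(path)
    finally:
        pysam.set_verbosity(verbosity)
    samples = list(vcf.header.samples)
    if tumor_sample is None:
        if len(samples) == 1:
            tumor_sample = samples[0]
        else:
            raise VcfParseError(
                f"{path}: tumor_sample required for multi-sample VCF; "
                f"available columns: {samples}"
            )
    elif tumor_sample not in samples:
        raise VcfParseError(
            f"{path}: no genotype column {tumor_sample!r}; available: {samples}"
        )
    if annotator is None:
        ann = _detect_annotator(vcf.header, config)
    else:
        ann = Annotator(annotator)
    sid = sample_id if sample_id is not None else tumor_sample

    out: list[AnnotatedVariant] = []
    n_dropped = 0
    n_unannotated = 0
    for rec in vcf:
        sample = rec.samples[tumor_sample]
        pass_flag = list(rec.filter.keys()) == ["PASS"]
        alts = rec.alts or ()
        for i, alt in enumerate(alts):
            if alt is None or alt == rec.ref:
                continue
            try:
                if caller is Caller.VARSCAN2:
                    vaf, depth = _varscan_vaf_depth(sample)
                else:
                    vaf, depth = _mutect2_vaf_depth(sample, i + 1)
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                call = VariantCall(
                    key=key, vaf=vaf, depth=depth, caller=caller,
                    pass_flag=pass_flag, sample_id=sid,
                )
            except (VcfParseError, ValueError) as exc:
                logger.debug("%s:%s dropped: %s", rec.chrom, rec.pos, exc)
                n_dropped += 1
                continue
            annotation = parse_annotation(dict(rec.info), ann, config, alt=alt)
            if (
                annotation.region_class is RegionClass.UNKNOWN
                and annotation.consequence is Consequence.UNKNOWN
            ):
                n_unannotated += 1
            out.append(AnnotatedVariant(call=call, annotation=annotation))
    if n_dropped:
        logger.warning("%s: dropped %d unparsable record(s)", path, n_dropped)
    if n_unannotated:
        logger.warning(
            "%s: %d record(s) without a usable annotation block "
            "(classified unknown/unknown)", path, n_unannotated,
        )
    return out


# --- writing ----------------------------------------------------------------

_REGION_TO_ANNOVAR = {
    RegionClass.EXONIC: "exonic",
    RegionClass.SPLICING: "splicing",
    RegionClass.INTRONIC: "intronic",
    RegionClass.UTR: "UTR3",
    RegionClass.INTERGENIC: "intergenic",
    RegionClass.OTHER_NONCODING: "ncRNA_exonic",
    RegionClass.UNKNOWN: ".",
}

_CONSEQUENCE_TO_ANNOVAR = {
    Consequence.SYNONYMOUS: "synonymous_SNV",
    Consequence.MISSENSE: "nonsynonymous_SNV",
    Consequence.NONSENSE: "stopgain",
    Consequence.FRAMESHIFT_INDEL: "frameshift_insertion",
    Consequence.INFRAME_INDEL: "nonframeshift_insertion",
    Consequence.SPLICE_SITE: ".",
    Consequence.UNKNOWN: ".",
}

_TO_SNPEFF = {
    (RegionClass.EXONIC, Consequence.SYNONYMOUS): "synonymous_variant",
    (RegionClass.EXONIC, Consequence.MISSENSE): "missense_variant",
    (RegionClass.EXONIC, Consequence.NONSENSE): "stop_gained",
    (RegionClass.EXONIC, Consequence.FRAMESHIFT_INDEL): "frameshift_variant",
    (RegionClass.EXONIC, Consequence.INFRAME_INDEL): "inframe_insertion",
    (RegionClass.SPLICING, Consequence.SPLICE_SITE): "splice_donor_variant",
    (RegionClass.INTRONIC, Consequence.UNKNOWN): "intron_variant",
    (RegionClass.UTR, Consequence.UNKNOWN): "3_prime_UTR_variant",
    (RegionClass.INTERGENIC, Consequence.UNKNOWN): "intergenic_region",
    (RegionClass.OTHER_NONCODING, Consequence.UNKNOWN): "non_coding_transcript_exon_variant",
}


def _vcf_header_lines(
    caller: Caller, annotator: Annotator, config: AnnotationConfig, contig: str, sample: str
) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=tmbkit ({caller.value}/{annotator.value} dialect)",
        f"##contig=<ID={contig},length=250000000>",
        '##FILTER=<ID=artifact,Description="Failed caller quality filters">',
    ]
    if annotator is Annotator.ANNOVAR:
        lines += [
            f'##INFO=<ID={config.region_key},Number=1,Type=String,Description="Region class">',
            f'##INFO=<ID={config.consequence_key},Number=1,Type=String,Description="Exonic consequence">',
            f'##INFO=<ID={config.gene_key},Number=1,Type=String,Description="Gene symbol">',
        ]
    else:
        lines.append(
            f'##INFO=<ID={config.snpeff_ann_key},Number=.,Type=String,'
            'Description="Functional annotations: Allele|Annotation|Impact|Gene">'
        )
    for key in config.population_af_keys.values():
        lines.append(
            f'##INFO=<ID={key},Number=1,Type=Float,Description="Population allele frequency">'
        )
    lines += [
        f'##INFO=<ID={config.cosmic_key},Number=1,Type=String,Description="COSMIC id">',
        f'##INFO=<ID={config.pathogenic_key},Number=1,Type=String,Description="Clinical significance">',
    ]
    if caller is Caller.VARSCAN2:
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency (percent)">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ]
    else:
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        ]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    return lines


def _info_field(v: AnnotatedVariant, annotator: Annotator, config: AnnotationConfig) -> str:
    ann = v.annotation
    parts: list[str] = []
    if annotator is Annotator.ANNOVAR:
        parts.append(f"{config.region_key}={_REGION_TO_ANNOVAR[ann.region_class]}")
        parts.append(f"{config.consequence_key}={_CONSEQUENCE_TO_ANNOVAR[ann.consequence]}")
        if ann.gene:
            parts.append(f"{config.gene_key}={ann.gene}")
    else:
        effect = _TO_SNPEFF.get((ann.region_class, ann.consequence), "intergenic_region")
        impact = "MODERATE"
        parts.append(
            f"{config.snpeff_ann_key}={v.key.alt}|{effect}|{impact}|{ann.gene or '.'}"
        )
    for db, key in config.population_af_keys.items():
        if db in ann.population_afs:
            parts.append(f"{key}={ann.population_afs[db]:.9g}")
    if ann.cosmic_hit:
        parts.append(f"{config.cosmic_key}=COSM1")
    if ann.pathogenic_flag is not None:
        parts.append(
            f"{config.pathogenic_key}={'Pathogenic' if ann.pathogenic_flag else 'Benign'}"
        )
    return ";".join(parts) if parts else "."


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    annotator: Annotator | str | None = None,
    config: AnnotationConfig = DEFAULT_ANNOTATION_CONFIG,
) -> None:
    """Write records back to a plain-text VCF 4.2 file.

    The caller and annotator dialect of the output follow the records
    themselves (all records in one file must share a caller). Writing a
    parsed cohort and re-reading it reproduces the same records.
    """
    if not variants:
        raise ValueError("cannot write an empty VCF without records")
    caller = variants[0].call.caller
    if annotator is None:
        ann = variants[0].annotation.annotator
    else:
        ann = Annotator(annotator)
    sample = variants[0].call.sample_id
    contig = variants[0].key.chrom
    lines = _vcf_header_lines(caller, ann, config, contig, sample)
    for v in sorted(variants, key=lambda x: (x.key.chrom, x.key.pos, x.key.alt)):
        filt = "PASS" if v.call.pass_flag else "artifact"
        info = _info_field(v, ann, config)
        if caller is Caller.VARSCAN2:
            fmt = "GT:FREQ:DP"
            gt = f"0/1:{v.call.vaf * 100:.6g}%:{v.call.depth}"
        else:
            alt_reads = int(round(v.call.vaf * v.call.depth))
            ref_reads = v.call.depth - alt_reads
            fmt = "GT:AD:DP:AF"
            gt = f"0/1:{ref_reads},{alt_reads}:{v.call.depth}:{v.call.vaf:.6g}"
        lines.append(
            f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}\t.\t{filt}\t{info}\t{fmt}\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
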