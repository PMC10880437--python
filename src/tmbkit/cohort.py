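"""Cohort-level summaries and biological curation of TMB-high cases.

Summaries mirror routine molecular-tumor-board reporting: per-tumor-type
medians and observed ranges, TMB histogram bins, and the top-decile
threshold used to flag TMB-high cases among microsatellite-stable,
POLE-wild-type tumors.

The curation engine reclassifies a flagged TMB-high sample as a true
hypermutator when any of the mismatch-repair / polymerase evidence lines
fires, otherwise looks for pathogenic variants (allelic ratio >= 10%) in
three DNA-damage-repair candidate genes (TP53, PTEN, ARID1A), and
otherwise leaves the elevation unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tmb import MsiStatus, PoleStatus, SampleMeta, TMBResult
from .filters import Preservation

__all__ = [
    "DEFAULT_BIN_EDGES",
    "DDR_CANDIDATE_GENES",
    "CurationCategory",
    "CurationFeatures",
    "CurationVerdict",
    "build_cohort_table",
    "summarize_by_type",
    "bin_counts",
    "top_decile_threshold",
    "curate_high_tmb",
]

#: Default TMB bins: [0,10], (10,30], (30,100], (100, inf). The low bin is
#: closed at 10 so "between 0 and 10 mut/Mb" counts a score of exactly 10.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 10.0, 30.0, 100.0)

DDR_CANDIDATE_GENES = ("TP53", "PTEN", "ARID1A")

MSI_SENSOR_SCORE_BOUND = 10.0  # percent, inclusive
DDR_MIN_ALLELIC_RATIO = 0.10  # fraction, inclusive


class CurationCategory(str, Enum):
    RECLASSIFIED_MSI_POLE = "reclassified_msi_pole"  # "true TMB high"
    DDR_CANDIDATE_EXPLAINED = "ddr_candidate_explained"
    UNEXPLAINED = "unexplained"


@dataclass(frozen=True)
class CurationFeatures:
    """Precomputed evidence for one TMB-high sample.

    Upstream tools supply these: MSIsensor score (percent of unstable
    microsatellites), pathogenic mismatch-repair gene calls, signature
    flags from mutational-signature fitting, and per-gene hits in the
    DNA-damage-repair candidate genes as (gene, vaf, pathogenic) tuples.
    Absent evidence is encoded as False / 0.
    """

    sample_id: str
    msi_sensor_score: float = 0.0
    mmr_pathogenic_variant: bool = False
    msi_signature: bool = False
    pole_proofreading_mut: bool = False
    apobec_signature: bool = False
    ddr_candidate_hits: tuple[tuple[str, float, bool], ...] = ()

    def __post_init__(self) -> None:
        if self.msi_sensor_score < 0:
            raise ValueError("msi_sensor_score must be >= 0")
        for gene, vaf, _ in self.ddr_candidate_hits:
            if gene not in DDR_CANDIDATE_GENES:
                raise ValueError(
                    f"{gene!r} is not a DDR candidate gene {DDR_CANDIDATE_GENES}"
                )
            if not 0.0 <= vaf <= 1.0:
                raise ValueError(f"ddr hit vaf out of [0,1]: {vaf}")


@dataclass(frozen=True)
class CurationVerdict:
    sample_id: str
    category: CurationCategory
    triggering_evidence: tuple[str, ...]


def build_cohort_table(
    metas: dict[str, SampleMeta],
    results: Sequence[TMBResult],
    contributive: Optional[dict[str, bool]] = None,
    include_noncontributive: bool = False,
) -> pd.DataFrame:
    """One row per sample for one profile, joining metadata and scores.

    Non-contributive samples (failed QC gate) are excluded unless
    explicitly requested.
    """
    rows = []
    for r in results:
        m = metas[r.sample_id]
        ok = True if contributive is None else contributive.get(r.sample_id, True)
        if not ok and not include_noncontributive:
            continue
        rows.append(
            {
                "sample_id": r.sample_id,
                "tumor_type": m.tumor_type,
                "preservation": m.preservation.value,
                "msi_status": m.msi_status.value,
                "pole_status": m.pole_status.value,
                "profile": r.profile_name,
                "n_retained": r.n_retained,
                "tmb": r.tmb,
                "contributive": ok,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and df.duplicated(["sample_id", "profile"]).any():
        raise ValueError("cohort table has duplicate (sample, profile) rows")
    return df


def _stratify(
    cohort: pd.DataFrame,
    msi_status: Optional[str] = None,
    pole_status: Optional[str] = None,
    preservation: Optional[str] = None,
) -> pd.DataFrame:
    df = cohort
    if msi_status is not None:
        df = df[df["msi_status"] == MsiStatus(msi_status).value]
    if pole_status is not None:
        df = df[df["pole_status"] == PoleStatus(pole_status).value]
    if preservation is not None:
        df = df[df["preservation"] == Preservation(preservation).value]
    return df


def summarize_by_type(
    cohort: pd.DataFrame,
    msi_status: Optional[str] = None,
    pole_status: Optional[str] = None,
    preservation: Optional[str] = None,
) -> pd.DataFrame:
    """Per-tumor-type n, median and observed min–max of TMB, optionally
    restricted to an MSI/POLE/preservation stratum. An empty stratum
    yields an empty summary."""
    df = _stratify(cohort, msi_status, pole_status, preservation)
    if df.empty:
        return pd.DataFrame(columns=["tumor_type", "n", "median_tmb", "min_tmb", "max_tmb"])
    g = df.groupby("tumor_type")["tmb"]
    out = pd.DataFrame(
        {
            "n": g.size(),
            "median_tmb": g.median(),
            "min_tmb": g.min(),
            "max_tmb": g.max(),
        }
    ).reset_index()
    return out.sort_values("median_tmb", ascending=False).reset_index(drop=True)


def bin_counts(
    cohort: pd.DataFrame, edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """TMB histogram per preservation over right-closed bins.

    With edges ``(e0, e1, ..., ek)`` the bins are ``[e0, e1]``,
    ``(e1, e2]``, ..., ``(ek, inf)``; counts partition the cohort.
    """
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    labels = (
        [f"[{edges[0]:g},{edges[1]:g}]"]
        + [f"({a:g},{b:g}]" for a, b in zip(edges[1:], edges[2:])]
        + [f"({edges[-1]:g},inf)"]
    )

    def _bin(t: float) -> str:
        if t <= edges[1]:
            return labels[0]
        for i, (a, b) in enumerate(zip(edges[1:], edges[2:])):
            if a < t <= b:
                return labels[i + 1]
        return labels[-1]

    rows = []
    preservations = sorted(cohort["preservation"].unique()) if not cohort.empty else []
    for pres in preservations:
        sub = cohort[cohort["preservation"] == pres]
        counts = {lab: 0 for lab in labels}
        for t in sub["tmb"]:
            counts[_bin(float(t))] += 1
        for lab in labels:
            rows.append({"preservation": pres, "bin": lab, "count": counts[lab]})
    if not rows:
        rows = [{"preservation": p, "bin": lab, "count": 0}
                for p in ("FFPE", "frozen") for lab in labels]
    return pd.DataFrame(rows)


def top_decile_threshold(values: Sequence[float]) -> float:
    """90th percentile (linear interpolation between order statistics);
    samples strictly above it form the top-decile TMB-high set."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 10:
        raise ValueError(
            f"need at least 10 values for a top-decile threshold, got {values.size}"
        )
    return float(np.percentile(values, 90))


def curate_high_tmb(features: CurationFeatures) -> CurationVerdict:
    """Classify one TMB-high sample from its curation evidence.

    Rules, in order:

    1. *reclassified_msi_pole* — MSIsensor score >= 10%, or a pathogenic
       mismatch-repair gene variant, or an MSI mutational signature, or a
       POLE proofreading-domain mutation, or an APOBEC signature. These
       are true hypermutators ("true TMB high").
    2. *ddr_candidate_explained* — otherwise, any pathogenic hit in
       TP53/PTEN/ARID1A with allelic ratio >= 10%.
    3. *unexplained* — otherwise.

    Every satisfied clause is listed as triggering evidence.
    """
    evidence: list[str] = []
    if features.msi_sensor_score >= MSI_SENSOR_SCORE_BOUND:
        evidence.append("msi_sensor_score>=10")
    if features.mmr_pathogenic_variant:
        evidence.append("mmr_pathogenic_variant")
    if features.msi_signature:
        evidence.append("msi_signature")
    if features.pole_proofreading_mut:
        evidence.append("pole_proofreading_mut")
    if features.apobec_signature:
        evidence.append("apobec_signature")
    if evidence:
        return CurationVerdict(
            features.sample_id, CurationCategory.RECLASSIFIED_MSI_POLE, tuple(evidence)
        )
    ddr = [
        f"ddr:{gene}"
        for gene, vaf, pathogenic in features.ddr_candidate_hits
        if pathogenic and vaf >= DDR_MIN_ALLELIC_RATIO
    ]
    if ddr:
        return CurationVerdict(
            features.sample_id, CurationCategory.DDR_CANDIDATE_EXPLAINED, tuple(ddr)
        )
    return CurationVerdict(features.sample_id, CurationCategory.UNEXPLAINED, ())
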