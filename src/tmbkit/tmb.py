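"""Sample QC gating, the TMB score, and VAF-sweep curves.

TMB is the count of variants retained by a filter profile divided by the
panel footprint in megabases (1.6 Mb for the built-in profiles). A
sample is *contributive* when it clears the sequencing-quality gate:
at least 20 million reads and at least 15% of the captured regions
covered above 1000X (the gate fails on the strict "<" side, so boundary
values pass).

The VAF sweep recomputes TMB over a grid of minimum-VAF cutoffs, holding
every other filter fixed. Because raising the cutoff can only shrink the
retained set, the curve is non-increasing; the cutoff where it flattens
(the plateau) is where low-VAF artifact mass has been exhausted and
likely reflects the true burden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .filters import (
    FilterProfile,
    FilterReport,
    Preservation,
    RunContext,
    apply_profile,
)
from .variants import AnnotatedVariant

__all__ = [
    "MsiStatus",
    "PoleStatus",
    "SampleMeta",
    "QCMetrics",
    "TMBResult",
    "VAFSweep",
    "MIN_TOTAL_READS",
    "MIN_FRAC_CAPTURED_1000X",
    "DEFAULT_SWEEP_GRID",
    "sample_qc",
    "compute_tmb",
    "run_sample",
    "vaf_sweep",
    "plateau_vaf",
    "results_to_frame",
    "sweeps_to_frame",
]

MIN_TOTAL_READS = 20_000_000
MIN_FRAC_CAPTURED_1000X = 0.15

#: 1%–30% in 1% steps; covers the informative range of the sweep.
DEFAULT_SWEEP_GRID: tuple[float, ...] = tuple(
    round(0.01 * i, 2) for i in range(1, 31)
)


class MsiStatus(str, Enum):
    MSI = "MSI"
    MSS = "MSS"
    UNKNOWN = "unknown"


class PoleStatus(str, Enum):
    MUTATED = "mutated"
    WT = "WT"
    UNKNOWN = "unknown"


@dataclass
class SampleMeta:
    sample_id: str
    preservation: Preservation
    run_id: str = ""
    tumor_type: str = ""
    msi_status: MsiStatus = MsiStatus.UNKNOWN
    pole_status: PoleStatus = PoleStatus.UNKNOWN
    dna_quality: Optional[str] = None  # "high" | "low", FFPE pre-analytics

    def __post_init__(self) -> None:
        self.preservation = Preservation(self.preservation)
        self.msi_status = MsiStatus(self.msi_status)
        self.pole_status = PoleStatus(self.pole_status)


@dataclass(frozen=True)
class QCMetrics:
    total_reads: int
    frac_captured_ge_1000x: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_captured_ge_1000x <= 1.0:
            raise ValueError(
                f"frac_captured_ge_1000x out of [0,1]: {self.frac_captured_ge_1000x}"
            )


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    profile_name: str
    n_retained: int
    panel_size_mb: float
    tmb: float
    report: FilterReport

    def __post_init__(self) -> None:
        if self.tmb != self.n_retained / self.panel_size_mb:
            raise ValueError("tmb must equal n_retained / panel_size_mb")


@dataclass(frozen=True)
class VAFSweep:
    sample_id: str
    grid: tuple[float, ...]
    tmb_at_cutoff: tuple[float, ...]

    def __post_init__(self) -> None:
        diffs = np.diff(self.tmb_at_cutoff)
        if len(diffs) and diffs.max() > 1e-12:
            raise ValueError("tmb_at_cutoff must be non-increasing along the grid")


def sample_qc(metrics: QCMetrics) -> bool:
    """Contributivity gate: fails on < 20M reads or < 15% of the capture
    above 1000X. Missing metrics are an error — the gate cannot be
    silently skipped."""
    if metrics.total_reads is None or metrics.frac_captured_ge_1000x is None:
        raise ValueError("QC metrics incomplete; contributivity cannot be assessed")
    return not (
        metrics.total_reads < MIN_TOTAL_READS
        or metrics.frac_captured_ge_1000x < MIN_FRAC_CAPTURED_1000X
    )


def compute_tmb(report: FilterReport, profile: FilterProfile) -> TMBResult:
    """Mutations per megabase from a filter report."""
    if profile.panel_size_mb <= 0:
        raise ValueError(f"panel_size_mb must be > 0: {profile.panel_size_mb}")
    n = report.n_retained
    return TMBResult(
        sample_id=report.sample_id,
        profile_name=profile.name,
        n_retained=n,
        panel_size_mb=profile.panel_size_mb,
        tmb=n / profile.panel_size_mb,
        report=report,
    )


def run_sample(
    variants: Sequence[AnnotatedVariant],
    meta: SampleMeta,
    run: Optional[RunContext],
    profile: FilterProfile,
    **kwargs,
) -> TMBResult:
    """Filter one sample's variants and score it in one call."""
    report = apply_profile(variants, meta.preservation, run, profile, **kwargs)
    if not report.sample_id:
        report.sample_id = meta.sample_id
    return compute_tmb(report, profile)


def vaf_sweep(
    variants: Sequence[AnnotatedVariant],
    meta: SampleMeta,
    run: Optional[RunContext],
    profile: FilterProfile,
    grid: Sequence[float] = DEFAULT_SWEEP_GRID,
) -> VAFSweep:
    """TMB as a function of the minimum-VAF cutoff.

    For each cutoff the profile's preservation-specific VAF bound is
    overridden by the cutoff (for both preservations, so the sample's
    own preservation is what matters) and the full cascade re-applied.
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("VAF grid is empty")
    if any(not 0.0 < g < 1.0 for g in grid):
        raise ValueError("VAF cutoffs must lie in (0,1)")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("VAF grid must be strictly ascending")
    tmbs = []
    for cutoff in grid:
        p = replace(
            profile,
            min_vaf_by_preservation={
                Preservation.FFPE: cutoff, Preservation.FROZEN: cutoff,
            },
        )
        tmbs.append(run_sample(variants, meta, run, p).tmb)
    return VAFSweep(sample_id=meta.sample_id, grid=grid, tmb_at_cutoff=tuple(tmbs))


def plateau_vaf(sweep: VAFSweep, rel_tol: float = 0.05) -> Optional[float]:
    """Smallest grid cutoff from which the curve is stable.

    Stable means every successive relative decrease beyond that point is
    at most ``rel_tol``; returns None when the curve never stabilizes.
    A zero TMB value is stable by definition (no further decrease is
    possible).
    """
    t = sweep.tmb_at_cutoff
    stable_from = len(t) - 1
    for i in range(len(t) - 2, -1, -1):
        drop = t[i] - t[i + 1]
        if t[i] == 0 or drop <= rel_tol * t[i]:
            stable_from = i
        else:
            break
    if stable_from == len(t) - 1 and len(t) > 1:
        # the last point alone carries no evidence of stability
        drop = t[-2] - t[-1]
        if not (t[-2] == 0 or drop <= rel_tol * t[-2]):
            return None
    return sweep.grid[stable_from]


# --- tabular output ---------------------------------------------------------


def results_to_frame(
    results: Sequence[TMBResult],
    metas: Optional[dict[str, SampleMeta]] = None,
    contributive: Optional[dict[str, bool]] = None,
) -> pd.DataFrame:
    """Per-sample results as a tidy table (one row per sample/profile),
    including per-stage attrition columns."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "profile": r.profile_name,
            "n_input": r.report.n_input,
            "n_retained": r.n_retained,
            "panel_size_mb": r.panel_size_mb,
            "tmb": r.tmb,
        }
        if metas and r.sample_id in metas:
            m = metas[r.sample_id]
            row.update(
                preservation=m.preservation.value,
                run_id=m.run_id,
                tumor_type=m.tumor_type,
                msi_status=m.msi_status.value,
                pole_status=m.pole_status.value,
            )
        if contributive is not None:
            row["contributive"] = contributive.get(r.sample_id, True)
        for stage, n in r.report.attrition.items():
            row[f"removed_{stage}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def sweeps_to_frame(sweeps: Sequence[VAFSweep]) -> pd.DataFrame:
    """Sweep curves in long format (sample_id, vaf_cutoff, tmb)."""
    rows = [
        {"sample_id": s.sample_id, "vaf_cutoff": g, "tmb": t}
        for s in sweeps
        for g, t in zip(s.grid, s.tmb_at_cutoff)
    ]
    return pd.DataFrame(rows)
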