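"""Independent brute-force reference implementations used as oracles.

These deliberately re-derive each filter decision from first principles
(direct transcription of the filter definitions), without reusing the
package's predicate functions, so that the cascade can be checked
variant-for-variant against them.
"""

from tmbkit.filters import Preservation, QualityPolicy, DriverPolicy
from tmbkit.variants import RegionClass


def naive_retained_keys(variants, preservation, run, profile):
    """Set of variant keys a naive per-variant evaluation retains."""
    preservation = Preservation(preservation)
    retained = set()
    for v in variants:
        ok = True
        # caller quality
        if profile.quality_policy in (QualityPolicy.REQUIRE_PASS, QualityPolicy.BOTH):
            if not v.call.pass_flag:
                ok = False
        # intra-run recurrence
        if profile.quality_policy in (
            QualityPolicy.INTRA_RUN_RECURRENCE, QualityPolicy.BOTH,
        ):
            frac = run.variant_presence.get(v.key, 0) / run.sample_count
            if frac > profile.recurrence_threshold:
                ok = False
        # germline by population MAF
        for db in profile.germline_dbs:
            af = v.annotation.population_afs.get(db)
            if af is not None and af > profile.maf_cutoff:
                ok = False
        # class / driver
        if profile.driver_policy is DriverPolicy.EXCLUDE_COSMIC and v.annotation.cosmic_hit:
            ok = False
        if v.annotation.region_class not in (RegionClass.EXONIC, RegionClass.SPLICING):
            ok = False
        if not profile.class_policy[v.annotation.consequence]:
            ok = False
        # VAF / depth
        if not (
            v.call.vaf > profile.min_vaf_by_preservation[preservation]
            and v.call.depth > profile.min_depth
        ):
            ok = False
        if ok:
            retained.add(v.key)
    return retained


def naive_bin_counts(values, edges):
    """Histogram over [e0,e1], (e1,e2], ..., (ek, inf) by direct scan."""
    edges = list(edges)
    counts = [0] * len(edges)
    for t in values:
        if t <= edges[1]:
            counts[0] += 1
            continue
        placed = False
        for i in range(1, len(edges) - 1):
            if edges[i] < t <= edges[i + 1]:
                counts[i] += 1
                placed = True
                break
        if not placed:
            counts[-1] += 1
    return counts
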