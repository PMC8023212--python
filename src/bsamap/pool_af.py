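"""Pooled allele frequencies and the candidate-variant filters.

The mapping logic is deterministic thresholding on per-pool allele
frequencies computed from allelic depths.  Quality filtering first removes
alignment artifacts (mutant-pool AF at or below 0.3), under-covered sites
(fewer than 10 informative reads) and low-confidence calls (GQ below 30),
all judged in the mutant pool by default.  Candidate selection then keeps
sites fixed for the alternate allele in the mutant bulk (AF 1.0, with an
optional tolerance for finite-coverage noise), below 0.5 in the azygous
bulk, and absent from the wild-type bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import VariantRecord


class PoolError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Thresholds of the two filtering stages.

    ``mutant_af_tolerance`` relaxes the exact mutant-pool AF = 1.0
    requirement to AF >= mutant_af_min - tolerance; finite coverage with
    sequencing error or phenotyping noise makes exact fixation fragile.
    ``artifact_af_any_pool`` extends the artifact removal to every pool
    (the default judges only the mutant pool, whose variants seed the
    analysis).  ``keep_missing_azygous`` keeps candidates whose azygous AF
    is undefined (zero informative reads).
    """

    min_depth: int = 10
    min_gq_mutant: int = 30
    artifact_af_max: float = 0.3
    artifact_af_any_pool: bool = False
    mutant_af_min: float = 1.0
    mutant_af_tolerance: float = 0.0
    azygous_af_max: float = 0.5
    require_absent_in_wildtype: bool = True
    wildtype_af_max: float = 0.0
    keep_missing_azygous: bool = False

    def __post_init__(self) -> None:
        for name in (
            "artifact_af_max",
            "mutant_af_min",
            "mutant_af_tolerance",
            "azygous_af_max",
            "wildtype_af_max",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise PoolError(f"{name} must lie in [0, 1]")
        if self.min_depth < 1:
            raise PoolError("min_depth must be >= 1")


@dataclass
class PoolAF:
    """Observed allele frequency of one pool at one site.

    ``af`` is ad_alt/(ad_ref + ad_alt) and None (missing) when no
    informative reads were observed.
    """

    chrom: str
    pos: int
    pool: str
    af: float | None
    depth_used: int
    gq: int


def compute_af(record: VariantRecord, pool: str) -> PoolAF:
    """Allele frequency of one pool from its allelic depths."""
    if pool not in record.samples:
        raise PoolError(f"pool {pool!r} not present at {record.chrom}:{record.pos}")
    call = record.samples[pool]
    denom = call.ad_ref + call.ad_alt
    af = call.ad_alt / denom if denom > 0 else None
    return PoolAF(record.chrom, record.pos, pool, af, denom, call.gq)


def apply_quality_filters(
    records: list[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Remove artifact-like, shallow and low-confidence sites.

    A record is dropped iff its mutant-pool AF is <= artifact_af_max
    (inclusive), its informative depth is below min_depth, or its GQ is
    below min_gq_mutant.  Drop counts are attributed to the first failing
    rule in the fixed order (af, depth, gq) for reproducible reports.
    """
    retained: list[VariantRecord] = []
    drops = {"af": 0, "depth": 0, "gq": 0}
    for rec in records:
        pools = ("mutant", "azygous", "wildtype") if config.artifact_af_any_pool else ("mutant",)
        afs = [compute_af(rec, p) for p in pools if p in rec.samples]
        mutant = compute_af(rec, "mutant")
        if any(a.af is not None and a.af <= config.artifact_af_max for a in afs) or (
            mutant.af is None
        ):
            drops["af"] += 1
        elif mutant.depth_used < config.min_depth:
            drops["depth"] += 1
        elif mutant.gq < config.min_gq_mutant:
            drops["gq"] += 1
        else:
            retained.append(rec)
    return retained, drops


def select_candidates(
    records: list[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Keep sites showing the causal-variant association signature.

    Mutant-pool AF >= mutant_af_min - mutant_af_tolerance, azygous-pool AF
    strictly below azygous_af_max, and (when required) wild-type-pool AF at
    or below wildtype_af_max.  Expects quality filters to have been applied
    already.
    """
    kept: list[VariantRecord] = []
    threshold = config.mutant_af_min - config.mutant_af_tolerance
    for rec in records:
        mutant = compute_af(rec, "mutant")
        if mutant.af is None or mutant.af < threshold:
            continue
        azygous = compute_af(rec, "azygous")
        if azygous.af is None:
            if not config.keep_missing_azygous:
                continue
        elif not azygous.af < config.azygous_af_max:
            continue
        if config.require_absent_in_wildtype and "wildtype" in rec.samples:
            wt = compute_af(rec, "wildtype")
            if wt.af is not None and wt.af > config.wildtype_af_max:
                continue
        kept.append(rec)
    return kept


def linkage_consistency(
    candidate: VariantRecord,
    records: list[VariantRecord],
    window_bp: int = 1_000_000,
    min_neighbors: int = 3,
    af_threshold: float = 0.8,
) -> float | None:
    """Fraction of nearby variants co-fixed with a candidate in the mutant pool.

    A genuine causal variant sits on a selected haplotype, so its mutant-pool
    neighbours within ``window_bp`` should also show high allele frequency.
    Returns the fraction of neighbours with AF >= af_threshold, or None
    when fewer than ``min_neighbors`` neighbours exist.
    """
    neighbors = [
        r
        for r in records
        if r.chrom == candidate.chrom
        and r.pos != candidate.pos
        and abs(r.pos - candidate.pos) <= window_bp
    ]
    if len(neighbors) < min_neighbors:
        return None
    high = 0
    for r in neighbors:
        af = compute_af(r, "mutant").af
        if af is not None and af >= af_threshold:
            high += 1
    return high / len(neighbors)
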