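"""End-to-end orchestration: simulate -> filter -> scan -> annotate -> report.

A run is fully determined by its :class:`RunConfig` and a master seed.  The
master seed is expanded with ``numpy.random.SeedSequence.spawn`` into one
child stream per stage (reference, mutagenesis, breeding, read simulation,
in that fixed order), so any stage can be re-run in isolation and
reproduces its part of the experiment bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import effect_annot, pool_af, region_scan, synthetic_cross
from .io_formats import write_fasta, write_gff3, write_tsv, write_vcf, POOL_NAMES
from .phenotype_stats import classify_phenotype, segregation_test
from .pool_af import FilterConfig
from .synthetic_cross import CrossDesign

logger = logging.getLogger("bsamap")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class ScanConfig:
    """Region-scan parameters; window/step of 0 means auto-scale.

    Auto-scaling starts from a window of 1/50 of the chromosome length (at
    the real-genome scale of ~50 Mb chromosomes this recovers the 1 Mb /
    100 kb defaults) but widens it when the variant density is so low that
    a window would hold fewer than ``target_variants_per_window`` variants
    in expectation: window means over a couple of variants are too noisy to
    threshold, and empty windows fragment the plateau.  The step is a tenth
    of the window.
    """

    window_bp: int = 0
    step_bp: int = 0
    af_threshold: float = 0.9
    min_windows: int = 2
    target_variants_per_window: int = 12

    def resolved(
        self, chrom_length: int, variant_density_per_bp: float | None = None
    ) -> tuple[int, int]:
        window = self.window_bp
        if not window:
            window = max(chrom_length // 50, 1)
            if variant_density_per_bp and variant_density_per_bp > 0:
                needed = int(self.target_variants_per_window / variant_density_per_bp)
                window = min(max(window, needed), chrom_length)
        step = self.step_bp or max(window // 10, 1)
        return window, step


@dataclass
class RunConfig:
    """Complete description of a synthetic mapping run."""

    n_chrom: int = 2
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    genes_per_chrom: int = 4
    n_mutations: int = 300
    transition_fraction: float = 0.9
    design: CrossDesign = field(default_factory=CrossDesign)
    filters: FilterConfig = field(
        default_factory=lambda: FilterConfig(
            mutant_af_tolerance=0.1, wildtype_af_max=0.05
        )
    )
    scan: ScanConfig = field(default_factory=ScanConfig)
    fvfm_cutoff: float = 0.6
    linkage_window_bp: int = 1_000_000
    linkage_min_neighbors: int = 3


@dataclass
class RunSummary:
    schema_version: int
    seed: int
    causal: dict
    n_individuals: int
    n_phenotype_mutant: int
    segregation_chi_square: float
    segregation_p_value: float
    n_variants_simulated: int
    n_variants_after_quality: int
    drop_counts: dict
    n_candidates: int
    region: dict | None
    causal_in_region: bool
    causal_in_candidates: bool
    causal_top_ranked: bool
    causal_recovered: bool
    top_annotation: dict | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_end_to_end(
    config: RunConfig, seed: int, out_dir: str | Path | None = None
) -> RunSummary:
    """Execute the whole pipeline once.

    When ``out_dir`` is given, all intermediate files are written there
    (reference.fasta, genes.gff3, pools.vcf, truth.tsv, individuals.tsv,
    candidates.tsv, effects.tsv, region.tsv, region.png, summary.json);
    otherwise the run is purely in-memory.  The summary records whether the
    planted causal variant fell inside the detected region, survived the
    candidate filters, and ranked first after effect prioritisation.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if logger.getEffectiveLevel() > logging.INFO:
            logger.setLevel(logging.INFO)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    try:
        return _run(config, seed, out)
    finally:
        if out is not None:
            logger.removeHandler(handler)
            handler.close()


def _run(config: RunConfig, seed: int, out: Path | None) -> RunSummary:
    ss = np.random.SeedSequence(seed)
    seed_ref, seed_mut, seed_breed, seed_reads = ss.spawn(4)
    logger.info("run start: seed=%d, config=%s", seed, config)

    # stage 1: reference genome and annotation
    genome, models = synthetic_cross.generate_reference(
        n_chrom=config.n_chrom,
        lengths=config.chrom_lengths,
        seed=seed_ref,
        genes_per_chrom=config.genes_per_chrom,
    )
    # stage 2: mutagenized line
    mutations = synthetic_cross.induce_mutations(
        genome,
        models,
        n_mutations=config.n_mutations,
        transition_fraction=config.transition_fraction,
        seed=seed_mut,
    )
    causal = mutations.causal
    logger.info("causal site: %s:%d %s>%s", causal.chrom, causal.pos, causal.ref, causal.alt)

    # stage 3: segregating population, phenotyping, pools
    individuals = synthetic_cross.breed_bc1f2(
        config.design, mutations, genome.lengths(), seed=seed_breed
    )
    classified = [
        classify_phenotype(ind.fvfm, config.fvfm_cutoff) for ind in individuals
    ]
    n_mut_pheno = sum(1 for c in classified if c == "mutant")
    seg = segregation_test(n_mut_pheno, len(individuals))
    pools = synthetic_cross.make_pools(individuals, config.design)

    # stage 4: pooled read evidence
    records = synthetic_cross.simulate_pool_reads(
        pools, mutations, config.design, seed=seed_reads
    )

    # stage 5: quality filters and candidate selection
    retained, drops = pool_af.apply_quality_filters(records, config.filters)
    logger.info(
        "quality filters (af<=%g, depth<%d, gq<%d): %d -> %d retained, drops %s",
        config.filters.artifact_af_max,
        config.filters.min_depth,
        config.filters.min_gq_mutant,
        len(records),
        len(retained),
        drops,
    )
    candidates = pool_af.select_candidates(retained, config.filters)
    logger.info(
        "candidate selection (mutant af>=%g, azygous af<%g, wildtype af<=%g): %d",
        config.filters.mutant_af_min - config.filters.mutant_af_tolerance,
        config.filters.azygous_af_max,
        config.filters.wildtype_af_max,
        len(candidates),
    )

    # stage 6: region scan on the mutant-pool profile; the profile is
    # descriptive (all sites plotted along the chromosome), the filters
    # above act only on candidate selection
    density = len(records) / sum(config.chrom_lengths)
    window, step = config.scan.resolved(max(config.chrom_lengths), density)
    profiles = region_scan.window_af_profile(
        records, "mutant", window, step, genome.lengths()
    )
    regions = [
        r
        for r in (
            region_scan.detect_peak_region(
                p, config.scan.af_threshold, config.scan.min_windows
            )
            for p in profiles.values()
        )
        if r is not None
    ]
    region = max(regions, key=lambda r: (r.n_windows, r.chrom), default=None)

    # stage 7: effect annotation, restricted to the detected region
    linkage = {
        (c.chrom, c.pos): pool_af.linkage_consistency(
            c, retained, config.linkage_window_bp, config.linkage_min_neighbors
        )
        for c in candidates
    }
    to_annotate = (
        [c for c in candidates if region.contains(c.chrom, c.pos)]
        if region is not None
        else candidates
    )
    annotations = effect_annot.annotate_candidates(
        to_annotate, models, genome, linkage
    )

    causal_in_region = region is not None and region.contains(causal.chrom, causal.pos)
    causal_in_candidates = any(
        c.chrom == causal.chrom and c.pos == causal.pos for c in candidates
    )
    top = annotations[0] if annotations else None
    causal_top_ranked = (
        top is not None
        and top.variant.chrom == causal.chrom
        and top.variant.pos == causal.pos
    )
    summary = RunSummary(
        schema_version=SUMMARY_SCHEMA_VERSION,
        seed=seed,
        causal={
            "chrom": causal.chrom,
            "pos": causal.pos,
            "ref": causal.ref,
            "alt": causal.alt,
        },
        n_individuals=len(individuals),
        n_phenotype_mutant=n_mut_pheno,
        segregation_chi_square=seg.chi_square,
        segregation_p_value=seg.p_value,
        n_variants_simulated=len(records),
        n_variants_after_quality=len(retained),
        drop_counts=drops,
        n_candidates=len(candidates),
        region=None
        if region is None
        else {
            "chrom": region.chrom,
            "start": region.start,
            "end": region.end,
            "peak_pos": region.peak_pos,
            "peak_af": region.peak_af,
        },
        causal_in_region=causal_in_region,
        causal_in_candidates=causal_in_candidates,
        causal_top_ranked=causal_top_ranked,
        causal_recovered=causal_in_region and causal_in_candidates and causal_top_ranked,
        top_annotation=None
        if top is None
        else {
            "chrom": top.variant.chrom,
            "pos": top.variant.pos,
            "gene": top.gene_id,
            "class": top.effect_class,
            "codon_change": top.codon_change(),
            "aa_change": top.aa_change(),
        },
    )

    if out is not None:
        write_fasta(genome, out / "reference.fasta")
        write_gff3(models, out / "genes.gff3")
        write_vcf(records, list(POOL_NAMES), out / "pools.vcf", genome)
        write_tsv(
            [
                {
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "is_causal": int(m.is_causal),
                    "mutant_dosage_fraction": f"{pools.fraction('mutant')[i]:.6f}",
                    "azygous_dosage_fraction": f"{pools.fraction('azygous')[i]:.6f}",
                }
                for i, m in enumerate(mutations)
            ],
            [
                "chrom",
                "pos",
                "ref",
                "alt",
                "is_causal",
                "mutant_dosage_fraction",
                "azygous_dosage_fraction",
            ],
            out / "truth.tsv",
        )
        write_tsv(
            [
                {
                    "individual": i,
                    "phenotype": ind.phenotype,
                    "fvfm": f"{ind.fvfm:.4f}",
                    "classified": cls,
                }
                for i, (ind, cls) in enumerate(zip(individuals, classified))
            ],
            ["individual", "phenotype", "fvfm", "classified"],
            out / "individuals.tsv",
        )
        write_tsv(
            [
                {
                    "chrom": c.chrom,
                    "pos": c.pos,
                    "ref": c.ref,
                    "alt": c.alt,
                    "af_mutant": _fmt_af(c, "mutant"),
                    "af_azygous": _fmt_af(c, "azygous"),
                    "af_wildtype": _fmt_af(c, "wildtype"),
                    "dp": c.samples["mutant"].dp,
                    "gq": c.samples["mutant"].gq,
                    "linkage_score": linkage.get((c.chrom, c.pos)),
                }
                for c in candidates
            ],
            [
                "chrom",
                "pos",
                "ref",
                "alt",
                "af_mutant",
                "af_azygous",
                "af_wildtype",
                "dp",
                "gq",
                "linkage_score",
            ],
            out / "candidates.tsv",
        )
        write_tsv(
            [
                {
                    "chrom": a.variant.chrom,
                    "pos": a.variant.pos,
                    "ref": a.variant.ref,
                    "alt": a.variant.alt,
                    "gene": a.gene_id,
                    "class": a.effect_class,
                    "codon_change": a.codon_change(),
                    "aa_change": a.aa_change(),
                    "aa_pos": a.aa_pos,
                    "linkage_score": a.linkage_score,
                }
                for a in annotations
            ],
            [
                "chrom",
                "pos",
                "ref",
                "alt",
                "gene",
                "class",
                "codon_change",
                "aa_change",
                "aa_pos",
                "linkage_score",
            ],
            out / "effects.tsv",
        )
        region_scan.region_report(
            region,
            candidates,
            profiles,
            str(out / "region.tsv"),
            str(out / "region.png"),
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        logger.info("summary: %s", summary.to_dict())
    return summary


def _fmt_af(record, pool: str) -> str:
    af = pool_af.compute_af(record, pool).af
    return "NA" if af is None else f"{af:.4f}"
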