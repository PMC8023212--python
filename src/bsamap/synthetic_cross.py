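"""Synthetic forward-genetics experiment generator.

Emulates the full mapping-by-sequencing design end to end: a random
reference genome with toy protein-coding genes, a chemically mutagenized
line carrying transition-biased homozygous SNPs (one of them a recessive
causal change planted as C->T in a CTC/CTT leucine codon, so the coding
consequence is Leu->Phe), a backcross-then-self (BC1F2) segregating
population bred with Haldane (no-interference) crossovers, phenotype
selection into a homozygous-mutant bulk and an azygous (non-mutant
segregant) bulk plus a wild-type bulk, and finally pooled short-read
evidence per site as binomially sampled allele depths with a Phred-scaled
genotype quality.

Every operation takes an explicit seed and uses a single
``numpy.random.Generator``; a fixed seed reproduces the output bit for bit.
Draw order within each operation is fixed and documented in the function
docstrings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DNA, Genome, GeneModel, POOL_NAMES, SampleCall, VariantRecord

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}
STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


class DesignError(ValueError):
    pass


@dataclass
class PoolSpec:
    mutant: int = 45
    azygous: int = 54
    wildtype: int = 50


@dataclass
class CrossDesign:
    """Parameters of the genetic experiment.

    recomb_rate is the expected number of crossovers per chromosome per
    meiosis (Morgans); physical position maps linearly onto the genetic
    map.  coverage_range is the interval the per-site per-pool mean read
    depth is drawn from.  misclassification is the probability a plant's
    phenotype label is flipped (phenotyping noise); seq_error the per-read
    allele miscall probability.
    """

    n_population: int = 300
    pool_sizes: PoolSpec = field(default_factory=PoolSpec)
    coverage_range: tuple[float, float] = (45.0, 65.0)
    recomb_rate: float = 1.0
    seq_error: float = 0.001
    misclassification: float = 0.01
    # phenotype-conditional Fv/Fm distributions, truncated to (0, 1)
    fvfm_wildtype: tuple[float, float] = (0.69, 0.05)
    fvfm_mutant: tuple[float, float] = (0.45, 0.07)
    # genotype-quality model: likelihood grid {0, 1/(2n), ..., 1}; n=1 is a
    # diploid-caller-style three-hypothesis GQ
    gq_grid_n: int = 1
    gq_cap: int = 99

    def __post_init__(self) -> None:
        lo, hi = self.coverage_range
        if not 0 < lo <= hi:
            raise DesignError("coverage_range must be 0 < low <= high")
        if self.recomb_rate < 0:
            raise DesignError("recomb_rate must be non-negative")
        if not 0.0 <= self.seq_error < 0.5:
            raise DesignError("seq_error must lie in [0, 0.5)")
        if not 0.0 <= self.misclassification <= 1.0:
            raise DesignError("misclassification must lie in [0, 1]")
        if self.gq_grid_n < 1:
            raise DesignError("gq_grid_n must be >= 1")


@dataclass
class Mutation:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    is_causal: bool = False


@dataclass
class MutationSet:
    """Induced SNPs of the mutagenized line, homozygous in that line."""

    mutations: list[Mutation]

    def __post_init__(self) -> None:
        n_causal = sum(m.is_causal for m in self.mutations)
        if n_causal != 1:
            raise DesignError(f"expected exactly one causal mutation, got {n_causal}")
        keys = {(m.chrom, m.pos) for m in self.mutations}
        if len(keys) != len(self.mutations):
            raise DesignError("mutation positions must be unique")

    @property
    def causal(self) -> Mutation:
        return next(m for m in self.mutations if m.is_causal)

    @property
    def causal_index(self) -> int:
        return next(i for i, m in enumerate(self.mutations) if m.is_causal)

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)


@dataclass
class IndividualGenotype:
    """One BC1F2 plant: mutant-line allele dosage per induced site."""

    dosages: np.ndarray  # int8, aligned with MutationSet order
    phenotype: str  # "mutant" | "wildtype-like"
    fvfm: float


# ---------------------------------------------------------------------------
# Reference genome with toy genes
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform ACGT sequence as a uint8 byte array."""
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[rng.integers(0, 4, size=length)]


def _build_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop; no internal stop by construction."""
    body = rng.choice(_NONSTOP_CODONS, size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(body) + stop


def generate_reference(
    n_chrom: int = 2,
    lengths: tuple[int, ...] = (5_000_000, 5_000_000),
    seed: int | None = None,
    genes_per_chrom: int = 4,
    cds_codon_range: tuple[int, int] = (200, 400),
    two_exon_fraction: float = 0.5,
    intron_length_range: tuple[int, int] = (100, 500),
) -> tuple[Genome, list[GeneModel]]:
    """Random reference genome plus a sparse toy gene annotation.

    Each chromosome receives ``genes_per_chrom`` non-overlapping genes, one
    per equal-width block, with random strand; a gene is split into two CDS
    exons by an intron with probability ``two_exon_fraction``.  Every CDS
    starts with ATG, ends with a stop and contains no internal stop on its
    own strand.  Draw order: per chromosome, background sequence first,
    then per gene (length, strand, exon split, placement).
    """
    if n_chrom != len(lengths):
        raise DesignError("lengths must have one entry per chromosome")
    if any(l < 10_000 for l in lengths):
        raise DesignError("chromosome lengths must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    for ci in range(n_chrom):
        name = f"chr{ci + 1}"
        length = lengths[ci]
        seq = _random_sequence(rng, length)
        block = length // max(genes_per_chrom, 1)
        for gi in range(genes_per_chrom):
            n_codons = int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _build_cds(rng, n_codons)
            two_exon = rng.random() < two_exon_fraction
            if two_exon:
                # split at a random interior point (not codon-aligned in
                # general; phases carry the frame across the intron)
                cut = int(rng.integers(3, len(cds) - 3))
                ilen = int(
                    rng.integers(intron_length_range[0], intron_length_range[1] + 1)
                )
                exon1, exon2 = cds[:cut], cds[cut:]
                intron = _random_sequence(rng, ilen).tobytes().decode()
                region_t = exon1 + intron + exon2
            else:
                exon1, exon2, ilen = cds, "", 0
                region_t = cds
            region = region_t
            if strand == "-":
                region = _revcomp(region_t)
            glen = len(region)
            lo = gi * block
            hi = lo + block - glen - 1
            if hi <= lo:
                raise DesignError(
                    f"gene of {glen} bp does not fit chromosome block of {block} bp"
                )
            g0 = int(rng.integers(lo + 1, hi))  # 0-based region start
            seq[g0 : g0 + glen] = np.frombuffer(region.encode(), dtype=np.uint8)
            gene_id = f"gene_{name}_{gi + 1}"
            len1, len2 = len(exon1), len(exon2)
            phase2 = (3 - len1 % 3) % 3
            if not two_exon:
                segments = [(g0 + 1, g0 + len1)]
                phases = [0]
            elif strand == "+":
                segments = [
                    (g0 + 1, g0 + len1),
                    (g0 + len1 + ilen + 1, g0 + glen),
                ]
                phases = [0, phase2]
            else:
                # translation-first exon sits at the genomic end
                segments = [
                    (g0 + 1, g0 + len2),
                    (g0 + len2 + ilen + 1, g0 + glen),
                ]
                phases = [phase2, 0]
            models.append(GeneModel(gene_id, name, strand, segments, phases))
        chromosomes[name] = seq.tobytes().decode()
    return Genome(chromosomes), models


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------

def cds_offset_to_genomic(model: GeneModel, offset: int) -> int:
    """Inverse of ``GeneModel.genomic_to_cds_offset`` (1-based result)."""
    remaining = offset + model.first_phase()
    for start, end in model.segments_in_translation_order():
        seg_len = end - start + 1
        if remaining < seg_len:
            return start + remaining if model.strand == "+" else end - remaining
        remaining -= seg_len
    raise ValueError(f"CDS offset {offset} outside {model.gene_id}")


def induce_mutations(
    genome: Genome,
    gene_models: list[GeneModel],
    n_mutations: int = 300,
    transition_fraction: float = 0.9,
    seed: int | None = None,
) -> MutationSet:
    """Plant transition-biased SNPs, one of them the causal Leu->Phe change.

    Non-causal positions are sampled uniformly without replacement across
    the genome; the alternate allele is the transition partner with
    probability ``transition_fraction``, else one of the two transversions.
    The causal mutation is forced onto the first base of a CTC or CTT
    leucine codon inside a CDS (chosen uniformly among all such codons), so
    the change is C->T in coding orientation and the protein change is
    leucine to phenylalanine.  Draw order: causal codon choice, then
    positions, then alt alleles.
    """
    if n_mutations < 1:
        raise DesignError("n_mutations must be >= 1")
    if not 0.0 <= transition_fraction <= 1.0:
        raise DesignError("transition_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    # candidate leucine codons across all CDSs
    leu_sites: list[tuple[GeneModel, int]] = []
    for model in gene_models:
        cds = model.cds_sequence(genome)
        for i in range(0, len(cds) - 2, 3):
            if cds[i : i + 3] in ("CTC", "CTT"):
                leu_sites.append((model, i))
    if not leu_sites:
        raise DesignError(
            "no CTC/CTT leucine codon available in any CDS; "
            "regenerate the reference with a different seed"
        )
    model, cds_off = leu_sites[int(rng.integers(len(leu_sites)))]
    causal_pos = cds_offset_to_genomic(model, cds_off)
    causal_ref = genome.base(model.chrom, causal_pos)
    causal_alt = TRANSITION[causal_ref]  # C->T on +, G->A on -
    causal = Mutation(model.chrom, causal_pos, causal_ref, causal_alt, is_causal=True)

    names = genome.names
    lens = [genome.length(c) for c in names]
    offsets = np.cumsum([0] + lens)
    total = int(offsets[-1])
    taken = {(causal.chrom, causal.pos)}
    mutations = [causal]
    while len(mutations) < n_mutations:
        g = int(rng.integers(total))
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        chrom = names[ci]
        pos = g - int(offsets[ci]) + 1
        if (chrom, pos) in taken:
            continue
        ref = genome.base(chrom, pos)
        if ref not in DNA:
            continue
        if rng.random() < transition_fraction:
            alt = TRANSITION[ref]
        else:
            alt = TRANSVERSIONS[ref][int(rng.integers(2))]
        taken.add((chrom, pos))
        mutations.append(Mutation(chrom, pos, ref, alt))
    mutations.sort(key=lambda m: (m.chrom, m.pos))
    return MutationSet(mutations)


# ---------------------------------------------------------------------------
# Breeding
# ---------------------------------------------------------------------------

def breed_bc1f2(
    design: CrossDesign,
    mutations: MutationSet,
    chrom_lengths: dict[str, int],
    seed: int | None = None,
) -> list[IndividualGenotype]:
    """Breed the BC1F2 population from the (uniformly heterozygous) F1.

    Each individual is the union of two independent F1 gametes.  Within a
    gamete the parental haplotype along a chromosome starts from a fair
    coin flip and switches at crossover points drawn as a Poisson process
    with mean ``recomb_rate`` crossovers per chromosome (Haldane model, no
    interference); crossover positions are uniform on the physical
    chromosome, which maps linearly onto the genetic map.

    The phenotype label is "mutant" iff the causal dosage is 2, then
    flipped with probability ``misclassification``; Fv/Fm is drawn from the
    label-conditional normal distribution truncated to (0, 1).  Draw order
    per individual: gametes (chromosomes in sorted order; per chromosome:
    start haplotype, crossover count, crossover positions), then the
    misclassification flip, then Fv/Fm.
    """
    rng = np.random.default_rng(seed)
    order = sorted(set(m.chrom for m in mutations))
    pos_by_chrom = {
        c: np.array([m.pos for m in mutations if m.chrom == c], dtype=float)
        for c in order
    }
    idx_by_chrom = {
        c: np.array(
            [i for i, m in enumerate(mutations) if m.chrom == c], dtype=int
        )
        for c in order
    }
    causal_idx = mutations.causal_index
    n_sites = len(mutations)
    individuals: list[IndividualGenotype] = []
    for _ in range(design.n_population):
        dosage = np.zeros(n_sites, dtype=np.int8)
        for _gamete in range(2):
            for c in order:
                if c not in chrom_lengths:
                    raise DesignError(f"no length known for chromosome {c}")
                length = chrom_lengths[c]
                start = int(rng.integers(2))  # 1 = mutant-line haplotype
                n_x = int(rng.poisson(design.recomb_rate))
                if n_x:
                    xpos = np.sort(rng.uniform(0, length, size=n_x))
                    switches = np.searchsorted(xpos, pos_by_chrom[c])
                else:
                    switches = np.zeros(len(pos_by_chrom[c]), dtype=int)
                hap = (start + switches) % 2
                dosage[idx_by_chrom[c]] += hap.astype(np.int8)
        phenotype = "mutant" if dosage[causal_idx] == 2 else "wildtype-like"
        if rng.random() < design.misclassification:
            phenotype = "wildtype-like" if phenotype == "mutant" else "mutant"
        mean, sd = (
            design.fvfm_mutant if phenotype == "mutant" else design.fvfm_wildtype
        )
        fvfm = rng.normal(mean, sd)
        while not 0.0 < fvfm < 1.0:  # truncation by rejection
            fvfm = rng.normal(mean, sd)
        individuals.append(IndividualGenotype(dosage, phenotype, float(fvfm)))
    return individuals


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

@dataclass
class Pools:
    """Phenotype-selected bulks as per-site mutant-allele dosage fractions."""

    dosage_fraction: dict[str, np.ndarray]  # pool name -> fraction per site
    members: dict[str, list[int]]  # indices into the individual list

    def fraction(self, pool: str) -> np.ndarray:
        return self.dosage_fraction[pool]


def make_pools(individuals: list[IndividualGenotype], design: CrossDesign) -> Pools:
    """Select the sequencing bulks from the phenotyped population.

    The mutant bulk takes the first ``pool_sizes.mutant`` individuals
    labelled mutant, the azygous bulk the first ``pool_sizes.azygous``
    labelled wild-type-like.  The wild-type bulk consists of separate
    wild-type plants carrying zero mutant-line alleles at every induced
    site.
    """
    mutant_idx = [i for i, ind in enumerate(individuals) if ind.phenotype == "mutant"]
    azygous_idx = [
        i for i, ind in enumerate(individuals) if ind.phenotype == "wildtype-like"
    ]
    sizes = design.pool_sizes
    if len(mutant_idx) < sizes.mutant or len(azygous_idx) < sizes.azygous:
        raise DesignError(
            f"not enough individuals per phenotype class "
            f"(mutant {len(mutant_idx)}/{sizes.mutant}, "
            f"azygous {len(azygous_idx)}/{sizes.azygous}); "
            "increase n_population"
        )
    mutant_idx = mutant_idx[: sizes.mutant]
    azygous_idx = azygous_idx[: sizes.azygous]
    n_sites = len(individuals[0].dosages)

    def _fraction(idx: list[int]) -> np.ndarray:
        total = np.zeros(n_sites, dtype=float)
        for i in idx:
            total += individuals[i].dosages
        return total / (2 * len(idx))

    return Pools(
        dosage_fraction={
            "mutant": _fraction(mutant_idx),
            "azygous": _fraction(azygous_idx),
            "wildtype": np.zeros(n_sites, dtype=float),
        },
        members={"mutant": mutant_idx, "azygous": azygous_idx, "wildtype": []},
    )


# ---------------------------------------------------------------------------
# Pooled read evidence
# ---------------------------------------------------------------------------

def _gq_and_gt(
    ad_alt: int, dp: int, seq_error: float, grid_n: int, cap: int
) -> tuple[int, str]:
    """Phred-scaled quality and call from a binomial likelihood grid.

    Hypotheses are pool allele fractions {0, 1/(2n), ..., 1}; each is
    error-adjusted with a base-error prior of max(seq_error, 0.01) so the
    model stays proper when the simulation is error-free.  GQ is the
    Phred-scaled ratio of the best to the second-best likelihood, capped;
    the call reports the argmax fraction collapsed to 0/0, 0/1 or 1/1.
    """
    if dp == 0:
        return 0, "./."
    ep = max(seq_error, 0.01)
    fracs = np.arange(2 * grid_n + 1) / (2 * grid_n)
    p = fracs * (1 - ep) + (1 - fracs) * ep
    loglik = ad_alt * np.log(p) + (dp - ad_alt) * np.log(1 - p)
    best = int(np.argmax(loglik))
    rest = np.delete(loglik, best)
    gq = 10.0 / math.log(10.0) * (loglik[best] - rest.max())
    gq = int(min(cap, round(gq)))
    fhat = fracs[best]
    gt = "0/0" if fhat == 0.0 else "1/1" if fhat == 1.0 else "0/1"
    return gq, gt


def simulate_pool_reads(
    pools: Pools,
    mutations: MutationSet,
    design: CrossDesign,
    seed: int | None = None,
) -> list[VariantRecord]:
    """Simulate pooled sequencing evidence at every induced site.

    Per site and pool (pools in the fixed order mutant, azygous, wildtype):
    depth ~ Poisson(mean), mean ~ Uniform(coverage_range); alt reads ~
    Binomial(depth, p) with p the pool dosage fraction perturbed by the
    per-read error rate (error reads flip allele).  Draw order per site and
    pool: coverage mean, depth, alt reads.
    """
    rng = np.random.default_rng(seed)
    e = design.seq_error
    records: list[VariantRecord] = []
    for si, mut in enumerate(mutations):
        samples: dict[str, SampleCall] = {}
        for pool in POOL_NAMES:
            f = float(pools.fraction(pool)[si])
            mean = rng.uniform(*design.coverage_range)
            dp = int(rng.poisson(mean))
            p = f * (1 - e) + (1 - f) * e
            ad_alt = int(rng.binomial(dp, p)) if dp else 0
            gq, gt = _gq_and_gt(ad_alt, dp, e, design.gq_grid_n, design.gq_cap)
            samples[pool] = SampleCall(
                gt=gt, ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp, gq=gq
            )
        records.append(VariantRecord(mut.chrom, mut.pos, mut.ref, mut.alt, samples))
    return records
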