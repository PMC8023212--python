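"""Constructive invariants and statistical laws of the experiment generator."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from Bio.Seq import Seq

from bsamap import (
    CrossDesign,
    MutationSet,
    PoolSpec,
    breed_bc1f2,
    generate_reference,
    induce_mutations,
    make_pools,
    simulate_pool_reads,
    write_vcf,
)
from bsamap.synthetic_cross import DesignError, Mutation, TRANSITION


def enumerate_pool_af(pool: str, r: Fraction) -> Fraction:
    """Exhaustive-enumeration oracle for the expected pooled marker AF.

    The F1 carries the mutant causal allele and mutant marker allele in
    coupling.  Its four gamete types (causal, marker) have probabilities
    (1,1): (1-r)/2, (0,0): (1-r)/2, (1,0): r/2, (0,1): r/2.  A BC1F2
    individual is an ordered pair of gametes (16 combinations); pools
    condition on the causal genotype.  Exact rational arithmetic.
    """
    gametes = {
        (1, 1): (1 - r) / 2,
        (0, 0): (1 - r) / 2,
        (1, 0): r / 2,
        (0, 1): r / 2,
    }
    total_p = Fraction(0)
    total_alleles = Fraction(0)
    for (c1, m1), p1 in gametes.items():
        for (c2, m2), p2 in gametes.items():
            p = p1 * p2
            causal_dosage = c1 + c2
            if pool == "mutant" and causal_dosage != 2:
                continue
            if pool == "azygous" and causal_dosage == 2:
                continue
            total_p += p
            total_alleles += p * (m1 + m2)
    return total_alleles / (2 * total_p)


class TestGenerateReference:
    def test_seed_determinism(self):
        a = generate_reference(1, (100_000,), seed=7, genes_per_chrom=2)
        b = generate_reference(1, (100_000,), seed=7, genes_per_chrom=2)
        assert a[0].chromosomes == b[0].chromosomes
        assert [m.cds_segments for m in a[1]] == [m.cds_segments for m in b[1]]

    def test_every_cds_is_a_clean_orf(self, toy_reference):
        genome, models = toy_reference
        for model in models:
            protein = str(Seq(model.cds_sequence(genome)).translate())
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_gene_too_long_for_chromosome(self):
        with pytest.raises(DesignError, match="does not fit"):
            generate_reference(
                1, (10_000,), seed=1, genes_per_chrom=4, cds_codon_range=(900, 1000)
            )


class TestInduceMutations:
    def test_causal_is_c_to_t_leucine_to_phenylalanine(self, toy_reference, toy_mutations):
        genome, models = toy_reference
        causal = toy_mutations.causal
        model = next(
            m
            for m in models
            if m.chrom == causal.chrom
            and m.genomic_to_cds_offset(causal.pos) is not None
        )
        offset = model.genomic_to_cds_offset(causal.pos)
        assert offset % 3 == 0  # first base of its codon
        cds = model.cds_sequence(genome)
        codon = cds[offset : offset + 3]
        assert codon in ("CTC", "CTT")  # leucine
        # coding-strand change is C->T: TTC/TTT both encode phenylalanine
        alt_coding = causal.alt if model.strand == "+" else {"A": "T"}[causal.alt]
        assert alt_coding == "T"
        mutant_codon = "T" + codon[1:]
        assert str(Seq(mutant_codon).translate()) == "F"

    def test_ref_alleles_match_genome_and_positions_unique(
        self, toy_reference, toy_mutations
    ):
        genome, _ = toy_reference
        seen = set()
        for m in toy_mutations:
            assert genome.base(m.chrom, m.pos) == m.ref
            assert m.ref != m.alt
            assert (m.chrom, m.pos) not in seen
            seen.add((m.chrom, m.pos))

    def test_pure_transitions_when_fraction_is_one(self, toy_reference):
        genome, models = toy_reference
        muts = induce_mutations(
            genome, models, n_mutations=200, transition_fraction=1.0, seed=5
        )
        for m in muts:
            assert m.alt == TRANSITION[m.ref]

    def test_empirical_transition_fraction(self, toy_reference):
        """Observed transition rate matches the configured probability.

        Binomial oracle: with n sites and success probability p the count
        lies within 3*sqrt(n*p*(1-p)) of n*p.
        """
        genome, models = toy_reference
        p = 0.7
        n = 10_000
        muts = induce_mutations(
            genome, models, n_mutations=n, transition_fraction=p, seed=6
        )
        observed = sum(1 for m in muts if m.alt == TRANSITION[m.ref])
        # the causal site is forced to a transition; 1/n effect, inside 3 sigma
        assert abs(observed - n * p) <= 3 * np.sqrt(n * p * (1 - p)) + 1


class TestBreeding:
    def test_no_recombination_means_perfect_linkage(self, toy_reference, toy_mutations):
        genome, _ = toy_reference
        design = CrossDesign(recomb_rate=0.0, misclassification=0.0)
        individuals = breed_bc1f2(design, toy_mutations, genome.lengths(), seed=3)
        chroms = [m.chrom for m in toy_mutations]
        for ind in individuals[:50]:
            for chrom in set(chroms):
                idx = [i for i, c in enumerate(chroms) if c == chrom]
                values = set(int(ind.dosages[i]) for i in idx)
                assert len(values) == 1

    def test_recessive_phenotype_fraction_near_one_quarter(
        self, toy_reference, toy_mutations, error_free_design
    ):
        genome, _ = toy_reference
        n_mutant = 0
        n_total = 0
        for seed in range(20):
            individuals = breed_bc1f2(
                error_free_design, toy_mutations, genome.lengths(), seed=seed
            )
            n_mutant += sum(1 for i in individuals if i.phenotype == "mutant")
            n_total += len(individuals)
        se = np.sqrt(0.25 * 0.75 / n_total)
        assert abs(n_mutant / n_total - 0.25) < 3 * se

    def test_unlinked_site_allele_frequency_near_half(self, toy_reference):
        """Mendelian expectation: selfed-F1 allele frequency is 1/2."""
        genome, models = toy_reference
        causal = None
        muts = induce_mutations(genome, models, n_mutations=10, seed=9)
        # pick a site on the other chromosome from the causal one
        causal = muts.causal
        other = [m for m in muts if m.chrom != causal.chrom]
        assert other
        design = CrossDesign(misclassification=0.0)
        total, count = 0, 0
        for seed in range(10):
            individuals = breed_bc1f2(design, muts, genome.lengths(), seed=seed)
            idx = [i for i, m in enumerate(muts) if m.chrom != causal.chrom][0]
            total += sum(int(ind.dosages[idx]) for ind in individuals)
            count += 2 * len(individuals)
        se = np.sqrt(0.5 * 0.5 / count)
        assert abs(total / count - 0.5) < 3 * se


class TestPools:
    def _pools(self, toy_reference, toy_mutations, design, seed=4):
        genome, _ = toy_reference
        individuals = breed_bc1f2(design, toy_mutations, genome.lengths(), seed=seed)
        return individuals, make_pools(individuals, design)

    def test_exact_pool_sizes(self, toy_reference, toy_mutations, error_free_design):
        individuals, pools = self._pools(
            toy_reference, toy_mutations, error_free_design
        )
        assert len(pools.members["mutant"]) == 45
        assert len(pools.members["azygous"]) == 54

    def test_azygous_pool_free_of_causal_homozygotes(
        self, toy_reference, toy_mutations, error_free_design
    ):
        individuals, pools = self._pools(
            toy_reference, toy_mutations, error_free_design
        )
        ci = toy_mutations.causal_index
        for i in pools.members["azygous"]:
            assert individuals[i].dosages[ci] < 2

    def test_wildtype_pool_has_zero_af_everywhere(
        self, toy_reference, toy_mutations, error_free_design
    ):
        _, pools = self._pools(toy_reference, toy_mutations, error_free_design)
        assert np.all(pools.fraction("wildtype") == 0.0)

    def test_insufficient_class_counts_raise(self, toy_reference, toy_mutations):
        genome, _ = toy_reference
        design = CrossDesign(n_population=60, misclassification=0.0)
        individuals = breed_bc1f2(design, toy_mutations, genome.lengths(), seed=4)
        with pytest.raises(DesignError, match="n_population"):
            make_pools(individuals, design)


class TestPoolReads:
    def test_fixed_pool_without_error_gives_pure_alt(
        self, toy_reference, toy_mutations, error_free_design
    ):
        genome, _ = toy_reference
        individuals = breed_bc1f2(
            error_free_design, toy_mutations, genome.lengths(), seed=4
        )
        pools = make_pools(individuals, error_free_design)
        pools.dosage_fraction["mutant"][:] = 1.0
        records = simulate_pool_reads(pools, toy_mutations, error_free_design, seed=5)
        for rec in records:
            call = rec.samples["mutant"]
            assert call.ad_alt == call.dp
            assert call.ad_ref == 0

    def test_same_seed_gives_bit_identical_vcf(
        self, tmp_path, toy_reference, toy_mutations, error_free_design
    ):
        genome, _ = toy_reference
        individuals = breed_bc1f2(
            error_free_design, toy_mutations, genome.lengths(), seed=4
        )
        pools = make_pools(individuals, error_free_design)
        paths = []
        for tag in ("a", "b"):
            records = simulate_pool_reads(
                pools, toy_mutations, error_free_design, seed=99
            )
            p = tmp_path / f"{tag}.vcf"
            write_vcf(records, ["mutant", "azygous", "wildtype"], p, genome)
            paths.append(p)
        assert paths[0].read_text() == paths[1].read_text()

    def test_azygous_af_at_causal_matches_one_third(
        self, toy_reference, toy_mutations, error_free_design
    ):
        """Mean azygous-pool AF at the causal site converges to 1/3."""
        genome, _ = toy_reference
        ci = toy_mutations.causal_index
        afs = []
        for seed in range(60):
            individuals = breed_bc1f2(
                error_free_design, toy_mutations, genome.lengths(), seed=seed
            )
            pools = make_pools(individuals, error_free_design)
            records = simulate_pool_reads(
                pools, toy_mutations, error_free_design, seed=1000 + seed
            )
            call = records[ci].samples["azygous"]
            afs.append(call.ad_alt / (call.ad_ref + call.ad_alt))
        mean = np.mean(afs)
        se = np.std(afs, ddof=1) / np.sqrt(len(afs))
        assert abs(mean - 1 / 3) < 3 * se


class TestLinkedAlleleFrequencyLaw:
    def test_linked_pair_matches_enumeration_oracle(self):
        """Simulated pool AFs at a linked marker match 1-r and (1+r)/3.

        One chromosome, causal at the centre, marker at a known map
        distance; the Haldane recombination fraction converts the map
        distance, and the exhaustive 16-gamete-pair oracle gives the exact
        expectations the simulation means must hit within 3 Monte-Carlo
        standard errors.
        """
        length = 1_000_000
        causal_pos = 200_000
        marker_pos = 500_000
        design = CrossDesign(
            misclassification=0.0, seq_error=0.0, coverage_range=(60.0, 60.0)
        )
        d_morgans = (marker_pos - causal_pos) / length * design.recomb_rate
        r = 0.5 * (1 - np.exp(-2 * d_morgans))  # Haldane
        r_frac = Fraction(r).limit_denominator(10**9)
        muts = MutationSet(
            [
                Mutation("chr1", causal_pos, "C", "T", is_causal=True),
                Mutation("chr1", marker_pos, "G", "A"),
            ]
        )
        lengths = {"chr1": length}
        obs = {"mutant": [], "azygous": []}
        for seed in range(200):
            individuals = breed_bc1f2(design, muts, lengths, seed=seed)
            pools = make_pools(individuals, design)
            for pool in obs:
                obs[pool].append(float(pools.fraction(pool)[1]))
        for pool in obs:
            expected = float(enumerate_pool_af(pool, r_frac))
            mean = np.mean(obs[pool])
            se = np.std(obs[pool], ddof=1) / np.sqrt(len(obs[pool]))
            assert abs(mean - expected) < 3 * se, (pool, mean, expected, se)


def test_master_seed_full_determinism(toy_reference, toy_mutations):
    """The whole generator chain is reproducible from one seed."""
    genome, _ = toy_reference
    design = CrossDesign()
    runs = []
    for _ in range(2):
        individuals = breed_bc1f2(design, toy_mutations, genome.lengths(), seed=21)
        pools = make_pools(individuals, design)
        records = simulate_pool_reads(pools, toy_mutations, design, seed=22)
        runs.append(
            [
                (r.chrom, r.pos, tuple(sorted((k, v.ad_ref, v.ad_alt, v.dp, v.gq) for k, v in r.samples.items())))
                for r in records
            ]
        )
    assert runs[0] == runs[1]
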