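# Methods

## Genetic model

The package models a single fully penetrant recessive locus in a
backcross-then-self design. A homozygous mutagenized line (all induced
SNPs homozygous) is crossed to wild type; the F1 is therefore
heterozygous at every induced site with all mutant alleles in coupling on
one haplotype. Selfing the F1 yields the BC₁F₂ population: each
individual is the union of two independent F1 gametes.

Meiosis follows the Haldane model (crossovers as a Poisson process with
no interference): per chromosome the number of crossovers is
Poisson(`recomb_rate`) and their positions are uniform on the physical
chromosome, which maps linearly onto the genetic map. The model is the
simplest one with closed-form expectations — for map distance d Morgans
the recombination fraction is r̃ = (1 − e^(−2d))/2 — so every simulated
statistic can be checked analytically. Chiasma interference, crossover
hotspots and non-uniform Morgans-per-megabase maps are deliberately out
of scope.

Conditioning on phenotype gives the pooled allele-frequency laws used
throughout: selecting homozygous mutants fixes the selected gamete to
carry the causal allele, so a marker at recombination fraction r has
expected pool frequency 1 − r; the complementary (azygous) selection is
the 1 MM : 2 Mm mixture with expectation (1 + r)/3. These closed forms
are verified in the tests against an exhaustive enumeration of the 16
ordered gamete pairs in exact rational arithmetic, and assume perfect
phenotype selection — phenotyping noise enters only through simulation.

## The synthetic experiment

`generate_reference` draws i.i.d. uniform ACGT sequence and plants a small
number of toy genes per chromosome (default 4, one per equal-width block,
random strand, 200–400 codons, half split by a 100–500 bp intron). Every
CDS starts ATG, ends with a stop and has no internal stop by
construction. The annotation is kept deliberately sparse — ~0.1% coding
fraction versus ~20–30% in a real compact plant genome — so that the
effect-severity ranking stage remains interpretable: with realistic gene
density a second linked missense variant would frequently share the causal
signature (as indeed happened in the real experiment the design mirrors,
resolved there by expression data, which is out of scope here).

`induce_mutations` plants `n_mutations` SNPs uniformly at random,
transition-biased (`transition_fraction` default 0.9, emulating NMU
chemistry). The causal mutation is forced onto the first base of a
CTC/CTT leucine codon inside a CDS, so the coding-strand change is C→T
and the protein change Leu→Phe. The per-genome mutation density is a
configuration default (300 SNPs over 10 Mb) chosen to give ~30 SNPs/Mb —
enough markers per window for a stable profile — with no claimed fidelity
to any particular mutagenized population.

Phenotype labels follow the causal dosage (mutant iff dosage 2), flipped
with `misclassification` probability 0.01 — a 1% phenotyping error rate
representing mis-scoring in a fluorescence screen. Fᵥ/Fₘ values are drawn
from label-conditional normals truncated to (0,1): wild-type-like
N(0.69, 0.05), mutant N(0.45, 0.07), chosen so the two classes straddle
the conventional 0.6 screening cutoff. These are configuration, not
claims about any instrument. Under these defaults the closed-form
expected accuracy of cutoff classification against the label is
0.25·Φ((0.6−0.45)/0.07) + 0.75·(1−Φ((0.6−0.69)/0.05)) ≈ 0.969, and the
simulation is tested against that expectation (not against a round
figure).

Pools take the first 45 mutant-labelled and first 54 wild-type-like
individuals; the wild-type bulk is 50 separate plants carrying no induced
alleles, serving purely as the background-exclusion track. Pooled reads
are simulated per site and pool as depth ~ Poisson(mean), mean ~
Uniform(45, 65) (each pool and site independently), and alt reads ~
Binomial(depth, p) with p the pool dosage fraction perturbed by the
per-read miscall rate `seq_error` (default 0.001). Read-level artifacts —
mapping bias, indels, duplicated regions — are not modelled, which is
precisely why the artifact-AF filter of the analysis (below) drops
nothing in clean simulations; passing tests therefore validate the
*logic* of the filters, not their real-data efficacy.

## Genotype quality

The simulator attaches a Phred-scaled genotype quality per pool and site:
the binomial likelihood of the observed allelic depths is evaluated over
a grid of pool allele fractions {0, 1/(2n), …, 1}, and GQ is
10·log₁₀(best/second-best), capped at 99. The default grid is n = 1,
i.e. the three diploid hypotheses {0, ½, 1} — the same shape as a diploid
caller's GQ, which is what downstream GQ≥30 thresholds were designed
for. A fine grid at the pool size (n = 45) is available but makes
adjacent hypotheses statistically indistinguishable at ~50× depth, so
every site would score GQ < 10 and a GQ threshold would be meaningless;
this is why the coarse grid is the default. The likelihood uses an error
prior of max(`seq_error`, 0.01) so the model stays proper when the
simulation itself is error-free (a fraction-1 hypothesis would otherwise
assign zero likelihood to a single reference read). Depth 0 yields GQ 0
and a missing call `./.`.

## Analysis stages and their thresholds

Quality filtering drops a site when, in the mutant pool, AF ≤ 0.3
(inclusive; artifact heuristic), informative depth < 10, or GQ < 30.
Drop counts are attributed to the first failing rule in the fixed order
(af, depth, gq) so reports are reproducible; filtering is order-
independent across records. By default only the mutant pool is judged
(it seeds the analysis); an any-pool mode exists.

Candidate selection keeps sites with mutant-pool AF ≥ 1.0 − tolerance,
azygous AF strictly < 0.5, and wild-type AF ≤ a noise floor. Two
defaults differ between the raw `FilterConfig` (exact 1.0, wild-type 0.0)
and the end-to-end pipeline, which uses tolerance 0.10 and wild-type
floor 0.05. The pipeline values are derived from its own noise model:
with 1% phenotype misclassification ~3% of the mutant bulk are
contaminants (95th percentile 4 of 45, allele deficit ≤ 8/90 ≈ 0.09), and
at 50× a single sequencing-error read in the wild-type pool (~5% of
sites at e = 0.001) would otherwise veto a true candidate. Exact
thresholds remain available for error-free analytic work.

The linkage-consistency score of a candidate is the fraction of other
variants within ±1 Mb whose mutant-pool AF ≥ 0.8 (missing when fewer
than 3 neighbours) — a genuine causal variant sits on a selected
haplotype and should be co-fixed with its neighbours.

The region scan computes sliding-window means of per-variant mutant-pool
AF. The profile is *descriptive* and is built from all sites — the
candidate filters act on candidate selection only; building the profile
from quality-filtered records punches holes into the plateau wherever
borderline-GQ flank sites were removed and fragments the detected region.
Window auto-sizing starts at 1/50 of the chromosome (recovering 1 Mb at
a ~50 Mb real chromosome) but widens until a window holds ~12 expected
variants, because means over 2–3 variants are too noisy to threshold and
empty windows (which conservatively break plateau runs rather than
interpolate) become common; the step is a tenth of the window. The
candidate region is the longest run of ≥2 consecutive windows with mean
AF ≥ 0.9 (ties leftmost), its peak the midpoint of the run's best
window. Raising the threshold never widens the region, and the whole
construction is shift-invariant.

Effect annotation classifies each candidate by context (intergenic,
intronic, CDS) and, for coding hits, substitutes the (strand-
complemented) alternate base into the phase-aware codon and translates
under the hard-coded standard genetic code (unit-tested against an
independent published table). Classes: synonymous, missense, nonsense,
stop-loss, start-loss (codon 1 losing Met). Exon-boundary variants are
classified by the base's own location; splice-site effects are out of
scope. When a gene has several transcripts the longest CDS is used by
default. Ranking is severity first (nonsense/start-loss, missense,
synonymous, intronic, intergenic), then linkage score descending
(missing last), then position. The annotation path is property-tested
against a brute-force oracle that rebuilds the mutant genome, re-splices,
translates with an independent library and diffs the proteins.

## Statistics utilities

Segregation testing is a Pearson χ² with 1 df against the 3:1
expectation, no Yates correction by default at n ≈ 300 (flag available);
p-values come from the χ² survival function (regularized incomplete
gamma, via scipy). The Fᵥ/Fₘ cutoff classifies *strictly below* 0.6 as
mutant — the mutant phenotype is a reduced ratio, so the boundary value
is wild-type-like. Isotope math is done in dimensionless fractions
internally, with ‰ only at the CLI boundary, and the identity
(δa−δp)/(1+δp) ≡ Ra/Rp − 1 is enforced to machine precision in tests.

## Determinism

Every stochastic operation takes an explicit seed and uses a single
`numpy.random.Generator` with documented draw order. The pipeline expands
its master seed via `SeedSequence.spawn` into one child per stage
(reference, mutagenesis, breeding, reads), so a fixed seed reproduces
every intermediate file bit for bit and single stages can be re-run in
isolation.

## Problem sizes used in validation

The statistical test suite uses: 1000 simulated populations of n = 300
for the segregation ratio; 200 replicate populations for pool-AF
convergence at map distances {0, 0.1, 0.25} Morgans at 60× error-free
coverage; 100 seeded end-to-end experiments on 2 × 5 Mb genomes with 300
SNPs at 50× for causal recovery; and ≥1000 random coding variants for
the annotation oracle. Under the default noise model (1% phenotype
misclassification), per-experiment survival of the causal variant through
the candidate filters is analytically ≈ 0.94–0.95 — the binomial and
pool-sampling noise at 50× occasionally pushes the observed azygous AF to
≥ 0.5 or the mutant AF below the tolerance — so recovery rates just below
95/100 are the expected behaviour of the method at these settings, not a
regression; error-free phenotyping raises per-run survival to ≈ 0.98.

## Known limitations

- No natural standing variation: the wild-type pool is trivially clean,
  so the background-exclusion filter is exercised only logically.
- No read-level simulation (FASTQ/alignment), no indels or CNVs, no
  multi-allelic sites (skipped, not decomposed, on input).
- Single causal locus with full penetrance; no QTL-style partial effects
  and no confidence intervals on the region bounds.
- The Fᵥ/Fₘ distributions are stylised two-component normals; real
  screens show CO₂- and stage-dependent shifts the generator ignores.
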