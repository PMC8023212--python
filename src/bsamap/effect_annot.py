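"""Coding-consequence annotation of candidate variants.

Classifies each variant by genomic context (intergenic, intronic, CDS) and,
for CDS hits, computes the strand- and phase-aware codon substitution and
amino-acid change under the standard nuclear genetic code.  Candidates are
prioritised by predicted severity, since a causal lesion for a strong
recessive phenotype is expected to alter the protein: premature stops and
start losses rank above missense changes, which rank above synonymous and
non-coding hits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Genome, GeneModel, VariantRecord

# Standard genetic code, hard-coded and unit-tested against an independent
# published table.  '*' denotes stop.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SEVERITY_RANK = {
    "nonsense": 0,
    "start_loss": 0,
    "stop_loss": 0,
    "missense": 1,
    "synonymous": 2,
    "intronic": 3,
    "intergenic": 4,
}


class AnnotationError(ValueError):
    pass


@dataclass
class Context:
    """Genomic context of a variant: intergenic, intronic(gene) or cds(gene, offset)."""

    kind: str  # "intergenic" | "intronic" | "cds"
    gene_id: str | None = None
    cds_offset: int | None = None  # 0-based, translation orientation


@dataclass
class EffectAnnotation:
    variant: VariantRecord
    gene_id: str | None
    effect_class: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_pos: int | None = None  # 1-based residue index
    linkage_score: float | None = None

    def codon_change(self) -> str | None:
        if self.codon_ref is None:
            return None
        return f"{self.codon_ref}>{self.codon_alt}"

    def aa_change(self) -> str | None:
        if self.aa_ref is None:
            return None
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def locate(variant: VariantRecord, gene_models: list[GeneModel]) -> list[Context]:
    """All genomic contexts of a variant (one per overlapping gene).

    A position inside a gene's CDS footprint but between CDS segments is
    intronic; inside a segment it is coding, with the 0-based offset in the
    spliced CDS counted in translation orientation (for a minus-strand
    gene the genomically last CDS base has offset 0).  With no overlapping
    gene the single context is intergenic.
    """
    contexts: list[Context] = []
    for model in gene_models:
        if model.chrom != variant.chrom:
            continue
        span_start, span_end = model.span()
        if not span_start <= variant.pos <= span_end:
            continue
        offset = model.genomic_to_cds_offset(variant.pos)
        if offset is None:
            contexts.append(Context("intronic", model.gene_id))
        else:
            contexts.append(Context("cds", model.gene_id, offset))
    if not contexts:
        contexts.append(Context("intergenic"))
    return contexts


def annotate_effect(
    variant: VariantRecord,
    context: Context,
    genome: Genome,
    gene_models: list[GeneModel],
) -> EffectAnnotation:
    """Codon and amino-acid consequence of a coding variant.

    Requires a cds context.  The alternate base is complemented for
    minus-strand genes before substitution into the codon.  Raises
    :class:`AnnotationError` when the record's ref allele disagrees with
    the genome (a coordinate bug, not a biological state).
    """
    if context.kind != "cds":
        raise AnnotationError("annotate_effect requires a cds context")
    model = next(m for m in gene_models if m.gene_id == context.gene_id)
    if genome.base(variant.chrom, variant.pos) != variant.ref:
        raise AnnotationError(
            f"ref allele {variant.ref} disagrees with genome at "
            f"{variant.chrom}:{variant.pos}"
        )
    cds = model.cds_sequence(genome)
    offset = context.cds_offset
    codon_idx, within = divmod(offset, 3)
    codon_ref = cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt_base = variant.alt if model.strand == "+" else _COMPLEMENT[variant.alt]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    elif aa_ref == "*":
        effect = "stop_loss"
    elif codon_idx == 0 and aa_ref == "M":
        effect = "start_loss"
    else:
        effect = "missense"
    return EffectAnnotation(
        variant=variant,
        gene_id=model.gene_id,
        effect_class=effect,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        aa_pos=codon_idx + 1,
    )


def annotate_candidates(
    candidates: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: Genome,
    linkage_scores: dict[tuple[str, int], float | None] | None = None,
) -> list[EffectAnnotation]:
    """Annotate and severity-rank candidate variants.

    Each candidate gets its most severe annotation across overlapping
    genes.  Sorting: severity (nonsense/start-loss first, then missense,
    synonymous, intronic, intergenic), then linkage-consistency score
    descending (missing last), then chromosome and position.
    """
    annotations: list[EffectAnnotation] = []
    for cand in candidates:
        best: EffectAnnotation | None = None
        for ctx in locate(cand, gene_models):
            if ctx.kind == "cds":
                ann = annotate_effect(cand, ctx, genome, gene_models)
            else:
                ann = EffectAnnotation(cand, ctx.gene_id, ctx.kind)
            if best is None or SEVERITY_RANK[ann.effect_class] < SEVERITY_RANK[best.effect_class]:
                best = ann
        if linkage_scores is not None:
            best.linkage_score = linkage_scores.get((cand.chrom, cand.pos))
        annotations.append(best)
    annotations.sort(
        key=lambda a: (
            SEVERITY_RANK[a.effect_class],
            -(a.linkage_score if a.linkage_score is not None else -1.0),
            a.variant.chrom,
            a.variant.pos,
        )
    )
    return annotations
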