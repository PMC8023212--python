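"""Readers and writers for the plain-text formats the pipeline touches.

The pipeline exchanges four formats: FASTA reference sequences, GFF3 gene
models, a narrow VCF 4.2 dialect carrying pooled read counts
(``GT:AD:DP:GQ``), and tab-separated report tables.  Coordinate conventions
are explicit and centralised here: VCF and GFF3 are 1-based inclusive on
disk, all internal interval arithmetic is 0-based half-open, and the two
helpers :func:`to_zero_based` / :func:`to_one_based` are the only place the
conversion happens.

The VCF dialect is deliberately minimal: bi-allelic SNPs only, one sample
column per pool, FILTER unused (filtering decisions live in the report
tables so the records remain immutable evidence).  Multi-allelic rows and
indels are skipped with a counter rather than decomposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger("bsamap")

VALID_BASES = frozenset("ACGTN")
DNA = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome / FASTA
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """An ordered set of named chromosomes over the ACGT(N) alphabet."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def base(self, chrom: str, pos_1based: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos_1based - 1]

    def slice(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence of a 0-based half-open interval."""
        return self.chromosomes[chrom][start0:end0]


def read_fasta(path: str | Path) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Parsing is case-insensitive; sequences are stored upper-case.  Raises
    :class:`FormatError` naming the offending line for empty records,
    duplicate names, or characters outside ACGTN.
    """
    chromosomes: dict[str, str] = {}
    name: str | None = None
    header_line = 0
    parts: list[str] = []

    def _flush(at_line: int) -> None:
        nonlocal name, parts
        if name is None:
            return
        seq = "".join(parts)
        if not seq:
            raise FormatError(
                f"{path}: empty record {name!r} (header at line {header_line})"
            )
        chromosomes[name] = seq
        name, parts = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in chromosomes:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate record name {name!r}"
                    )
                header_line = lineno
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid character(s) "
                        f"{''.join(sorted(bad))!r} in record {name!r}"
                    )
                parts.append(seq)
        _flush(lineno)
    if not chromosomes:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(chromosomes)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Gene models / GFF3
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A single coding transcript: ordered CDS segments on one chromosome.

    ``cds_segments`` are (start, end) pairs in 1-based inclusive *genomic*
    coordinates, sorted in genomic order regardless of strand; ``phases``
    are the GFF3 frame offsets, index-aligned with the segments.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    phases: list[int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.cds_segments) != len(self.phases):
            raise FormatError(f"{self.gene_id}: phases/segments length mismatch")
        last_end = 0
        for start, end in self.cds_segments:
            if start <= last_end:
                raise FormatError(
                    f"{self.gene_id}: CDS segments overlap or are unsorted"
                )
            if end < start:
                raise FormatError(f"{self.gene_id}: segment end < start")
            last_end = end
        if self.effective_cds_length() % 3 != 0:
            raise FormatError(
                f"{self.gene_id}: CDS length {self.effective_cds_length()} "
                "not divisible by 3 after phase adjustment"
            )

    # -- translation-order helpers -------------------------------------

    def segments_in_translation_order(self) -> list[tuple[int, int]]:
        if self.strand == "+":
            return list(self.cds_segments)
        return list(reversed(self.cds_segments))

    def first_phase(self) -> int:
        """Phase of the first segment in translation order."""
        return self.phases[0] if self.strand == "+" else self.phases[-1]

    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    def effective_cds_length(self) -> int:
        return self.cds_length() - self.first_phase()

    def cds_sequence(self, genome: Genome) -> str:
        """Spliced CDS in translation orientation (phase-trimmed)."""
        pieces = []
        for start, end in self.cds_segments:
            s0, e0 = to_zero_based(start, end)
            pieces.append(genome.slice(self.chrom, s0, e0))
        seq = "".join(pieces)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq[self.first_phase() :]

    def genomic_to_cds_offset(self, pos_1based: int) -> int | None:
        """0-based offset within the spliced, phase-trimmed CDS.

        Returns None when the position falls outside every CDS segment.
        Offsets count in translation orientation: for a minus-strand gene
        the genomically *last* CDS base has offset 0.
        """
        offset = 0
        for start, end in self.segments_in_translation_order():
            if start <= pos_1based <= end:
                if self.strand == "+":
                    offset += pos_1based - start
                else:
                    offset += end - pos_1based
                offset -= self.first_phase()
                return offset if offset >= 0 else None
            offset += end - start + 1
        return None

    def span(self) -> tuple[int, int]:
        """(start, end) 1-based inclusive of the whole CDS footprint."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]


def read_gff3(
    path: str | Path, mrna_policy: str = "first"
) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file.

    Models whose CDS length is not divisible by 3 after phase adjustment
    are skipped with a warning.  ``mrna_policy`` selects which transcript
    of a gene is kept: ``"first"`` (default), ``"longest"`` (longest CDS)
    or ``"all"``.
    """
    if mrna_policy not in {"first", "longest", "all"}:
        raise ValueError(f"unknown mrna_policy {mrna_policy!r}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        candidates: list[GeneModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            segments, phases = [], []
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                if cds.frame in (None, "."):
                    raise FormatError(
                        f"{path}: CDS of {mrna.id} at {cds.start} has no phase"
                    )
                segments.append((cds.start, cds.end))
                phases.append(int(cds.frame))
            if not segments:
                continue
            try:
                candidates.append(
                    GeneModel(gene.id, gene.seqid, gene.strand, segments, phases)
                )
            except FormatError as exc:
                logger.warning("skipping transcript of %s: %s", gene.id, exc)
        if not candidates:
            continue
        if mrna_policy == "all":
            models.extend(candidates)
        elif mrna_policy == "longest":
            models.append(max(candidates, key=lambda m: m.cds_length()))
        else:
            models.append(candidates[0])
    # orphan CDS features (no mRNA parent) violate the expected hierarchy
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="mRNA"))
        if not parents:
            raise FormatError(f"{path}: CDS at {cds.seqid}:{cds.start} has no mRNA parent")
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/CDS rows for a set of single-transcript gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span()
            common = f"{m.chrom}\tbsamap\t"
            fh.write(
                f"{common}gene\t{start}\t{end}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.1"
            fh.write(
                f"{common}mRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            for (s, e), phase in zip(m.cds_segments, m.phases):
                fh.write(
                    f"{common}CDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Variants / VCF dialect
# ---------------------------------------------------------------------------

POOL_NAMES = ("mutant", "azygous", "wildtype")


@dataclass
class SampleCall:
    """Per-pool evidence at one site."""

    gt: str
    ad_ref: int
    ad_alt: int
    dp: int
    gq: int

    def __post_init__(self) -> None:
        if self.ad_ref + self.ad_alt > self.dp:
            raise FormatError("AD sum exceeds DP")
        if self.gq < 0:
            raise FormatError("negative GQ")


@dataclass
class VariantRecord:
    """One bi-allelic SNP with per-pool read-count evidence."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    samples: dict[str, SampleCall]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos}: ref equals alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise FormatError(f"{self.chrom}:{self.pos}: not a SNP")


REQUIRED_FORMAT_KEYS = ("GT", "AD", "DP", "GQ")


def read_vcf(
    path: str | Path, skip_stats: dict[str, int] | None = None
) -> list[VariantRecord]:
    """Parse the pipeline's VCF dialect into :class:`VariantRecord` rows.

    Multi-allelic sites and indels are skipped; counts of skipped rows are
    logged and, when ``skip_stats`` (a dict) is supplied, accumulated into
    it under ``"multiallelic"`` and ``"indel"``.
    """
    stats = skip_stats if skip_stats is not None else {}
    stats.setdefault("multiallelic", 0)
    stats.setdefault("indel", 0)
    records: list[VariantRecord] = []
    sample_names: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                sample_names = cols[9:]
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(f"{path}:{lineno}: too few columns")
            chrom, pos, _, ref, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            if "," in alt:
                stats["multiallelic"] += 1
                continue
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                stats["indel"] += 1
                continue
            fmt_keys = cols[8].split(":")
            missing = [k for k in REQUIRED_FORMAT_KEYS if k not in fmt_keys]
            if missing:
                raise FormatError(
                    f"{path}:{lineno}: record {chrom}:{pos} missing FORMAT "
                    f"key(s) {','.join(missing)}"
                )
            samples: dict[str, SampleCall] = {}
            for name, cell in zip(sample_names, cols[9:]):
                values = dict(zip(fmt_keys, cell.split(":")))
                ad_ref, ad_alt = (int(x) for x in values["AD"].split(","))
                samples[name] = SampleCall(
                    gt=values["GT"],
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    dp=int(values["DP"]),
                    gq=int(values["GQ"]),
                )
            records.append(VariantRecord(chrom, pos, ref, alt, samples))
    if stats["multiallelic"] or stats["indel"]:
        logger.info(
            "read_vcf: skipped %d multi-allelic and %d indel rows",
            stats["multiallelic"],
            stats["indel"],
        )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    pool_names: Sequence[str],
    path: str | Path,
    genome: Genome | None = None,
) -> None:
    """Write records as minimal VCF 4.2 with FORMAT ``GT:AD:DP:GQ``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if genome is not None:
            for name, length in genome.lengths().items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
            'Description="Phred-scaled genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pool_names)
            + "\n"
        )
        for rec in records:
            cells = []
            for name in pool_names:
                call = rec.samples[name]
                cells.append(
                    f"{call.gt}:{call.ad_ref},{call.ad_alt}:{call.dp}:{call.gq}"
                )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t.\t"
                "GT:AD:DP:GQ\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv(rows: Sequence[dict], columns: Sequence[str], path: str | Path) -> None:
    """Tab-delimited report with a header row; None rendered as 'NA'."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "NA" if row.get(c) is None else str(row.get(c)) for c in columns
                )
                + "\n"
            )
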