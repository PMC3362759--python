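"""Gene models: strand-aware exon/junction structure parsed from GTF.

Internal coordinates are 0-based half-open genome-wide; GTF I/O converts
1-based inclusive coordinates at the boundary. Genes are grouped by the
``gene_id`` attribute (annotation semantics), never by genomic overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeInterval",
    "Transcript",
    "Gene",
    "Junction",
    "read_gtf",
    "write_gtf",
    "internal_exons",
    "junctions",
    "exons_to_bed",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A closed-open genomic interval; length = end - start."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Transcript:
    """An ordered multi-exon transcript (exons in genomic order)."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomeInterval]
    coding_flag: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            # introns must have length >= 1
            if b.start - a.end < 1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping/abutting exons {a} {b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.strand != self.strand:
                raise ValueError(f"{self.gene_id}: inconsistent transcript {t.transcript_id}")


@dataclass(frozen=True)
class Junction:
    """An intron, by its splice-site boundary coordinates.

    ``donor_pos`` is the exon/intron boundary at the intron 5' end and
    ``acceptor_pos`` the boundary at the intron 3' end, both in transcript
    orientation. On the + strand donor < acceptor genomically; roles swap
    on the - strand.
    """

    donor_pos: int
    acceptor_pos: int
    strand: str


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, coding_only: bool = False) -> list[Gene]:
    """Parse exon features from a GTF file into validated genes.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    A transcript is considered coding when its records carry
    ``transcript_biotype``/``gene_biotype`` ``protein_coding`` or any CDS
    feature; annotations without biotypes can mark coding status with a
    custom ``coding`` attribute. Transcripts violating structural
    invariants are skipped with a warning, not fatal.
    """
    exon_rows: dict[str, list[GenomeInterval]] = {}
    meta: dict[str, dict] = {}
    coding_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("%s:%d: short GTF line skipped", path, lineno)
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            if feature == "CDS":
                coding_ids.add(tid)
                continue
            if feature != "exon":
                continue
            try:
                iv = GenomeInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                logger.warning("%s:%d: invalid exon skipped (%s)", path, lineno, exc)
                continue
            exon_rows.setdefault(tid, []).append(iv)
            biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
            coding = attrs.get("coding", "")
            if biotype == "protein_coding" or coding in ("1", "true", "True"):
                coding_ids.add(tid)
            meta[tid] = {
                "gene_id": attrs.get("gene_id", tid),
                "strand": strand,
                "chrom": chrom,
            }

    genes: dict[str, Gene] = {}
    for tid, exons in exon_rows.items():
        info = meta[tid]
        try:
            t = Transcript(
                transcript_id=tid,
                gene_id=info["gene_id"],
                strand=info["strand"],
                exons=exons,
                coding_flag=tid in coding_ids,
            )
        except ValueError as exc:
            logger.warning("transcript %s skipped: %s", tid, exc)
            continue
        if coding_only and not t.coding_flag:
            continue
        g = genes.get(t.gene_id)
        if g is None:
            g = Gene(t.gene_id, info["chrom"], info["strand"], [])
            genes[t.gene_id] = g
        if t.strand != g.strand:
            logger.warning("transcript %s skipped: strand differs from gene", tid)
            continue
        g.transcripts.append(t)
    return [genes[k] for k in sorted(genes)]


def write_gtf(genes: list[Gene], path) -> None:
    """Write exon features (plus a CDS line per coding transcript) as GTF."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'coding "{1 if t.coding_flag else 0}";'
                    )
                    fh.write(
                        f"{e.chrom}\tepisplice\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )


def internal_exons(t: Transcript) -> list[GenomeInterval]:
    """Exons excluding the transcript's first and last (either strand the
    genomic extremes are the transcript's terminal exons)."""
    return t.exons[1:-1]


def junctions(t: Transcript) -> list[Junction]:
    """One junction per intron, donor/acceptor roles assigned by strand."""
    out = []
    for a, b in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            out.append(Junction(donor_pos=a.end, acceptor_pos=b.start, strand="+"))
        else:
            out.append(Junction(donor_pos=b.start, acceptor_pos=a.end, strand="-"))
    return out


def exons_to_bed(genes: list[Gene], path) -> None:
    """BED6 export of every transcript's exons (name = transcript_id)."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\t{e.start}\t{e.end}\t{t.transcript_id}\t0\t{t.strand}\n"
                    )
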