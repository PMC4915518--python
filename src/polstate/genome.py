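"""Gene annotation and genome containers.

Coordinates are 0-based half-open throughout the package; GFF3 conversion
happens at the I/O boundary.  Strand is "+" or "-".  Transcript classes follow
the yeast annotation convention: protein-coding mRNAs plus the CUT / SUT
classes of lncRNA and snoRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

TRANSCRIPT_CLASSES = ("mRNA", "CUT", "SUT", "snoRNA")


@dataclass(frozen=True)
class Gene:
    """A transcript with class label and (optional) exon structure.

    ``exons`` are genomic intervals in ascending coordinate order; introns are
    derived as the gaps between consecutive exons.  ``expression`` is the
    expected polymerase crosslinking density (reads/nt) when known.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: tuple[tuple[int, int], ...] = ()
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.name}: exon ({s},{e}) outside transcript")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (single-nt anchor, strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pa(self) -> int:
        """Poly(A) / 3' end anchor (last transcribed nt, strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = sorted(self.exons)
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    @property
    def has_intron(self) -> bool:
        return len(self.exons) > 1

    @property
    def exon1_length(self) -> int | None:
        """TSS -> 5' splice site distance (nt); None for intronless genes."""
        if not self.has_intron:
            return None
        ex = sorted(self.exons)
        return (ex[0][1] - ex[0][0]) if self.strand == "+" else (ex[-1][1] - ex[-1][0])

    @property
    def five_prime_ss(self) -> int | None:
        """Genomic position of the first 5' splice site (intron-side base)."""
        if not self.has_intron:
            return None
        introns = self.introns
        return introns[0][0] if self.strand == "+" else introns[-1][1] - 1

    def to_transcript(self, genomic_pos: int) -> int:
        """Genomic position -> nt offset from the TSS along the transcript."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos

    def with_expression(self, expression: float) -> "Gene":
        return replace(self, expression=expression)


@dataclass
class GenomeModel:
    """A (synthetic or real) genome: chromosome sizes plus annotation.

    ``nucleosome_repeat`` and ``first_nucleosome_offset`` describe the regular
    nucleosome array laid down gene-by-gene from the TSS; the first nucleosome
    occupies [TSS+offset, TSS+offset+repeat) in transcript orientation.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)
    nucleosome_repeat: int = 150
    first_nucleosome_offset: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.name}: unknown chromosome {g.chrom}")
            if g.end > sizes[g.chrom]:
                raise ValueError(f"gene {g.name}: extends past end of {g.chrom}")
            if g.biotype not in TRANSCRIPT_CLASSES and g.biotype != "unknown":
                raise ValueError(f"gene {g.name}: unknown class {g.biotype!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_of_class(self, biotype: str) -> list[Gene]:
        return [g for g in self.genes if g.biotype == biotype]

    def nucleosomes_for_gene(self, gene: Gene) -> list[tuple[int, int]]:
        """Genomic intervals of the gene's nucleosome array (ascending order)."""
        out = []
        off = self.first_nucleosome_offset
        rep = self.nucleosome_repeat
        t = off
        while t + rep <= gene.length:
            if gene.strand == "+":
                out.append((gene.start + t, gene.start + t + rep))
            else:
                out.append((gene.end - t - rep, gene.end - t))
            t += rep
        return sorted(out)

    def nucleosome_intervals(self) -> list[tuple[str, int, int, str]]:
        """All nucleosome intervals as (chrom, start, end, strand) records."""
        out = []
        for g in self.genes:
            for s, e in self.nucleosomes_for_gene(g):
                out.append((g.chrom, s, e, g.strand))
        return out
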