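"""Shared domain types for the APA divergence pipeline.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based; intervals are half-open ``[start, end)``
unless a field is explicitly documented as an inclusive single base (cleavage
sites, read anchors).  On-disk formats (VCF, GTF, tailmap TSV) are 1-based
inclusive and converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Allele / strain labels.  "BL" is the reference strain (genome A, the
#: C57BL/6J analogue); "SP" is the alternate strain (genome B, SPRET/EiJ).
BL = "BL"
SP = "SP"

PAS_CATEGORIES = ("Terminal", "Tandem3UTR", "AltLastExon", "Intronic", "InternalExon")


@dataclass(frozen=True)
class TailRead:
    """One aligned 3'-end read reduced to its tailmap record.

    ``pos`` is the protocol's quantification anchor (0-based): the aligned
    3'-end base for 3' READS reads, the aligned 5'-end base for 3' mRNA-Seq
    reads.  ``tail_t`` is the number of non-genomic T at the read 5' end
    (evidence of a genuine poly(A) tail).  ``allele`` is the simulated true
    allele of origin ("BL"/"SP") or "." when unknown.
    """

    chrom: str
    pos: int
    strand: str
    tail_t: int
    sample: str
    replicate: int
    allele: str
    read_id: str


@dataclass(frozen=True)
class GenomicWindow:
    """Strand-annotated window with an anchor (cleavage site) inside it.

    Stored on the forward strand (``start < end`` in genome coordinates);
    upstream/downstream semantics are resolved at sequence-extraction time.
    """

    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    anchor: int  # 0-based cleavage-site base, start <= anchor < end

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")
        if not self.start <= self.anchor < self.end:
            raise ValueError("anchor outside window")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class PasCluster:
    """A called cleavage-site cluster and its empirical-FDR statistics.

    ``site`` is the representative cleavage site (position of maximum read
    coverage).  ``r`` is the PASS-read count R; ``e`` the enrichment of PASS
    coverage over RNA-Seq background coverage; ``p_emp`` the dominance
    p-value Pi = n_i / N and ``q`` the estimated FDR Qi.
    """

    chrom: str
    strand: str
    site: int
    span_start: int
    span_end: int  # inclusive member-site bounds
    r: int
    e: float = 0.0
    p_emp: float = 1.0
    q: float = 1.0
    replicate: int = 0

    @property
    def size(self) -> int:
        """Cluster size in nt (member-site span, inclusive)."""
        return self.span_end - self.span_start + 1


@dataclass
class ReferencePas:
    """A reference pAs: 48-nt window in strain-A coordinates plus annotation."""

    pas_id: str
    window: GenomicWindow
    source: str  # "A-only" | "B-only" | "shared"
    r: int
    gene_id: str | None = None
    biotype: str = "intergenic"
    category: str | None = None


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # sorted genomic [start, end)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def end3(self, strand: str) -> int:
        """0-based coordinate of the transcript's 3'-most base."""
        return self.exons[-1][1] - 1 if strand == "+" else self.exons[0][0]

    def last_exon(self, strand: str) -> tuple[int, int]:
        return self.exons[-1] if strand == "+" else self.exons[0]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GeneAnnotation:
    """In-memory gene models, indexable by chromosome."""

    genes: dict[str, Gene] = field(default_factory=dict)

    def add(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene

    def by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)
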