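"""Cross-strain reference pAs construction.

Strain-specific clusters survive only if the -124..+24 region flanking their
cleavage site can be lifted to the other strain's genome and back identically
(the functional equivalent of the reciprocal UCSC LiftOver filter, driven by
the VCF-derived chain).  Survivors from both strains are merged into one
reference set in strain-A coordinates, then assigned a gene, biotype and one
of five positional categories.
"""

from __future__ import annotations

import numpy as np

from .cluster import WINDOW_HALF
from .liftover import VariantMap
from .types import Gene, GeneAnnotation, GenomicWindow, PasCluster, ReferencePas

FLANK_UP, FLANK_DOWN = 124, 24  # reciprocal-mappability flank around the site

_BIOTYPE_PRIORITY = {"protein_coding": 0, "lincRNA": 1, "other_ncRNA": 2}


def _flank_span(site: int, strand: str) -> tuple[int, int]:
    """Half-open genomic span of the strand-aware -124..+24 flank."""
    if strand == "+":
        return site - FLANK_UP, site + FLANK_DOWN + 1
    return site - FLANK_DOWN, site + FLANK_UP + 1


def mappability_filter(clusters: list[PasCluster], vmap: VariantMap,
                       source_strain: str = "A") -> list[PasCluster]:
    """Keep clusters whose cleavage-site flank lifts over reciprocally.

    ``source_strain`` "A" filters A-coordinate clusters against genome B;
    "B" filters B-coordinate clusters and re-expresses survivors in A
    coordinates (representative site mapped through the chain).
    """
    direction = "AtoB" if source_strain == "A" else "BtoA"
    out: list[PasCluster] = []
    for c in clusters:
        lo, hi = _flank_span(c.site, c.strand)
        length = (vmap.chrom_lengths_a if source_strain == "A" else vmap.chrom_lengths_b)[c.chrom]
        if lo < 0 or hi > length:
            continue
        mapped = vmap.liftover_window(c.chrom, lo, hi, direction, require_reciprocal=True)
        if mapped is None:
            continue
        if source_strain == "B":
            site_a = vmap.liftover_position(c.chrom, c.site, "BtoA")
            if site_a is None:
                continue
            c = replace_site(c, site_a)
        out.append(c)
    return out


def replace_site(c: PasCluster, new_site: int) -> PasCluster:
    shift = new_site - c.site
    return PasCluster(chrom=c.chrom, strand=c.strand, site=new_site,
                      span_start=c.span_start + shift, span_end=c.span_end + shift,
                      r=c.r, e=c.e, p_emp=c.p_emp, q=c.q, replicate=c.replicate)


def merge_reference(clusters_a: list[PasCluster], clusters_b_in_a: list[PasCluster],
                    chrom_lengths: dict[str, int],
                    merge_distance: int = 24) -> list[ReferencePas]:
    """Combine the two strains' surviving clusters into one reference set.

    Same-strand representative sites within ``merge_distance`` collapse to a
    single shared entry anchored at the higher-R member's site; the rest pass
    through as strain-specific.  Windows are the fixed -24..+24 span around
    the chosen site.
    """
    used_b: set[int] = set()
    entries: list[tuple[PasCluster, str]] = []
    b_by_key: dict[tuple[str, str], list[PasCluster]] = {}
    for c in clusters_b_in_a:
        b_by_key.setdefault((c.chrom, c.strand), []).append(c)
    for key in b_by_key:
        b_by_key[key].sort(key=lambda c: c.site)
    for ca in sorted(clusters_a, key=lambda c: (c.chrom, c.strand, c.site)):
        cands = b_by_key.get((ca.chrom, ca.strand), [])
        sites = np.array([c.site for c in cands])
        match = None
        if len(sites):
            order = np.argsort(np.abs(sites - ca.site), kind="stable")
            for j in order:
                if abs(int(sites[j]) - ca.site) > merge_distance:
                    break
                if id(cands[j]) not in used_b:
                    match = cands[j]
                    break
        if match is None:
            entries.append((ca, "A-only"))
        else:
            used_b.add(id(match))
            keep = ca if ca.r >= match.r else match
            merged = PasCluster(chrom=ca.chrom, strand=ca.strand, site=keep.site,
                                span_start=min(ca.span_start, match.span_start),
                                span_end=max(ca.span_end, match.span_end),
                                r=ca.r + match.r, e=keep.e, p_emp=keep.p_emp, q=keep.q)
            entries.append((merged, "shared"))
    for key, cands in b_by_key.items():
        for c in cands:
            if id(c) not in used_b:
                entries.append((c, "B-only"))
    entries.sort(key=lambda t: (t[0].chrom, t[0].strand, t[0].site))
    out: list[ReferencePas] = []
    for i, (c, source) in enumerate(entries):
        L = chrom_lengths[c.chrom]
        win = GenomicWindow(c.chrom, c.strand,
                            max(0, c.site - WINDOW_HALF),
                            min(L, c.site + WINDOW_HALF + 1), c.site)
        out.append(ReferencePas(pas_id=f"pas{i:05d}", window=win, source=source, r=c.r))
    return out


# ------------------------------------------------------------ annotation
def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _assign_gene(win: GenomicWindow, genes: list[Gene]) -> Gene | None:
    best: tuple[int, int, str, Gene] | None = None
    for g in genes:
        if g.strand != win.strand or g.chrom != win.chrom:
            continue
        ov = _overlap(win.start, win.end, g.start, g.end)
        if ov <= 0:
            continue
        key = (_BIOTYPE_PRIORITY.get(g.biotype, 3), -ov, g.gene_id)
        if best is None or key < (best[0], best[1], best[2]):
            best = (*key, g)
    return best[3] if best else None


def _categorize(site: int, gene: Gene, terminal_tolerance: int) -> str:
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    strand = gene.strand
    ends = [t.end3(strand) for t in gene.transcripts]
    if any(abs(site - e) <= terminal_tolerance for e in ends):
        return "Terminal"
    # longest-ending transcript: 3' end most downstream in transcript direction
    def downstreamness(t):
        return t.end3(strand) if strand == "+" else -t.end3(strand)

    rep_tx = max(gene.transcripts, key=downstreamness)
    le = rep_tx.last_exon(strand)
    if le[0] <= site < le[1]:
        return "Tandem3UTR"
    for t in gene.transcripts:
        if t is rep_tx:
            continue
        alt_le = t.last_exon(strand)
        if alt_le[0] <= site < alt_le[1]:
            return "AltLastExon"
    for es, ee in rep_tx.exons:
        if es <= site < ee:
            return "InternalExon"
    return "Intronic"


def annotate_pas(reference: list[ReferencePas], annotation: GeneAnnotation,
                 terminal_tolerance: int = 50) -> list[ReferencePas]:
    """Assign gene, biotype and positional category to each reference pAs.

    Gene assignment is by window/gene-span overlap with biotype priority
    protein_coding > lincRNA > other_ncRNA (ties broken by longest overlap);
    the five categories apply only to protein-coding assignments and use the
    representative cleavage site: Terminal within ``terminal_tolerance`` nt
    of any annotated transcript 3' end, then tandem 3' UTR / alternative
    last exon / internal exon / intronic by containment.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for pas in reference:
        gene = _assign_gene(pas.window, by_chrom.get(pas.window.chrom, []))
        if gene is None:
            pas.gene_id, pas.biotype, pas.category = None, "intergenic", None
            continue
        pas.gene_id = gene.gene_id
        pas.biotype = gene.biotype
        pas.category = (
            _categorize(pas.window.anchor, gene, terminal_tolerance)
            if gene.biotype == "protein_coding"
            else None
        )
    return reference


def reference_from_truth(truth, chrom_lengths: dict[str, int]) -> list[ReferencePas]:
    """Reference windows built directly from planted cleavage sites.

    Convenience for analyses that start from known sites (quantification,
    divergence, flank features) without rerunning discovery.
    """
    out = []
    for i, pas in enumerate(truth.all_pas()):
        L = chrom_lengths[pas.chrom]
        win = GenomicWindow(pas.chrom, pas.strand,
                            max(0, pas.site - WINDOW_HALF),
                            min(L, pas.site + WINDOW_HALF + 1), pas.site)
        out.append(ReferencePas(pas_id=pas.pas_id, window=win, source="shared", r=0,
                                gene_id=pas.gene_id, biotype="protein_coding",
                                category=pas.category))
    return out


# ---------------------------------------------------------- serialization
def reference_to_frame(reference: list[ReferencePas]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [p.window.chrom for p in reference],
            "start": [p.window.start for p in reference],
            "end": [p.window.end for p in reference],
            "name": [p.pas_id for p in reference],
            "score": [p.r for p in reference],
            "strand": [p.window.strand for p in reference],
            "site": [p.window.anchor for p in reference],
            "source": [p.source for p in reference],
            "gene_id": [p.gene_id if p.gene_id else "." for p in reference],
            "biotype": [p.biotype for p in reference],
            "category": [p.category if p.category else "." for p in reference],
        }
    )


def frame_to_reference(df) -> list[ReferencePas]:
    out = []
    for row in df.itertuples():
        win = GenomicWindow(row.chrom, row.strand, int(row.start), int(row.end),
                            int(row.site))
        out.append(ReferencePas(pas_id=row.name, window=win, source=row.source,
                                r=int(row.score),
                                gene_id=None if row.gene_id == "." else row.gene_id,
                                biotype=row.biotype,
                                category=None if row.category == "." else row.category))
    return out
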