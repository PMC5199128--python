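"""Readers and writers for the pipeline's on-disk formats.

External formats follow their usual conventions (1-based VCF/GTF, 0-based
half-open BED); everything is converted to 0-based internal coordinates here
and nowhere else.  FASTA is read through pyfaidx, VCF through pysam and GTF
through gffutils; the custom tailmap TSV (the reduced 3'-end read stream) has
its own line-based parser with line-number errors.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

from .liftover import Variant, VariantMap
from .types import Gene, GeneAnnotation, TailRead, Transcript

TAILMAP_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "tail_T_count",
    "sample",
    "replicate",
    "true_allele",
    "read_id",
]


# ----------------------------------------------------------------- FASTA
def write_fasta(path: str | os.PathLike, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------------- VCF
def write_vcf(
    path: str | os.PathLike,
    vmap: VariantMap,
    seqs_a: dict[str, str],
    source: str = "apadiv",
) -> None:
    """Write the inter-strain variant map as VCF 4.2 (genome A as reference)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom, length in vmap.chrom_lengths_a.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in vmap.variants:
            if v.vtype == "SNP":
                pos1, ref, alt = v.pos + 1, v.ref, v.alt
            else:
                # anchored indel representation; the simulator never places
                # an indel at the first base of a chromosome
                anchor = seqs_a[v.chrom][v.pos - 1]
                pos1 = v.pos  # anchor base, 1-based
                ref, alt = anchor + v.ref, anchor + v.alt
            fh.write(f"{v.chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_vcf(path: str | os.PathLike) -> VariantMap:
    variants: list[Variant] = []
    chrom_lengths: dict[str, int] = {}
    with pysam.VariantFile(str(path)) as vf:
        for chrom, contig in vf.header.contigs.items():
            chrom_lengths[chrom] = contig.length
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == len(alt) == 1:
                variants.append(Variant(rec.chrom, rec.start, ref, alt))
            elif len(ref) > 1 and len(alt) == 1:
                variants.append(Variant(rec.chrom, rec.start + 1, ref[1:], ""))
            elif len(alt) > 1 and len(ref) == 1:
                variants.append(Variant(rec.chrom, rec.start + 1, "", alt[1:]))
            else:
                raise ValueError(f"unsupported VCF record {rec.chrom}:{rec.pos}")
    return VariantMap(variants, chrom_lengths)


# ------------------------------------------------------------------- GTF
def write_gtf(path: str | os.PathLike, annotation: GeneAnnotation) -> None:
    def attrs(**kv: str) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w") as fh:
        for gene in annotation:
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        "apadiv",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs(gene_id=gene.gene_id, gene_biotype=gene.biotype),
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                s, e = tx.span()
                a = attrs(
                    gene_id=gene.gene_id,
                    transcript_id=tx.transcript_id,
                    gene_biotype=gene.biotype,
                )
                fh.write(
                    f"{gene.chrom}\tapadiv\ttranscript\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{a}\n"
                )
                for es, ee in tx.exons:
                    fh.write(
                        f"{gene.chrom}\tapadiv\texon\t{es + 1}\t{ee}\t.\t{gene.strand}\t.\t{a}\n"
                    )


def read_gtf(path: str | os.PathLike) -> GeneAnnotation:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ann = GeneAnnotation()
    for g in db.features_of_type("gene"):
        gene = Gene(
            gene_id=g.attributes["gene_id"][0],
            chrom=g.seqid,
            strand=g.strand,
            start=g.start - 1,
            end=g.end,
            biotype=g.attributes.get("gene_biotype", ["protein_coding"])[0],
        )
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
            )
            gene.transcripts.append(
                Transcript(transcript_id=t.attributes["transcript_id"][0], exons=exons)
            )
        ann.add(gene)
    return ann


# ------------------------------------------------------------------ BED6
def write_bed6(path: str | os.PathLike, df: pd.DataFrame) -> None:
    """Write a BED6 table (columns chrom, start, end, name, score, strand)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=cols)
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    if df["start"].isna().any() or df["end"].isna().any():
        raise ValueError(f"malformed BED6 in {path}")
    return df


# --------------------------------------------------------------- tailmap
def write_tailmap(path: str | os.PathLike, reads: Iterable[TailRead]) -> None:
    """Serialize a read stream as tailmap TSV (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TAILMAP_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.tail_t}\t"
                f"{r.sample}\t{r.replicate}\t{r.allele}\t{r.read_id}\n"
            )


def read_tailmap(path: str | os.PathLike) -> list[TailRead]:
    reads: list[TailRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TAILMAP_COLUMNS:
            raise ValueError(f"{path}: line 1: bad tailmap header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TAILMAP_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected 8 fields")
            try:
                reads.append(
                    TailRead(
                        chrom=parts[0],
                        pos=int(parts[1]) - 1,
                        strand=parts[2],
                        tail_t=int(parts[3]),
                        sample=parts[4],
                        replicate=int(parts[5]),
                        allele=parts[6],
                        read_id=parts[7],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return reads


# ----------------------------------------------------------- results TSV
def write_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
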