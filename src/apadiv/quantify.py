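"""Usage quantification: window counting, allele assignment and filters.

3' mRNA-Seq reads increment a reference pAs when their 5'-end anchor lies in
its 48-nt window on the same strand.  F1 (and mock-F1) reads are assigned to
the parental allele with the strictly smaller mismatch count over the
variants their alignment overlaps; ties are ambiguous and excluded from
allelic counts while still contributing to totals.  The mock-F1 binomial
filter then removes pAs whose allelic read recovery is worse than expected
under the genome-wide assignability rate.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom

from .liftover import VariantMap
from .types import BL, SP, ReferencePas, TailRead

AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------- allele
class _VariantIndex:
    """Sorted variant spans (A coordinates) per chromosome."""

    def __init__(self, vmap: VariantMap):
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for v in vmap.variants:
            by_chrom[v.chrom].append((v.pos, v.pos + max(len(v.ref), 1)))
        for chrom, spans in by_chrom.items():
            spans.sort()
            self.starts[chrom] = np.array([s for s, _ in spans])
            self.ends[chrom] = np.array([e for _, e in spans])

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        s = self.starts.get(chrom)
        if s is None:
            return 0
        e = self.ends[chrom]
        return int(np.searchsorted(s, end, side="left") - np.searchsorted(e, start, side="right"))


def read_interval(read: TailRead, read_length: int) -> tuple[int, int]:
    """Aligned genomic span of a 3' mRNA-Seq read from its 5'-end anchor.

    The read extends from the anchor upstream into the transcript body.
    """
    if read.strand == "+":
        return read.pos - read_length + 1, read.pos + 1
    return read.pos, read.pos + read_length


def assign_allele(read: TailRead, vmap: VariantMap | _VariantIndex,
                  read_length: int = 50,
                  variant_alleles: list[str] | None = None) -> str:
    """Assign one read to BL, SP or ambiguous by mismatch count.

    The read's base at each overlapped variant position matches one allele;
    by default (error-free simulation) every overlapped variant matches the
    read's true allele of origin.  ``variant_alleles`` overrides this with an
    explicit per-variant match list (for constructed cases, e.g. ties).  The
    allele with strictly fewer mismatches wins; equal distances (including
    reads overlapping no variant) are ambiguous.
    """
    start, end = read_interval(read, read_length)
    if start < 0:
        raise ValueError(f"read {read.read_id} extends outside the genome")
    if variant_alleles is None:
        index = vmap if isinstance(vmap, _VariantIndex) else _VariantIndex(vmap)
        n = index.count_overlapping(read.chrom, start, end)
        if n == 0 or read.allele not in (BL, SP):
            return AMBIGUOUS
        return read.allele
    dist_bl = sum(1 for a in variant_alleles if a == SP)
    dist_sp = sum(1 for a in variant_alleles if a == BL)
    if dist_bl < dist_sp:
        return BL
    if dist_sp < dist_bl:
        return SP
    return AMBIGUOUS


def assign_alleles(reads: list[TailRead], vmap: VariantMap, read_length: int = 50) -> list[str]:
    index = _VariantIndex(vmap)
    return [assign_allele(r, index, read_length) for r in reads]


# --------------------------------------------------------------- counting
class WindowIndex:
    def __init__(self, reference: list[ReferencePas]):
        self.trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.by_id = {p.pas_id: p for p in reference}
        for p in reference:
            w = p.window
            self.trees[(w.chrom, w.strand)].addi(w.start, w.end, p)

    def lookup(self, chrom: str, strand: str, pos: int) -> ReferencePas | None:
        hits = self.trees[(chrom, strand)][pos]
        if not hits:
            return None
        # overlapping windows are rare; prefer the nearest anchor
        return min(hits, key=lambda iv: abs(iv.data.window.anchor - pos)).data


def count_reads(reads: list[TailRead], reference: list[ReferencePas],
                allele_labels: list[str] | None = None) -> tuple[pd.DataFrame, int]:
    """Count reads into reference windows.

    A read is counted iff its anchor position falls inside a same-strand
    48-nt window (inclusive ends); all other reads (e.g. internal
    mispriming) are discarded and reported.  Returns a long-format table
    (pas_id, gene_id, sample, replicate, allele, count) and the discarded
    read count; column ``allele`` is the provided label ("both" when no
    labels are given).
    """
    index = WindowIndex(reference)
    counts: dict[tuple, int] = defaultdict(int)
    discarded = 0
    labels = allele_labels if allele_labels is not None else ["both"] * len(reads)
    for read, label in zip(reads, labels):
        pas = index.lookup(read.chrom, read.strand, read.pos)
        if pas is None:
            discarded += 1
            continue
        counts[(pas.pas_id, pas.gene_id, read.sample, read.replicate, label)] += 1
    rows = [(*k, v) for k, v in sorted(counts.items(), key=lambda kv: str(kv[0]))]
    df = pd.DataFrame(rows, columns=["pas_id", "gene_id", "sample", "replicate", "allele", "count"])
    return df, discarded


def pivot_counts(df: pd.DataFrame, reference: list[ReferencePas],
                 condition_of: dict[tuple[str, str], str]) -> pd.DataFrame:
    """Aggregate a long count table to pas x condition (replicates summed).

    ``condition_of`` maps (sample, allele) -> condition name; unmapped
    combinations are dropped.  All reference pAs appear, zero-filled.
    """
    df = df.copy()
    df["condition"] = [condition_of.get((s, a)) for s, a in zip(df["sample"], df["allele"])]
    df = df.dropna(subset=["condition"])
    wide = df.pivot_table(index="pas_id", columns="condition", values="count",
                          aggfunc="sum", fill_value=0)
    idx = pd.Index([p.pas_id for p in reference], name="pas_id")
    wide = wide.reindex(idx, fill_value=0)
    wide.insert(0, "gene_id", [p.gene_id for p in reference])
    return wide.reset_index()


# ------------------------------------------------------------ mock filter
def mock_f1_filter(parental_counts: dict[str, pd.Series],
                   mock_counts: dict[str, pd.Series],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Binomial calibration of allelic read recovery per pAs.

    ``parental_counts[allele]`` are per-pAs read counts from the parental
    strain's own dataset; ``mock_counts[allele]`` are the reads from the
    pooled mock-F1 dataset unambiguously assigned back to that allele.  The
    genome-wide assignable fraction p = Total_mock / Total_parental is
    estimated per allele (replicates pooled); a pAs is dropped when, for
    either allele, the lower-tail exact binomial probability
    P(X <= mock | n=parental, p) < alpha, or parental < mock.  Returns a
    per-pAs report with a boolean ``retained`` column.
    """
    report = {}
    for allele in (BL, SP):
        par = parental_counts[allele]
        mock = mock_counts[allele].reindex(par.index, fill_value=0)
        total_par = int(par.sum())
        if total_par == 0:
            raise ValueError("parental dataset has zero reads in reference pAs")
        p = float(mock.sum()) / total_par
        pvals = binom.cdf(mock.to_numpy(), par.to_numpy(), p)
        report[f"parental_{allele}"] = par
        report[f"mock_{allele}"] = mock
        report[f"p_{allele}"] = pd.Series(pvals, index=par.index)
        report[f"drop_{allele}"] = pd.Series(
            (pvals < alpha) | (par.to_numpy() < mock.to_numpy()), index=par.index
        )
    out = pd.DataFrame(report)
    out["retained"] = ~(out[f"drop_{BL}"] | out[f"drop_{SP}"])
    out.index.name = "pas_id"
    return out


# ------------------------------------------------------ expression filter
def expression_filter(table: pd.DataFrame, mode: str,
                      conditions: tuple[str, str] | None = None) -> tuple[set, set]:
    """Eligible genes and pAs for differential-usage testing.

    ``table`` is a pas x condition frame (columns ``pas_id``, ``gene_id``
    and one column per condition, replicates summed except where noted).

    parental mode: a gene is eligible when >= 2 of its pAs have >= 10 reads
    from the two strains together and its per-strain totals over those pAs
    are >= 20 in both strains.

    allelic mode: a pAs is eligible when its per-allele mean count across
    replicates is >= 5 for both alleles (``table`` must additionally carry
    ``n_replicates``-normalized means via the ``*_mean`` columns, or plain
    summed columns with ``n_replicates`` passed through conditions); the
    gene needs >= 2 such pAs and per-allele totals >= 20.
    """
    if mode not in ("parental", "allelic"):
        raise ValueError(f"unknown mode {mode!r}")
    c1, c2 = conditions if conditions else (("BL", "SP") if mode == "parental" else ("F1_BL", "F1_SP"))
    genes_ok: set = set()
    pas_ok: set = set()
    for gene_id, grp in table.groupby("gene_id"):
        a = grp[c1].to_numpy()
        b = grp[c2].to_numpy()
        if mode == "parental":
            eligible = (a + b) >= 10
            ok = eligible.sum() >= 2 and a[eligible].sum() >= 20 and b[eligible].sum() >= 20
        else:
            mean_a = grp[f"{c1}_mean"].to_numpy() if f"{c1}_mean" in grp else a / 2.0
            mean_b = grp[f"{c2}_mean"].to_numpy() if f"{c2}_mean" in grp else b / 2.0
            eligible = (mean_a >= 5) & (mean_b >= 5)
            ok = eligible.sum() >= 2 and a[eligible].sum() >= 20 and b[eligible].sum() >= 20
        if ok:
            genes_ok.add(gene_id)
            pas_ok.update(grp.loc[eligible, "pas_id"])
    return genes_ok, pas_ok
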