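"""pAs cluster discovery from 3' READS reads with an empirical FDR.

Reads with >= 2 non-genomic 5' T (PASS reads) define candidate cleavage
sites; sites within 24 nt are clustered, wide components are decomposed
greedily around coverage maxima.  Each cluster gets a PASS count R and an
enrichment E of PASS coverage over RNA-Seq background coverage; a dominance
p-value Pi = n_i/N (clusters beating it on both R and E) is computed against
the real set and against subsamples of the pseudo-site null (clusters called
from 0-T reads), whose ratio estimates the per-cluster FDR Q.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .types import GenomicWindow, PasCluster, TailRead

CLUSTER_GAP = 24  # nt; "within 24 nt" taken inclusively


# ------------------------------------------------------------- splitting
def split_reads_by_tail(reads: list[TailRead]) -> tuple[list[TailRead], list[TailRead]]:
    """PASS reads (tail T >= 2) and pseudo-site reads (tail T == 0).

    Reads with exactly one non-genomic T support neither set and are dropped.
    """
    pass_reads: list[TailRead] = []
    pseudo: list[TailRead] = []
    for r in reads:
        if r.tail_t < 0:
            raise ValueError(f"negative tail T count on read {r.read_id}")
        if r.tail_t >= 2:
            pass_reads.append(r)
        elif r.tail_t == 0:
            pseudo.append(r)
    return pass_reads, pseudo


def site_histograms(reads: list[TailRead]) -> dict[tuple[str, str], dict[int, int]]:
    """Per (chrom, strand) map of cleavage-site position -> read count."""
    hist: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for r in reads:
        hist[(r.chrom, r.strand)][r.pos] += 1
    return {k: dict(v) for k, v in hist.items()}


# ------------------------------------------------------------ clustering
def _components(positions: np.ndarray, gap: int) -> list[np.ndarray]:
    """Single-linkage components: split where consecutive sites are > gap apart."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > gap) + 1
    return np.split(positions, breaks)


def _decompose(pos: np.ndarray, cnt: dict[int, int], gap: int) -> list[tuple[int, np.ndarray]]:
    """Greedy decomposition of one linkage component into (rep, members)."""
    out: list[tuple[int, np.ndarray]] = []
    stack = [pos]
    while stack:
        p = stack.pop()
        if len(p) == 0:
            continue
        if p[-1] - p[0] <= gap:
            counts = np.array([cnt[x] for x in p])
            rep = int(p[np.argmax(counts)])  # argmax: first max = smallest coord
            out.append((rep, p))
            continue
        counts = np.array([cnt[x] for x in p])
        rep = int(p[np.argmax(counts)])
        near = np.abs(p - rep) <= gap
        out.append((rep, p[near]))
        for comp in _components(p[~near], gap):
            stack.append(comp)
    return out


def cluster_sites(histogram: dict[int, int], chrom: str, strand: str,
                  gap: int = CLUSTER_GAP, replicate: int = 0) -> list[PasCluster]:
    """Cluster cleavage sites on one strand of one chromosome.

    Sites within ``gap`` nt of each other are linked; a component spanning
    more than ``gap`` nt is decomposed by repeatedly taking the position of
    maximum coverage as the representative site, assigning all sites within
    ``gap`` nt to it, and re-clustering the remainder.  Coverage ties break
    toward the smaller coordinate.
    """
    positions = np.array(sorted(histogram), dtype=np.int64)
    clusters: list[PasCluster] = []
    for comp in _components(positions, gap):
        for rep, members in _decompose(comp, histogram, gap):
            r = int(sum(histogram[m] for m in members))
            clusters.append(
                PasCluster(chrom=chrom, strand=strand, site=rep,
                           span_start=int(members.min()), span_end=int(members.max()),
                           r=r, replicate=replicate)
            )
    clusters.sort(key=lambda c: c.site)
    return clusters


def call_clusters(reads: list[TailRead], replicate: int = 0) -> list[PasCluster]:
    """Cluster a read stream across all chromosomes and strands."""
    out: list[PasCluster] = []
    for (chrom, strand), hist in sorted(site_histograms(reads).items()):
        out.extend(cluster_sites(hist, chrom, strand, replicate=replicate))
    return out


# ------------------------------------------------------------ enrichment
class BackgroundIndex:
    """Sorted per-(chrom, strand) read start positions from a BED6 frame."""

    def __init__(self, bed: pd.DataFrame):
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        if len(bed):
            for (chrom, strand), grp in bed.groupby(["chrom", "strand"]):
                self._pos[(chrom, strand)] = np.sort(grp["start"].to_numpy())

    def count(self, chrom: str, strand: str, lo: int, hi: int) -> int:
        """Reads with start in [lo, hi] inclusive."""
        pos = self._pos.get((chrom, strand))
        if pos is None:
            return 0
        return int(np.searchsorted(pos, hi, side="right") - np.searchsorted(pos, lo))


BG_WINDOW_UP, BG_WINDOW_DOWN, BG_WINDOW_SIZE = 500, 50, 550


def enrichment_stats(cluster: PasCluster, background: BackgroundIndex,
                     pseudocount: float = 1.0) -> tuple[int, float]:
    """R and E for one cluster.

    E = (PASS reads / cluster size) / ((background reads in the strand-aware
    -500..+50 window around the representative site + pseudocount) / 550).
    """
    if cluster.size <= 0:
        raise ValueError("cluster size must be positive")
    if cluster.strand == "+":
        lo, hi = cluster.site - BG_WINDOW_UP, cluster.site + BG_WINDOW_DOWN
    else:
        lo, hi = cluster.site - BG_WINDOW_DOWN, cluster.site + BG_WINDOW_UP
    bg = background.count(cluster.chrom, cluster.strand, lo, hi)
    pass_cov = cluster.r / cluster.size
    bg_cov = (bg + pseudocount) / BG_WINDOW_SIZE
    e = pass_cov / bg_cov
    cluster.e = e
    return cluster.r, e


def attach_enrichment(clusters: list[PasCluster], background: BackgroundIndex,
                      pseudocount: float = 1.0) -> None:
    for c in clusters:
        enrichment_stats(c, background, pseudocount)


# ----------------------------------------------------------- empirical p
def _dominance_p(query: np.ndarray, pool: np.ndarray, n_total: int) -> np.ndarray:
    """P = (#pool rows strictly greater on both R and E) / n_total."""
    r_q, e_q = query[:, 0][:, None], query[:, 1][:, None]
    dom = (pool[None, :, 0] > r_q) & (pool[None, :, 1] > e_q)
    return dom.sum(axis=1) / n_total


def empirical_p(clusters: list[PasCluster]) -> None:
    """Pi = n_i / N with n_i the clusters dominating cluster i on R and E."""
    if not clusters:
        raise ValueError("no clusters")
    arr = np.array([[c.r, c.e] for c in clusters], dtype=float)
    p = _dominance_p(arr, arr, len(clusters))
    for c, pi in zip(clusters, p):
        c.p_emp = float(pi)


def estimate_q(real_clusters: list[PasCluster], pseudo_clusters: list[PasCluster],
               n_subsamples: int = 100, seed: int = 0) -> None:
    """Per-cluster FDR Q = E[Pi(0T)] / Pi(2T), clamped to [0, 1].

    The pseudo set is subsampled to the size of the real set ``n_subsamples``
    times (without replacement when it is large enough, with replacement
    otherwise); Pi(0T) is the dominance p of each real cluster against each
    subsample.  Pi(2T) = 0 yields Q = 0 by convention.
    """
    if n_subsamples < 1:
        raise ValueError("n_subsamples must be >= 1")
    if not pseudo_clusters:
        raise ValueError("pseudo-site set is empty")
    empirical_p(real_clusters)
    rng = np.random.default_rng(seed)
    real = np.array([[c.r, c.e] for c in real_clusters], dtype=float)
    pseudo = np.array([[c.r, c.e] for c in pseudo_clusters], dtype=float)
    n_real, n_pseudo = len(real), len(pseudo)
    replace = n_pseudo < n_real
    sel = np.zeros(n_pseudo)
    for _ in range(n_subsamples):
        idx = rng.choice(n_pseudo, size=n_real, replace=replace)
        sel += np.bincount(idx, minlength=n_pseudo)
    # mean over subsamples of the dominance count, as one weighted pass
    dom = (pseudo[None, :, 0] > real[:, 0][:, None]) & (
        pseudo[None, :, 1] > real[:, 1][:, None]
    )
    mean_p0 = dom @ (sel / (n_subsamples * n_real))
    for c, p0 in zip(real_clusters, mean_p0):
        c.q = 0.0 if c.p_emp == 0 else float(min(1.0, p0 / c.p_emp))


# -------------------------------------------------------- reproducibility
def reproducibility_filter(rep1: list[PasCluster], rep2: list[PasCluster],
                           q_threshold: float = 0.05,
                           match_distance: int = CLUSTER_GAP) -> list[PasCluster]:
    """Keep clusters supported in both replicates at low Q.

    A cluster is retained iff the other replicate has a cluster whose
    representative site lies within ``match_distance`` and both Q values are
    below ``q_threshold``; matched pairs are merged (site from the higher-R
    member, R summed).  This is the package's documented stand-in for the
    published IDR procedure, preserving its intent: replicate-supported,
    low-FDR clusters.
    """
    by_key: dict[tuple[str, str], list[PasCluster]] = defaultdict(list)
    for c in rep2:
        by_key[(c.chrom, c.strand)].append(c)
    for key in by_key:
        by_key[key].sort(key=lambda c: c.site)
    out: list[PasCluster] = []
    used: set[int] = set()
    for c1 in sorted(rep1, key=lambda c: (c.chrom, c.strand, c.site)):
        cands = by_key.get((c1.chrom, c1.strand), [])
        sites = np.array([c.site for c in cands])
        if len(sites) == 0:
            continue
        order = np.argsort(np.abs(sites - c1.site), kind="stable")
        match = None
        for j in order:
            if abs(int(sites[j]) - c1.site) > match_distance:
                break
            if id(cands[j]) not in used:
                match = cands[j]
                break
        if match is None:
            continue
        used.add(id(match))
        if max(c1.q, match.q) >= q_threshold:
            continue
        keep, other = (c1, match) if c1.r >= match.r else (match, c1)
        out.append(
            PasCluster(chrom=c1.chrom, strand=c1.strand, site=keep.site,
                       span_start=min(c1.span_start, match.span_start),
                       span_end=max(c1.span_end, match.span_end),
                       r=c1.r + match.r, e=keep.e,
                       p_emp=max(c1.p_emp, match.p_emp), q=max(c1.q, match.q))
        )
    out.sort(key=lambda c: (c.chrom, c.strand, c.site))
    return out


# -------------------------------------------------------------- windows
WINDOW_HALF = 24  # -24..+24 inclusive around the representative site


def windows_48(clusters: list[PasCluster], chrom_lengths: dict[str, int]) -> list[GenomicWindow]:
    """Fixed windows of offsets -24..+24 around each representative site.

    The window covers 49 positions as literally defined (both boundary
    offsets inclusive), clipped at chromosome ends.
    """
    out = []
    for c in clusters:
        L = chrom_lengths[c.chrom]
        start = max(0, c.site - WINDOW_HALF)
        end = min(L, c.site + WINDOW_HALF + 1)
        out.append(GenomicWindow(c.chrom, c.strand, start, end, c.site))
    return out


def discover(reads: list[TailRead], background: BackgroundIndex,
             q_threshold: float = 0.05, n_subsamples: int = 100,
             seed: int = 0) -> list[PasCluster]:
    """Full per-strain discovery: replicate calling, Q estimation, filtering."""
    reps = sorted({r.replicate for r in reads})
    per_rep: list[list[PasCluster]] = []
    for rep in reps:
        sub = [r for r in reads if r.replicate == rep]
        pass_reads, pseudo_reads = split_reads_by_tail(sub)
        real = call_clusters(pass_reads, replicate=rep)
        pseudo = call_clusters(pseudo_reads, replicate=rep)
        attach_enrichment(real, background)
        attach_enrichment(pseudo, background)
        if real:
            estimate_q(real, pseudo, n_subsamples=n_subsamples, seed=seed + rep)
        per_rep.append(real)
    if len(per_rep) == 1:
        return [c for c in per_rep[0] if c.q < q_threshold]
    merged = per_rep[0]
    for nxt in per_rep[1:]:
        merged = reproducibility_filter(merged, nxt, q_threshold=q_threshold)
    return merged


# ---------------------------------------------------------- serialization
def clusters_to_frame(clusters: list[PasCluster]) -> pd.DataFrame:
    """BED6+ representation: span as the interval, R as the score."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in clusters],
            "start": [c.span_start for c in clusters],
            "end": [c.span_end + 1 for c in clusters],
            "name": [f"{c.chrom}:{c.site}:{c.strand}" for c in clusters],
            "score": [c.r for c in clusters],
            "strand": [c.strand for c in clusters],
            "site": [c.site for c in clusters],
            "E": [c.e for c in clusters],
            "P_emp": [c.p_emp for c in clusters],
            "Q": [c.q for c in clusters],
        }
    )


def frame_to_clusters(df: pd.DataFrame) -> list[PasCluster]:
    return [
        PasCluster(chrom=row.chrom, strand=row.strand, site=int(row.site),
                   span_start=int(row.start), span_end=int(row.end) - 1,
                   r=int(row.score), e=float(row.E), p_emp=float(row.P_emp),
                   q=float(row.Q))
        for row in df.itertuples()
    ]
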