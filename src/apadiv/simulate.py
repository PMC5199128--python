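"""Synthetic study generator: a diploid strain pair, planted APA architecture
with cis/trans effects, and all downstream read streams.

The generator emulates the design of the real experiment at desk scale: two
inbred strains whose genomes differ by SNPs and short indels, fibroblast-like
gene expression (log-normal gene weights, Dirichlet per-gene pAs usage),
3' READS-style reads with non-genomic T tails for site discovery, 3' mRNA-Seq
reads for usage quantification in parents and F1 hybrids, and a mock F1 pool.
Cis effects are written into exactly one allele's sequence (a disrupted
AAUAAA polyadenylation signal, or a shortened upstream poly(U) tract); trans
effects shift parental usage only, with the two F1 alleles agreeing — the
definitional contrast the F1 design exploits.

Reads are emitted at the aligned level (tailmap records), never as FASTQ:
read alignment is outside the pipeline's scope.  Every simulated read carries
its true allele of origin so assignment accuracy is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .liftover import Variant, VariantMap
from .types import BL, SP, Gene, GeneAnnotation, TailRead, Transcript

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------- config
@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the package's standing desk-scale analogue of the real
    study: variant density near the SPRET/EiJ level (~1 SNP per 100 bp),
    about half of genes with a single pAs, cis effects roughly three times
    as common as trans effects, and planted usage shifts of 30 percentage
    points.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 500_000
    snp_rate: float = 0.013
    indel_rate: float = 0.002
    n_genes: int = 150
    pas_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.30, 3: 0.15, 4: 0.07, 5: 0.03}
    )
    expression_lognormal_mu_sigma: tuple[float, float] = (0.0, 1.0)
    usage_dirichlet_alpha: float = 2.0
    cis_effect_fraction: float = 0.15
    trans_effect_fraction: float = 0.05
    cis_delta_usage: float = 30.0  # percent
    trans_delta_usage: float = 30.0  # percent
    read_depth_per_sample: int = 150_000
    tail_T_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.15, 1: 0.15, 2: 0.30, 3: 0.25, 4: 0.15}
    )
    noise_tail_T_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.95, 2: 0.05}
    )
    cleavage_jitter_sd_nt: float = 2.0
    background_noise_read_fraction: float = 0.05
    mispriming_rate: float = 0.02
    # plumbing parameters of the synthetic architecture
    read_length: int = 88
    background_depth: int = 100_000
    pas_signal_prob: float = 0.9
    polyu_prob: float = 0.35
    polyu_length: int = 6
    cis_effect_types: tuple[str, ...] = ("pas", "polyU")
    gene_length: int = 4000
    gene_spacing: int = 1200

    def __post_init__(self) -> None:
        for name in (
            "cis_effect_fraction",
            "trans_effect_fraction",
            "background_noise_read_fraction",
            "mispriming_rate",
            "pas_signal_prob",
            "polyu_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cis_effect_fraction + self.trans_effect_fraction > 1.0:
            raise ValueError("cis + trans effect fractions must not exceed 1")
        if self.snp_rate < 0 or self.indel_rate < 0:
            raise ValueError("variant rates must be >= 0")
        if self.chrom_length_bp <= 0:
            raise ValueError("zero-length chromosome")
        if self.chrom_length_bp < 10_000:
            raise ValueError("chrom_length_bp must be >= 10,000")
        for dist in (self.pas_per_gene_distribution, self.tail_T_distribution,
                     self.noise_tail_T_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("categorical distribution must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Named deterministic random stream derived from the seed."""
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------- truth
@dataclass
class PlantedPas:
    pas_id: str
    gene_id: str
    chrom: str
    strand: str
    site: int  # A-genome 0-based cleavage base
    category: str
    effect: str = "none"  # none | cis | trans
    causal_variant: str = ""  # e.g. "AAUAAA>AAGAAA at -23"
    mutated_allele: str = ""  # allele carrying the cis variant
    true_delta: float = 0.0  # parental usage difference BL - SP, percent
    usage: dict[str, float] = field(default_factory=dict)  # condition -> prob


@dataclass
class PlantedGene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    weight: float = 0.0  # expression weight (log-normal draw)
    pas: list[PlantedPas] = field(default_factory=list)
    misprime_anchor: int = -1

    def usage_vector(self, condition: str) -> np.ndarray:
        return np.array([p.usage[condition] for p in self.pas])


@dataclass
class PlantedTruth:
    genes: list[PlantedGene]
    annotation: GeneAnnotation

    def all_pas(self) -> list[PlantedPas]:
        return [p for g in self.genes for p in g.pas]

    def pas_by_id(self) -> dict[str, PlantedPas]:
        return {p.pas_id: p for p in self.all_pas()}


@dataclass
class StrainPairGenome:
    """Two haploid genomes plus the variant map aligning them."""

    seqs_a: dict[str, str]
    seqs_b: dict[str, str]
    vmap: VariantMap
    # raw draft variants (pos, kind, length) kept so planting can rebuild
    draft: list[tuple[str, int, str, int]] = field(default_factory=list)


# ------------------------------------------------------- genome pair
def _draw_variant_sites(rng: np.random.Generator, length: int, rate: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero(rng.random(length) < rate).astype(np.int64)


def generate_genome_pair(config: SimConfig) -> StrainPairGenome:
    """Random genome A plus a variant map at the configured densities.

    Overlapping indel placements are resolved by dropping later colliders
    (equivalent to a re-draw under the Bernoulli placement model).
    """
    rng = config.rng(1)
    seqs_a: dict[str, str] = {}
    draft: list[tuple[str, int, str, int]] = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length_bp
        seq = rng.choice(np.array(list("ACGT")), size=L)
        seqs_a[chrom] = "".join(seq)
        snp_pos = _draw_variant_sites(rng, L, config.snp_rate)
        indel_pos = _draw_variant_sites(rng, L, config.indel_rate)
        events = [(int(p), "SNP", 1) for p in snp_pos]
        for p in indel_pos:
            kind = "INS" if rng.random() < 0.5 else "DEL"
            ln = int(rng.integers(1, 7))
            events.append((int(p), kind, ln))
        events.sort()
        last_end = -2
        for pos, kind, ln in events:
            span = ln if kind == "DEL" else 1
            if pos <= last_end + 1 or pos < 2 or pos + span >= L - 2:
                continue  # collision with previous event: drop (re-draw model)
            draft.append((chrom, pos, kind, ln))
            last_end = pos + span - 1
    genomes = StrainPairGenome(seqs_a=seqs_a, seqs_b={}, vmap=None, draft=draft)  # type: ignore[arg-type]
    _finalize_genomes(genomes, config)
    return genomes


def _finalize_genomes(genomes: StrainPairGenome, config: SimConfig,
                      extra_variants: list[Variant] | None = None,
                      forbidden: dict[str, list[tuple[int, int]]] | None = None) -> None:
    """Build the final variant map and genome B from drafts + planted variants."""
    rng = config.rng(2)
    variants: list[Variant] = []
    forbidden = forbidden or {}
    bases = "ACGT"
    for chrom, pos, kind, ln in genomes.draft:
        spans = forbidden.get(chrom, [])
        span_end = pos + (ln if kind == "DEL" else 1)
        if any(pos < fe and span_end > fs for fs, fe in spans):
            continue
        seq = genomes.seqs_a[chrom]
        if kind == "SNP":
            ref = seq[pos]
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            variants.append(Variant(chrom, pos, ref, alt))
        elif kind == "DEL":
            variants.append(Variant(chrom, pos, seq[pos : pos + ln], ""))
        else:
            ins = "".join(rng.choice(np.array(list(bases)), size=ln))
            variants.append(Variant(chrom, pos, "", ins))
    if extra_variants:
        # planted causal variants take precedence over colliding drafts
        occupied = [(v.chrom, v.pos, v.pos + max(len(v.ref), 1)) for v in extra_variants]
        def collides(v: Variant) -> bool:
            e = v.pos + max(len(v.ref), 1)
            return any(c == v.chrom and v.pos < oe and e > os_ for c, os_, oe in occupied)
        variants = [v for v in variants if not collides(v)] + list(extra_variants)
    chrom_lengths = {c: len(s) for c, s in genomes.seqs_a.items()}
    genomes.vmap = VariantMap(variants, chrom_lengths)
    genomes.seqs_b = {
        c: genomes.vmap.apply_to_sequence(c, s) for c, s in genomes.seqs_a.items()
    }


# ----------------------------------------------------- genes and pAs
# sense-space offsets of the planted architecture (gene length 4000)
_EXON1 = (0, 600)
_INTRON = (600, 1400)
_ALE_EXON = (700, 1000)
_TANDEM_OFFSETS = (2000, 2600, 3200)
_ALE_PAS, _INTRONIC_PAS, _INTERNAL_PAS = 850, 1150, 300
_MISPRIME_OFF = 450
_PAS_MOTIF_OFF = (-25, -20)  # sense offsets of the planted AAUAAA (inclusive)
_PAS_MUT_INDEX = 2  # AAUAAA -> AAGAAA
_POLYU_OFF_START = -52


def _sense_to_genomic(site: int, strand: str, off: int) -> int:
    return site + off if strand == "+" else site - off


def _write_sense_motif(seq: list[str], site: int, strand: str, off_start: int, motif: str) -> tuple[int, int]:
    """Write ``motif`` (sense orientation, DNA) into a flank; returns genomic span."""
    if strand == "+":
        g0 = site + off_start
        seq[g0 : g0 + len(motif)] = list(motif)
        return g0, g0 + len(motif)
    g1 = site - off_start  # genomic coord of sense offset off_start
    g0 = g1 - len(motif) + 1
    seq[g0 : g0 + len(motif)] = list(revcomp(motif))
    return g0, g0 + len(motif)


def _gene_exons(start: int, end: int, strand: str, which: str) -> list[tuple[int, int]]:
    """Genomic exons for transcript T1 (full) or T2 (alternative last exon)."""
    L = end - start

    def g(lo: int, hi: int) -> tuple[int, int]:
        if strand == "+":
            return start + lo, start + hi
        return end - hi, end - lo

    if which == "T1":
        ex = [g(*_EXON1), g(_INTRON[1], L)]
    else:
        ex = [g(*_EXON1), g(*_ALE_EXON)]
    return sorted(ex)


def _pick_categories(k: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Category + sense offset for each of k pAs (terminal always present)."""
    extras_pool = [
        ("AltLastExon", _ALE_PAS),
        ("Intronic", _INTRONIC_PAS),
        ("InternalExon", _INTERNAL_PAS),
    ]
    out: list[tuple[str, int]] = []
    if k >= 1:
        out.append(("Terminal", -1))  # offset filled later (gene end)
    n_tandem = min(max(k - 2, 0), len(_TANDEM_OFFSETS))
    for off in _TANDEM_OFFSETS[:n_tandem]:
        out.append(("Tandem3UTR", off))
    while len(out) < k:
        if rng.random() < 0.55:
            used = {o for _, o in out}
            free = [o for o in _TANDEM_OFFSETS if o not in used]
            if free:
                out.append(("Tandem3UTR", free[0]))
                continue
        cat, off = extras_pool[int(rng.integers(0, len(extras_pool)))]
        if all(c != cat for c, _ in out):
            out.append((cat, off))
    return out[:k]


def plant_genes_and_pas(genomes: StrainPairGenome, config: SimConfig) -> tuple[GeneAnnotation, PlantedTruth]:
    """Place gene models and pAs, write flank motifs, plant cis/trans effects.

    Mutates ``genomes`` in place: planted sequence elements are written into
    genome A, causal cis variants are added to the variant map, and genome B
    is rebuilt.
    """
    rng = config.rng(3)
    slot = config.gene_length + config.gene_spacing
    capacity_per_chrom = (config.chrom_length_bp - 2 * slot) // slot
    chroms = sorted(genomes.seqs_a)
    if config.n_genes > capacity_per_chrom * len(chroms):
        raise ValueError("too many genes for the configured genome size")

    seq_lists = {c: list(s) for c, s in genomes.seqs_a.items()}
    genes: list[PlantedGene] = []
    annotation = GeneAnnotation()
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    extra_variants: list[Variant] = []

    ks = list(config.pas_per_gene_distribution)
    kp = np.array([config.pas_per_gene_distribution[k] for k in ks])
    mu, sigma = config.expression_lognormal_mu_sigma
    weights = rng.lognormal(mu, sigma, size=config.n_genes)

    # effect assignment: per multi-pAs protein-coding gene
    cis_cycle = 0
    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        slot_idx = gi // len(chroms)
        start = slot + slot_idx * slot + int(rng.integers(0, config.gene_spacing // 2))
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        u = rng.random()
        biotype = "protein_coding" if u < 0.92 else ("lincRNA" if u < 0.96 else "other_ncRNA")
        k = int(rng.choice(ks, p=kp)) if biotype == "protein_coding" else 1
        gene = PlantedGene(
            gene_id=f"G{gi:04d}", chrom=chrom, strand=strand,
            start=start, end=end, biotype=biotype, weight=float(weights[gi]),
        )
        cats = _pick_categories(k, rng)
        L = end - start
        has_ale = any(c == "AltLastExon" for c, _ in cats)
        seq = seq_lists[chrom]
        for pi, (cat, off) in enumerate(cats):
            off = L - 1 if cat == "Terminal" else off
            site = _sense_to_genomic(start if strand == "+" else end - 1, strand, off)
            pas = PlantedPas(
                pas_id=f"{gene.gene_id}.p{pi}", gene_id=gene.gene_id,
                chrom=chrom, strand=strand, site=site,
                # positional categories are defined for protein-coding genes only
                category=cat if biotype == "protein_coding" else None,
            )
            gene.pas.append(pas)
            # protect the cleavage site from background indels
            forbidden[chrom].append((site - 2, site + 3))
            if rng.random() < config.pas_signal_prob:
                s0, s1 = _write_sense_motif(seq, site, strand, _PAS_MOTIF_OFF[0], "AATAAA")
                forbidden[chrom].append((s0, s1))
            if rng.random() < config.polyu_prob:
                t0, t1 = _write_sense_motif(
                    seq, site, strand, _POLYU_OFF_START, "T" * config.polyu_length
                )
                forbidden[chrom].append((t0, t1))
        # mispriming anchor: internal A-rich tract in exon 1
        anchor = _sense_to_genomic(start if strand == "+" else end - 1, strand, _MISPRIME_OFF)
        a0, a1 = _write_sense_motif(seq, anchor, strand, 0, "A" * 10)
        forbidden[chrom].append((a0, a1))
        gene.misprime_anchor = anchor

        # gene models
        txs = [Transcript(f"{gene.gene_id}.t1", _gene_exons(start, end, strand, "T1"))]
        if has_ale:
            txs.append(Transcript(f"{gene.gene_id}.t2", _gene_exons(start, end, strand, "T2")))
        annotation.add(Gene(gene.gene_id, chrom, strand, start, end, biotype, txs))
        genes.append(gene)

    # ---- usage vectors and effects ---------------------------------
    alpha = config.usage_dirichlet_alpha
    for gene in genes:
        k = len(gene.pas)
        base = rng.dirichlet([alpha] * k) if k > 1 else np.array([1.0])
        effect = "none"
        if k > 1 and gene.biotype == "protein_coding":
            u = rng.random()
            if u < config.cis_effect_fraction:
                effect = "cis"
            elif u < config.cis_effect_fraction + config.trans_effect_fraction:
                effect = "trans"
        if effect == "none":
            for pi, pas in enumerate(gene.pas):
                pas.usage = {c: float(base[pi]) for c in ("BL", "SP", "F1_BL", "F1_SP")}
            continue

        target = int(rng.integers(0, k))
        delta = (config.cis_delta_usage if effect == "cis" else config.trans_delta_usage) / 100.0
        lo, hi = delta / 2 + 0.05, 1 - delta / 2 - 0.05
        u0 = float(np.clip(base[target], lo, hi))
        base = base.copy()
        others = np.delete(base, target)
        others = others / others.sum() * (1 - u0) if others.sum() > 0 else others
        def vec(center: float) -> np.ndarray:
            v = np.empty(k)
            v[target] = center
            scale = (1 - center) / (1 - u0)
            v[np.arange(k) != target] = others * scale
            return v

        high, low = vec(u0 + delta / 2), vec(u0 - delta / 2)
        tgt = gene.pas[target]
        if effect == "cis":
            ctype = config.cis_effect_types[cis_cycle % len(config.cis_effect_types)]
            cis_cycle += 1
            mutated = BL if rng.random() < 0.5 else SP
            chrom, strand, site = gene.chrom, gene.strand, tgt.site
            seq = seq_lists[chrom]
            if ctype == "pas":
                # disrupted signal lowers usage of the mutated allele
                s0, s1 = _write_sense_motif(seq, site, strand, _PAS_MOTIF_OFF[0], "AATAAA")
                forbidden[chrom].append((s0, s1))
                mut_off = _PAS_MOTIF_OFF[0] + _PAS_MUT_INDEX
                gpos = _sense_to_genomic(site, strand, mut_off)
                ref_base = seq[gpos]
                mut_base = "G" if strand == "+" else "C"
                if mutated == BL:
                    seq[gpos] = mut_base
                    extra_variants.append(Variant(chrom, gpos, mut_base, ref_base))
                else:
                    extra_variants.append(Variant(chrom, gpos, ref_base, mut_base))
                tgt.causal_variant = f"AAUAAA>AAGAAA at {mut_off}"
                allele_vec = {mutated: low, ({BL, SP} - {mutated}).pop(): high}
            else:
                # shortened poly(U) tract relieves repression: mutated allele up.
                # The mutated allele carries T*remaining + C*(L-remaining) over
                # the tract span; per-base SNPs restore the intact run in the
                # other allele, so A coordinates never shift.
                remaining = int(rng.integers(2, config.polyu_length))
                plen = config.polyu_length
                # repression relief scales with disruption depth: a fully
                # broken tract (2 U left) realizes the configured delta,
                # shallower breaks proportionally less
                depth_factor = (plen - remaining) / (plen - 2)
                d_scaled = delta * depth_factor
                high, low = vec(u0 + d_scaled / 2), vec(u0 - d_scaled / 2)
                intact = "T" * plen
                broken = "T" * remaining + "C" * (plen - remaining)
                motif_a = broken if mutated == BL else intact
                s0, s1 = _write_sense_motif(seq, site, strand, _POLYU_OFF_START, motif_a)
                forbidden[chrom].append((s0, s1))
                for j in range(remaining, plen):
                    gpos = _sense_to_genomic(site, strand, _POLYU_OFF_START + j)
                    sense_alt = "T" if mutated == BL else "C"
                    alt = sense_alt if strand == "+" else sense_alt.translate(_COMP)
                    extra_variants.append(Variant(chrom, gpos, seq[gpos], alt))
                tgt.causal_variant = f"U{plen}>U{remaining} at {_POLYU_OFF_START}"
                allele_vec = {mutated: high, ({BL, SP} - {mutated}).pop(): low}
            tgt.mutated_allele = mutated
            usage = {
                "BL": allele_vec[BL],
                "SP": allele_vec[SP],
                "F1_BL": allele_vec[BL],
                "F1_SP": allele_vec[SP],
            }
        else:  # trans: parental difference with no sequence cause
            up = BL if rng.random() < 0.5 else SP
            mid = vec(u0)
            usage = {
                "BL": high if up == BL else low,
                "SP": low if up == BL else high,
                "F1_BL": mid,
                "F1_SP": mid,
            }
            tgt.causal_variant = f"trans shift toward {up}"
        tgt.effect = effect
        for pi, pas in enumerate(gene.pas):
            pas.usage = {c: float(usage[c][pi]) for c in usage}
        tgt.true_delta = (tgt.usage["BL"] - tgt.usage["SP"]) * 100.0

    genomes.seqs_a = {c: "".join(s) for c, s in seq_lists.items()}
    _finalize_genomes(genomes, config, extra_variants=extra_variants, forbidden=forbidden)
    truth = PlantedTruth(genes=genes, annotation=annotation)
    return annotation, truth


# -------------------------------------------------------------- reads
def _draw_tails(rng: np.random.Generator, dist: dict[int, float], n: int) -> np.ndarray:
    vals = np.array(sorted(dist))
    p = np.array([dist[v] for v in sorted(dist)])
    return rng.choice(vals, size=n, p=p)


def _jitter(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """Rounded Gaussian cleavage jitter truncated at +/-12 nt."""
    if sd <= 0:
        return np.zeros(n, dtype=np.int64)
    j = np.rint(rng.normal(0.0, sd, size=n)).astype(np.int64)
    return np.clip(j, -12, 12)


def _gene_probs(genes: list[PlantedGene]) -> np.ndarray:
    w = np.array([g.weight for g in genes])
    return w / w.sum()


def simulate_3reads(truth: PlantedTruth, genomes: StrainPairGenome, config: SimConfig) -> list[TailRead]:
    """3' READS-like tailmap reads, two replicates per strain.

    BL reads are in genome-A coordinates, SP reads in genome-B coordinates
    (each parent aligned against its own genome, as in the real protocol).
    Background noise reads are placed uniformly within gene spans with the
    noise tail distribution, emulating internal-priming artifacts.
    """
    rng = config.rng(4)
    out: list[TailRead] = []
    probs = _gene_probs(truth.genes)
    n_noise = int(round(config.read_depth_per_sample * config.background_noise_read_fraction))
    n_true = config.read_depth_per_sample - n_noise
    rid = 0
    for strain in (BL, SP):
        for rep in (1, 2):
            sample = f"3READS_{strain}"
            gene_counts = rng.multinomial(n_true, probs) if n_true > 0 else np.zeros(len(probs), int)
            for g, ng in zip(truth.genes, gene_counts):
                if ng == 0:
                    continue
                usage = g.usage_vector(strain)
                pas_counts = rng.multinomial(ng, usage)
                for pas, c in zip(g.pas, pas_counts):
                    if c == 0:
                        continue
                    site = pas.site
                    if strain == SP:
                        site = genomes.vmap.liftover_position(pas.chrom, site)
                        if site is None:  # cleavage site protected; cannot happen
                            continue
                    pos = site + _jitter(rng, config.cleavage_jitter_sd_nt, c)
                    tails = _draw_tails(rng, config.tail_T_distribution, c)
                    for p, t in zip(pos, tails):
                        out.append(TailRead(pas.chrom, int(p), pas.strand, int(t),
                                            sample, rep, strain, f"r{rid}"))
                        rid += 1
            # internal noise
            noise_genes = rng.choice(len(truth.genes), size=n_noise, p=probs)
            tails = _draw_tails(rng, config.noise_tail_T_distribution, n_noise)
            for gi, t in zip(noise_genes, tails):
                g = truth.genes[gi]
                lo, hi = g.start, g.end
                if strain == SP:
                    lo = genomes.vmap.liftover_position(g.chrom, lo) or lo
                    hi = genomes.vmap.liftover_position(g.chrom, hi - 1) or hi - 1
                    hi += 1
                pos = int(rng.integers(lo, hi))
                out.append(TailRead(g.chrom, pos, g.strand, int(t),
                                    sample, rep, strain, f"r{rid}"))
                rid += 1
    return out


def simulate_3mrnaseq(truth: PlantedTruth, genomes: StrainPairGenome, config: SimConfig,
                      condition: str) -> list[TailRead]:
    """3' mRNA-Seq-like reads for one condition, in reference (A) coordinates.

    ``condition`` is one of ``parentBL``, ``parentSP``, ``F1``.  The tailmap
    ``pos`` is the read 5'-end (quantification anchor).  A ``mispriming_rate``
    fraction of reads starts at a planted internal A-rich tract to exercise
    the window-membership filter.  F1 reads carry their true allele.
    """
    if condition not in ("parentBL", "parentSP", "F1"):
        raise ValueError(f"unknown condition {condition!r}")
    stream = {"parentBL": 5, "parentSP": 6, "F1": 7}[condition]
    rng = config.rng(stream)
    out: list[TailRead] = []
    probs = _gene_probs(truth.genes)
    rid = 0
    sample = {"parentBL": "M_BL", "parentSP": "M_SP", "F1": "M_F1"}[condition]
    for rep in (1, 2):
        n_mis = rng.binomial(config.read_depth_per_sample, config.mispriming_rate)
        n_real = config.read_depth_per_sample - n_mis
        gene_counts = rng.multinomial(n_real, probs)
        for g, ng in zip(truth.genes, gene_counts):
            if ng == 0:
                continue
            if condition == "F1":
                cells = np.concatenate([
                    0.5 * g.usage_vector("F1_BL"), 0.5 * g.usage_vector("F1_SP")
                ])
                counts = rng.multinomial(ng, cells)
                alleles = [BL] * len(g.pas) + [SP] * len(g.pas)
                pas_list = g.pas + g.pas
            else:
                strain = BL if condition == "parentBL" else SP
                counts = rng.multinomial(ng, g.usage_vector(strain))
                alleles = [strain] * len(g.pas)
                pas_list = g.pas
            for pas, allele, c in zip(pas_list, alleles, counts):
                if c == 0:
                    continue
                pos = pas.site + _jitter(rng, config.cleavage_jitter_sd_nt, c)
                for p in pos:
                    out.append(TailRead(pas.chrom, int(p), pas.strand, 0,
                                        sample, rep, allele, f"q{rid}"))
                    rid += 1
        # misprimed reads: 5' end at the internal A-rich anchor
        mis_genes = rng.choice(len(truth.genes), size=n_mis, p=probs)
        for gi in mis_genes:
            g = truth.genes[gi]
            if condition == "F1":
                allele = BL if rng.random() < 0.5 else SP
            else:
                allele = BL if condition == "parentBL" else SP
            out.append(TailRead(g.chrom, g.misprime_anchor, g.strand, 0,
                                sample, rep, allele, f"q{rid}"))
            rid += 1
    return out


def pool_mock_f1(bl_reads: list[TailRead], sp_reads: list[TailRead]) -> list[TailRead]:
    """Pool parental 3' mRNA-Seq reads into a mock F1 dataset.

    The sample label becomes "mock"; the strain of origin is retained as the
    read's true allele so mock allele assignment can be benchmarked.
    """
    return [replace(r, sample="mock") for r in bl_reads] + [
        replace(r, sample="mock") for r in sp_reads
    ]


def simulate_background_rnaseq(truth: PlantedTruth, config: SimConfig,
                               genomes: StrainPairGenome | None = None) -> dict[str, "pd.DataFrame"]:
    """Background poly(A) RNA-Seq coverage for the enrichment statistic E.

    Reads are point intervals placed uniformly within gene spans, with
    per-gene totals proportional to gene expression.  Returned per strain
    ("BL" in A coordinates; "SP" in B coordinates when ``genomes`` given).
    """
    import pandas as pd

    rng = config.rng(8)
    probs = _gene_probs(truth.genes)
    out: dict[str, pd.DataFrame] = {}
    for strain in (BL, SP):
        gene_counts = rng.multinomial(config.background_depth, probs)
        rows = []
        for g, ng in zip(truth.genes, gene_counts):
            if ng == 0:
                continue
            lo, hi = g.start, g.end
            if strain == SP and genomes is not None:
                lo = genomes.vmap.liftover_position(g.chrom, lo) or lo
                hi = (genomes.vmap.liftover_position(g.chrom, hi - 1) or hi - 1) + 1
            pos = rng.integers(lo, hi, size=ng)
            for p in pos:
                rows.append((g.chrom, int(p), int(p) + 1, g.gene_id, 0, g.strand))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        out[strain] = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out


def simulate_pars_tracks(truth: PlantedTruth, config: SimConfig,
                         baseline: float = 20.0, dip_factor: float = 3.0) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Structure-probing count pairs (V1 paired, S1 unpaired) per chromosome.

    Counts are Poisson within gene spans with a planted accessibility dip
    (elevated S1) at sense offsets -30..-15 of every pAs.
    """
    rng = config.rng(9)
    tracks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    lengths: dict[str, int] = {}
    for g in truth.genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end + 200)
    for chrom, L in lengths.items():
        v1 = np.zeros(L)
        s1 = np.zeros(L)
        for g in truth.genes:
            if g.chrom != chrom:
                continue
            v1[g.start : g.end] = rng.poisson(baseline, g.end - g.start)
            s1[g.start : g.end] = rng.poisson(baseline, g.end - g.start)
            for pas in g.pas:
                if g.strand == "+":
                    lo, hi = pas.site - 30, pas.site - 15 + 1
                else:
                    lo, hi = pas.site + 15, pas.site + 30 + 1
                s1[lo:hi] = rng.poisson(baseline * dip_factor, hi - lo)
        tracks[chrom] = (v1, s1)
    return tracks
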