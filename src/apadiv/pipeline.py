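"""End-to-end orchestration of the synthetic APA divergence analysis.

Wires the stages together the way the numbered analysis drivers use them:
simulate -> discover (per strain) -> build cross-strain reference ->
quantify (parents, F1, mock F1) -> filter -> test divergence -> classify
cis/trans.  Each stage returns plain tables/objects so tests and the
acceptance script can enter at any point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cluster, divergence, quantify, reference as refmod
from .cluster import BackgroundIndex
from .simulate import (PlantedTruth, SimConfig, StrainPairGenome,
                       generate_genome_pair, plant_genes_and_pas, pool_mock_f1,
                       simulate_3mrnaseq, simulate_3reads,
                       simulate_background_rnaseq)
from .types import BL, SP, GeneAnnotation, ReferencePas, TailRead


@dataclass
class SimBundle:
    config: SimConfig
    genomes: StrainPairGenome
    annotation: GeneAnnotation
    truth: PlantedTruth
    reads_3reads: list[TailRead] = field(default_factory=list)
    mrna: dict[str, list[TailRead]] = field(default_factory=dict)
    mock: list[TailRead] = field(default_factory=list)
    background: dict[str, pd.DataFrame] = field(default_factory=dict)


def simulate_all(config: SimConfig, with_3reads: bool = True) -> SimBundle:
    genomes = generate_genome_pair(config)
    annotation, truth = plant_genes_and_pas(genomes, config)
    bundle = SimBundle(config=config, genomes=genomes, annotation=annotation, truth=truth)
    if with_3reads:
        bundle.reads_3reads = simulate_3reads(truth, genomes, config)
        bundle.background = simulate_background_rnaseq(truth, config, genomes)
    bundle.mrna = {
        cond: simulate_3mrnaseq(truth, genomes, config, cond)
        for cond in ("parentBL", "parentSP", "F1")
    }
    bundle.mock = pool_mock_f1(bundle.mrna["parentBL"], bundle.mrna["parentSP"])
    return bundle


# -------------------------------------------------------------- discovery
def run_discovery(bundle: SimBundle, q_threshold: float = 0.05,
                  n_subsamples: int = 100, seed: int = 0) -> dict[str, list]:
    """Replicate-filtered clusters per strain (SP in genome-B coordinates)."""
    out = {}
    for strain in (BL, SP):
        reads = [r for r in bundle.reads_3reads if r.sample == f"3READS_{strain}"]
        bg = BackgroundIndex(bundle.background[strain])
        out[strain] = cluster.discover(reads, bg, q_threshold=q_threshold,
                                       n_subsamples=n_subsamples, seed=seed)
    return out


def build_reference(bundle: SimBundle, clusters_by_strain: dict[str, list]) -> list[ReferencePas]:
    vmap = bundle.genomes.vmap
    surv_a = refmod.mappability_filter(clusters_by_strain[BL], vmap, "A")
    surv_b = refmod.mappability_filter(clusters_by_strain[SP], vmap, "B")
    ref = refmod.merge_reference(surv_a, surv_b, vmap.chrom_lengths_a)
    return refmod.annotate_pas(ref, bundle.annotation)


def reference_from_truth(bundle: SimBundle) -> list[ReferencePas]:
    return refmod.reference_from_truth(bundle.truth, bundle.genomes.vmap.chrom_lengths_a)


# ----------------------------------------------------------- quantification
@dataclass
class QuantResult:
    parental: pd.DataFrame  # pas x {BL, SP}
    allelic: pd.DataFrame  # pas x {F1_BL, F1_SP}
    mock_report: pd.DataFrame
    discarded: dict[str, int]


def quantify_all(bundle: SimBundle, reference: list[ReferencePas],
                 mock_alpha: float = 0.05) -> QuantResult:
    cfg = bundle.config
    discarded: dict[str, int] = {}
    # parents: counted against their own condition, no allele assignment
    par_reads = bundle.mrna["parentBL"] + bundle.mrna["parentSP"]
    par_counts, discarded["parental"] = quantify.count_reads(par_reads, reference)
    parental = quantify.pivot_counts(
        par_counts, reference,
        {("M_BL", "both"): "BL", ("M_SP", "both"): "SP"},
    )
    # F1: allele assignment, ambiguous reads excluded from allelic columns
    f1_reads = bundle.mrna["F1"]
    f1_labels = quantify.assign_alleles(f1_reads, bundle.genomes.vmap, cfg.read_length)
    f1_counts, discarded["F1"] = quantify.count_reads(f1_reads, reference, f1_labels)
    allelic = quantify.pivot_counts(
        f1_counts, reference,
        {("M_F1", BL): "F1_BL", ("M_F1", SP): "F1_SP"},
    )
    # mock F1: pooled parents processed like the real F1
    mock_labels = quantify.assign_alleles(bundle.mock, bundle.genomes.vmap, cfg.read_length)
    mock_counts, discarded["mock"] = quantify.count_reads(bundle.mock, reference, mock_labels)
    mock = quantify.pivot_counts(
        mock_counts, reference,
        {("mock", BL): "mock_BL", ("mock", SP): "mock_SP"},
    )
    joined = parental.merge(mock, on=["pas_id", "gene_id"], how="left").fillna(0)
    mock_report = quantify.mock_f1_filter(
        {BL: joined.set_index("pas_id")["BL"], SP: joined.set_index("pas_id")["SP"]},
        {BL: joined.set_index("pas_id")["mock_BL"], SP: joined.set_index("pas_id")["mock_SP"]},
        alpha=mock_alpha,
    )
    return QuantResult(parental=parental, allelic=allelic,
                       mock_report=mock_report, discarded=discarded)


# --------------------------------------------------------------- divergence
@dataclass
class DivergenceResult:
    parental_records: pd.DataFrame
    allelic_records: pd.DataFrame
    calls: pd.DataFrame
    eligible_genes_parental: set
    eligible_genes_allelic: set


def run_divergence(quant: QuantResult, mock_filter: bool = True) -> DivergenceResult:
    genes_p, pas_p = quantify.expression_filter(quant.parental, "parental")
    allelic_tab = quant.allelic
    if mock_filter:
        # mock-F1 calibration first, so the >=2-pAs structure of the allelic
        # expression filter is evaluated on the pAs that actually remain
        retained = set(quant.mock_report.index[quant.mock_report["retained"]])
        allelic_tab = allelic_tab[allelic_tab["pas_id"].isin(retained)]
    genes_a, pas_a = quantify.expression_filter(allelic_tab, "allelic")
    par_tab = quant.parental[quant.parental["pas_id"].isin(pas_p)]
    all_tab = allelic_tab[allelic_tab["pas_id"].isin(pas_a)]
    par_rec = divergence.call_divergent(divergence.usage_test(par_tab, ("BL", "SP")))
    all_rec = divergence.call_divergent(divergence.usage_test(all_tab, ("F1_BL", "F1_SP")))
    calls = divergence.classify_cis_trans(par_rec, all_rec)
    return DivergenceResult(par_rec, all_rec, calls, genes_p, genes_a)


def pas_site_records(reference: list[ReferencePas],
                     records: pd.DataFrame | None = None) -> pd.DataFrame:
    """pas_id/gene_id/chrom/strand/site (+delta_usage) frame for flank work."""
    df = pd.DataFrame(
        {
            "pas_id": [p.pas_id for p in reference],
            "gene_id": [p.gene_id for p in reference],
            "chrom": [p.window.chrom for p in reference],
            "strand": [p.window.strand for p in reference],
            "site": [p.window.anchor for p in reference],
            "category": [p.category for p in reference],
        }
    )
    if records is not None:
        df = df.merge(records[["pas_id", "delta_usage", "p_adj", "divergent"]],
                      on="pas_id", how="inner")
    return df
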