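"""Generate the standing synthetic study and write all inputs to results/sim.

Produces the two strain genomes, their variant map, the gene annotation, the
3' READS discovery reads, the 3' mRNA-Seq streams for both parents and the
F1 hybrid, the pooled mock-F1 stream, the RNA-Seq background coverage and
the planted ground truth.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import SIMDIR, STUDY_CONFIG

from apadiv import io as fio
from apadiv import pipeline


def main() -> None:
    os.makedirs(SIMDIR, exist_ok=True)
    bundle = pipeline.simulate_all(STUDY_CONFIG)
    fio.write_fasta(os.path.join(SIMDIR, "genome_A.fa"), bundle.genomes.seqs_a)
    fio.write_fasta(os.path.join(SIMDIR, "genome_B.fa"), bundle.genomes.seqs_b)
    fio.write_vcf(os.path.join(SIMDIR, "variants.vcf"), bundle.genomes.vmap,
                  bundle.genomes.seqs_a)
    fio.write_gtf(os.path.join(SIMDIR, "annotation.gtf"), bundle.annotation)
    fio.write_tailmap(os.path.join(SIMDIR, "reads_3reads.tsv"), bundle.reads_3reads)
    for cond, reads in bundle.mrna.items():
        fio.write_tailmap(os.path.join(SIMDIR, f"reads_mrna_{cond}.tsv"), reads)
    fio.write_tailmap(os.path.join(SIMDIR, "reads_mrna_mock.tsv"), bundle.mock)
    for strain, bed in bundle.background.items():
        fio.write_bed6(os.path.join(SIMDIR, f"background_{strain}.bed"), bed)
    truth = pd.DataFrame(
        [{"pas_id": p.pas_id, "gene_id": p.gene_id, "chrom": p.chrom,
          "strand": p.strand, "site": p.site + 1, "category": p.category,
          "effect": p.effect, "causal_variant": p.causal_variant,
          "true_delta": p.true_delta} for p in bundle.truth.all_pas()]
    )
    fio.write_table(os.path.join(SIMDIR, "planted_truth.tsv"), truth)
    n_effects = truth["effect"].value_counts().to_dict()
    print(f"simulated {len(bundle.truth.genes)} genes, {len(truth)} pAs "
          f"({len(bundle.genomes.vmap.variants)} variants); planted effects: {n_effects}")


if __name__ == "__main__":
    main()
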