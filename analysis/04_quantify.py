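"""Quantify pAs usage: parents, F1 alleles, and the mock-F1 calibration.

Counts 3' mRNA-Seq read anchors into the 48-nt reference windows, assigns
F1 and mock reads to alleles by discriminating variants, and applies the
binomial mock-F1 filter.  Writes the parental and allelic count tables and
the mock-filter report.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import SIMDIR, STUDY_CONFIG, rpath

from apadiv import io as fio
from apadiv import quantify
from apadiv import reference as refmod
from apadiv.types import BL, SP


def main() -> None:
    ref = refmod.frame_to_reference(fio.read_table(rpath("reference_pas.tsv")))
    vmap = fio.read_vcf(os.path.join(SIMDIR, "variants.vcf"))
    L = STUDY_CONFIG.read_length

    par_reads = fio.read_tailmap(os.path.join(SIMDIR, "reads_mrna_parentBL.tsv")) + \
        fio.read_tailmap(os.path.join(SIMDIR, "reads_mrna_parentSP.tsv"))
    par_counts, d_par = quantify.count_reads(par_reads, ref)
    parental = quantify.pivot_counts(
        par_counts, ref, {("M_BL", "both"): "BL", ("M_SP", "both"): "SP"})
    fio.write_table(rpath("counts_parental.tsv"), parental)

    f1_reads = fio.read_tailmap(os.path.join(SIMDIR, "reads_mrna_F1.tsv"))
    f1_labels = quantify.assign_alleles(f1_reads, vmap, L)
    f1_counts, d_f1 = quantify.count_reads(f1_reads, ref, f1_labels)
    allelic = quantify.pivot_counts(
        f1_counts, ref, {("M_F1", BL): "F1_BL", ("M_F1", SP): "F1_SP"})
    fio.write_table(rpath("counts_allelic.tsv"), allelic)

    mock_reads = fio.read_tailmap(os.path.join(SIMDIR, "reads_mrna_mock.tsv"))
    mock_labels = quantify.assign_alleles(mock_reads, vmap, L)
    mock_counts, _ = quantify.count_reads(mock_reads, ref, mock_labels)
    mock = quantify.pivot_counts(
        mock_counts, ref, {("mock", BL): "mock_BL", ("mock", SP): "mock_SP"})
    joined = parental.merge(mock, on=["pas_id", "gene_id"], how="left").fillna(0)
    report = quantify.mock_f1_filter(
        {BL: joined.set_index("pas_id")["BL"], SP: joined.set_index("pas_id")["SP"]},
        {BL: joined.set_index("pas_id")["mock_BL"],
         SP: joined.set_index("pas_id")["mock_SP"]})
    fio.write_table(rpath("mock_filter_report.tsv"), report.reset_index())

    amb = sum(lab == "ambiguous" for lab in f1_labels) / len(f1_labels)
    print(f"parental: {int(parental[['BL', 'SP']].sum().sum())} reads counted "
          f"({d_par} discarded); F1: {amb:.1%} ambiguous reads; "
          f"mock filter retains {int(report['retained'].sum())}/{len(report)} pAs")


if __name__ == "__main__":
    main()
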