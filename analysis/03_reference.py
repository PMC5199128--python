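"""Build the annotated cross-strain reference pAs set.

Clusters whose -124..+24 cleavage-site flank lifts over reciprocally (and
colinearly) between the two genomes are merged across strains in strain-A
coordinates, then assigned genes, biotypes and positional categories.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import SIMDIR, rpath

from apadiv import cluster as clmod
from apadiv import io as fio
from apadiv import reference as refmod


def main() -> None:
    vmap = fio.read_vcf(os.path.join(SIMDIR, "variants.vcf"))
    ann = fio.read_gtf(os.path.join(SIMDIR, "annotation.gtf"))
    ca = clmod.frame_to_clusters(fio.read_table(rpath("clusters_BL.tsv")))
    cb = clmod.frame_to_clusters(fio.read_table(rpath("clusters_SP.tsv")))
    surv_a = refmod.mappability_filter(ca, vmap, "A")
    surv_b = refmod.mappability_filter(cb, vmap, "B")
    ref = refmod.merge_reference(surv_a, surv_b, vmap.chrom_lengths_a)
    refmod.annotate_pas(ref, ann)
    frame = refmod.reference_to_frame(ref)
    out = rpath("reference_pas.tsv")
    fio.write_table(out, frame)
    print(f"mappability: {len(ca)}->{len(surv_a)} (BL), {len(cb)}->{len(surv_b)} (SP)")
    print(f"reference: {len(ref)} pAs, sources "
          f"{frame['source'].value_counts().to_dict()}; categories "
          f"{frame['category'].value_counts().to_dict()} -> {out}")


if __name__ == "__main__":
    main()
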