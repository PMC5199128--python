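"""Sequence features of cis-divergent pAs flanks.

Variant densities in the element windows, the 8-nt sliding-window
localization, hexamer enhancer/repressor quadrants, motif-mutation effects
for AAUAAA / AUUAAA / UUUUUU, the poly(U) disruption-depth analysis, and the
trans-set hexamer comparison.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import SIMDIR, rpath

from apadiv import flank
from apadiv import io as fio
from apadiv import pipeline
from apadiv import reference as refmod


def main() -> None:
    ref = refmod.frame_to_reference(fio.read_table(rpath("reference_pas.tsv")))
    vmap = fio.read_vcf(os.path.join(SIMDIR, "variants.vcf"))
    seqs_a = fio.read_fasta(os.path.join(SIMDIR, "genome_A.fa"))
    seqs_b = fio.read_fasta(os.path.join(SIMDIR, "genome_B.fa"))
    records = fio.read_table(rpath("allelic_records.tsv"))
    calls = fio.read_table(rpath("cis_trans_calls.tsv"))
    sites = pipeline.pas_site_records(ref, records)

    cis_ids = set(calls.loc[calls["call"] == "cis", "pas_id"])
    trans_ids = set(calls.loc[calls["call"] == "trans", "pas_id"])
    ctl_ids = set(flank.select_controls(records)["pas_id"])
    cis_rec = sites[sites["pas_id"].isin(cis_ids)]
    ctl_rec = sites[sites["pas_id"].isin(ctl_ids)]
    print(f"{len(cis_rec)} cis-divergent vs {len(ctl_rec)} control pAs")

    dens = flank.compare_density(flank.variant_density(cis_rec, vmap),
                                 flank.variant_density(ctl_rec, vmap))
    fio.write_table(rpath("flank", "variant_density.tsv"), dens)
    print("variant density (cis vs control):")
    print(dens.to_string(index=False))

    sliding = flank.sliding_density(cis_rec, ctl_rec, vmap)
    fio.write_table(rpath("flank", "sliding_density.tsv"), sliding)
    sig = sliding.loc[sliding["significant"], "offset"].tolist()
    print(f"sliding windows: {len(sliding)} tested, significant at offsets {sig}")

    profs = flank.build_flank_profiles(cis_rec, seqs_a, seqs_b, vmap)
    ctl_profs = flank.build_flank_profiles(ctl_rec, seqs_a, seqs_b, vmap)
    quad = flank.hexamer_quadrants(profs)
    fio.write_table(rpath("flank", "hexamer_quadrants.tsv"), quad)
    top = quad[quad["quadrant"] == "enhancer"].head(3)["hexamer"].tolist()
    print(f"top enhancer-quadrant hexamers: {top}")

    for motif in ("AAUAAA", "AUUAAA", "UUUUUU"):
        eff = flank.motif_presence_effect(profs + ctl_profs, motif)
        print(f"{motif}: oriented median delta {eff['median_oriented_delta']:+.1f} "
              f"(n={eff['n_one_allele']}), MWU p {eff['p_value']:.3g}")

    polyu = flank.polyu_tract_analysis(profs + ctl_profs, 6)
    fio.write_table(rpath("flank", "polyu_depth.tsv"), polyu)
    print("poly(U) disruption depth:")
    print(polyu.to_string(index=False))

    trans_rec = sites[sites["pas_id"].isin(trans_ids)]
    if len(trans_rec) >= 2 and len(ctl_rec) >= 2:
        trans_profs = flank.build_flank_profiles(trans_rec, seqs_a, seqs_b, vmap)
        hx = flank.compare_hexamers_groups(trans_profs, ctl_profs)
        fio.write_table(rpath("flank", "trans_hexamers.tsv"), hx)
        print(f"trans-set hexamers: {int(hx['significant'].sum())} significant "
              f"of {len(hx)} (none expected: trans effects have no sequence cause)")


if __name__ == "__main__":
    main()
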