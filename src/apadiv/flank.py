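"""Sequence-level characterization of cis-divergent pAs flanks.

All analyses operate on transcript-oriented, RNA-alphabet flank sequences of
offsets -100..+100 around the cleavage site (offset 0), extracted per allele
(A genome directly; B genome through the liftover chain).  The flank is
divided into the classical element windows: auxiliary upstream AUE
[-100,-40), core upstream CUE [-40,0), core downstream CDE (0,40] and
auxiliary downstream ADE (40,100].
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, mannwhitneyu

from .liftover import VariantMap
from .simulate import revcomp
from .types import BL, SP

FLANK_HALF = 100
OFF0 = FLANK_HALF  # string index of offset 0
ELEMENT_WINDOWS = {"AUE": (-100, -40), "CUE": (-40, 0), "CDE": (1, 41), "ADE": (41, 101)}
UPSTREAM = (-100, 0)  # half-open sense-offset region, "100 nt upstream"
DOWNSTREAM = (1, 101)
CONTROL_P_ADJ = 0.5
CONTROL_MAX_DELTA = 5.0


@dataclass
class FlankProfile:
    """Allele-resolved flank of one pAs (RNA alphabet, transcript-oriented)."""

    pas_id: str
    chrom: str
    strand: str
    site: int  # A coordinates
    seq_bl: str  # 201 nt, index i = offset i - 100
    seq_sp: str
    delta_usage: float = np.nan  # allelic delta, BL - SP, percent

    def seq(self, allele: str) -> str:
        return self.seq_bl if allele == BL else self.seq_sp

    def region(self, allele: str, lo: int, hi: int) -> str:
        """Subsequence over half-open sense offsets [lo, hi)."""
        return self.seq(allele)[lo + OFF0 : hi + OFF0]


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_flank(seqs_a: dict[str, str], seqs_b: dict[str, str], vmap: VariantMap,
                  chrom: str, strand: str, site: int) -> tuple[str, str] | None:
    """Per-allele flank sequences, or None when the site does not lift over."""
    site_b = vmap.liftover_position(chrom, site, "AtoB")
    if site_b is None:
        return None
    out = []
    for seqs, s in ((seqs_a, site), (seqs_b, site_b)):
        lo, hi = s - FLANK_HALF, s + FLANK_HALF + 1
        if lo < 0 or hi > len(seqs[chrom]):
            return None
        raw = seqs[chrom][lo:hi]
        out.append(_to_rna(raw if strand == "+" else revcomp(raw)))
    return out[0], out[1]


def build_flank_profiles(pas_records: pd.DataFrame, seqs_a, seqs_b, vmap) -> list[FlankProfile]:
    """Flank profiles for a records frame with pas_id/chrom/strand/site[/delta]."""
    profiles = []
    for _, row in pas_records.iterrows():
        fl = extract_flank(seqs_a, seqs_b, vmap, row["chrom"], row["strand"], int(row["site"]))
        if fl is None:
            continue
        profiles.append(FlankProfile(row["pas_id"], row["chrom"], row["strand"],
                                     int(row["site"]), fl[0], fl[1],
                                     float(row.get("delta_usage", np.nan))))
    return profiles


# ---------------------------------------------------------------- groups
def select_controls(records: pd.DataFrame, p_adj_min: float = CONTROL_P_ADJ,
                    max_delta: float = CONTROL_MAX_DELTA) -> pd.DataFrame:
    """Non-divergent controls: adjusted p > 0.5 and |delta usage| < 5%."""
    keep = (records["p_adj"] > p_adj_min) & (records["delta_usage"].abs() < max_delta)
    return records[keep.fillna(False)]


def _safe_mwu(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


# -------------------------------------------------------- variant density
def _variant_offsets(vmap: VariantMap, chrom: str, strand: str, site: int) -> np.ndarray:
    """Sense offsets of variants (leftmost base) within the -100..+100 flank."""
    pos = vmap.positions_array(chrom)
    lo, hi = site - FLANK_HALF - 1, site + FLANK_HALF + 1
    sel = pos[(pos >= lo) & (pos <= hi)]
    off = sel - site if strand == "+" else site - sel
    return off[(off >= -FLANK_HALF) & (off <= FLANK_HALF)]


def variant_density(pas_records: pd.DataFrame, vmap: VariantMap) -> pd.DataFrame:
    """Per-pAs variant densities over the full flank and the four windows.

    Indels count once, anchored at their leftmost reference position.  The
    full-flank density uses the 200-position region of offsets [-100, 100).
    """
    rows = []
    for _, row in pas_records.iterrows():
        off = _variant_offsets(vmap, row["chrom"], row["strand"], int(row["site"]))
        dens = {"pas_id": row["pas_id"],
                "density": float(((off >= -100) & (off < 100)).sum()) / 200.0}
        for name, (lo, hi) in ELEMENT_WINDOWS.items():
            dens[name] = float(((off >= lo) & (off < hi)).sum()) / (hi - lo)
        rows.append(dens)
    return pd.DataFrame(rows)


def compare_density(cis_density: pd.DataFrame, control_density: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney comparison of cis vs control densities per window."""
    rows = []
    for col in ["density", *ELEMENT_WINDOWS]:
        p = _safe_mwu(cis_density[col], control_density[col])
        rows.append((col, cis_density[col].mean(), control_density[col].mean(), p))
    return pd.DataFrame(rows, columns=["window", "mean_cis", "mean_control", "p_value"])


def sliding_density(cis_records: pd.DataFrame, control_records: pd.DataFrame,
                    vmap: VariantMap, window: int = 8, step: int = 1) -> pd.DataFrame:
    """Positional variant enrichment: 8-nt sliding windows over [-100, 100).

    Per window position, per-pAs variant counts are compared between the cis
    and control sets by Mann-Whitney U; p-values are Bonferroni-adjusted
    across all 200 - window + 1 tested windows.
    """
    if len(cis_records) < 2 or len(control_records) < 2:
        raise ValueError("each set needs at least 2 pAs")

    def indicator_matrix(records: pd.DataFrame) -> np.ndarray:
        mat = np.zeros((len(records), 2 * FLANK_HALF), dtype=float)
        for i, (_, row) in enumerate(records.iterrows()):
            off = _variant_offsets(vmap, row["chrom"], row["strand"], int(row["site"]))
            off = off[(off >= -FLANK_HALF) & (off < FLANK_HALF)]
            mat[i, off + FLANK_HALF] = 1.0
        return mat

    kernel = np.ones(window)
    cis = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"),
                              1, indicator_matrix(cis_records))
    ctl = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"),
                              1, indicator_matrix(control_records))
    n_windows = cis.shape[1]
    starts = np.arange(-FLANK_HALF, FLANK_HALF - window + 1, step)
    rows = []
    for j, start in enumerate(starts):
        p = _safe_mwu(cis[:, j], ctl[:, j])
        rows.append((int(start), cis[:, j].mean(), ctl[:, j].mean(), p))
    df = pd.DataFrame(rows, columns=["offset", "mean_cis", "mean_control", "p_value"])
    df["p_bonferroni"] = np.minimum(df["p_value"] * n_windows, 1.0)
    df["significant"] = df["p_bonferroni"] < 0.05
    return df


# -------------------------------------------------------------- hexamers
def hexamer_counts(seq: str) -> dict[str, int]:
    """Overlapping hexamer occurrence counts in an RNA sequence."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - 5):
        h = seq[i : i + 6]
        counts[h] = counts.get(h, 0) + 1
    return counts


def hexamer_quadrants(cis_profiles: list[FlankProfile], side: str = "upstream") -> pd.DataFrame:
    """Enhancer/repressor quadrant assignment from allelic hexamer shifts.

    The cis set is split by allelic usage bias (group 1 toward BL, group 2
    toward SP); for each hexamer the allelic occurrence difference (BL - SP)
    over the chosen 100-nt side is summed per group.  Hexamers more frequent
    in the higher-usage allele in both groups (diff > 0 in group 1 and < 0
    in group 2) are pAs-enhancer candidates; the reverse are repressors.
    ``score`` = group1 - group2 difference ranks candidates.
    """
    lo, hi = UPSTREAM if side == "upstream" else DOWNSTREAM
    g1 = [p for p in cis_profiles if p.delta_usage > 0]
    g2 = [p for p in cis_profiles if p.delta_usage < 0]
    if not g1 or not g2:
        raise ValueError("both bias groups must be non-empty")
    sums: dict[str, np.ndarray] = {}
    for gi, group in enumerate((g1, g2)):
        for prof in group:
            cb = hexamer_counts(prof.region(BL, lo, hi))
            cs = hexamer_counts(prof.region(SP, lo, hi))
            for h in set(cb) | set(cs):
                if h not in sums:
                    sums[h] = np.zeros(2)
                sums[h][gi] += cb.get(h, 0) - cs.get(h, 0)
    rows = []
    for h, (d1, d2) in sorted(sums.items()):
        if d1 > 0 and d2 < 0:
            quadrant = "enhancer"
        elif d1 < 0 and d2 > 0:
            quadrant = "repressor"
        else:
            quadrant = "neither"
        rows.append((h, d1, d2, quadrant, d1 - d2))
    df = pd.DataFrame(rows, columns=["hexamer", "diff_group1", "diff_group2",
                                     "quadrant", "score"])
    return df.sort_values("score", ascending=False).reset_index(drop=True)


# ------------------------------------------------------ motif mutation
def motif_intact(profile: FlankProfile, allele: str, motif: str,
                 region: tuple[int, int] = UPSTREAM) -> bool:
    return motif in profile.region(allele, *region)


def motif_mutated(profile: FlankProfile, motif: str,
                  region: tuple[int, int] = UPSTREAM) -> bool:
    """Motif present intact in exactly one allele's region."""
    return motif_intact(profile, BL, motif, region) != motif_intact(profile, SP, motif, region)


def motif_mutation_classes(decreased: list[FlankProfile], increased: list[FlankProfile],
                           unchanged: list[FlankProfile], motif: str,
                           region: tuple[int, int] = UPSTREAM) -> tuple[pd.DataFrame, float]:
    """3x2 mutated/not-mutated contingency across allelic-usage groups.

    Groups follow the allelic comparison: usage decreased (delta < 0),
    increased (delta > 0) and unchanged (controls); a chi-squared test asks
    whether the motif's mutation rate differs across groups.
    """
    if len(motif) != 6:
        raise ValueError("motif must be a hexamer")
    rows = []
    for name, group in (("decreased", decreased), ("increased", increased),
                        ("unchanged", unchanged)):
        mut = sum(motif_mutated(p, motif, region) for p in group)
        rows.append((name, mut, len(group) - mut))
    table = pd.DataFrame(rows, columns=["group", "mutated", "not_mutated"])
    counts = table[["mutated", "not_mutated"]].to_numpy()
    if counts.sum() == 0 or (counts.sum(axis=0) == 0).any():
        p = 1.0
    else:
        p = float(chi2_contingency(counts[counts.sum(axis=1) > 0]).pvalue)
    return table, p


def motif_presence_effect(profiles: list[FlankProfile], motif: str,
                          region: tuple[int, int] = UPSTREAM) -> dict:
    """Allelic usage shift attributable to single-allele motif presence.

    pAs with the motif in exactly one allele form the test group with delta
    usage oriented so positive means the motif-bearing allele is used more;
    pAs with the motif in both alleles or neither form the reference group
    (raw BL - SP delta, symmetric under the null).
    """
    one_allele, both_neither = [], []
    for p in profiles:
        in_bl = motif_intact(p, BL, motif, region)
        in_sp = motif_intact(p, SP, motif, region)
        if in_bl != in_sp:
            one_allele.append(p.delta_usage if in_bl else -p.delta_usage)
        else:
            both_neither.append(p.delta_usage)
    empty = not one_allele or not both_neither
    return {
        "n_one_allele": len(one_allele),
        "n_both_neither": len(both_neither),
        "median_oriented_delta": float(np.median(one_allele)) if one_allele else np.nan,
        "median_reference_delta": float(np.median(both_neither)) if both_neither else np.nan,
        "p_value": np.nan if empty else _safe_mwu(one_allele, both_neither),
    }


# --------------------------------------------------------------- poly(U)
def _max_u_run(seq: str) -> int:
    runs = re.findall(r"U+", seq)
    return max((len(r) for r in runs), default=0)


def polyu_tract_analysis(profiles: list[FlankProfile], tract_length: int = 6,
                         region: tuple[int, int] = UPSTREAM) -> pd.DataFrame:
    """Delta-usage distributions by poly(U) tract disruption depth.

    Background ("Bg"): both alleles carry a maximal U-run of exactly
    ``tract_length`` in the upstream region.  Class ``U_k``: exactly one
    allele carries the intact run while the other's maximal run has length
    k < tract_length; delta usage is oriented to the intact allele.  Each
    class is compared to background by Mann-Whitney U.
    """
    if tract_length < 3:
        raise ValueError("tract_length must be >= 3")
    groups: dict[str, list[float]] = {"Bg": []}
    for p in profiles:
        m_bl = _max_u_run(p.region(BL, *region))
        m_sp = _max_u_run(p.region(SP, *region))
        if m_bl == tract_length and m_sp == tract_length:
            groups["Bg"].append(p.delta_usage)
        elif m_bl == tract_length and m_sp < tract_length:
            groups.setdefault(f"U_{m_sp}", []).append(p.delta_usage)
        elif m_sp == tract_length and m_bl < tract_length:
            groups.setdefault(f"U_{m_bl}", []).append(-p.delta_usage)
    rows = []
    for name in sorted(groups, key=lambda n: (n != "Bg", n)):
        vals = groups[name]
        p = np.nan
        if name != "Bg" and groups["Bg"] and vals:
            p = _safe_mwu(vals, groups["Bg"])
        rows.append((name, len(vals), float(np.median(vals)) if vals else np.nan, p))
    return pd.DataFrame(rows, columns=["group", "n", "median_oriented_delta", "p_value"])


# ------------------------------------------------- trans-set hexamers
def compare_hexamers_groups(trans_profiles: list[FlankProfile],
                            control_profiles: list[FlankProfile],
                            region: tuple[int, int] = UPSTREAM) -> pd.DataFrame:
    """Per-hexamer frequency comparison between trans-regulated and control
    pAs upstream regions (reference-allele sequence), Fisher tests with BH
    adjustment.  Total window counts per set are |set| * (region length - 5).
    """
    def totals(profiles: list[FlankProfile]) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        total = 0
        for p in profiles:
            seq = p.region(BL, *region)
            total += max(len(seq) - 5, 0)
            for h, c in hexamer_counts(seq).items():
                counts[h] = counts.get(h, 0) + c
        return counts, total

    ct, nt = totals(trans_profiles)
    cc, nc = totals(control_profiles)
    rows = []
    for h in sorted(set(ct) | set(cc)):
        a, b = ct.get(h, 0), cc.get(h, 0)
        _, p = fisher_exact([[a, nt - a], [b, nc - b]])
        rows.append((h, a, b, a / nt if nt else np.nan, b / nc if nc else np.nan, p))
    df = pd.DataFrame(rows, columns=["hexamer", "count_trans", "count_control",
                                     "freq_trans", "freq_control", "p_value"])
    if len(df):
        from .divergence import bh_adjust

        df["p_adj"] = bh_adjust(df["p_value"])
        df["significant"] = df["p_adj"] < 0.05
    return df
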