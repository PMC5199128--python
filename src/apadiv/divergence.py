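"""Differential pAs usage and cis/trans attribution.

Per pAs, usage is its read count as a fraction of its gene's reads in a
condition.  Strain (parental) and F1-allele comparisons use a two-sided
Fisher's exact test on the 2x2 table [pAs reads, other-pAs-of-gene reads] x
condition, with replicates summed — an exactly specified surrogate for a
dispersion-aware per-bin model, documented as such.  P-values are
Benjamini-Hochberg adjusted within each family (parental, allelic); an event
is divergent at adjusted p < 0.01 and |delta usage| > 10 percentage points.
A parental-divergent pAs is classified cis when the F1 alleles reproduce the
difference in the same direction, trans when the F1 alleles agree (the
shared trans environment explanation), and ambiguous otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

DIVERGENT_ALPHA = 0.01
MIN_DELTA = 10.0  # percentage points
TRANS_ALPHA = 0.05
TRANS_MAX_DELTA = 5.0


def usage_test(table: pd.DataFrame, conditions: tuple[str, str]) -> pd.DataFrame:
    """Per-pAs Fisher tests of usage between two conditions.

    ``table`` has columns pas_id, gene_id and one count column per condition
    (replicates summed).  Genes with zero reads in a condition are skipped
    with a reason.  Returns a UsageRecord frame with usage percents, delta
    (first minus second condition) and the raw p-value.
    """
    c1, c2 = conditions
    rows = []
    for gene_id, grp in table.groupby("gene_id", sort=True):
        n1, n2 = int(grp[c1].sum()), int(grp[c2].sum())
        if n1 == 0 or n2 == 0:
            for pas_id in grp["pas_id"]:
                rows.append((pas_id, gene_id, np.nan, np.nan, np.nan, np.nan,
                             f"zero gene count in {c1 if n1 == 0 else c2}"))
            continue
        for _, row in grp.iterrows():
            k1, k2 = int(row[c1]), int(row[c2])
            u1, u2 = 100.0 * k1 / n1, 100.0 * k2 / n2
            _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
            rows.append((row["pas_id"], gene_id, u1, u2, u1 - u2, p, ""))
    return pd.DataFrame(
        rows, columns=["pas_id", "gene_id", f"usage_{c1}", f"usage_{c2}",
                       "delta_usage", "p_value", "skip_reason"]
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_divergent(records: pd.DataFrame, alpha: float = DIVERGENT_ALPHA,
                   min_delta: float = MIN_DELTA) -> pd.DataFrame:
    """Attach BH-adjusted p-values and the divergent flag.

    Divergent iff adjusted p < ``alpha`` and |delta usage| > ``min_delta``.
    Records skipped by the usage test are carried through as non-divergent.
    """
    out = records.copy()
    tested = out["p_value"].notna()
    out["p_adj"] = np.nan
    out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p_value"])
    out["divergent"] = tested & (out["p_adj"] < alpha) & (out["delta_usage"].abs() > min_delta)
    return out


def classify_cis_trans(parental: pd.DataFrame, allelic: pd.DataFrame,
                       trans_alpha: float = TRANS_ALPHA,
                       trans_max_delta: float = TRANS_MAX_DELTA,
                       alpha: float = DIVERGENT_ALPHA,
                       min_delta: float = MIN_DELTA) -> pd.DataFrame:
    """Per-pAs cis/trans call from parental and F1-allelic usage records.

    conserved: not parental-divergent.  cis: the allelic comparison is also
    divergent (same thresholds) with the same sign as the parental delta.
    trans: the allelic comparison is clearly null (adjusted p >
    ``trans_alpha`` and |allelic delta| < ``trans_max_delta``).  Everything
    else is ambiguous.  pAs missing from the allelic analysis are excluded
    with a reason.
    """
    par = parental.set_index("pas_id")
    alle = allelic.set_index("pas_id")
    rows = []
    for pas_id, prow in par.iterrows():
        if pas_id not in alle.index:
            rows.append((pas_id, prow["gene_id"], bool(prow["divergent"]), np.nan,
                         np.nan, "excluded", "no allelic record"))
            continue
        arow = alle.loc[pas_id]
        pdiv = bool(prow["divergent"])
        adelta, apadj = float(arow["delta_usage"]), float(arow["p_adj"]) if pd.notna(arow["p_adj"]) else np.nan
        adiv = bool(arow["divergent"])
        if not pdiv:
            call = "conserved"
        elif adiv and np.sign(adelta) == np.sign(float(prow["delta_usage"])):
            call = "cis"
        elif pd.notna(apadj) and apadj > trans_alpha and abs(adelta) < trans_max_delta:
            call = "trans"
        else:
            call = "ambiguous"
        rows.append((pas_id, prow["gene_id"], pdiv, adelta, apadj, call, ""))
    return pd.DataFrame(rows, columns=["pas_id", "gene_id", "parental_divergent",
                                       "allelic_delta", "allelic_p_adj", "call", "reason"])


CODING_CATEGORIES = frozenset({"AltLastExon", "InternalExon", "Intronic"})
NONCODING_CATEGORIES = frozenset({"Tandem3UTR", "Terminal"})


def category_enrichment_test(divergent: pd.Series, categories: pd.Series) -> tuple[np.ndarray, float]:
    """Coding vs non-coding enrichment of divergent pAs (Fisher's exact).

    Builds the 2x2 table [[coding divergent, coding non-divergent],
    [non-coding divergent, non-coding non-divergent]] over pAs whose
    category affects the coding sequence (alternative last exon, internal
    exon, intronic) versus 3' UTR-only categories (tandem 3' UTR, terminal).
    """
    coding = categories.isin(CODING_CATEGORIES)
    noncoding = categories.isin(NONCODING_CATEGORIES)
    div = divergent.astype(bool)
    table = np.array([
        [int((coding & div).sum()), int((coding & ~div).sum())],
        [int((noncoding & div).sum()), int((noncoding & ~div).sum())],
    ])
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty coding or non-coding stratum")
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
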