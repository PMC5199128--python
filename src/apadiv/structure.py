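"""RNA secondary-structure analyses around cleavage sites.

Two backends compute a per-window minimum free energy (MFE).  The default
surrogate is Nussinov base-pair maximization (Watson-Crick plus G.U wobble,
minimum hairpin loop of 3 unpaired bases) scored at -1 per pair; it is exact
for its own energy model and preserves the *relative* allelic stability
differences the analysis tests.  An adapter invokes an external RNAfold
binary when one is available, passing its thermodynamic MFE through.  All
group comparisons are backend-agnostic.

PARS scores summarize structure-probing data: per base,
log2((V1 + c) / (S1 + c)) after scaling both libraries to equal totals,
positive meaning a propensity for double-stranded conformation.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .flank import ELEMENT_WINDOWS, FlankProfile
from .types import BL, SP

_CAN_PAIR = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")})
MIN_LOOP = 3
PAIR_ENERGY = -1.0
RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    mfe: float
    backend: str


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


def nussinov_mfe(seq: str) -> float:
    """Maximum base pairing as a pseudo-energy (-1 per pair, min loop 3)."""
    n = len(seq)
    if n < MIN_LOOP + 2:
        return 0.0
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            if can_pair(seq[i], seq[j]):
                inner = dp[i + 1, j - 1] if j - 1 >= i + 1 else 0
                best = max(best, inner + 1)
            for k in range(i + MIN_LOOP + 1, j):
                if can_pair(seq[i], seq[k]):
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, inner + 1 + right)
            dp[i, j] = best
    return PAIR_ENERGY * float(dp[0, n - 1])


def rnafold_mfe(seq: str, binary: str = "RNAfold") -> float:
    """MFE from an external thermodynamic folder (ViennaRNA RNAfold)."""
    proc = subprocess.run(
        [binary, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    last = proc.stdout.strip().splitlines()[-1]
    return float(last.rsplit("(", 1)[1].rstrip(")").strip())


def fold_mfe(sequence: str, backend: str = "nussinov") -> FoldResult:
    """Fold one RNA sequence with the selected backend.

    ``backend`` is "nussinov" (default surrogate), "rnafold" (requires the
    binary on PATH), or a path to an RNAfold-compatible executable.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 1 or not set(seq) <= RNA_ALPHABET:
        raise ValueError(f"invalid RNA sequence {sequence!r}")
    if backend == "nussinov":
        return FoldResult(seq, nussinov_mfe(seq), "nussinov")
    binary = "RNAfold" if backend == "rnafold" else backend
    if shutil.which(binary) is None:
        raise FileNotFoundError(f"folding backend {binary!r} not found")
    return FoldResult(seq, rnafold_mfe(seq, binary), "rnafold")


# -------------------------------------------------------- allelic delta-MFE
def allelic_mfe_analysis(groups: dict[str, list[FlankProfile]],
                         backend: str = "nussinov") -> pd.DataFrame:
    """Allelic MFE differences per element window, biased groups vs controls.

    ``groups`` maps group name -> flank profiles; it must contain a
    "control" group, with the remaining groups (e.g. usage biased toward BL
    / toward SP) each compared to it by two-sample Kolmogorov-Smirnov on the
    per-pAs delta MFE = MFE(BL window) - MFE(SP window).
    """
    if "control" not in groups:
        raise ValueError("groups must include 'control'")
    for name, profs in groups.items():
        if len(profs) < 2:
            raise ValueError(f"group {name!r} needs >= 2 pAs")

    @lru_cache(maxsize=None)
    def mfe(seq: str) -> float:
        return fold_mfe(seq, backend).mfe

    deltas: dict[tuple[str, str], np.ndarray] = {}
    for name, profs in groups.items():
        for win, (lo, hi) in ELEMENT_WINDOWS.items():
            deltas[(name, win)] = np.array(
                [mfe(p.region(BL, lo, hi)) - mfe(p.region(SP, lo, hi)) for p in profs]
            )
    rows = []
    for name in groups:
        if name == "control":
            continue
        for win in ELEMENT_WINDOWS:
            d, c = deltas[(name, win)], deltas[("control", win)]
            p = float(ks_2samp(d, c).pvalue)
            rows.append((name, win, float(np.mean(d)), float(np.mean(c)), p))
    return pd.DataFrame(rows, columns=["group", "window", "mean_delta_mfe",
                                       "mean_control_delta_mfe", "ks_p"])


# ------------------------------------------------------------------- PARS
def pars_scores(v1_counts: np.ndarray, s1_counts: np.ndarray,
                pseudocount: float = 5.0) -> np.ndarray:
    """Per-base PARS track from paired (V1) and unpaired (S1) probe counts.

    Libraries are scaled to equal totals before the per-base
    log2((V1 + c) / (S1 + c)) ratio.
    """
    v1 = np.asarray(v1_counts, dtype=float)
    s1 = np.asarray(s1_counts, dtype=float)
    if v1.shape != s1.shape:
        raise ValueError("count tracks must have equal length")
    if (v1 < 0).any() or (s1 < 0).any():
        raise ValueError("negative probe counts")
    tv, ts = v1.sum(), s1.sum()
    if tv > 0 and ts > 0:
        mean_total = (tv + ts) / 2.0
        v1 = v1 * (mean_total / tv)
        s1 = s1 * (mean_total / ts)
    return np.log2((v1 + pseudocount) / (s1 + pseudocount))


def pars_metagene(pars_track: dict[str, np.ndarray], pas_records: pd.DataFrame,
                  half: int = 100, distal_only: bool = False) -> pd.DataFrame:
    """Mean PARS per sense offset (-half..+half) across pAs.

    ``pas_records`` needs pas_id/gene_id/chrom/strand/site; with
    ``distal_only`` each gene contributes only its 3'-most (most downstream)
    pAs.  Offsets are transcript-oriented.
    """
    if len(pas_records) == 0:
        raise ValueError("empty pAs set")
    records = pas_records
    if distal_only:
        def downstream_rank(row):
            return row["site"] if row["strand"] == "+" else -row["site"]
        records = records.loc[
            records.apply(downstream_rank, axis=1).groupby(records["gene_id"]).idxmax()
        ]
    offsets = np.arange(-half, half + 1)
    acc = np.zeros(len(offsets))
    n = np.zeros(len(offsets))
    for _, row in records.iterrows():
        track = pars_track[row["chrom"]]
        site = int(row["site"])
        pos = site + offsets if row["strand"] == "+" else site - offsets
        ok = (pos >= 0) & (pos < len(track))
        acc[ok] += track[pos[ok]]
        n[ok] += 1
    return pd.DataFrame({"offset": offsets, "mean_pars": acc / np.maximum(n, 1),
                         "n_pas": n.astype(int)})
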