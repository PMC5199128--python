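"""Coordinate liftover between a strain pair, derived from their variant map.

The two haploid genomes A (reference strain) and B (alternate strain) differ
by a sorted, non-overlapping set of SNPs and short indels.  Outside variant
positions the genomes are colinear, so every position maps through a block
chain built from cumulative indel length differences.  Positions inside a
deleted segment are unmappable in the other genome.  The reciprocal-
mappability filter of the reference module is built on this: a window is kept
only if lifting it over and back returns the original endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SNP, INS, DEL = "SNP", "INS", "DEL"

UNMAPPABLE = -1


@dataclass(frozen=True)
class Variant:
    """One inter-strain difference, in genome-A coordinates.

    ``pos`` is 0-based: the affected base for a SNP, the first deleted base
    for a DEL, and the base *before which* the inserted sequence sits for an
    INS.  ``ref`` / ``alt`` are the A and B sequences over the affected span
    (empty string on the zero-length side of an indel).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return SNP
        if len(self.ref) == 0:
            return INS
        if len(self.alt) == 0:
            return DEL
        raise ValueError(f"unsupported variant shape {self.ref}>{self.alt}")


class _ChromChain:
    """Per-chromosome mapping arrays for one direction (source -> target)."""

    def __init__(self, pos: np.ndarray, len_src: np.ndarray, len_tgt: np.ndarray):
        self.pos = pos
        self.len_src = len_src
        self.len_tgt = len_tgt
        self.src_end = pos + len_src
        # cumulative offset applying to positions at/after each variant's end
        self.cum = np.concatenate([[0], np.cumsum(len_tgt - len_src)])

    def map(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=np.int64)
        if len(self.pos) == 0:
            return p.copy()
        idx = np.searchsorted(self.src_end, p, side="right")
        out = p + self.cum[idx]
        # positions inside a source-only (deleted) span are unmappable;
        # SNP spans (len_src == len_tgt) map base-for-base
        cand = np.clip(np.searchsorted(self.pos, p, side="right") - 1, 0, None)
        inside = (p >= self.pos[cand]) & (p < self.src_end[cand])
        deleted = inside & (self.len_tgt[cand] == 0)
        return np.where(deleted, UNMAPPABLE, out)


class VariantMap:
    """Sorted inter-strain variants plus the derived liftover chain."""

    def __init__(self, variants: list[Variant], chrom_lengths_a: dict[str, int]):
        self.variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
        self.chrom_lengths_a = dict(chrom_lengths_a)
        self._validate()
        self._chains_ab: dict[str, _ChromChain] = {}
        self._chains_ba: dict[str, _ChromChain] = {}
        self.chrom_lengths_b: dict[str, int] = {}
        self._build()

    def _validate(self) -> None:
        prev: dict[str, int] = {}
        for v in self.variants:
            v.vtype  # shape check
            if v.chrom in prev and v.pos < prev[v.chrom]:
                raise ValueError(f"overlapping variants near {v.chrom}:{v.pos}")
            prev[v.chrom] = v.pos + max(len(v.ref), 1)

    def _build(self) -> None:
        by_chrom: dict[str, list[Variant]] = {c: [] for c in self.chrom_lengths_a}
        for v in self.variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for chrom, vs in by_chrom.items():
            pos_a = np.array([v.pos for v in vs], dtype=np.int64)
            len_a = np.array([len(v.ref) for v in vs], dtype=np.int64)
            len_b = np.array([len(v.alt) for v in vs], dtype=np.int64)
            self._chains_ab[chrom] = _ChromChain(pos_a, len_a, len_b)
            # variant positions in B coordinates: shift by offsets accrued before
            off_before = self._chains_ab[chrom].cum[:-1] if len(vs) else pos_a
            pos_b = pos_a + off_before
            self._chains_ba[chrom] = _ChromChain(pos_b, len_b.copy(), len_a.copy())
            la = self.chrom_lengths_a.get(chrom, 0)
            self.chrom_lengths_b[chrom] = int(la + (len_b - len_a).sum())

    # ------------------------------------------------------------------
    def by_chrom(self, chrom: str) -> list[Variant]:
        return [v for v in self.variants if v.chrom == chrom]

    def positions_array(self, chrom: str) -> np.ndarray:
        """Leftmost A-coordinates of all variants on ``chrom`` (for density)."""
        return self._chains_ab[chrom].pos

    def map_positions(self, chrom: str, positions, direction: str = "AtoB") -> np.ndarray:
        """Vectorized liftover; unmappable positions become -1.

        Raises for positions outside the source chromosome bounds.
        """
        if chrom not in self._chains_ab:
            raise KeyError(f"unknown chromosome {chrom!r}")
        chain = self._chains_ab[chrom] if direction == "AtoB" else self._chains_ba[chrom]
        length = (
            self.chrom_lengths_a[chrom] if direction == "AtoB" else self.chrom_lengths_b[chrom]
        )
        p = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if ((p < 0) | (p >= length)).any():
            raise ValueError(f"position outside chromosome bounds on {chrom}")
        return chain.map(p)

    def liftover_position(self, chrom: str, pos: int, direction: str = "AtoB") -> int | None:
        """Map one position; returns None when it falls in a deleted segment."""
        out = int(self.map_positions(chrom, [pos], direction)[0])
        return None if out == UNMAPPABLE else out

    def liftover_window(
        self, chrom: str, start: int, end: int, direction: str = "AtoB", require_reciprocal: bool = True
    ) -> tuple[int, int] | None:
        """Map a half-open window through both endpoints, colinearly.

        Returns the mapped ``(start, end)`` or None when the window is not
        fully alignable between the genomes: an endpoint falls in a deleted
        segment, the mapped span changes length (an indel lies inside the
        window), or (with ``require_reciprocal``) the round trip does not
        restore the original endpoints.
        """
        a = self.liftover_position(chrom, start, direction)
        b = self.liftover_position(chrom, end - 1, direction)
        if a is None or b is None or a > b:
            return None
        if b - a != (end - 1) - start:
            return None
        if require_reciprocal:
            back = "BtoA" if direction == "AtoB" else "AtoB"
            ra = self.liftover_position(chrom, a, back)
            rb = self.liftover_position(chrom, b, back)
            if ra != start or rb != end - 1:
                return None
        return a, b + 1

    # ------------------------------------------------------------------
    def apply_to_sequence(self, chrom: str, seq_a: str) -> str:
        """Construct the genome-B chromosome sequence from genome A."""
        parts: list[str] = []
        cursor = 0
        for v in self.by_chrom(chrom):
            parts.append(seq_a[cursor : v.pos])
            parts.append(v.alt)
            cursor = v.pos + len(v.ref)
        parts.append(seq_a[cursor:])
        out = "".join(parts)
        if len(out) != self.chrom_lengths_b[chrom]:
            raise AssertionError("chain length inconsistency")
        return out
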