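"""Seed-region base-preference profiles and length distributions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
SEED_POSITIONS = (2, 7)  # 1-based, inclusive


@dataclass
class SeedProfile:
    positions: Tuple[int, ...]
    freq: pd.DataFrame  # positions x bases, rows sum to 1
    consensus: str
    n_sequences: int
    n_excluded: int = 0


def seed_profile(sequences: Sequence[str],
                 weights: Optional[Sequence[float]] = None,
                 positions: Tuple[int, int] = SEED_POSITIONS) -> SeedProfile:
    """Position-wise base frequencies over the seed region (default 2-7).

    Sequences shorter than the last seed position are excluded (counted in
    ``n_excluded``). Optional weights (e.g. read counts) weight each
    sequence's contribution. Consensus ties break alphabetically.
    """
    lo, hi = positions
    pos_list = tuple(range(lo, hi + 1))
    if weights is None:
        weights = [1.0] * len(sequences)
    if len(weights) != len(sequences):
        raise ValueError("weights length mismatch")
    mat = np.zeros((len(pos_list), 4))
    n_used, n_excluded = 0, 0
    for seq, w in zip(sequences, weights):
        s = seq.upper().replace("U", "T")
        if len(s) < hi:
            n_excluded += 1
            continue
        n_used += 1
        for row, p in enumerate(pos_list):
            base = s[p - 1]
            if base in BASES:
                mat[row, BASES.index(base)] += w
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(sums > 0, mat / sums, 0.0)
    consensus = "".join(BASES[int(np.argmax(row))] for row in freq)
    return SeedProfile(
        positions=pos_list,
        freq=pd.DataFrame(freq, index=list(pos_list), columns=list(BASES)),
        consensus=consensus, n_sequences=n_used, n_excluded=n_excluded)


def length_distribution(lengths: Sequence[int],
                        read_counts: Optional[Sequence[float]] = None,
                        bins: Tuple[int, int] = (15, 45)) -> pd.DataFrame:
    """Integer-binned length histogram, by distinct sequence and by reads."""
    lo, hi = bins
    idx = range(lo, hi + 1)
    distinct = pd.Series(0.0, index=idx)
    reads = pd.Series(0.0, index=idx)
    if read_counts is None:
        read_counts = [1.0] * len(lengths)
    for length, c in zip(lengths, read_counts):
        if lo <= length <= hi:
            distinct[length] += 1
            reads[length] += c
    return pd.DataFrame({"n_distinct": distinct, "n_reads": reads})
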