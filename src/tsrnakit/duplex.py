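"""Seed-match target scanning and nearest-neighbor duplex MFE.

A candidate site is a 3'UTR window whose 6-mer is the exact reverse
complement of regulator positions 2-7 (the seed; no G:U allowed there).
Each candidate window (seed site extended 30 nt upstream on the UTR) is
scored by a dynamic program over intermolecular duplex alignments allowing
stacks, bulges and internal loops (G:U permitted outside the seed); hits
with minimum free energy at or below the retention threshold (default
-20 kcal/mol) survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .energy_params import DEFAULT_ENERGY_MODEL, PAIRS, EnergyModel

ENERGY_THRESHOLD = -20.0  # kcal/mol
SEED_UPSTREAM_EXTENSION = 30  # nt of UTR 5' of the seed site in the window

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(_rna(seq)))


@dataclass(frozen=True)
class DuplexHit:
    regulator_id: str
    gene_id: str
    site_start: int  # 1-based closed, on the UTR
    site_end: int
    mfe: float
    seed_class: str  # "full_2_7"
    duplex_trace: Tuple[Tuple[int, int], ...]  # (regulator pos, window pos)


def seed_scan(regulator_seq: str, utr_seq: str,
              seed_positions: Tuple[int, int] = (2, 7)
              ) -> List[Tuple[int, int]]:
    """All UTR windows reverse-complementary to the regulator seed.

    Returns 1-based closed (start, end) seed-site intervals on the UTR.
    """
    reg = _rna(regulator_seq)
    utr = _rna(utr_seq)
    lo, hi = seed_positions
    if len(reg) < hi + 1:
        raise ValueError(f"regulator shorter than {hi + 1} nt")
    seed = reg[lo - 1:hi]
    site = reverse_complement(seed)  # exact WC, no G:U in the seed
    k = len(site)
    out = []
    pos = utr.find(site)
    while pos != -1:
        out.append((pos + 1, pos + k))
        pos = utr.find(site, pos + 1)
    return out


def duplex_mfe(regulator_seq: str, window_seq: str,
               model: EnergyModel = DEFAULT_ENERGY_MODEL
               ) -> Tuple[Optional[float], Tuple[Tuple[int, int], ...]]:
    """Minimum free energy of an intermolecular duplex, by dynamic programming.

    The regulator is read 5'->3'; the window is a UTR fragment read 5'->3'
    and paired antiparallel. States are "last paired position" pairs; moves
    append one more base pair at a gap of at most ``max_loop`` unpaired
    nucleotides per side, costing a stack energy (contiguous) or a linear
    bulge/internal-loop penalty. Returns (mfe, trace) where the trace lists
    paired (regulator position, window position) 1-based tuples, or
    (None, ()) when no admissible duplex exists (window < 8 nt or no
    complementary pair).
    """
    reg = _rna(regulator_seq)
    win = _rna(window_seq)
    if len(win) < 8:
        return None, ()
    m, n = len(reg), len(win)
    rev = win[::-1]  # rev[k] is window position n-k (0-based k)
    maxg = model.max_loop
    INF = float("inf")
    best = [[INF] * n for _ in range(m)]
    parent: Dict[Tuple[int, int], Optional[Tuple[int, int]]] = {}
    cells = [(i, k) for i in range(m) for k in range(n)
             if (reg[i], rev[k]) in PAIRS]
    for i, k in cells:
        best[i][k] = model.init_penalty
        parent[(i, k)] = None
    # pairs extend with increasing i and k; process in lexicographic order
    for i, k in sorted(cells):
        e = best[i][k]
        if e == INF:
            continue
        for di in range(1, maxg + 2):
            i2 = i + di
            if i2 >= m:
                break
            for dk in range(1, maxg + 2):
                k2 = k + dk
                if k2 >= n or (reg[i2], rev[k2]) not in PAIRS:
                    continue
                if di == 1 and dk == 1:
                    step = model.stack(reg[i], reg[i2], rev[k], rev[k2])
                else:
                    step = model.gap_cost(di - 1, dk - 1)
                if e + step < best[i2][k2] - 1e-12:
                    best[i2][k2] = e + step
                    parent[(i2, k2)] = (i, k)
    mfe = INF
    arg = None
    for i, k in cells:
        if best[i][k] < mfe:
            mfe = best[i][k]
            arg = (i, k)
    if arg is None:
        return None, ()
    trace = []
    node: Optional[Tuple[int, int]] = arg
    while node is not None:
        i, k = node
        trace.append((i + 1, n - k))  # back to 1-based window coordinates
        node = parent[node]
    trace.reverse()
    return float(mfe), tuple(trace)


def predict_targets(regulators: Mapping[str, str], utrs: Mapping[str, str],
                    energy_threshold: float = ENERGY_THRESHOLD,
                    model: EnergyModel = DEFAULT_ENERGY_MODEL
                    ) -> List[DuplexHit]:
    """Seed-scan every (regulator, UTR) pair, energy-filter, keep best hit.

    One best (lowest-MFE) hit per (regulator, gene); ties broken by the
    leftmost seed site.
    """
    hits: List[DuplexHit] = []
    for reg_id in sorted(regulators):
        reg_seq = regulators[reg_id]
        for gene_id in sorted(utrs):
            utr = _rna(utrs[gene_id])
            best_hit: Optional[DuplexHit] = None
            for site_start, site_end in seed_scan(reg_seq, utr):
                win_start = max(1, site_start - SEED_UPSTREAM_EXTENSION)
                window = utr[win_start - 1:site_end]
                mfe, trace = duplex_mfe(reg_seq, window, model)
                if mfe is None or mfe > energy_threshold:
                    continue
                # shift trace window coordinates back onto the UTR
                utr_trace = tuple((ri, wi + win_start - 1) for ri, wi in trace)
                hit = DuplexHit(reg_id, gene_id, site_start, site_end,
                                mfe, "full_2_7", utr_trace)
                if best_hit is None or mfe < best_hit.mfe - 1e-12 or (
                        abs(mfe - best_hit.mfe) <= 1e-12
                        and site_start < best_hit.site_start):
                    best_hit = hit
            if best_hit is not None:
                hits.append(best_hit)
    return hits


def hits_to_table(hits: Sequence[DuplexHit]):
    import pandas as pd

    return pd.DataFrame(
        [(h.regulator_id, h.gene_id, h.site_start, h.site_end, h.mfe,
          h.seed_class) for h in hits],
        columns=["regulator_id", "gene_id", "site_start", "site_end", "mfe",
                 "seed_class"])
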