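"""Nearest-neighbor duplex energy parameters (kcal/mol at 37 C).

A Turner-2004-style stacking table for intermolecular RNA duplexes. A stack
is two consecutive base pairs written

    5'-X1 X2-3'
    3'-Y1 Y2-5'

and keyed as ``"X1X2/Y1Y2"`` where Y1 pairs X1 and Y2 pairs X2. Watson-Crick
values are the standard published set; G:U wobble stacks use a simplified,
uniformly stabilizing set (all canonical stacks <= 0). DNA input is treated
as RNA (T = U). Unpaired nucleotides in bulges and internal loops are
penalized linearly; duplex initiation carries a fixed positive cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

#: Watson-Crick / wobble pairing (RNA alphabet, T treated as U upstream).
PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

# Unique Watson-Crick stacks (Turner 2004 DeltaG37); the rest follow by the
# rotational symmetry  X1X2/Y1Y2 == reverse-of-Y1Y2 / reverse-of-X1X2.
_WC_UNIQUE = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}

# Simplified wobble set: any stack containing a G:U pair. Milder than WC
# stacks, never destabilizing (keeps the monotonicity property: adding a
# canonical stack never raises the energy).
_WOBBLE_GU = -0.5


def _rotate(key: str) -> str:
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


def _build_stack_table() -> Dict[str, float]:
    table: Dict[str, float] = {}
    for key, dg in _WC_UNIQUE.items():
        table[key] = dg
        table[_rotate(key)] = dg
    alphabet = "ACGU"
    for x1 in alphabet:
        for x2 in alphabet:
            for y1 in alphabet:
                for y2 in alphabet:
                    if (x1, y1) in PAIRS and (x2, y2) in PAIRS:
                        key = f"{x1}{x2}/{y1}{y2}"
                        if key not in table:
                            table[key] = _WOBBLE_GU
    return table


STACK_ENERGIES: Dict[str, float] = _build_stack_table()


@dataclass(frozen=True)
class EnergyModel:
    """Parameterization of the duplex free-energy model."""

    stack_energies: Dict[str, float] = field(
        default_factory=lambda: dict(STACK_ENERGIES))
    init_penalty: float = 4.09
    bulge_penalty: float = 3.0  # kcal/mol per unpaired nt, one-sided gap
    internal_loop_penalty: float = 1.5  # kcal/mol per unpaired nt, two-sided
    max_loop: int = 4  # max unpaired nt per side between consecutive pairs

    def validate(self) -> None:
        wc = {"AU", "UA", "CG", "GC"}
        for key, dg in self.stack_energies.items():
            top, bottom = key.split("/")
            if {top[0] + bottom[0], top[1] + bottom[1]} <= wc and dg > 0:
                raise ValueError(f"Watson-Crick stack {key} must be <= 0")
        if self.init_penalty < 0 or self.bulge_penalty < 0 \
                or self.internal_loop_penalty < 0:
            raise ValueError("penalties must be >= 0")

    def stack(self, x1: str, x2: str, y1: str, y2: str) -> float:
        return self.stack_energies[f"{x1}{x2}/{y1}{y2}"]

    def gap_cost(self, gap_top: int, gap_bottom: int) -> float:
        """Cost of unpaired nucleotides between two consecutive pairs."""
        if gap_top == 0 and gap_bottom == 0:
            raise ValueError("no gap")
        if gap_top > 0 and gap_bottom > 0:
            return self.internal_loop_penalty * (gap_top + gap_bottom)
        return self.bulge_penalty * (gap_top + gap_bottom)


DEFAULT_ENERGY_MODEL = EnergyModel()
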