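"""Formal net-charge accounting for protein domains.

Charges are compositional integers (no pKa/pH model): Arg and Lys +1, Asp
and Glu -1, His 0 by default, optional +1/-1 terminal contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_CHARGES: Dict[str, int] = {"R": 1, "K": 1, "D": -1, "E": -1, "H": 0}


@dataclass(frozen=True)
class ChargeRule:
    charges: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHARGES))
    count_n_terminus: bool = False
    count_c_terminus: bool = False

    def __post_init__(self):
        bad = set(self.charges) - AA20
        if bad:
            raise ValueError(f"charges assigned to non-standard letters: {sorted(bad)}")

    def residue_charge(self, aa: str) -> int:
        return self.charges.get(aa, 0)


def net_charge(sequence: str, rule: ChargeRule = ChargeRule()) -> int:
    """Sum of per-residue formal charges plus terminal contributions."""
    seq = sequence.strip().upper()
    total = 0
    for i, aa in enumerate(seq):
        if aa not in AA20:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        total += rule.residue_charge(aa)
    if rule.count_n_terminus:
        total += 1
    if rule.count_c_terminus:
        total -= 1
    return total


def window_profile(sequence: str, window: int,
                   rule: ChargeRule = ChargeRule()) -> np.ndarray:
    """Sliding net charge, one value per window start position.

    Terminal contributions are applied only to windows that actually contain
    the respective terminus.
    """
    seq = sequence.strip().upper()
    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    per_res = np.empty(len(seq), dtype=int)
    for i, aa in enumerate(seq):
        if aa not in AA20:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        per_res[i] = rule.residue_charge(aa)
    csum = np.concatenate([[0], np.cumsum(per_res)])
    n = len(seq) - window + 1
    out = csum[window:] - csum[:n]
    out = out.astype(int)
    if rule.count_n_terminus:
        out[0] += 1
    if rule.count_c_terminus:
        out[n - 1] -= 1
    return out
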