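"""Inverted-repeat (IR) promoter-box scanning and split-anchor conservation
profiling.

An IR box is two hexamers in inverted orientation separated by a short
spacer; a hit is scored by the Hamming distance between the second hexamer
and the reverse complement of the first.  Because the pair is its own
reverse complement, each (position, spacer) is reported once, never once per
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import hamming, revcomp, validate_dna

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class IRBox:
    window_id: str
    hex1_start: int
    hex2_start: int
    spacer: int
    mismatches: int = 0
    hexamer_len: int = 6

    @property
    def total_span(self) -> int:
        return 2 * self.hexamer_len + self.spacer

    @property
    def centre_distance(self) -> int:
        """Centre-to-centre distance between the two hexamers, in bp."""
        return self.hex2_start - self.hex1_start

    def __post_init__(self):
        if self.hex2_start - (self.hex1_start + self.hexamer_len) != self.spacer:
            raise ValueError("inconsistent IRBox geometry")


@dataclass
class ConservationProfile:
    """Per-column base counts and information content of an aligned stack.

    ``counts`` has shape (n_columns, 4) over A,C,G,T; ``information`` is
    2 - Shannon entropy (log2) per column, in bits.  ``labels`` names each
    column; ``anchor`` tags the anchoring scheme used to build the stack.
    """

    counts: np.ndarray
    n_sequences: int
    anchor: str = "none"
    labels: list = field(default_factory=list)
    skipped: int = 0

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.25)

    @property
    def information(self) -> np.ndarray:
        p = self.probabilities
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)


def profile_from_probs(probs: np.ndarray, anchor: str = "pfm") -> ConservationProfile:
    """Wrap an (n_columns, 4) probability matrix as a profile (counts = probs)."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 4:
        raise ValueError("expected an (n_columns, 4) matrix over A,C,G,T")
    return ConservationProfile(counts=probs, n_sequences=1, anchor=anchor)


def scan(
    window: str,
    hexamer_len: int = 6,
    spacers: Iterable[int] = (15, 16),
    max_mismatch: int = 1,
    window_id: str = "",
) -> list[IRBox]:
    """Exhaustive (position, spacer) scan for inverted-hexamer boxes.

    Boxes are sorted by (mismatches, hex1_start, spacer).
    """
    window = window.upper()
    validate_dna(window)
    spacers = sorted(set(int(s) for s in spacers))
    if not spacers or min(spacers) < 0:
        raise ValueError("spacers must be non-negative")
    min_len = 2 * hexamer_len + max(spacers)
    if len(window) < min_len:
        raise ValueError(
            f"window length {len(window)} < minimal box span {min_len}")
    hits = []
    for spacer in spacers:
        span = 2 * hexamer_len + spacer
        for pos in range(len(window) - span + 1):
            hex1 = window[pos : pos + hexamer_len]
            hex2 = window[pos + hexamer_len + spacer : pos + span]
            mm = hamming(hex2, revcomp(hex1))
            if mm <= max_mismatch:
                hits.append(
                    IRBox(window_id=window_id, hex1_start=pos,
                          hex2_start=pos + hexamer_len + spacer,
                          spacer=spacer, mismatches=mm,
                          hexamer_len=hexamer_len)
                )
    hits.sort(key=lambda b: (b.mismatches, b.hex1_start, b.spacer))
    return hits


def redundancy_filter(windows: Sequence[str], threshold: float = 0.90) -> list[str]:
    """Greedy redundancy filter over equal-length windows.

    In input order, a window is kept iff its ungapped identity (exact
    matches / length) to every previously kept window is < ``threshold``.
    """
    windows = [w.upper() for w in windows]
    if not windows:
        return []
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows must all have equal length")
    kept: list[str] = []
    for w in windows:
        if all((L - hamming(w, k)) / L < threshold for k in kept):
            kept.append(w)
    return kept


def split_profile(
    windows: Sequence[str],
    boxes: Sequence[Optional[IRBox]],
    pseudocount: float = 0.0,
) -> ConservationProfile:
    """Split-anchor conservation profile of a set of windows with IR boxes.

    Columns upstream of and including hexamer 1 are stacked right-aligned on
    the hexamer-1 anchor; the hexamer-2 columns are stacked independently on
    the hexamer-2 anchor, so variable spacer lengths cannot smear them.
    Windows whose box is None are skipped and counted in ``skipped``.
    """
    pairs = [(w.upper(), b) for w, b in zip(windows, boxes) if b is not None]
    skipped = len(windows) - len(pairs)
    if not pairs:
        return ConservationProfile(counts=np.zeros((0, 4)), n_sequences=0,
                                   anchor="split", skipped=skipped)
    hlen = pairs[0][1].hexamer_len
    if any(b.hexamer_len != hlen for _, b in pairs):
        raise ValueError("mixed hexamer lengths")
    # columns available upstream of (and including) hexamer 1, right-aligned
    n_up = min(b.hex1_start + hlen for _, b in pairs)
    n_cols = n_up + hlen
    counts = np.full((n_cols, 4), float(pseudocount))
    for w, b in pairs:
        hex1_end = b.hex1_start + hlen
        for col in range(n_up):
            base = w[hex1_end - n_up + col]
            if base in _BASE_INDEX:
                counts[col, _BASE_INDEX[base]] += 1
        for col in range(hlen):
            base = w[b.hex2_start + col]
            if base in _BASE_INDEX:
                counts[n_up + col, _BASE_INDEX[base]] += 1
    labels = [f"up{-(n_up - i)}" for i in range(n_up - hlen)]
    labels += [f"hex1.{i + 1}" for i in range(hlen)]
    labels += [f"hex2.{i + 1}" for i in range(hlen)]
    return ConservationProfile(counts=counts, n_sequences=len(pairs),
                               anchor="split", labels=labels, skipped=skipped)


def naive_profile(windows: Sequence[str]) -> ConservationProfile:
    """Fixed-coordinate stack of equal-length windows (no anchoring)."""
    windows = [w.upper() for w in windows]
    if not windows:
        return ConservationProfile(counts=np.zeros((0, 4)), n_sequences=0,
                                   anchor="fixed")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows must all have equal length")
    counts = np.zeros((L, 4))
    for w in windows:
        for col, base in enumerate(w):
            if base in _BASE_INDEX:
                counts[col, _BASE_INDEX[base]] += 1
    return ConservationProfile(counts=counts, n_sequences=len(windows),
                               anchor="fixed",
                               labels=[str(i) for i in range(L)])


def write_meme_minimal(profile: ConservationProfile, name: str, path) -> None:
    """Write a profile as a MEME-minimal-format position frequency matrix."""
    p = profile.probabilities
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {p.shape[0]} "
            f"nsites= {profile.n_sequences} E= 0\n"
        )
        for row in p:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
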