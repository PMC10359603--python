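"""Classification of candidate proteins as activator-like (DUF6499+DUF2285,
carrying the AWEFLRRN motif) versus antiactivator-like (lone DUF2285), and
the ordered curation filters with a stage-by-stage report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from ._seq import hamming

DUF6499_MOTIF = "AWEFLRRN"

FSEA_LIKE = "FSEA_LIKE"
QSEM_LIKE = "QSEM_LIKE"
REJECTED = "REJECTED"

REASON_NONE = "NONE"
REASON_TOO_LONG = "TOO_LONG"
REASON_AMBIGUOUS = "AMBIGUOUS"
REASON_DUPLICATE = "DUPLICATE_DUF6499"
REASON_NO_MOTIF = "NO_MOTIF_POST_ALIGN"

STAGE_ORDER = (REASON_DUPLICATE, REASON_TOO_LONG, REASON_NO_MOTIF,
               REASON_AMBIGUOUS)


@dataclass(frozen=True)
class DomainCall:
    motif: str
    start: int  # 1-based residue index
    mismatches: int
    matched: str


@dataclass(frozen=True)
class Candidate:
    id: str
    sequence: str
    provenance: str = "SINGLE_ORF"  # SINGLE_ORF | PRF_FUSED

    def normalized(self) -> str:
        return self.sequence.strip().upper()


@dataclass(frozen=True)
class HomologClass:
    label: str
    reject_reason: str = REASON_NONE
    call: Optional[DomainCall] = None

    def __post_init__(self):
        if (self.reject_reason == REASON_NONE) != (self.label != REJECTED):
            raise ValueError("reject_reason must be NONE iff not REJECTED")


@dataclass
class CurationReport:
    input_count: int = 0
    removed: dict = field(default_factory=lambda: {s: 0 for s in STAGE_ORDER})
    surviving: int = 0
    fraction_prf_fused: float = 0.0
    fraction_surviving: float = 0.0

    def reconciles(self) -> bool:
        return self.input_count == self.surviving + sum(self.removed.values())


def find_motif(
    protein: str,
    motif: str = DUF6499_MOTIF,
    max_mismatch: int = 2,
    region_end: int = 60,
) -> Optional[DomainCall]:
    """Best Hamming match of ``motif`` fully inside residues 1..region_end.

    Fewest mismatches wins, then the 5'-most start; None if no placement has
    <= ``max_mismatch`` mismatches (or the motif does not fit).
    """
    if not protein:
        raise ValueError("empty protein")
    seq = protein.strip().upper()
    m = len(motif)
    limit = min(region_end, len(seq))
    best: Optional[tuple] = None
    for start in range(0, limit - m + 1):
        mm = hamming(seq[start : start + m], motif)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, start)
    if best is None:
        return None
    mm, start = best
    return DomainCall(motif=motif, start=start + 1, mismatches=mm,
                      matched=seq[start : start + m])


def classify(protein: str, call: Optional[DomainCall]) -> HomologClass:
    """Activator-like iff the DUF6499 motif is present, else antiactivator-like."""
    if call is not None:
        return HomologClass(label=FSEA_LIKE, call=call)
    return HomologClass(label=QSEM_LIKE)


def _anchored_motif_ok(candidate: Candidate, motif: str, max_mismatch: int,
                       region_end: int) -> bool:
    """Default 'aligned-view' validation: anchor on the best motif hit and
    require it within tolerance.  An externally produced MSA can replace
    this check via the ``msa_validator`` hook of :func:`curate`."""
    return find_motif(candidate.normalized(), motif=motif,
                      max_mismatch=max_mismatch, region_end=region_end) is not None


def msa_motif_validator(
    msa: dict, motif: str = DUF6499_MOTIF, max_mismatch: int = 2
) -> Callable:
    """Build a validator from an external alignment {id: aligned sequence}.

    The motif column window is located from the majority best-hit columns of
    the alignment; a sequence passes iff its residues in those columns match
    the motif within ``max_mismatch`` (gaps count as mismatches).
    """
    from collections import Counter

    starts = Counter()
    for aligned in msa.values():
        degapped = aligned.replace("-", "").upper()
        call = find_motif(degapped, motif=motif, max_mismatch=max_mismatch,
                          region_end=len(degapped))
        if call is None:
            continue
        # map degapped start back to an alignment column
        count, col = 0, None
        for j, ch in enumerate(aligned):
            if ch != "-":
                count += 1
                if count == call.start:
                    col = j
                    break
        if col is not None:
            starts[col] += 1
    if not starts:
        raise ValueError("no motif anchor found in the alignment")
    anchor_col = starts.most_common(1)[0][0]

    def validator(candidate: Candidate, *_args) -> bool:
        aligned = msa.get(candidate.id)
        if aligned is None:
            return False
        cols = [c for c in range(anchor_col, len(aligned))
                if aligned[c] != "-"][: len(motif)]
        window = "".join(aligned[c] for c in cols).upper()
        if len(window) < len(motif):
            return False
        return hamming(window, motif) <= max_mismatch

    return validator


def curate(
    candidates: Sequence[Candidate],
    lone_duf6499_ids: Iterable[str] = (),
    max_len: int = 400,
    motif: str = DUF6499_MOTIF,
    max_mismatch: int = 2,
    region_end: int = 60,
    msa_validator: Optional[Callable] = None,
) -> tuple[list[tuple[Candidate, HomologClass]], CurationReport]:
    """Ordered curation filters with a reconciling report.

    Stages, in order: (1) drop lone-DUF6499 duplicates; (2) drop sequences
    longer than ``max_len``; (3) drop activator-like sequences whose motif
    fails validation in the aligned view; (4) drop sequences containing the
    ambiguity character 'X'.  The report records per-stage removals, the
    surviving fraction, and the fraction of kept activator-like candidates
    with frameshift-fusion provenance.
    """
    dup_ids = set(lone_duf6499_ids)
    validate = msa_validator or _anchored_motif_ok
    report = CurationReport(input_count=len(candidates))
    results: list[tuple[Candidate, HomologClass]] = []
    kept: list[tuple[Candidate, HomologClass]] = []
    for cand in candidates:
        seq = cand.normalized()
        call = find_motif(seq, motif=motif, max_mismatch=max_mismatch,
                          region_end=region_end) if seq else None
        cls = classify(seq, call)
        reason = REASON_NONE
        if cand.id in dup_ids:
            reason = REASON_DUPLICATE
        elif len(seq) > max_len:
            reason = REASON_TOO_LONG
        elif cls.label == FSEA_LIKE and not validate(cand, motif, max_mismatch,
                                                     region_end):
            reason = REASON_NO_MOTIF
        elif "X" in seq:
            reason = REASON_AMBIGUOUS
        if reason == REASON_NONE:
            kept.append((cand, cls))
            results.append((cand, cls))
        else:
            report.removed[reason] += 1
            results.append((cand, HomologClass(label=REJECTED,
                                               reject_reason=reason)))
    report.surviving = len(kept)
    if report.input_count:
        report.fraction_surviving = report.surviving / report.input_count
    fsea_kept = [c for c, cls in kept if cls.label == FSEA_LIKE]
    if fsea_kept:
        report.fraction_prf_fused = (
            sum(c.provenance == "PRF_FUSED" for c in fsea_kept) / len(fsea_kept)
        )
    return results, report
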