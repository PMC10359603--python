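"""Detection of +1 programmed ribosomal frameshift (PRF) sites joining
overlapping ORF pairs, and reconstruction of the fused polypeptide.

Coordinates are 0-based half-open on the forward strand.  ORFs on the minus
strand additionally carry *oriented* coordinates, i.e. positions in the
reverse complement of the locus; frame is always the oriented frame (start of
the reading frame modulo 3 in the oriented sequence).  The slippery-motif
position of a :class:`PRFSiteCall` is an oriented coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._seq import STOP_CODONS, hamming, revcomp, translate, validate_dna

DEFAULT_SLIPPERY = "TGGGGG"


class FusionError(ValueError):
    """A PRF call whose fusion product contains an internal stop.

    Carries the oriented coordinate of the offending stop codon in
    ``stop_position``; signals a false PRF call.
    """

    def __init__(self, message: str, stop_position: int):
        super().__init__(message)
        self.stop_position = stop_position


@dataclass(frozen=True)
class NucleotideLocus:
    id: str
    sequence: str
    taxon: Optional[str] = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"locus {self.id}: empty sequence")
        validate_dna(self.sequence, f"locus {self.id}")


@dataclass(frozen=True)
class AnnotatedORF:
    """A stop-to-stop open reading frame.

    ``start``/``end`` are forward-strand 0-based half-open; ``end`` includes
    the stop codon when ``stop_terminated``.  ``frame`` is the oriented frame
    (0/1/2).  ``has_start`` is False for open-5' (start-less) ORFs reported
    when modelling misannotated starts.
    """

    locus_id: str
    start: int
    end: int
    strand: str
    frame: int
    translation: str
    has_start: bool = True
    stop_terminated: bool = True
    n_warning: bool = False

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def oriented(self, locus_len: int) -> tuple[int, int]:
        """(start, end) in the oriented (coding-strand) coordinate system."""
        if self.strand == "+":
            return self.start, self.end
        return locus_len - self.end, locus_len - self.start


@dataclass(frozen=True)
class PRFSiteCall:
    locus_id: str
    upstream: AnnotatedORF
    downstream: AnnotatedORF
    motif_start: int  # oriented 0-based
    motif_seq: str
    shift: int = 1
    overlap_nt: int = 0
    motif_mismatches: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class ReconstructedProtein:
    sequence: str
    provenance: str  # SINGLE_ORF | PRF_FUSED
    locus_id: str
    junction_residue: Optional[int] = None  # 1-based, last residue before edit

    def __post_init__(self):
        if "*" in self.sequence:
            raise ValueError("internal stop in reconstructed protein")
        if self.provenance == "PRF_FUSED":
            if self.junction_residue is None:
                raise ValueError("PRF_FUSED requires junction_residue")
            if not 1 <= self.junction_residue < len(self.sequence):
                raise ValueError("junction_residue out of range")


def _orfs_in_oriented_seq(
    seq: str,
    locus: NucleotideLocus,
    strand: str,
    min_len_codons: int,
    include_startless: bool,
    n_warning: bool,
) -> list[AnnotatedORF]:
    L = len(seq)
    out = []
    for frame in range(3):
        seg_start = frame
        pos = frame
        while pos + 3 <= L:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                out.extend(
                    _emit_segment(
                        seq, locus, strand, frame, seg_start, pos + 3, True,
                        min_len_codons, include_startless, n_warning,
                    )
                )
                seg_start = pos + 3
            pos += 3
        # trailing open-3' segments are not reported
    return out


def _emit_segment(
    seq, locus, strand, frame, seg_start, seg_end, stop_terminated,
    min_len_codons, include_startless, n_warning,
) -> list[AnnotatedORF]:
    """Emit the ORF for one stop-to-stop segment (oriented coords)."""
    coding = seq[seg_start : seg_end - 3]
    atg_rel = -1
    for i in range(0, len(coding) - 2, 3):
        if coding[i : i + 3] == "ATG":
            atg_rel = i
            break
    records = []
    L = len(seq)

    def make(o_start: int, has_start: bool) -> Optional[AnnotatedORF]:
        tr = translate(seq[o_start : seg_end - 3])
        if len(tr) < min_len_codons or "*" in tr:
            return None
        if strand == "+":
            f_start, f_end = o_start, seg_end
        else:
            f_start, f_end = L - seg_end, L - o_start
        return AnnotatedORF(
            locus_id=locus.id, start=f_start, end=f_end, strand=strand,
            frame=frame, translation=tr, has_start=has_start,
            stop_terminated=stop_terminated, n_warning=n_warning,
        )

    if include_startless:
        rec = make(seg_start, atg_rel == 0)
        if rec is not None:
            records.append(rec)
    elif atg_rel >= 0:
        rec = make(seg_start + atg_rel, True)
        if rec is not None:
            records.append(rec)
    return records


def find_orfs(
    locus: NucleotideLocus,
    min_len_codons: int = 1,
    include_startless: bool = False,
) -> list[AnnotatedORF]:
    """Scan all six frames for stop-to-stop ORFs.

    By default ORFs begin at the first in-frame ATG of their segment; with
    ``include_startless=True`` each segment is reported from its 5' boundary
    (open 5' end), modelling misannotated start codons.  Sequences that are
    more than 50% N are flagged (``n_warning``) but still scanned.
    """
    if min_len_codons < 1:
        raise ValueError("min_len_codons must be >= 1")
    seq = locus.sequence.upper()
    n_warning = seq.count("N") > len(seq) / 2
    orfs = _orfs_in_oriented_seq(
        seq, locus, "+", min_len_codons, include_startless, n_warning
    )
    orfs += _orfs_in_oriented_seq(
        revcomp(seq), locus, "-", min_len_codons, include_startless, n_warning
    )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def detect_prf(
    locus: NucleotideLocus,
    orfs: Iterable[AnnotatedORF],
    motif: str = DEFAULT_SLIPPERY,
    max_mismatch: int = 0,
    window_nt: int = 45,
) -> list[PRFSiteCall]:
    """Return one call per qualifying ORF pair.

    A pair qualifies when both ORFs are on the same strand, the downstream
    ORF is in the +1 oriented frame relative to the upstream one, they
    overlap by >= 1 nt, and the upstream ORF carries the slippery motif
    (<= ``max_mismatch`` mismatches) within ``window_nt`` of its stop codon.
    Per pair the best motif placement wins (fewest mismatches, then 3'-most);
    calls are sorted by (mismatches, ascending motif start).
    """
    motif = motif.upper()
    seq = locus.sequence.upper()
    L = len(seq)
    oriented = {"+": seq, "-": revcomp(seq)}
    calls = []
    orfs = list(orfs)
    for up in orfs:
        for down in orfs:
            if up is down or up.strand != down.strand:
                continue
            if down.frame != (up.frame + 1) % 3:
                continue
            u0, u1 = up.oriented(L)
            d0, d1 = down.oriented(L)
            # downstream must extend past the upstream stop; its 5' boundary
            # is unconstrained (stop-to-stop segments may reach further 5')
            if d1 <= u1:
                continue
            overlap = min(u1, d1) - max(u0, d0)
            if overlap < 1:
                continue
            oseq = oriented[up.strand]
            stop_start = u1 - 3 if up.stop_terminated else u1
            lo = max(u0, stop_start - window_nt)
            best = None  # (mismatches, motif_start)
            for ms in range(lo, stop_start - len(motif) + 1):
                mm = hamming(oseq[ms : ms + len(motif)], motif)
                if mm > max_mismatch:
                    continue
                if best is None or mm < best[0] or (mm == best[0] and ms > best[1]):
                    best = (mm, ms)
            if best is None:
                continue
            mm, ms = best
            calls.append(
                PRFSiteCall(
                    locus_id=locus.id, upstream=up, downstream=down,
                    motif_start=ms, motif_seq=oriented[up.strand][ms : ms + len(motif)],
                    overlap_nt=overlap, motif_mismatches=mm, strand=up.strand,
                )
            )
    calls.sort(key=lambda c: (c.motif_mismatches, c.motif_start))
    return calls


def fuse(
    locus: NucleotideLocus,
    call: Optional[PRFSiteCall] = None,
    *,
    orf: Optional[AnnotatedORF] = None,
) -> ReconstructedProtein:
    """Apply the +1 edit of ``call`` and translate the fused polypeptide.

    Translation proceeds in the upstream frame through the final nucleotide
    of the slippery motif (last complete upstream codon), then resumes one
    nucleotide further 3' in the downstream frame up to the downstream stop.
    With ``call=None`` and an ``orf``, returns the plain single-ORF
    translation (provenance SINGLE_ORF).
    """
    seq = locus.sequence.upper()
    L = len(seq)
    if call is None:
        if orf is None:
            raise ValueError("need either a PRF call or a single ORF")
        o0, o1 = orf.oriented(L)
        oseq = seq if orf.strand == "+" else revcomp(seq)
        tr = translate(oseq[o0 : o1 - 3 if orf.stop_terminated else o1])
        if "*" in tr:
            raise FusionError("internal stop in single-ORF translation",
                              o0 + 3 * tr.index("*"))
        return ReconstructedProtein(sequence=tr, provenance="SINGLE_ORF",
                                    locus_id=locus.id)

    oseq = seq if call.strand == "+" else revcomp(seq)
    u0, _ = call.upstream.oriented(L)
    _, d1 = call.downstream.oriented(L)
    motif_end = call.motif_start + len(call.motif_seq)
    # last upstream codon fully contained in [u0, motif_end)
    up_nt = motif_end - u0
    up_nt -= up_nt % 3
    up_tr = translate(oseq[u0 : u0 + up_nt])
    if "*" in up_tr:
        raise FusionError("stop upstream of the frameshift site",
                          u0 + 3 * up_tr.index("*"))
    resume = motif_end + 1  # the +1 edit: skip one nucleotide
    down_end = d1 - 3 if call.downstream.stop_terminated else d1
    if (down_end - resume) % 3 != 0:
        raise FusionError(
            f"frameshift edit at {motif_end} does not reach the downstream "
            f"frame of ORF ending at {d1}", resume)
    down_tr = translate(oseq[resume:down_end])
    if "*" in down_tr:
        raise FusionError("internal stop after fusion",
                          resume + 3 * down_tr.index("*"))
    fusion = up_tr + down_tr
    return ReconstructedProtein(
        sequence=fusion, provenance="PRF_FUSED", locus_id=locus.id,
        junction_residue=len(up_tr),
    )


def reconstruct_locus(
    locus: NucleotideLocus,
    min_len_codons: int = 30,
    motif: str = DEFAULT_SLIPPERY,
    max_mismatch: int = 0,
    window_nt: int = 45,
    include_startless: bool = False,
) -> tuple[list[ReconstructedProtein], list[PRFSiteCall]]:
    """find_orfs -> detect_prf -> fuse, skipping false calls (FusionError)."""
    orfs = find_orfs(locus, min_len_codons, include_startless=include_startless)
    calls = detect_prf(locus, orfs, motif=motif, max_mismatch=max_mismatch,
                       window_nt=window_nt)
    proteins = []
    kept_calls = []
    for call in calls:
        try:
            proteins.append(fuse(locus, call))
            kept_calls.append(call)
        except FusionError:
            continue
    return proteins, kept_calls
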