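"""Ground-truth simulators for every input class the pipeline consumes.

Three generators are provided:

* :func:`gen_loci` — nucleotide loci carrying activator-like genes split
  across two overlapping ORFs joined by a +1 frameshift at a slippery site,
  single-ORF antiactivator-like genes, and decoy ORFs;
* :func:`gen_upstreams` — fixed-length promoter windows with one planted
  inverted-repeat box of variable spacer length;
* :func:`gen_emsa` — gel-shift binding curves from a specific-binding-with-
  Hill-slope model with multiplicative lane noise and an optional constant
  co-purified unbound band.

All generators are deterministic in their seed, byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import CODONS_FOR, STOP_CODONS, revcomp, translate
from .irbox_scan import BASES, ConservationProfile
from .prf_reconstruct import NucleotideLocus

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DUF6499_MOTIF = "AWEFLRRN"
MOTIF_RESIDUE_START = 31  # 1-based residue index of the planted motif

FSEA_LIKE = "FSEA_LIKE"
QSEM_LIKE = "QSEM_LIKE"
DECOY = "DECOY"


class GeometryError(ValueError):
    """Requested gene geometry cannot be constructed."""


@dataclass(frozen=True)
class SimLocusSpec:
    seed: int = 0
    n_fsea_like: int = 1
    n_qsem_like: int = 0
    n_decoys: int = 0
    orf1_len_codons: int = 80
    orf2_len_codons: int = 60
    overlap_nt: int = 14
    slippery_motif: str = "TGGGGG"
    background_gc: float = 0.5
    mutation_rate: float = 0.0
    flank_nt: int = 50
    drop_orf1_start: bool = False  # misannotation mode: ORF1 start unannotated

    def validate(self) -> None:
        if len(self.slippery_motif) != 6:
            raise ValueError("slippery_motif must be a 6-mer")
        if self.overlap_nt < 1:
            raise ValueError("overlap_nt must be >= 1")
        if self.overlap_nt >= 3 * min(self.orf1_len_codons, self.orf2_len_codons):
            raise ValueError("overlap_nt too large for the requested ORFs")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must be in [0,1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0,1]")
        if min(self.n_fsea_like, self.n_qsem_like, self.n_decoys) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TruthRecord:
    locus_id: str
    klass: str
    protein: str = ""
    prf_motif_start: Optional[int] = None  # forward-strand 0-based
    junction_residue: Optional[int] = None
    orf1: Optional[tuple] = None  # (start, end) 0-based half-open
    orf2: Optional[tuple] = None
    ir_box: Optional[tuple] = None  # (hex1_start, hex2_start)
    spacer: Optional[int] = None


@dataclass
class SimTruth:
    genes: list = field(default_factory=list)

    def by_id(self) -> dict:
        return {g.locus_id: g for g in self.genes}

    def to_json(self) -> str:
        return json.dumps([dataclasses.asdict(g) for g in self.genes], indent=1)


def _rand_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _rand_codon(rng: np.random.Generator, aa: str) -> str:
    return CODONS_FOR[aa][rng.integers(len(CODONS_FOR[aa]))]


def _rand_sense_codon(rng: np.random.Generator, mid_not_t: bool = False) -> str:
    while True:
        aa = AA20[rng.integers(len(AA20))]
        codon = _rand_codon(rng, aa)
        if mid_not_t and codon[1] == "T":
            continue
        return codon


def _motif_free(protein: str, motif: str = DUF6499_MOTIF, max_mm: int = 2,
                region_end: int = 60) -> bool:
    from .homolog_curation import find_motif

    return find_motif(protein, motif=motif, max_mismatch=max_mm,
                      region_end=region_end) is None


def _build_fsea_gene(spec: SimLocusSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """Construct one frameshift-split gene; returns (gene DNA, geometry)."""
    n1, n2, ov = spec.orf1_len_codons, spec.orf2_len_codons, spec.overlap_nt
    motif = spec.slippery_motif.upper()
    if motif[0:3] in STOP_CODONS or motif[3:6] in STOP_CODONS:
        raise GeometryError("slippery motif contains an in-frame stop codon")
    if ov % 3 != 2:
        raise GeometryError(
            "a +1-frame ORF pair sharing an in-frame stop requires "
            f"overlap_nt = 2 (mod 3); got {ov}")
    if ov < 14:
        raise GeometryError("overlap_nt < 14 leaves no room for the ORF2 start")
    # ORF1 codon layout: 0=ATG, motif residues 31..38, codons n1-3/n1-2 =
    # the slippery 6-mer, codon n1-1 = TAA.  ORF2 starts (ATG, +1 frame) at
    # a = 3*n1 - ov; its start codon spans ORF1 codons c and c+1.
    a = 3 * n1 - ov
    c = (a - 1) // 3
    if c < MOTIF_RESIDUE_START + len(DUF6499_MOTIF):  # keep clear of the motif
        raise GeometryError("overlap reaches into the DUF6499 motif region")
    if c + 1 > n1 - 4:
        raise GeometryError("ORF2 start collides with the slippery site")
    if n1 < 45:
        raise GeometryError("orf1_len_codons must be >= 45")
    pre_codons = (ov - 2) // 3  # ORF2 codons 5' of the frameshift junction
    n_free = n2 - pre_codons - 2  # after forced post-junction codon and stop
    if n_free < 0:
        raise GeometryError("orf2_len_codons too short for the overlap")

    codons = ["ATG"]
    for i in range(1, n1 - 3):
        in_overlap = c <= i <= n1 - 4
        codons.append(_rand_sense_codon(rng, mid_not_t=in_overlap))
    for j, aa in enumerate(DUF6499_MOTIF):
        codons[MOTIF_RESIDUE_START - 1 + j] = _rand_codon(rng, aa)
    # plant the ORF2 ATG across ORF1 codons c and c+1
    codons[c] = ("A", "C", "G", "T")[rng.integers(4)] + "AT"  # any sense xAT
    codons[c + 1] = "G" + ("GC", "GA", "GG", "CC")[rng.integers(4)]
    if motif[1:4] in STOP_CODONS:
        raise GeometryError("slippery motif creates a +1-frame stop")
    codons += [motif[0:3], motif[3:6], "TAA"]
    orf1 = "".join(codons)
    assert len(orf1) == 3 * n1

    # ORF1's stop TAA contributes A,A to the first post-junction +1 codon
    first_third = ("A", "C", "G")[rng.integers(3)]  # K or N, never a stop
    tail_codons = [first_third]
    for _ in range(n_free):
        tail_codons.append(_rand_sense_codon(rng))
    tail_codons.append("TAA")
    gene = orf1 + "".join(tail_codons)

    m_start = 3 * (n1 - 3)
    m_end = m_start + 6
    orf2_end = 3 * n1 + 1 + 3 * (n_free + 1)  # last nt of the +1-frame TAA
    up_tr = translate(gene[0 : m_end])
    down_tr = translate(gene[m_end + 1 : orf2_end - 3])
    fusion = up_tr + down_tr
    if "*" in fusion:
        raise GeometryError("internal stop in constructed fusion")
    geometry = dict(
        orf1=(0, 3 * n1), orf2=(a, orf2_end), motif_start=m_start,
        junction_residue=len(up_tr), protein=fusion,
    )
    return gene, geometry


def _build_single_orf(rng: np.random.Generator, n_codons: int) -> tuple[str, str]:
    while True:
        codons = ["ATG"] + [_rand_sense_codon(rng) for _ in range(n_codons - 2)]
        codons.append("TAA")
        gene = "".join(codons)
        protein = translate(gene[:-3])
        if _motif_free(protein):
            return gene, protein


def gen_loci(spec: SimLocusSpec):
    """Generate loci, GFF3 annotation rows and the ground truth.

    Returns ``(loci, gff_rows, truth)`` where ``gff_rows`` are 9-tuple GFF3
    records (1-based inclusive coordinates).
    """
    spec.validate()
    # separate streams: mutation draws must not perturb construction, so the
    # same seed yields identical pre-mutation loci at any mutation_rate
    rng = np.random.default_rng([spec.seed, 0])
    mut_rng = np.random.default_rng([spec.seed, 1])
    loci: list[NucleotideLocus] = []
    gff_rows: list[tuple] = []
    truth = SimTruth()

    def add_locus(lid, gene, klass, geometry=None, protein=""):
        # close the gene's reading frame immediately upstream so a flank ATG
        # cannot extend the planted ORF's translation start
        flank5 = _rand_background(rng, spec.flank_nt - 3, spec.background_gc) + "TAA"
        flank3 = _rand_background(rng, spec.flank_nt, spec.background_gc)
        off = len(flank5)
        seq = flank5 + gene + flank3
        if spec.mutation_rate > 0:
            seq = _mutate(mut_rng, seq, spec.mutation_rate)
        loci.append(NucleotideLocus(id=lid, sequence=seq))
        rec = TruthRecord(locus_id=lid, klass=klass, protein=protein)
        if geometry is not None:
            rec.protein = geometry["protein"]
            rec.prf_motif_start = off + geometry["motif_start"]
            rec.junction_residue = geometry["junction_residue"]
            rec.orf1 = (off + geometry["orf1"][0], off + geometry["orf1"][1])
            rec.orf2 = (off + geometry["orf2"][0], off + geometry["orf2"][1])
            if not spec.drop_orf1_start:
                gff_rows.append(_gff_row(lid, rec.orf1, "CDS", "orf1"))
            gff_rows.append(_gff_row(lid, rec.orf2, "CDS", "orf2"))
            gff_rows.append(
                _gff_row(lid, (rec.prf_motif_start,
                               rec.prf_motif_start + 6),
                         "sequence_feature", "prf_site"))
        else:
            start, end = off, off + len(gene)
            gff_rows.append(_gff_row(lid, (start, end), "CDS", "orf"))
        truth.genes.append(rec)

    for i in range(spec.n_fsea_like):
        while True:
            gene, geometry = _build_fsea_gene(spec, rng)
            # reject rare accidental extra motif copies near the slippery site
            window = gene[max(0, geometry["motif_start"] - 45):
                          geometry["motif_start"] + 6]
            if window.count(spec.slippery_motif.upper()) == 1 and \
                    _motif_free(geometry["protein"][40:],
                                region_end=len(geometry["protein"])):
                break
        add_locus(f"fsea_{i:04d}", gene, FSEA_LIKE, geometry=geometry)
    for i in range(spec.n_qsem_like):
        gene, protein = _build_single_orf(rng, spec.orf2_len_codons)
        add_locus(f"qsem_{i:04d}", gene, QSEM_LIKE, protein=protein)
    for i in range(spec.n_decoys):
        gene, protein = _build_single_orf(rng, spec.orf2_len_codons)
        add_locus(f"decoy_{i:04d}", gene, DECOY, protein=protein)
    return loci, gff_rows, truth


def _gff_row(lid, interval, ftype, name):
    start, end = interval
    return (lid, "duf-scout-sim", ftype, start + 1, end, ".", "+", ".",
            f"ID={lid}.{name};Name={name}")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# upstream windows with planted IR boxes


def gen_upstreams(
    n: int,
    spacer_probs: dict,
    pfm: ConservationProfile,
    seed: int = 0,
    window_len: int = 80,
    background_gc: float = 0.5,
    hexamer_len: int = 6,
    fixed_box_offset: Optional[int] = None,
):
    """Fixed-length DNA windows each carrying one planted IR box.

    ``pfm`` gives per-column base probabilities for hexamer 1 (``hexamer_len``
    columns); hexamer 2 is drawn from the reverse-complemented matrix so the
    planted pair is inverted up to sampling.  Returns ``(windows, truth)``
    with truth rows ``(window_id, hex1_start, hex2_start, spacer)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    probs = pfm.probabilities
    if probs.shape[0] != hexamer_len:
        raise ValueError(f"pfm must have {hexamer_len} columns per hexamer")
    spacers = sorted(spacer_probs)
    weights = np.array([spacer_probs[s] for s in spacers], dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("spacer probabilities must sum to 1")
    max_span = 2 * hexamer_len + max(spacers)
    if window_len < max_span:
        raise ValueError("window_len too short to hold the IR box")
    rng = np.random.default_rng(seed)
    rc_probs = probs[::-1, ::-1]  # reverse columns, complement base order
    windows, truth = [], []
    base_list = list(BASES)
    for i in range(n):
        spacer = int(rng.choice(spacers, p=weights))
        span = 2 * hexamer_len + spacer
        if fixed_box_offset is None:
            pos = int(rng.integers(0, window_len - span + 1))
        else:
            pos = fixed_box_offset
            if pos + span > window_len:
                raise ValueError("fixed_box_offset places the box out of range")
        bg = _rand_background(rng, window_len, background_gc)
        hex1 = "".join(base_list[rng.choice(4, p=probs[c])] for c in range(hexamer_len))
        hex2 = "".join(base_list[rng.choice(4, p=rc_probs[c])] for c in range(hexamer_len))
        w = (bg[:pos] + hex1 + bg[pos + hexamer_len : pos + hexamer_len + spacer]
             + hex2 + bg[pos + span :])
        assert len(w) == window_len
        windows.append(w)
        truth.append((f"win_{i:05d}", pos, pos + hexamer_len + spacer, spacer))
    return windows, truth


# ---------------------------------------------------------------------------
# EMSA binding curves


def gen_emsa(
    concentrations: Sequence[float],
    kd: float,
    hill: float,
    bmax: float = 1.0,
    noise_sd: float = 0.0,
    constant_unbound_frac: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated gel-shift lanes.

    bound = bmax * X^h / (kd^h + X^h) * (1 + eps), eps ~ N(0, noise_sd);
    specific unbound gets an independent multiplicative error; a co-purified
    band of constant intensity ``constant_unbound_frac * bmax`` is added to
    the unbound signal of every lane and reported in a ``copurified`` column.
    """
    X = np.asarray(list(concentrations), dtype=float)
    if np.any(X <= 0):
        raise ValueError("concentrations must be positive")
    if kd <= 0 or hill <= 0:
        raise ValueError("kd and hill must be positive")
    if not (0 <= noise_sd <= 1 and 0 <= constant_unbound_frac <= 1):
        raise ValueError("fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        frac = X ** hill / (kd ** hill + X ** hill)
        eps_b = rng.normal(0.0, noise_sd, size=len(X)) if noise_sd > 0 else 0.0
        eps_u = rng.normal(0.0, noise_sd, size=len(X)) if noise_sd > 0 else 0.0
        bound = np.clip(bmax * frac * (1.0 + eps_b), 0.0, None)
        unbound_specific = np.clip(bmax * (1.0 - frac) * (1.0 + eps_u), 0.0, None)
        copurified = np.full(len(X), constant_unbound_frac * bmax)
        for j in range(len(X)):
            rows.append(
                dict(concentration_nM=X[j], rep=rep, bound=bound[j],
                     unbound=unbound_specific[j] + copurified[j],
                     copurified=copurified[j])
            )
    df = pd.DataFrame(rows)
    if constant_unbound_frac == 0:
        df = df.drop(columns=["copurified"])
    return df


# ---------------------------------------------------------------------------
# writers (plain-text outputs only)


def write_fasta(records, path) -> None:
    """records: iterable of (id, sequence) or NucleotideLocus."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, NucleotideLocus):
                rid, seq = rec.id, rec.sequence
            else:
                rid, seq = rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_truth_json(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def write_emsa_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
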