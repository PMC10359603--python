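"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import io

import numpy as np
import pytest

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_b1, _b2, _b3) in enumerate(
    (a, b, c) for a in _bases for b in _bases for c in _bases
):
    CODON_TABLE[_b1 + _b2 + _b3] = _aas[_i]


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def translate_naive(seq: str) -> str:
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def write_multimodel_pdb(models, chain: str = "A") -> io.StringIO:
    """Serialize models ({resnum: {atom: xyz}}) as multi-model PDB text."""
    buf = io.StringIO()
    for mi, model in enumerate(models, 1):
        buf.write(f"MODEL     {mi:4d}\n")
        serial = 1
        for res in sorted(model):
            for name, xyz in model[res].items():
                element = name.strip()[0]
                buf.write(
                    "ATOM  {:5d} {:^4s} ALA {}{:4d}    "
                    "{:8.3f}{:8.3f}{:8.3f}  1.00  0.00           {:>2s}\n".format(
                        serial, name, chain, res, xyz[0], xyz[1], xyz[2], element
                    )
                )
                serial += 1
        buf.write("ENDMDL\n")
    buf.write("END\n")
    buf.seek(0)
    return buf


def jittered_ensemble(rng, n_models=5, n_res=10, scale=0.2):
    base = {
        r: {a: rng.normal(size=3) * 6.0 for a in ("N", "CA", "C", "O")}
        for r in range(1, n_res + 1)
    }
    return [
        {
            r: {a: xyz + rng.normal(scale=scale, size=3) for a, xyz in atoms.items()}
            for r, atoms in base.items()
        }
        for _ in range(n_models)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


# ---------------------------------------------------------------------------
# brute-force reference implementations


def brute_force_orfs(seq: str, min_len_codons: int):
    """Translate every frame on both strands and split on stops; report
    ATG-started, stop-terminated ORFs as (start, end, strand, translation)
    in forward coordinates."""
    out = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            segments = []
            seg_start = frame
            for pos in range(frame, L - 2, 3):
                if CODON_TABLE.get(s[pos : pos + 3]) == "*":
                    segments.append((seg_start, pos + 3))
                    seg_start = pos + 3
            for a, b in segments:
                atg = None
                for p in range(a, b - 3, 3):
                    if s[p : p + 3] == "ATG":
                        atg = p
                        break
                if atg is None:
                    continue
                tr = translate_naive(s[atg : b - 3])
                if "*" in tr or len(tr) < min_len_codons:
                    continue
                if strand == "+":
                    out.add((atg, b, "+", tr))
                else:
                    out.add((L - b, L - atg, "-", tr))
    return out


def brute_force_motif(protein: str, motif: str, max_mismatch: int, region_end: int):
    """All-offsets Hamming scan; (mismatches, 1-based start) of the best hit."""
    best = None
    seq = protein.strip().upper()
    for start in range(0, min(region_end, len(seq)) - len(motif) + 1):
        mm = sum(a != b for a, b in zip(seq[start : start + len(motif)], motif))
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, start + 1)
    return best


def brute_force_ir(window: str, hexamer_len: int, spacers, max_mismatch: int):
    """Double loop over all positions and spacers."""
    hits = set()
    for spacer in spacers:
        span = 2 * hexamer_len + spacer
        for pos in range(0, len(window) - span + 1):
            h1 = window[pos : pos + hexamer_len]
            h2 = window[pos + hexamer_len + spacer : pos + span]
            mm = sum(a != b for a, b in zip(h2, rc(h1)))
            if mm <= max_mismatch:
                hits.add((pos, spacer, mm))
    return hits


def brute_force_redundancy(windows, threshold):
    kept = []
    for w in windows:
        ok = True
        for k in kept:
            ident = sum(a == b for a, b in zip(w, k)) / len(w)
            if ident >= threshold:
                ok = False
                break
        if ok:
            kept.append(w)
    return kept


def _quat_to_matrix(q):
    q = q / np.linalg.norm(q, axis=-1, keepdims=True)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        -2,
    )


def brute_force_superposition_rmsd(a, b, rng, n_coarse=600, n_refine=40):
    """Minimal RMSD over rotations via quaternion grid refinement."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsds(quats):
        mats = _quat_to_matrix(quats)  # (m, 3, 3)
        moved = np.einsum("mij,nj->mni", mats, a0)
        return np.sqrt(np.mean(np.sum((moved - b0) ** 2, axis=2), axis=1))

    quats = rng.normal(size=(n_coarse, 4))
    vals = rmsds(quats)
    best_q = quats[np.argmin(vals)]
    best = vals.min()
    scale = 0.5
    for _ in range(n_refine):
        cand = best_q + rng.normal(scale=scale, size=(200, 4))
        vals = rmsds(cand)
        i = np.argmin(vals)
        if vals[i] < best:
            best = vals[i]
            best_q = cand[i]
        scale *= 0.7
    return float(best)
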