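"""Multi-model structure ensembles: PDB reading, Kabsch superposition, and
ensemble RMSD statistics over residue/atom subsets.

Residues are keyed by author numbering throughout; hydrogens are ignored
and altloc A is selected on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

BACKBONE_HEAVY = ("N", "CA", "C", "O")


class MissingAtomsError(KeyError):
    """A requested residue/atom is absent from at least one model."""


@dataclass
class StructureEnsemble:
    """Ordered models; each maps author residue number -> atom name -> xyz."""

    models: List[Dict[int, Dict[str, np.ndarray]]]
    id: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coordinates(
        self,
        residues: Iterable[int],
        atoms: Sequence[str] = BACKBONE_HEAVY,
    ) -> np.ndarray:
        """(n_models, n_points, 3) array for the residue/atom selection.

        Raises :class:`MissingAtomsError` listing every absent residue/atom.
        """
        residues = list(residues)
        missing = []
        stacks = []
        for mi, model in enumerate(self.models):
            pts = []
            for res in residues:
                res_atoms = model.get(res)
                for name in atoms:
                    if res_atoms is None or name not in res_atoms:
                        missing.append((mi + 1, res, name))
                    else:
                        pts.append(res_atoms[name])
            stacks.append(pts)
        if missing:
            listing = ", ".join(f"model {m}: residue {r} atom {a}"
                                for m, r, a in missing[:20])
            raise MissingAtomsError(
                f"{len(missing)} missing atoms in selection ({listing}...)")
        arr = np.array(stacks, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite coordinates in ensemble")
        return arr


def read_ensemble(pdb_source, id: str = "", chain: Optional[str] = None) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a StructureEnsemble.

    Single-model files yield one model.  Altloc A is kept, hydrogens and
    heteroatoms are dropped; residues are keyed by author numbering.  With
    ``chain=None`` the first chain encountered is used.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(id or "ensemble", pdb_source)
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"malformed PDB: {exc}") from exc
    models = []
    use_chain = chain
    for model in structure:
        residues: Dict[int, Dict[str, np.ndarray]] = {}
        for ch in model:
            if use_chain is None:
                use_chain = ch.id
            if ch.id != use_chain:
                continue
            for residue in ch:
                hetflag, resseq, _icode = residue.id
                if hetflag != " ":
                    continue
                atom_map = {}
                for atom in residue.get_unpacked_list():
                    if atom.element in ("H", "D"):
                        continue
                    altloc = atom.get_altloc()
                    if altloc not in (" ", "A"):
                        continue
                    if atom.get_name() in atom_map:
                        continue
                    atom_map[atom.get_name()] = np.asarray(atom.coord, dtype=float)
                if atom_map:
                    residues[resseq] = atom_map
        models.append(residues)
    if not models:
        raise ValueError("no models in PDB input")
    return StructureEnsemble(models=models, id=id)


def kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``a`` onto ``b``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det +1) such that ``a @ rotation.T + translation`` best fits ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected two equal-shape (n, 3) point sets")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    # degenerate (collinear) sets have no unique rotation
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    t = cb - rot @ ca
    moved = a @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, t, rmsd


def _superpose_onto(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    rot, t, _ = kabsch(coords, ref)
    return coords @ rot.T + t


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    residues: Iterable[int],
    atoms: Sequence[str] = BACKBONE_HEAVY,
    convention: str = "to_mean",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Ensemble spread in Angstroms under one of two conventions.

    ``to_mean``: iteratively superpose every model onto the evolving mean
    coordinates until the mean moves by < ``tol``; report the mean RMSD of
    the models to the mean.  ``pairwise``: mean over all model pairs of the
    pairwise superposed RMSD.
    """
    coords = ensemble.coordinates(residues, atoms)
    m = coords.shape[0]
    if convention == "pairwise":
        if m < 2:
            return 0.0
        vals = [kabsch(coords[i], coords[j])[2]
                for i in range(m) for j in range(i + 1, m)]
        return float(np.mean(vals))
    if convention != "to_mean":
        raise ValueError(f"unknown convention {convention!r}")
    if m == 1:
        return 0.0
    aligned = coords.copy()
    mean = aligned[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([_superpose_onto(c, mean) for c in aligned])
        new_mean = aligned.mean(axis=0)
        delta = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if delta < tol:
            break
    else:
        warnings.warn("mean-structure iteration did not converge")
    rmsds = [np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))) for c in aligned]
    return float(np.mean(rmsds))


def ensemble_stats(
    ensemble: StructureEnsemble,
    residues: Iterable[int],
    atoms: Sequence[str] = BACKBONE_HEAVY,
) -> dict:
    """Both RMSD conventions plus bookkeeping, ready for JSON output."""
    residues = list(residues)
    return {
        "n_models": ensemble.n_models,
        "residues": [min(residues), max(residues)] if residues else None,
        "atoms": list(atoms),
        "rmsd_to_mean": ensemble_rmsd(ensemble, residues, atoms, "to_mean"),
        "rmsd_pairwise": ensemble_rmsd(ensemble, residues, atoms, "pairwise"),
    }
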