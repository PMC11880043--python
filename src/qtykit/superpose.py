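"""Optimal rigid-body superposition (Kabsch) and RMSD.

The Kabsch algorithm finds, in closed form via SVD, the proper rotation
R (det = +1) and translation t minimizing Σᵢ |R·Pᵢ + t − Qᵢ|² over paired
coordinates.  When the SVD returns a reflection (det(V·Wᵀ) = −1) the sign
of the smallest singular vector is flipped so that only rigid motions —
never mirror images — are reported; a chiral structure therefore keeps a
strictly positive RMSD against its mirror image.

`superpose_models` adds the protein-level conveniences: CA-only (or
all-atom) coordinate extraction through a residue pairing, and optional
outlier-rejection cycles in the style of PyMOL's `align` refinement,
where pairs farther than a cutoff from the current fit are discarded and
the fit repeated.  Both the all-pair and the refined RMSD are reported so
that published values computed with unknown refinement settings can be
bracketed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .structure import Atom, Residue, ResiduePairing, StructureModel, StructureError

__all__ = ["SuperpositionResult", "kabsch", "superpose_models", "apply_transform"]


@dataclass(frozen=True)
class SuperpositionResult:
    """A rigid transform (x ↦ rotation·x + translation) and its fit quality."""

    rotation: np.ndarray  # 3×3 proper rotation, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å, over the pairs used in the final fit
    n_pairs_used: int
    n_rejected: int = 0
    cycles_run: int = 0
    rmsd_all_pairs: Optional[float] = None  # pre-rejection RMSD, if cycles > 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is improper (det != +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid motion to an N×3 coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Superpose P onto Q: the proper rotation/translation minimizing RMSD.

    Parameters are N×3 arrays of paired coordinates (N ≥ 3).  Collinear
    or otherwise degenerate point sets still return a minimizer, but the
    rotation is then not unique (any spin about the degenerate axis is
    equally optimal).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"need matching N×3 arrays, got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    residual = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return SuperpositionResult(
        rotation=R,
        translation=cq - R @ cp,
        rmsd=rmsd,
        n_pairs_used=n,
    )


def _paired_coords(
    a: StructureModel,
    b: StructureModel,
    pairing: ResiduePairing,
    atoms: str,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Coordinate arrays for the pairing plus, per row, the owning pair index."""
    pa, pb, owner = [], [], []
    for i, (ka, kb) in enumerate(pairing.pairs):
        ra, rb = a.residue(ka), b.residue(kb)
        if atoms == "ca":
            ca_a, ca_b = ra.ca, rb.ca
            if ca_a is None or ca_b is None:
                raise StructureError(f"pair {ka}/{kb} lacks a CA atom")
            pa.append(ca_a.pos)
            pb.append(ca_b.pos)
            owner.append(i)
        else:  # all heavy atoms common by name
            names_b = {at.name: at for at in rb.atoms}
            for at in ra.atoms:
                mate = names_b.get(at.name)
                if mate is not None:
                    pa.append(at.pos)
                    pb.append(mate.pos)
                    owner.append(i)
    return np.array(pa), np.array(pb), owner


def superpose_models(
    a: StructureModel,
    b: StructureModel,
    pairing: ResiduePairing,
    *,
    cycles: int = 0,
    cutoff: float = 2.0,
    atoms: str = "ca",
) -> SuperpositionResult:
    """Superpose model ``a`` onto model ``b`` over a residue pairing.

    By default the fit uses CA atoms only (``atoms="all"`` uses every
    heavy atom shared by name within each residue pair).  With
    ``cycles > 0``, after each fit the residue pairs whose coordinates sit
    farther than ``cutoff`` Å from their mates are rejected and the fit
    repeated, mimicking PyMOL align's refinement; rejection stops early
    once no pair exceeds the cutoff.  The pre-rejection RMSD is kept in
    ``rmsd_all_pairs``.  Refined RMSD never exceeds the all-pair RMSD's
    fit on the surviving subset; dropping below 3 pairs is an error.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if atoms not in ("ca", "all"):
        raise ValueError(f"atoms must be 'ca' or 'all', got {atoms!r}")
    P, Q, owner = _paired_coords(a, b, pairing, atoms)
    result = kabsch(P, Q)
    rmsd_all = result.rmsd
    keep = np.ones(len(P), dtype=bool)
    cycles_run = 0
    for _ in range(cycles):
        dist = np.linalg.norm(result.transform(P) - Q, axis=1)
        bad_pairs = {owner[i] for i in np.nonzero((dist > cutoff) & keep)[0]}
        if not bad_pairs:
            break
        keep &= np.array([o not in bad_pairs for o in owner])
        if keep.sum() < 3:
            raise StructureError(
                "outlier rejection left fewer than 3 atom pairs"
            )
        result = kabsch(P[keep], Q[keep])
        cycles_run += 1
    n_rejected = len({owner[i] for i in np.nonzero(~keep)[0]})
    return dc_replace(
        result,
        n_rejected=n_rejected,
        cycles_run=cycles_run,
        rmsd_all_pairs=rmsd_all if cycles > 0 else None,
    )


def apply_transform(
    model: StructureModel, result: SuperpositionResult
) -> StructureModel:
    """Return a copy of ``model`` with the rigid motion applied to every atom."""
    residues = []
    for res in model.residues:
        atoms = tuple(
            Atom(
                name=a.name,
                element=a.element,
                pos=tuple(result.transform(a.xyz[None, :])[0]),
                occupancy=a.occupancy,
                b_factor=a.b_factor,
            )
            for a in res.atoms
        )
        residues.append(
            Residue(
                chain=res.chain,
                number=res.number,
                icode=res.icode,
                name=res.name,
                is_polymer=res.is_polymer,
                atoms=atoms,
            )
        )
    return StructureModel(id=model.id, residues=tuple(residues))
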