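"""Synthetic sequences and structures with known ground truth.

Every other module can be exercised without downloading anything: this
module builds membrane-protein-like records (hydrophobic TM helices
joined by polar loops), CA-trace helical-bundle coordinates with
standard α-helix geometry (1.5 Å rise, 100° twist, 2.3 Å axial radius —
conventional values, used here as fixture parameters, not scientific
claims), and noise-perturbed copies with a known expected RMSD.

All generators are pure functions of their parameters plus an explicit
seed, and the emitted FASTA / TM-TSV / PDB files round-trip through the
package's own readers, so tests exercise the genuine I/O paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .seq_io import (
    ProteinRecord,
    TMSegment,
    attach_segments,
    write_fasta,
    write_tm_annotations,
)
from .structure import Atom, Residue, StructureModel, write_pdb

__all__ = [
    "SyntheticProtein",
    "ideal_helix",
    "synthetic_tm_protein",
    "perturb_structure",
    "write_fixture",
]

PathLike = Union[str, Path]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

HYDROPHOBIC_POOL = "LIVFMWA"
POLAR_POOL = "DENQHKRSTGY"


@dataclass(frozen=True)
class SyntheticProtein:
    """A generated record + structure pair with its generation truth."""

    record: ProteinRecord
    model: StructureModel
    truth: dict  # segments, exposure classes, noise sigma, seed


def ideal_helix(
    n: int, *, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """CA coordinates of an ideal α-helix along +z.

    CA i sits at (radius·cos(i·twist), radius·sin(i·twist), i·rise) with
    the twist in degrees; the defaults give the canonical 3.6
    residues/turn and a constant consecutive CA–CA distance of ≈3.8 Å.
    """
    if n < 1:
        raise ValueError(f"need at least one residue, got {n}")
    i = np.arange(n, dtype=float)
    ang = np.deg2rad(twist) * i
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * i]
    )


def _bundle_coords(
    n_helices: int, helix_len: int, loop_len: int, spacing: float = 10.0
) -> np.ndarray:
    """CA trace of an antiparallel helix bundle with straight loop connectors.

    Helix axes stand on a circle of radius ``spacing`` around the bundle
    (z) axis, alternating up/down.  Loop CAs interpolate linearly between
    consecutive helix ends — a topology fixture, not a realistic loop.
    """
    coords: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    for h in range(n_helices):
        ang = 2.0 * math.pi * h / max(n_helices, 1)
        offset = np.array([spacing * math.cos(ang), spacing * math.sin(ang), 0.0])
        helix = ideal_helix(helix_len)
        if h % 2 == 1:  # antiparallel: flip alternating helices
            helix = helix[::-1] * np.array([1.0, -1.0, -1.0])
            helix[:, 2] += helix_len * 1.5
        helix = helix + offset
        if prev_end is not None and loop_len > 0:
            start = helix[0]
            t = np.linspace(0.0, 1.0, loop_len + 2)[1:-1, None]
            coords.append(prev_end + t * (start - prev_end))
        coords.append(helix)
        prev_end = helix[-1]
    return np.concatenate(coords)


def synthetic_tm_protein(
    n_helices: int = 4,
    helix_len: int = 20,
    loop_len: int = 6,
    hydrophobic_bias: float = 0.9,
    seed: int = 0,
) -> SyntheticProtein:
    """Generate a membrane-protein-like record with a CA-trace bundle.

    TM segments draw residues from the hydrophobic pool {L,I,V,F,M,W,A}
    with probability ``hydrophobic_bias`` (1.0 → purely hydrophobic TM
    segments) and from a polar pool otherwise; loops are polar.  The
    model has exactly one CA per sequence position.  Truth records the
    TM segments, a per-residue exposure class (CA farther from the
    bundle axis than its helix axis → "exposed", else "buried"; loops
    are "exposed"), and the seed.  Deterministic given the parameters.
    """
    if min(n_helices, helix_len) < 1 or loop_len < 0:
        raise ValueError("sizes must be positive (loop_len may be 0)")
    rng = np.random.default_rng(seed)
    seq_parts: list[str] = []
    segments: list[TMSegment] = []
    pos = 1
    for h in range(n_helices):
        if h > 0 and loop_len > 0:
            seq_parts.append(
                "".join(rng.choice(list(POLAR_POOL), size=loop_len))
            )
            pos += loop_len
        tm = [
            str(rng.choice(list(HYDROPHOBIC_POOL)))
            if rng.random() < hydrophobic_bias
            else str(rng.choice(list(POLAR_POOL)))
            for _ in range(helix_len)
        ]
        seq_parts.append("".join(tm))
        segments.append(TMSegment(pos, pos + helix_len - 1))
        pos += helix_len
    sequence = "".join(seq_parts)
    record = attach_segments(
        ProteinRecord(id=f"synTM_s{seed}", sequence=sequence), segments
    )
    coords = _bundle_coords(n_helices, helix_len, loop_len)
    assert len(coords) == len(sequence)
    spacing = 10.0
    exposure = []
    residues = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords), start=1):
        axial = math.hypot(xyz[0], xyz[1])
        in_tm = any(i in s for s in segments)
        exposure.append("exposed" if (not in_tm or axial > spacing) else "buried")
        residues.append(
            Residue(
                chain="A",
                number=i,
                icode="",
                name=_ONE_TO_THREE[aa],
                is_polymer=True,
                atoms=(Atom(name="CA", element="C", pos=tuple(xyz)),),
            )
        )
    model = StructureModel(id=record.id, residues=tuple(residues))
    return SyntheticProtein(
        record=record,
        model=model,
        truth={
            "segments": tuple(segments),
            "exposure": tuple(exposure),
            "sigma": 0.0,
            "seed": seed,
        },
    )


def perturb_structure(
    model: StructureModel, sigma: float, seed: int
) -> StructureModel:
    """Add i.i.d. Gaussian noise (σ per coordinate, Å) to every atom.

    After optimal superposition onto the original, the expected RMSD is
    close to σ·√3 for large atom counts (slightly below: the fitted 6
    rigid degrees of freedom absorb ~6/(3N) of the noise variance).
    Deterministic per seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []
    for res in model.residues:
        atoms = tuple(
            Atom(
                name=a.name,
                element=a.element,
                pos=tuple(np.asarray(a.pos) + rng.normal(0.0, sigma, 3)),
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
    return StructureModel(id=f"{model.id}_perturbed", residues=tuple(residues))


def write_fixture(protein: SyntheticProtein, out_dir: PathLike) -> dict[str, Path]:
    """Write FASTA + TM TSV + PDB for a synthetic protein; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{protein.record.id}.fasta",
        "tm": out / f"{protein.record.id}.tm.tsv",
        "pdb": out / f"{protein.record.id}.pdb",
    }
    write_fasta([protein.record], paths["fasta"])
    write_tm_annotations({protein.record.id: list(protein.record.segments)}, paths["tm"])
    write_pdb(protein.model, paths["pdb"])
    return paths
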