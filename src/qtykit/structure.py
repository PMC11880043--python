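"""Structure parsing and residue correspondence.

PDB and mmCIF files are read through gemmi into a small uniform model:
chains → residues → heavy atoms with Cartesian coordinates in Å.  Only
the first model of multi-model files is kept, alternate locations are
resolved to the highest-occupancy conformer (ties favour altloc 'A'),
and hydrogens are dropped everywhere — cryo-EM depositions lack them and
all downstream geometry (RMSD, SASA, contacts) is heavy-atom only.

Residues are keyed by author numbering (chain id, author residue number,
insertion code), which for the cryo-EM entries studied here matches
UniProt numbering; predicted models that number from 1 can be brought
onto the same axis with a per-chain offset, or paired sequence-wise with
the QTY-aware "align" policy.

Trimming rule: when native and analog models are paired by residue
number, residues present in only one model — unresolved loops in the
experimental structure, extra termini in the prediction — simply drop
out of the pairing.  That is the whole loop-trimming convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import gemmi
import numpy as np
from Bio import Align

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResiduePairing",
    "StructureError",
    "read_structure",
    "write_pdb",
    "extract_protomer",
    "pair_residues",
    "select_atoms",
    "THREE_TO_ONE",
]

PathLike = Union[str, Path]

#: 3-letter → 1-letter codes for the 20 standard residues.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ResidueKey = tuple[str, int, str]  # (chain id, author number, insertion code)


class StructureError(ValueError):
    """Unreadable file, empty model, or invalid selection/pairing."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]  # Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    icode: str
    name: str  # 3-letter (or ligand) code
    is_polymer: bool
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class StructureModel:
    """An ordered collection of residues from one structural model."""

    id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError(f"model {self.id!r}: duplicate residue keys")
        for r in self.residues:
            for a in r.atoms:
                if not np.all(np.isfinite(a.xyz)):
                    raise StructureError(
                        f"model {self.id!r}: non-finite coordinates on "
                        f"{r.name} {r.key} atom {a.name}"
                    )

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def polymer_residues(self, chain: Optional[str] = None) -> list[Residue]:
        return [
            r
            for r in self.residues
            if r.is_polymer and (chain is None or r.chain == chain)
        ]

    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_polymer]

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise StructureError(f"model {self.id!r}: no residue with key {key}")

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords() for r in self.residues])


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties → 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A")
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: PathLike, *, model_id: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file (auto-detected) into a :class:`StructureModel`.

    First model only; altlocs resolved deterministically; hydrogens
    dropped; hetero residues (ligands, cofactors, waters) retained and
    flagged non-polymer.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no models")
    model = st[0]
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                )
                for a in _resolve_altlocs(res)
                if not a.is_hydrogen()
            )
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    is_polymer=res.name in THREE_TO_ONE
                    and res.het_flag != "H",
                    atoms=atoms,
                )
            )
    if not residues:
        raise StructureError(f"{path}: no atoms found")
    return StructureModel(id=model_id or path.stem, residues=tuple(residues))


def write_pdb(model: StructureModel, path: PathLike) -> None:
    """Write the model as a fixed-column PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = model.id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        ch = chains.get(res.chain)
        if ch is None:
            ch = gemmi.Chain(res.chain)
            chains[res.chain] = ch
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
        gr.het_flag = "A" if res.is_polymer else "H"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            gr.add_atom(ga)
        ch.add_residue(gr)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_protomer(model: StructureModel, chain: str) -> StructureModel:
    """Cut one protomer out of a multimeric model.

    Keeps the chain's polymer residues plus every hetero residue whose
    nearest polymer atom belongs to that chain (so a cofactor bound in
    chain A travels with chain A).
    """
    polymer = model.polymer_residues(chain)
    if not polymer:
        raise StructureError(
            f"model {model.id!r}: no polymer chain {chain!r} "
            f"(chains present: {model.chains})"
        )
    poly_by_chain: dict[str, np.ndarray] = {}
    for ch in model.chains:
        res = model.polymer_residues(ch)
        if res:
            poly_by_chain[ch] = np.concatenate([r.coords() for r in res])
    kept_het: list[Residue] = []
    for het in model.hetero_residues():
        xyz = het.coords()
        best_chain, best_d = None, np.inf
        for ch, coords in poly_by_chain.items():
            d = np.min(
                np.linalg.norm(xyz[:, None, :] - coords[None, :, :], axis=-1)
            )
            if d < best_d:
                best_chain, best_d = ch, d
        if best_chain == chain:
            kept_het.append(het)
    ordered = [r for r in model.residues if r in set(polymer) | set(kept_het)]
    return StructureModel(id=f"{model.id}_{chain}", residues=tuple(ordered))


@dataclass(frozen=True)
class ResiduePairing:
    """One-to-one residue correspondence between two models."""

    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]
    policy: str = "resnum"

    def __len__(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "ResiduePairing":
        return ResiduePairing(
            pairs=tuple((b, a) for a, b in self.pairs), policy=self.policy
        )

    def mapped(self, key_b: ResidueKey) -> Optional[ResidueKey]:
        """Key in model A corresponding to ``key_b`` in model B, if any."""
        for a, b in self.pairs:
            if b == key_b:
                return a
        return None


#: Residue pairs the QTY code interconverts; under the "align" policy
#: these columns score as matches.
_QTY_EQUIV = {("L", "Q"), ("I", "T"), ("V", "T"), ("F", "Y")}


def _qty_aligner() -> Align.PairwiseAligner:
    letters = "ACDEFGHIKLMNPQRSTVWYX"
    mat = np.full((len(letters), len(letters)), -1.0)
    np.fill_diagonal(mat, 1.0)
    idx = {c: i for i, c in enumerate(letters)}
    for a, b in _QTY_EQUIV:
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = 1.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.Array(
        letters, 2, mat
    )
    aligner.mode = "global"
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    return aligner


def _pair_chain_resnum(
    res_a: Sequence[Residue], res_b: Sequence[Residue], offset: int
) -> list[tuple[ResidueKey, ResidueKey]]:
    with_ca_a = {
        (r.number, r.icode): r for r in res_a if r.ca is not None
    }
    pairs = []
    for r in res_b:
        if r.ca is None:
            continue
        match = with_ca_a.get((r.number + offset, r.icode))
        if match is not None:
            pairs.append((match.key, r.key))
    return pairs


def _pair_chain_align(
    res_a: Sequence[Residue], res_b: Sequence[Residue]
) -> list[tuple[ResidueKey, ResidueKey]]:
    ca_a = [r for r in res_a if r.ca is not None]
    ca_b = [r for r in res_b if r.ca is not None]
    if not ca_a or not ca_b:
        return []
    seq_a = "".join(r.one_letter for r in ca_a)
    seq_b = "".join(r.one_letter for r in ca_b)
    aln = _qty_aligner().align(seq_a, seq_b)[0]
    pairs = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pairs.append((ca_a[i].key, ca_b[j].key))
    return pairs


def pair_residues(
    a: StructureModel,
    b: StructureModel,
    policy: str = "resnum",
    *,
    chain_map: Optional[dict[str, str]] = None,
    offset: int = 0,
) -> ResiduePairing:
    """Establish a one-to-one residue correspondence between two models.

    policy="resnum"
        Pair residues sharing author number + insertion code (after
        mapping chains via ``chain_map`` and adding ``offset`` to B's
        numbers); residues present in only one model are dropped — this
        implements the loop-trimming convention.
    policy="align"
        Pair by global sequence alignment in which the QTY substitution
        pairs count as matches; aligned columns with a CA in both models
        are kept.  Use when the two models share no numbering scheme.

    Both members of every pair have a CA atom.  Fewer than 3 resulting
    pairs is an error.
    """
    if policy not in ("resnum", "align"):
        raise StructureError(f"unknown pairing policy {policy!r}")
    chains_a, chains_b = a.chains, b.chains
    if chain_map is None:
        # same-name chains when possible, else pair chains in order
        common = [c for c in chains_a if c in chains_b]
        if common:
            chain_map = {c: c for c in common}
        else:
            chain_map = dict(zip(chains_a, chains_b))
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for ch_a, ch_b in chain_map.items():
        res_a = a.polymer_residues(ch_a)
        res_b = b.polymer_residues(ch_b)
        if policy == "resnum":
            pairs.extend(_pair_chain_resnum(res_a, res_b, offset))
        else:
            pairs.extend(_pair_chain_align(res_a, res_b))
    if len(pairs) < 3:
        raise StructureError(
            f"insufficient common residues: {len(pairs)} pair(s) between "
            f"{a.id!r} and {b.id!r}"
        )
    return ResiduePairing(pairs=tuple(pairs), policy=policy)


def select_atoms(
    model: StructureModel, selector: str
) -> list[tuple[Residue, Atom]]:
    """Evaluate a selection string against the model.

    Grammar: clauses joined by ``and``; each clause is one of
    ``chain <id>``, ``resn <name>`` (residue/ligand 3-letter name), or
    ``resi <number>`` (author residue number).  Example:
    ``"chain A and resn FAD"``.
    """
    clauses = [c.strip() for c in selector.split(" and ")]
    tests = []
    for clause in clauses:
        parts = clause.split()
        if len(parts) != 2 or parts[0] not in ("chain", "resn", "resi"):
            raise StructureError(f"cannot parse selector clause {clause!r}")
        kw, val = parts
        if kw == "chain":
            tests.append(lambda r, v=val: r.chain == v)
        elif kw == "resn":
            tests.append(lambda r, v=val: r.name == v.upper())
        else:
            tests.append(lambda r, v=int(val): r.number == v)
    out = []
    for res in model.residues:
        if all(t(res) for t in tests):
            out.extend((res, atom) for atom in res.atoms)
    return out
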