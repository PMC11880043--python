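"""Binding-site geometry: ligand contact residues, inter-cofactor
distances, and native-vs-analog pocket conservation.

All distances are heavy-atom Euclidean distances in Å; the per-residue
distance recorded in a contact report is the *minimum* over all
heavy-atom pairs.  The default contact cutoff is 4.0 Å, the conventional
threshold for direct protein–ligand contact.  An alternative
"centroid" convention (distance between selection centroids) is offered
for cofactor separations, since published inter-cofactor figures do not
always say which convention they use; reports always name the convention
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    ResidueKey,
    ResiduePairing,
    StructureModel,
    StructureError,
    select_atoms,
)

__all__ = [
    "Contact",
    "ContactReport",
    "contact_residues",
    "min_distance",
    "pocket_conservation",
]


@dataclass(frozen=True)
class Contact:
    residue: ResidueKey
    name: str  # 3-letter residue name
    distance: float  # Å, min heavy-atom distance to the selection


@dataclass(frozen=True)
class ContactReport:
    model_id: str
    ligand_selector: str
    cutoff: float
    contacts: tuple[Contact, ...]  # sorted by distance

    @property
    def residue_keys(self) -> frozenset:
        return frozenset(c.residue for c in self.contacts)


def contact_residues(
    model: StructureModel,
    ligand_selector: str,
    cutoff: float = 4.0,
) -> ContactReport:
    """Polymer residues with any heavy atom within ``cutoff`` Å of the
    selection.

    The selection's own residues are excluded; each contact records the
    minimum heavy-atom distance, and contacts are sorted nearest first.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    selected = select_atoms(model, ligand_selector)
    if not selected:
        raise StructureError(
            f"selector {ligand_selector!r} matches no atoms in {model.id!r}"
        )
    sel_keys = {res.key for res, _ in selected}
    sel_coords = np.array([atom.pos for _, atom in selected])
    tree = cKDTree(sel_coords)
    contacts = []
    for res in model.residues:
        if not res.is_polymer or res.key in sel_keys:
            continue
        d, _ = tree.query(res.coords(), k=1)
        dmin = float(np.min(d))
        if dmin <= cutoff:
            contacts.append(Contact(residue=res.key, name=res.name, distance=dmin))
    contacts.sort(key=lambda c: (c.distance, c.residue))
    return ContactReport(
        model_id=model.id,
        ligand_selector=ligand_selector,
        cutoff=cutoff,
        contacts=tuple(contacts),
    )


def min_distance(
    model: StructureModel,
    selector_a: str,
    selector_b: str,
    *,
    convention: str = "min-heavy-atom",
) -> tuple[float, Optional[tuple[str, str]]]:
    """Distance between two disjoint selections.

    convention="min-heavy-atom"
        Minimum pairwise heavy-atom distance; also returns the achieving
        atom pair as ``(residue_name.atom, residue_name.atom)``.
    convention="centroid"
        Distance between the unweighted centroids of the two selections
        (atom pair is None).
    """
    sel_a = select_atoms(model, selector_a)
    sel_b = select_atoms(model, selector_b)
    if not sel_a or not sel_b:
        raise StructureError(
            f"empty selection: {selector_a!r} -> {len(sel_a)} atoms, "
            f"{selector_b!r} -> {len(sel_b)} atoms"
        )
    ids_a = {(res.key, atom.name) for res, atom in sel_a}
    ids_b = {(res.key, atom.name) for res, atom in sel_b}
    if ids_a & ids_b:
        raise StructureError(
            f"selections {selector_a!r} and {selector_b!r} share atoms"
        )
    xa = np.array([atom.pos for _, atom in sel_a])
    xb = np.array([atom.pos for _, atom in sel_b])
    if convention == "centroid":
        return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0))), None
    if convention != "min-heavy-atom":
        raise ValueError(f"unknown distance convention {convention!r}")
    dmat = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
    res_a, atom_a = sel_a[i]
    res_b, atom_b = sel_b[j]
    pair = (f"{res_a.name}{res_a.number}.{atom_a.name}",
            f"{res_b.name}{res_b.number}.{atom_b.name}")
    return float(dmat[i, j]), pair


def pocket_conservation(
    native_report: ContactReport,
    analog_report: ContactReport,
    pairing: ResiduePairing,
) -> dict:
    """Compare a native and an analog binding pocket through a pairing.

    Analog contact residues are mapped into native numbering via the
    pairing (native model = pairing side A, analog = side B).  The score
    is the Jaccard index of the mapped contact sets — a descriptive
    conservation measure, not a published statistic.  The per-residue
    table marks each native-keyed residue as kept / lost / gained; a
    pocket residue whose identity changed across the pairing (e.g. a
    hydrophobic contact replaced by a nearby polar one) shows up as one
    "lost" plus one "gained" row.  Analog contacts with no counterpart in
    the pairing are reported under ``unpaired_analog_contacts``, never
    dropped silently.
    """
    native_set = set(native_report.residue_keys)
    analog_names: Mapping[ResidueKey, str] = {
        c.residue: c.name for c in analog_report.contacts
    }
    mapped_analog = {}
    unpaired = []
    for key in analog_report.residue_keys:
        mapped = pairing.mapped(key)
        if mapped is None:
            unpaired.append(key)
        else:
            mapped_analog[mapped] = key
    analog_set = set(mapped_analog)
    union = native_set | analog_set
    inter = native_set & analog_set
    jaccard = len(inter) / len(union) if union else 1.0
    native_names = {c.residue: c.name for c in native_report.contacts}
    table = []
    for key in sorted(union):
        if key in inter:
            status = "kept"
        elif key in native_set:
            status = "lost"
        else:
            status = "gained"
        table.append(
            {
                "native_key": key,
                "native_name": native_names.get(key, ""),
                "analog_key": mapped_analog.get(key),
                "analog_name": analog_names.get(mapped_analog.get(key), ""),
                "status": status,
            }
        )
    return {
        "jaccard": jaccard,
        "n_native": len(native_set),
        "n_analog": len(analog_set),
        "n_kept": len(inter),
        "table": table,
        "unpaired_analog_contacts": sorted(unpaired),
        "score_definition": "jaccard-of-mapped-contact-sets",
    }
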