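import gemmi
import numpy as np
import pytest

import qtykit as q
from qtykit.structure import StructureError


def atom_line(
    serial, name, resname, chain, resnum, x, y, z,
    element=" C", altloc=" ", occ=1.0, het=False,
):
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
        f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
        f"          {element:>2}\n"
    )


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Three CA atoms in chain A plus a two-atom HEM near residue 1."""
    text = (
        atom_line(1, " CA ", "GLY", "A", 1, 0.0, 0.0, 0.0)
        + atom_line(2, " CA ", "LEU", "A", 2, 3.8, 0.0, 0.0)
        + atom_line(3, " CA ", "VAL", "A", 3, 7.6, 0.0, 0.0)
        + "END\n"
    )
    p = tmp_path / "tri.pdb"
    p.write_text(text)
    return p


class TestReadStructure:
    def test_minimal_pdb(self, tripeptide_pdb):
        model = q.read_structure(tripeptide_pdb)
        assert model.n_atoms == 3
        assert len(model.residues) == 3
        assert [r.name for r in model.residues] == ["GLY", "LEU", "VAL"]
        assert model.residues[1].ca.pos == pytest.approx((3.8, 0.0, 0.0))

    def test_pdb_and_mmcif_equivalent(self, tripeptide_pdb, tmp_path):
        st = gemmi.read_structure(str(tripeptide_pdb))
        st.setup_entities()
        cif_path = tmp_path / "tri.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        from_pdb = q.read_structure(tripeptide_pdb, model_id="m")
        from_cif = q.read_structure(cif_path, model_id="m")
        assert [r.name for r in from_cif.residues] == [
            r.name for r in from_pdb.residues
        ]
        assert np.allclose(from_cif.all_coords(), from_pdb.all_coords())

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = (
            atom_line(1, " CA ", "SER", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.6)
            + atom_line(2, " CA ", "SER", "A", 1, 1.0, 0.0, 0.0, altloc="B", occ=0.4)
            + "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        model = q.read_structure(p)
        assert model.n_atoms == 1
        assert model.residues[0].ca.pos == pytest.approx((0.0, 0.0, 0.0))

    def test_altloc_tie_prefers_a(self, tmp_path):
        text = (
            atom_line(1, " CA ", "SER", "A", 1, 1.0, 0.0, 0.0, altloc="B", occ=0.5)
            + atom_line(2, " CA ", "SER", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.5)
            + "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        assert q.read_structure(p).residues[0].ca.pos == pytest.approx(
            (0.0, 0.0, 0.0)
        )

    def test_hydrogens_dropped(self, tmp_path):
        text = (
            atom_line(1, " CA ", "GLY", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, " HA ", "GLY", "A", 1, 0.5, 0.5, 0.0, element=" H")
            + "END\n"
        )
        p = tmp_path / "h.pdb"
        p.write_text(text)
        assert q.read_structure(p).n_atoms == 1

    def test_zero_atoms_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(StructureError, match="no atoms"):
            q.read_structure(p)

    def test_hetero_flagged_nonpolymer(self, tmp_path):
        text = (
            atom_line(1, " CA ", "GLY", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, " CA ", "LEU", "A", 2, 3.8, 0.0, 0.0)
            + atom_line(3, "FE  ", "HEM", "A", 101, 2.0, 3.0, 0.0,
                        element="FE", het=True)
            + "END\n"
        )
        p = tmp_path / "het.pdb"
        p.write_text(text)
        model = q.read_structure(p)
        assert [r.is_polymer for r in model.residues] == [True, True, False]


class TestWritePdb:
    def test_round_trip(self, bundle, tmp_path):
        out = tmp_path / "m.pdb"
        q.write_pdb(bundle.model, out)
        back = q.read_structure(out)
        assert back.n_atoms == bundle.model.n_atoms
        assert np.allclose(
            back.all_coords(), bundle.model.all_coords(), atol=1e-3
        )
        assert [r.name for r in back.residues] == [
            r.name for r in bundle.model.residues
        ]


class TestExtractProtomer:
    @pytest.fixture
    def dimer(self, tmp_path):
        text = (
            atom_line(1, " CA ", "GLY", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, " CA ", "LEU", "A", 2, 3.8, 0.0, 0.0)
            + atom_line(3, " CA ", "GLY", "B", 1, 50.0, 0.0, 0.0)
            + atom_line(4, " CA ", "LEU", "B", 2, 53.8, 0.0, 0.0)
            + atom_line(5, "FE  ", "HEM", "C", 201, 1.0, 3.0, 0.0,
                        element="FE", het=True)
            + "END\n"
        )
        p = tmp_path / "dimer.pdb"
        p.write_text(text)
        return q.read_structure(p)

    def test_single_chain_kept(self, dimer):
        protomer = q.extract_protomer(dimer, "B")
        assert {r.chain for r in protomer.residues if r.is_polymer} == {"B"}

    def test_cofactor_travels_with_nearest_chain(self, dimer):
        a = q.extract_protomer(dimer, "A")
        assert any(r.name == "HEM" for r in a.residues)
        b = q.extract_protomer(dimer, "B")
        assert not any(r.name == "HEM" for r in b.residues)

    def test_unknown_chain_errors(self, dimer):
        with pytest.raises(StructureError, match="no polymer chain"):
            q.extract_protomer(dimer, "Z")


class TestPairResidues:
    def test_identical_models_fully_paired(self, bundle):
        pairing = q.pair_residues(bundle.model, bundle.model)
        assert len(pairing) == len(bundle.model.residues)
        assert all(a == b for a, b in pairing.pairs)

    def test_missing_residues_trimmed(self, bundle):
        truncated = q.StructureModel(
            id="trunc",
            residues=tuple(
                r for r in bundle.model.residues if not 10 <= r.number <= 20
            ),
        )
        pairing = q.pair_residues(bundle.model, truncated)
        assert len(pairing) == len(bundle.model.residues) - 11
        assert all(not 10 <= a[1] <= 20 for a, _ in pairing.pairs)

    def test_pairing_symmetry(self, bundle):
        truncated = q.StructureModel(
            id="trunc", residues=bundle.model.residues[5:]
        )
        fwd = q.pair_residues(bundle.model, truncated)
        rev = q.pair_residues(truncated, bundle.model)
        assert set(fwd.reversed().pairs) == set(rev.pairs)

    def test_trimming_monotonicity(self, bundle):
        full = q.pair_residues(bundle.model, bundle.model)
        smaller = q.StructureModel(id="s", residues=bundle.model.residues[::2])
        reduced = q.pair_residues(bundle.model, smaller)
        assert len(reduced) < len(full)
        assert set(reduced.pairs) <= set(full.pairs)

    def test_offset_bridges_renumbering(self, bundle):
        renumbered = q.StructureModel(
            id="renum",
            residues=tuple(
                q.Residue(r.chain, r.number - 100, r.icode, r.name,
                          r.is_polymer, r.atoms)
                for r in bundle.model.residues
            ),
        )
        pairing = q.pair_residues(bundle.model, renumbered, offset=100)
        assert len(pairing) == len(bundle.model.residues)

    def test_align_policy_pairs_qty_column(self, bundle):
        """A QTY-substituted model pairs site-by-site under 'align'."""
        qty_model = q.StructureModel(
            id="qty",
            residues=tuple(
                q.Residue(
                    r.chain, r.number + 7, r.icode,  # different numbering
                    {"LEU": "GLN", "ILE": "THR", "VAL": "THR",
                     "PHE": "TYR"}.get(r.name, r.name),
                    r.is_polymer, r.atoms,
                )
                for r in bundle.model.residues
            ),
        )
        pairing = q.pair_residues(bundle.model, qty_model, "align")
        assert len(pairing) == len(bundle.model.residues)
        assert all(a[1] + 7 == b[1] for a, b in pairing.pairs)

    def test_too_few_pairs_errors(self, bundle):
        tiny = q.StructureModel(id="t", residues=bundle.model.residues[:2])
        shifted = q.StructureModel(
            id="s",
            residues=tuple(
                q.Residue(r.chain, r.number + 500, r.icode, r.name,
                          r.is_polymer, r.atoms)
                for r in bundle.model.residues
            ),
        )
        with pytest.raises(StructureError, match="insufficient common residues"):
            q.pair_residues(tiny, tiny)
        with pytest.raises(StructureError, match="insufficient common residues"):
            q.pair_residues(bundle.model, shifted)


class TestSelectAtoms:
    def test_selectors(self, bundle):
        model = bundle.model
        assert len(q.select_atoms(model, "chain A")) == model.n_atoms
        resi = q.select_atoms(model, "resi 5")
        assert len(resi) == 1 and resi[0][0].number == 5
        name5 = model.residues[4].name
        combined = q.select_atoms(model, f"chain A and resi 5 and resn {name5}")
        assert len(combined) == 1

    def test_bad_selector(self, bundle):
        with pytest.raises(StructureError, match="cannot parse"):
            q.select_atoms(bundle.model, "within 4 of resn FAD")
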