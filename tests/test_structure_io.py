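import math

import numpy as np
import pytest

from rcckit.errors import EmptyStructureError, PDBInputError, UnknownChainError
from rcckit.fixtures import make_ideal_helix, make_random_chain
from rcckit.structure_io import (
    Atom,
    Residue,
    parse_structure,
    residue_envelope,
    select_residues,
    strip_side_chains,
    write_pdb,
)


def atom_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    xyz,
    occ=1.00,
    altloc=" ",
    element=None,
    record="ATOM",
):
    """Hand-rolled, column-exact PDB record (independent of write_pdb)."""
    element = element or name[0]
    padded = f" {name:<3s}" if len(element) == 1 and len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:5d} {padded}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def tri_gly_text(extra_lines=()):
    lines = []
    serial = 1
    for i in range(3):
        for name, off in (("N", 0.0), ("CA", 1.5), ("C", 2.4), ("O", 3.0)):
            lines.append(
                atom_line(serial, name, "GLY", "A", i + 1, (i * 4.0 + off, 0.0, 0.0))
            )
            serial += 1
    lines.extend(extra_lines)
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestParseStructure:
    def test_three_glycines_ordinals(self):
        s = parse_structure(tri_gly_text())
        assert len(s.chains) == 1
        chain = s.chains[0]
        assert [r.ordinal_index for r in chain] == [0, 1, 2]
        assert [r.residue_name for r in chain] == ["GLY"] * 3
        assert all(len(r.atoms) == 4 for r in chain)

    def test_water_hetatm_dropped(self):
        water = atom_line(99, "O", "HOH", "A", 50, (30.0, 30.0, 30.0), record="HETATM")
        plain = parse_structure(tri_gly_text())
        with_water = parse_structure(tri_gly_text([water]))
        assert with_water.n_residues == plain.n_residues == 3

    def test_altloc_highest_occupancy_wins(self):
        lines = [
            atom_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0)),
            atom_line(2, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.6, altloc="A"),
            atom_line(3, "CA", "ALA", "A", 1, (9.0, 0.0, 0.0), occ=0.4, altloc="B"),
            "END",
        ]
        s = parse_structure("\n".join(lines) + "\n")
        (res,) = s.chains[0]
        ca = [a for a in res.atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].coords[0] == pytest.approx(1.0)

    def test_altloc_tie_alphabetical(self):
        lines = [
            atom_line(1, "CA", "ALA", "A", 1, (5.0, 0.0, 0.0), occ=0.5, altloc="B"),
            atom_line(2, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.5, altloc="A"),
            "END",
        ]
        s = parse_structure("\n".join(lines) + "\n")
        (res,) = s.chains[0]
        assert res.atoms[0].coords[0] == pytest.approx(1.0)

    def test_mse_hetatm_kept_as_polymer(self):
        mse = atom_line(
            90, "CA", "MSE", "A", 4, (12.0, 0.0, 0.0), record="HETATM", element="C"
        )
        s = parse_structure(tri_gly_text([mse]))
        chain = s.chains[0]
        assert len(chain) == 4
        assert chain[-1].residue_name == "MSE"
        assert chain[-1].ordinal_index == 3

    def test_multi_model_default_first(self):
        lines = ["MODEL        1"]
        lines.append(atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0)))
        lines.append("ENDMDL")
        lines.append("MODEL        2")
        lines.append(atom_line(1, "CA", "GLY", "A", 1, (9.0, 9.0, 9.0)))
        lines.append("ENDMDL")
        lines.append("END")
        text = "\n".join(lines) + "\n"
        first = parse_structure(text)
        second = parse_structure(text, model=1)
        assert first.chains[0][0].atoms[0].coords[0] == pytest.approx(0.0)
        assert second.chains[0][0].atoms[0].coords[0] == pytest.approx(9.0)

    def test_hydrogens_dropped_by_default(self):
        h = atom_line(50, "H", "GLY", "A", 1, (0.5, 0.5, 0.5), element="H")
        s = parse_structure(tri_gly_text([h]))
        assert all(a.element != "H" for r in s.chains[0] for a in r.atoms)
        s2 = parse_structure(tri_gly_text([h]), include_hydrogens=True)
        assert any(a.element == "H" for a in s2.chains[0][0].atoms)

    def test_no_amino_acids_is_error(self):
        water_only = (
            atom_line(1, "O", "HOH", "A", 1, (0.0, 0.0, 0.0), record="HETATM")
            + "\nEND\n"
        )
        with pytest.raises(EmptyStructureError):
            parse_structure(water_only)

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(PDBInputError):
            parse_structure(tmp_path / "nope.pdb")


def two_chain_structure():
    lines = [
        atom_line(1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0)),
        atom_line(2, "CA", "GLY", "A", 2, (4.0, 0.0, 0.0)),
        "TER",
        atom_line(3, "CA", "GLY", "B", 1, (20.0, 0.0, 0.0)),
        "END",
    ]
    return parse_structure("\n".join(lines) + "\n")


class TestSelectResidues:
    def test_single_chain(self):
        s = two_chain_structure()
        got = select_residues(s, ["A"])
        assert [r.chain_id for r in got] == ["A", "A"]

    def test_default_all_chains(self):
        s = two_chain_structure()
        assert [r.chain_id for r in select_residues(s)] == ["A", "A", "B"]

    def test_order_is_file_order_not_request_order(self):
        s = two_chain_structure()
        got = select_residues(s, ["B", "A"])
        assert [r.chain_id for r in got] == ["A", "A", "B"]

    def test_unknown_chain_raises(self):
        with pytest.raises(UnknownChainError):
            select_residues(two_chain_structure(), ["Z"])


def residue_with(names):
    return Residue(
        chain_id="A",
        author_seq_id=1,
        ordinal_index=0,
        residue_name="ALA",
        atoms=[
            Atom(name=n, element=n[0], coords=np.array([float(i), 0.0, 0.0]))
            for i, n in enumerate(names)
        ],
    )


class TestStripSideChains:
    def test_alanine_loses_cb(self):
        (res,) = strip_side_chains([residue_with(["N", "CA", "C", "O", "CB"])])
        assert [a.name for a in res.atoms] == ["N", "CA", "C", "O"]

    def test_glycine_unchanged(self):
        (res,) = strip_side_chains([residue_with(["N", "CA", "C", "O"])])
        assert len(res.atoms) == 4

    def test_ca_trace_kept(self):
        (res,) = strip_side_chains([residue_with(["CA"])])
        assert [a.name for a in res.atoms] == ["CA"]

    def test_oxt_is_backbone(self):
        (res,) = strip_side_chains([residue_with(["N", "CA", "C", "O", "OXT"])])
        assert len(res.atoms) == 5

    def test_residue_without_backbone_dropped_no_renumber(self):
        r0 = residue_with(["N", "CA", "C", "O"])
        r1 = residue_with(["CB"])
        r1.ordinal_index = 1
        r2 = residue_with(["CA"])
        r2.ordinal_index = 2
        out = strip_side_chains([r0, r1, r2])
        assert [r.ordinal_index for r in out] == [0, 2]

    def test_idempotent(self, helix30):
        once = strip_side_chains(helix30)
        twice = strip_side_chains(once)
        assert [[a.name for a in r.atoms] for r in once] == [
            [a.name for a in r.atoms] for r in twice
        ]


class TestResidueEnvelope:
    def test_single_atom(self):
        res = residue_with(["CA"])
        res.atoms = [Atom(name="CA", element="C", coords=np.array([1.0, 2.0, 3.0]))]
        env = residue_envelope(res)
        assert np.allclose(env.center, [1.0, 2.0, 3.0])
        assert env.radius == 0.0

    def test_two_atoms_symmetric(self):
        res = residue_with(["A", "B"])
        res.atoms = [
            Atom(name="X1", element="C", coords=np.zeros(3)),
            Atom(name="X2", element="C", coords=np.array([2.0, 0.0, 0.0])),
        ]
        env = residue_envelope(res)
        assert np.allclose(env.center, [1.0, 0.0, 0.0])
        assert env.radius == pytest.approx(1.0)

    def test_three_atom_triangle_derived(self):
        # atoms (0,0,0), (4,0,0), (0,4,0): center (4/3, 4/3, 0);
        # distances: sqrt(32)/3, sqrt(80)/3, sqrt(80)/3 -> radius sqrt(80)/3
        res = residue_with(["A", "B", "C"])
        res.atoms = [
            Atom(name="X1", element="C", coords=np.zeros(3)),
            Atom(name="X2", element="C", coords=np.array([4.0, 0.0, 0.0])),
            Atom(name="X3", element="C", coords=np.array([0.0, 4.0, 0.0])),
        ]
        env = residue_envelope(res)
        assert np.allclose(env.center, [4.0 / 3.0, 4.0 / 3.0, 0.0])
        assert env.radius == pytest.approx(math.sqrt(80.0) / 3.0, abs=1e-12)

    def test_every_atom_within_radius(self):
        for seed in range(5):
            for res in make_random_chain(20, seed, "backbone_plus_dummy_sidechain"):
                env = residue_envelope(res)
                dists = np.linalg.norm(res.coord_array() - env.center, axis=1)
                assert (dists <= env.radius + 1e-9).all()

    def test_no_atoms_is_contract_violation(self):
        res = residue_with(["CA"])
        res.atoms = []
        with pytest.raises(ValueError):
            residue_envelope(res)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "mode", ["ca_only", "backbone", "backbone_plus_dummy_sidechain"]
    )
    def test_fixture_roundtrip(self, mode):
        original = make_ideal_helix(12, mode)
        reparsed = select_residues(parse_structure(write_pdb(original)))
        assert len(reparsed) == len(original)
        for a, b in zip(original, reparsed):
            assert a.ordinal_index == b.ordinal_index
            assert a.residue_name == b.residue_name
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            # PDB coordinates carry 3 decimals
            assert np.allclose(a.coord_array(), b.coord_array(), atol=5.1e-4)

    def test_two_chain_roundtrip(self):
        s = two_chain_structure()
        flat = select_residues(s)
        reparsed = select_residues(parse_structure(write_pdb(flat)))
        assert [r.key for r in reparsed] == [r.key for r in flat]
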