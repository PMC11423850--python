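import numpy as np
import pytest

from quatbind import structure_io as sio
from quatbind.structure_io import (
    AssemblyBuildError,
    AtomRecord,
    PdbCapacityError,
    StructureParseError,
    TransformOperator,
    build_assemblies,
    parse_oper_expression,
    parse_structure,
    split_for_pdb,
    write_structure,
)


class TestOperExpression:
    def test_comma_list(self):
        assert parse_oper_expression("1,2") == [("1",), ("2",)]

    def test_range(self):
        assert parse_oper_expression("1-4") == [("1",), ("2",), ("3",), ("4",)]

    def test_cartesian_product(self):
        assert parse_oper_expression("(1-2)(5)") == [("1", "5"), ("2", "5")]

    def test_icosahedral_style(self):
        assert len(parse_oper_expression("(1-60)(61)")) == 60

    def test_deeper_nesting_rejected(self):
        with pytest.raises(AssemblyBuildError, match="grammar"):
            parse_oper_expression("(1)(2)(3)")

    def test_empty_selection_rejected(self):
        with pytest.raises(AssemblyBuildError):
            parse_oper_expression("")


class TestTransformOperator:
    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])  # det = -1
        with pytest.raises(AssemblyBuildError, match="proper rotation"):
            TransformOperator("m", R, np.zeros(3))

    def test_non_orthogonal_rejected(self):
        R = np.eye(3)
        R[0, 1] = 0.05
        with pytest.raises(AssemblyBuildError):
            TransformOperator("m", R, np.zeros(3))

    def test_compose_matches_sequential_application(self):
        rng = np.random.default_rng(3)

        def random_rot(seed):
            from scipy.spatial.transform import Rotation

            return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()

        a = TransformOperator("a", random_rot(1), np.array([1.0, -2.0, 3.0]))
        b = TransformOperator("b", random_rot(2), np.array([0.5, 0.0, -1.0]))
        x = rng.normal(size=(10, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(x), a.apply(b.apply(x)), atol=1e-12
        )


class TestParse:
    def test_fixture_homodimer_definition(self, dimer_fixture):
        path, _ = dimer_fixture
        parsed = parse_structure(path)
        assert parsed.chain_ids() == ["A"]
        assert len(parsed.assemblies) == 1
        assert "1" in parsed.operators and parsed.operators["1"].is_identity

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            parse_structure("/nonexistent/file.cif")

    def test_unreadable_header_is_parse_error(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\n_atom_site.id\n_atom_site.id\n")  # duplicate item
        with pytest.raises((StructureParseError, Exception)):
            parsed = parse_structure(bad)
            assert parsed.atoms  # must not return a partial result silently

    def test_no_coordinates_is_error(self, tmp_path):
        empty = tmp_path / "empty.cif"
        empty.write_text("data_empty\n_cell.length_a 1.0\n")
        with pytest.raises(StructureParseError, match="atom_site"):
            parse_structure(empty)

    def test_missing_assembly_records_gives_empty_definitions(self, tmp_path):
        cif = tmp_path / "noasm.cif"
        cif.write_text(
            "data_noasm\nloop_\n_atom_site.group_PDB\n_atom_site.id\n"
            "_atom_site.type_symbol\n_atom_site.label_atom_id\n"
            "_atom_site.label_comp_id\n_atom_site.label_asym_id\n"
            "_atom_site.auth_seq_id\n_atom_site.Cartn_x\n_atom_site.Cartn_y\n"
            "_atom_site.Cartn_z\nATOM 1 C CA ALA A 1 0.0 0.0 0.0\n"
        )
        parsed = parse_structure(cif)
        assert parsed.assemblies == []
        assert len(parsed.atoms) == 1


class TestAltLoc:
    def test_highest_occupancy_kept(self):
        mk = lambda alt, occ: AtomRecord(1, "CA", "C", "ALA", "A", 1, "",
                                         np.zeros(3), occupancy=occ, altloc=alt)
        kept = sio._select_altloc([mk("A", 0.4), mk("B", 0.6)])
        assert len(kept) == 1 and kept[0].altloc == "B"

    def test_tie_broken_by_altloc_order(self):
        mk = lambda alt: AtomRecord(1, "CA", "C", "ALA", "A", 1, "",
                                    np.zeros(3), occupancy=0.5, altloc=alt)
        kept = sio._select_altloc([mk("B"), mk("A")])
        assert kept[0].altloc == "A"


class TestBuildAssemblies:
    def test_identity_operator_preserves_coordinates(self, monomer_fixture):
        path, _ = monomer_fixture
        parsed = parse_structure(path)
        asm = build_assemblies(parsed)[0]
        orig = np.array([a.coords for a in parsed.atoms])
        built = np.array([a.coords for a in asm.atoms])
        np.testing.assert_array_equal(orig, built)

    def test_operator_duplication_matrix_oracle(self, dimer_fixture):
        path, _ = dimer_fixture
        parsed = parse_structure(path)
        asm = build_assemblies(parsed)[0]
        assert asm.chain_ids() == ["A", "A-2"]
        op = parsed.operators["2"]
        orig = np.array([a.coords for a in parsed.atoms])
        copy = np.array([a.coords for a in asm.atoms if a.asym_id == "A-2"])
        oracle = orig @ op.R.T + op.t  # independent matrix application
        np.testing.assert_allclose(copy, oracle, atol=1e-9)

    def test_atom_count_conservation(self, dimer_fixture):
        path, _ = dimer_fixture
        parsed = parse_structure(path)
        asm = build_assemblies(parsed)[0]
        n_opers = 2  # generator "1,2" over one asym unit
        assert len(asm.atoms) == n_opers * len(parsed.atoms)

    def test_rigid_body_preserves_intra_chain_distances(self, dimer_fixture):
        path, _ = dimer_fixture
        parsed = parse_structure(path)
        asm = build_assemblies(parsed)[0]
        orig = np.array([a.coords for a in parsed.atoms])[:40]
        copy = np.array([a.coords for a in asm.atoms if a.asym_id == "A-2"])[:40]
        d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=2)
        d_copy = np.linalg.norm(copy[:, None] - copy[None, :], axis=2)
        np.testing.assert_allclose(d_copy, d_orig, atol=1e-6)

    def test_unknown_operator_id_named_in_error(self, tmp_path, monomer_fixture):
        path, _ = monomer_fixture
        parsed = parse_structure(path)
        parsed.assemblies[0].generators = [("99", ["A"])]
        with pytest.raises(AssemblyBuildError, match="99"):
            build_assemblies(parsed)

    def test_deterministic_provenance(self, dimer_fixture):
        path, _ = dimer_fixture
        p1 = build_assemblies(parse_structure(path))[0].provenance
        p2 = build_assemblies(parse_structure(path))[0].provenance
        assert p1 == p2

    def test_nmr_first_model_only(self, tmp_path):
        mk = lambda model, x: AtomRecord(1, "CA", "C", "ALA", "A", 1, "",
                                         np.array([x, 0.0, 0.0]), model_num=model)
        atoms = [mk(1, 0.0), mk(2, 5.0)]
        sio.write_mmcif(atoms, tmp_path / "nmr.cif",
                        operators={"1": TransformOperator("1", np.eye(3), np.zeros(3))},
                        assemblies=[sio.AssemblyDefinition("1", [("1", ["A"])])])
        parsed = parse_structure(tmp_path / "nmr.cif")
        assert parsed.model_numbers == [1, 2]
        asm = build_assemblies(parsed)[0]
        assert len(asm.atoms) == 1 and asm.atoms[0].coords[0] == 0.0


class TestWriteRoundTrip:
    def test_mmcif_round_trip_atom_count(self, hetero_fixture, tmp_path):
        path, _ = hetero_fixture
        parsed = parse_structure(path)
        out = tmp_path / "rt.cif"
        write_structure(parsed.atoms, out, format="mmcif")
        again = parse_structure(out)
        assert len(again.atoms) == len(parsed.atoms)

    def test_pdb_round_trip_coordinates(self, hetero_fixture, tmp_path):
        path, _ = hetero_fixture
        parsed = parse_structure(path)
        out = tmp_path / "rt.pdb"
        write_structure(parsed.atoms, out, format="pdb")
        again = parse_structure(out)
        a = np.array([x.coords for x in parsed.atoms])
        b = np.array([x.coords for x in again.atoms])
        np.testing.assert_allclose(a, b, atol=1e-3)

    def test_mmcif_pdb_mmcif_composition(self, hetero_fixture, tmp_path):
        path, _ = hetero_fixture
        parsed = parse_structure(path)
        write_structure(parsed.atoms, tmp_path / "a.pdb", format="pdb")
        mid = parse_structure(tmp_path / "a.pdb")
        write_structure(mid.atoms, tmp_path / "b.cif", format="mmcif")
        final = parse_structure(tmp_path / "b.cif")
        def comp(parsed_struct):
            return [(a.asym_id, a.seq_id, a.comp_id, a.name) for a in parsed_struct.atoms]
        assert comp(final) == comp(parsed)
        a = np.array([x.coords for x in parsed.atoms])
        b = np.array([x.coords for x in final.atoms])
        np.testing.assert_allclose(a, b, atol=1e-3)

    def test_pdb_write_over_62_chains_is_capacity_error(self, giant_fixture, tmp_path):
        path, _ = giant_fixture
        parsed = parse_structure(path)
        with pytest.raises(PdbCapacityError, match="split_for_pdb"):
            write_structure(parsed.atoms, tmp_path / "giant.pdb", format="pdb")

    def test_two_chain_fixture_single_pdb(self, hetero_fixture, tmp_path):
        path, _ = hetero_fixture
        parsed = parse_structure(path)
        write_structure(parsed.atoms, tmp_path / "ok.pdb", format="pdb")
        assert (tmp_path / "ok.pdb").exists()


class TestSplitForPdb:
    def test_100_chain_split(self, giant_fixture, tmp_path):
        path, _ = giant_fixture
        parsed = parse_structure(path)
        asm = build_assemblies(parsed)[0]
        paths, mapping = split_for_pdb(asm, tmp_path)
        assert len(paths) == 2
        counts = [sum(1 for r in mapping if r[1] == i) for i in (1, 2)]
        assert counts == [62, 38]
        assert len(mapping) == 100

    def test_mapping_is_bijection(self, giant_fixture, tmp_path):
        path, _ = giant_fixture
        asm = build_assemblies(parse_structure(path))[0]
        _, mapping = split_for_pdb(asm, tmp_path)
        new_ids = [(idx, new) for _, idx, new in mapping]
        origs = [orig for orig, _, _ in mapping]
        assert len(set(new_ids)) == len(mapping)
        assert sorted(origs) == sorted(asm.chain_ids())

    def test_62_chain_fixture_one_file(self, fixture_dir, tmp_path):
        from quatbind.fixtures import FixtureSpec, make_structure_fixture

        path, _ = make_structure_fixture(
            FixtureSpec("many_chain_giant", seed=2, params={"n_chains": 62}), fixture_dir
        )
        asm = build_assemblies(parse_structure(path))[0]
        paths, mapping = split_for_pdb(asm, tmp_path)
        assert len(paths) == 1 and len(mapping) == 62

    def test_split_files_parse_back(self, giant_fixture, tmp_path):
        path, _ = giant_fixture
        asm = build_assemblies(parse_structure(path))[0]
        paths, mapping = split_for_pdb(asm, tmp_path)
        total = sum(len(parse_structure(p).atoms) for p in paths)
        assert total == len(asm.atoms)


class TestModifiedResidues:
    def test_parent_comp_applied_in_assembly(self, tmp_path):
        import numpy as np

        atoms = [
            AtomRecord(1, "CA", "C", "MSE", "A", 1, "", np.zeros(3)),
            AtomRecord(2, "CA", "C", "ALA", "A", 2, "", np.array([3.8, 0.0, 0.0])),
        ]
        mods = sio.ModifiedResidueMap(entries=[("A", 1, "MSE", "MET")])
        path = tmp_path / "mod.cif"
        sio.write_mmcif(
            atoms, path,
            operators={"1": TransformOperator("1", np.eye(3), np.zeros(3))},
            assemblies=[sio.AssemblyDefinition("1", [("1", ["A"])])],
            mod_residues=mods,
        )
        parsed = parse_structure(path)
        assert parsed.mod_residues.entries == [("A", 1, "MSE", "MET")]
        assert parsed.atoms[0].comp_id == "MSE"  # parse keeps the original
        asm = build_assemblies(parsed)[0]
        assert asm.atoms[0].comp_id == "MET"  # assembly sees the parent
        np.testing.assert_array_equal(asm.atoms[0].coords, atoms[0].coords)
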