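"""Coordination shells, denticity, distances and buried surface area."""

import numpy as np
import pytest

from lanmkit import synthetic_data as sd
from lanmkit.structure_sites import (
    StructureParseError,
    carboxylate_denticity,
    coordination_shell,
    find_metal_sites,
    interface_bsa,
    load_structure,
    pair_distance,
    select_atoms,
    shrake_rupley_sasa,
    site_comparison,
)

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  O   GLY A   1       2.100   1.100   0.000  1.00  0.00           O
END
"""


class TestLoadStructure:
    def test_minimal_pdb_fixture(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        st = load_structure(path)
        atoms = select_atoms(st)
        assert len(atoms) == 3
        assert [a[3] for a in atoms] == ["N", "CA", "O"]

    def test_synthetic_site_round_trips_coordinates(self, tmp_path):
        st, truth = sd.gen_metal_site(seed=9)
        before = {a[:4]: a[4] for a in select_atoms(st)}
        path = tmp_path / "site.pdb"
        path.write_text(st.make_pdb_string())
        st2 = load_structure(path)
        after = {a[:4]: a[4] for a in select_atoms(st2)}
        assert set(before) == set(after)
        for key, xyz in before.items():
            assert np.allclose(xyz, after[key], atol=1e-3)

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "broken.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(StructureParseError):
            load_structure(path)

    def test_altloc_policy_keeps_highest_occupancy(self, tmp_path, build_structure):
        st = build_structure([
            ("A", "GLU", 1, "OE1", "O", (0, 0, 0), 0.3, "A"),
            ("A", "GLU", 1, "OE1", "O", (5, 0, 0), 0.7, "B"),
            ("A", "GLU", 1, "OE2", "O", (1, 0, 0), 1.0),
        ])
        path = tmp_path / "alt.pdb"
        path.write_text(st.make_pdb_string())
        st2 = load_structure(path)
        atoms = select_atoms(st2, atom_names={"OE1"})
        assert len(atoms) == 1
        assert atoms[0][4][0] == pytest.approx(5.0, abs=1e-3)


class TestMetalSites:
    def test_fixture_with_mixed_ions(self, build_structure):
        st = build_structure(
            [("A", "LA", i, "LA", "La", (float(i * 10), 0, 0)) for i in (1, 2, 3)]
            + [("A", "NA", 9, "NA", "Na", (50.0, 0, 0))]
        )
        sites = find_metal_sites(st)
        assert len(sites) == 4
        assert [s.element for s in sites] == ["La", "La", "La", "Na"]

    def test_metal_free_model(self, build_structure):
        st = build_structure([("A", "GLY", 1, "CA", "C", (0, 0, 0))])
        assert find_metal_sites(st) == []

    def test_low_occupancy_excluded(self, build_structure):
        st = build_structure([
            ("A", "LA", 1, "LA", "La", (0, 0, 0), 1.0),
            ("A", "LA", 2, "LA", "La", (10, 0, 0), 0.3),
        ])
        assert len(find_metal_sites(st)) == 1


class TestCoordinationShell:
    def test_planned_cn_with_decoys(self):
        st, truth = sd.gen_metal_site(cn=10, n_decoys=3, seed=4)
        site = coordination_shell(st, find_metal_sites(st)[0])
        assert site.coordination_number == 10
        assert all(d.distance <= 3.0 for d in site.donors)
        # sorted by distance
        dists = [d.distance for d in site.donors]
        assert dists == sorted(dists)

    def test_empty_neighbourhood(self, build_structure):
        st = build_structure([
            ("A", "LA", 1, "LA", "La", (0, 0, 0)),
            ("A", "HOH", 2, "O", "O", (5.0, 0, 0)),
        ])
        site = coordination_shell(st, find_metal_sites(st)[0])
        assert site.coordination_number == 0

    def test_against_brute_force_oracle(self):
        st, _ = sd.gen_metal_site(cn=8, denticity_plan=("bidentate",), seed=7)
        site = coordination_shell(st, find_metal_sites(st)[0], cutoff=3.0)
        mpos = np.array(site.position)
        count = sum(
            1
            for a in select_atoms(st)
            if a[2] != "LA"
            and a[4] is not None
            and np.linalg.norm(a[4] - mpos) <= 3.0
        )
        assert site.coordination_number == count

    def test_waters_tagged(self):
        st, truth = sd.gen_metal_site(cn=9, denticity_plan=("bidentate",), seed=2)
        site = coordination_shell(st, find_metal_sites(st)[0])
        assert site.n_waters == truth["n_waters_in_shell"]


class TestDenticity:
    def test_planned_modes_recovered(self):
        plan = ("bidentate", "monodentate", "bidentate")
        st, truth = sd.gen_metal_site(cn=10, denticity_plan=plan, seed=3)
        site = coordination_shell(st, find_metal_sites(st)[0])
        calls = carboxylate_denticity(st, site)
        assert [c.mode for c in calls] == list(plan)
        for call in calls:
            n_in = sum(d <= 3.0 for d in call.o_distances)
            assert (call.mode == "bidentate") == (n_in == 2)

    def test_explicit_distances(self, build_structure):
        st = build_structure([
            ("A", "LA", 1, "LA", "La", (0, 0, 0)),
            ("A", "GLU", 2, "OE1", "O", (2.4, 0, 0)),
            ("A", "GLU", 2, "OE2", "O", (3.6, 0, 0)),
        ])
        site = coordination_shell(st, find_metal_sites(st)[0])
        (call,) = carboxylate_denticity(st, site)
        assert call.mode == "monodentate"
        assert call.o_distances == pytest.approx((2.4, 3.6))

    def test_rigid_motion_invariance(self, rng):
        st, truth = sd.gen_metal_site(
            cn=10, denticity_plan=("bidentate", "monodentate"), seed=6
        )
        before = [
            c.mode
            for c in carboxylate_denticity(
                st, coordination_shell(st, find_metal_sites(st)[0])
            )
        ]
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        t = rng.uniform(-50, 50, 3)
        import gemmi

        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        new = q @ xyz + t
                        atom.pos = gemmi.Position(*new)
        after = [
            c.mode
            for c in carboxylate_denticity(
                st, coordination_shell(st, find_metal_sites(st)[0])
            )
        ]
        assert before == after


class TestPairDistance:
    def test_two_atoms(self, build_structure):
        st = build_structure([
            ("A", "GLY", 1, "O", "O", (0, 0, 0)),
            ("B", "GLY", 1, "N", "N", (0, 0, 3.0)),
        ])
        d = pair_distance(select_atoms(st, chain="A"), select_atoms(st, chain="B"))
        assert d == pytest.approx(3.0)

    def test_self_selection_distinct_pairs(self, build_structure):
        st = build_structure([
            ("A", "GLU", 1, "OE1", "O", (0, 0, 0)),
            ("A", "GLU", 1, "OE2", "O", (2.2, 0, 0)),
        ])
        sel = select_atoms(st, chain="A")
        assert pair_distance(sel, sel) == pytest.approx(2.2)

    def test_empty_selection_raises(self, build_structure):
        st = build_structure([("A", "GLY", 1, "O", "O", (0, 0, 0))])
        with pytest.raises(ValueError, match="selection"):
            pair_distance(select_atoms(st, chain="Z"), select_atoms(st))


class TestBuriedSurfaceArea:
    def test_far_apart_chains_bury_nothing(self, build_structure):
        st = build_structure([
            ("A", "GLY", 1, "CA", "C", (0, 0, 0)),
            ("B", "GLY", 1, "CA", "C", (100.0, 0, 0)),
        ])
        report = interface_bsa(st, "A", "B")
        assert report.buried_area == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_overlap_matches_analytic_caps(self, build_structure):
        # two identical carbons 2 A apart: each loses a spherical cap of
        # area 2*pi*R*h with R = r_vdw + probe and h = R - d/2
        d = 2.0
        st = build_structure([
            ("A", "GLY", 1, "CA", "C", (0, 0, 0)),
            ("B", "GLY", 1, "CA", "C", (d, 0, 0)),
        ])
        R = 1.70 + 1.4
        analytic = 2 * (2 * np.pi * R * (R - d / 2))
        report = interface_bsa(st, "A", "B", sphere_points=4000)
        assert report.buried_area == pytest.approx(analytic, rel=0.02)

    def test_symmetry(self, build_structure):
        atoms = [
            ("A", "GLY", i, "CA", "C", tuple(xyz))
            for i, xyz in enumerate(
                [(0, 0, 0), (1.5, 0, 0), (3.0, 0.5, 0), (0, 1.5, 0.5)], start=1
            )
        ] + [
            ("B", "GLY", i, "CA", "C", tuple(xyz))
            for i, xyz in enumerate(
                [(0, 0, 3.2), (1.5, 0.3, 3.4), (3.0, 0.2, 3.6)], start=1
            )
        ]
        st = build_structure(atoms)
        ab = interface_bsa(st, "A", "B")
        ba = interface_bsa(st, "B", "A")
        assert ab.buried_area == pytest.approx(ba.buried_area, rel=1e-12)
        assert ab.buried_area > 0

    def test_point_count_convergence(self, build_structure):
        atoms = [
            ("A", "GLY", 1, "CA", "C", (0, 0, 0)),
            ("A", "GLY", 1, "CB", "C", (1.5, 0, 0)),
            ("B", "GLY", 1, "CA", "C", (0.7, 0, 3.1)),
            ("B", "GLY", 1, "N", "N", (2.0, 0.5, 3.0)),
        ]
        st = build_structure(atoms)
        coarse = interface_bsa(st, "A", "B", sphere_points=960).buried_area
        fine = interface_bsa(st, "A", "B", sphere_points=4000).buried_area
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_missing_chain_raises(self, build_structure):
        st = build_structure([("A", "GLY", 1, "CA", "C", (0, 0, 0))])
        with pytest.raises(ValueError):
            interface_bsa(st, "A", "Z")

    def test_sasa_isolated_atom_is_full_sphere(self):
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), 1.4, 960)
        assert sasa[0] == pytest.approx(4 * np.pi * 3.1**2, rel=1e-9)


class TestSiteComparison:
    def test_identical_models_no_shifts(self):
        st1, _ = sd.gen_metal_site(seed=5)
        st2, _ = sd.gen_metal_site(seed=5)
        result = site_comparison(st1, st2, [(("A", 200), ("A", 200))])
        assert result["carboxylate_shifts"] == []
        assert result["sites"][0]["delta_cn"] == 0

    def test_single_moved_oxygen_flags_one_shift(self):
        # same geometry except one carboxylate goes bidentate -> monodentate:
        # exactly one shift, coordination number drops by one
        st1, _ = sd.gen_metal_site(
            cn=10, denticity_plan=("bidentate", "bidentate"), seed=8
        )
        st2, _ = sd.gen_metal_site(
            cn=9, denticity_plan=("bidentate", "monodentate"), seed=8
        )
        result = site_comparison(st1, st2, [(("A", 200), ("A", 200))])
        assert len(result["carboxylate_shifts"]) == 1
        shift = result["carboxylate_shifts"][0]
        assert (shift["mode_1"], shift["mode_2"]) == ("bidentate", "monodentate")
        assert result["sites"][0]["delta_cn"] == -1

    def test_unmapped_sites_listed(self):
        st1, _ = sd.gen_metal_site(seed=5)
        st2, _ = sd.gen_metal_site(seed=5)
        result = site_comparison(st1, st2, [])
        assert result["unpaired_1"] == [("A", 200)]
        assert result["unpaired_2"] == [("A", 200)]
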