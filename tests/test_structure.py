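"""SASA, buried interfaces and filament expansion on atomic models."""

import numpy as np
import pytest

from zpfilament.helix import HelicalSymmetry
from zpfilament.structure import (
    SelectionSpec,
    StructureModel,
    VDW_RADII,
    buried_area,
    buried_fraction,
    com_distance,
    expand_filament,
    make_synthetic_subunit_structure,
    read_structure,
    sasa,
)


def atoms(coords, radius=1.7, chain="A", element="C"):
    n = len(coords)
    return StructureModel(
        coords=np.asarray(coords, dtype=float),
        radii=np.full(n, radius),
        chains=np.array([chain] * n),
        resnums=np.arange(1, n + 1),
        elements=np.array([element] * n),
    )


class TestSasa:
    def test_single_sphere_matches_analytic_area(self):
        """Numeric SASA of one atom is 4*pi*(r+probe)^2 within 0.5%."""
        model = atoms([[0.0, 0.0, 0.0]], radius=1.7)
        _, total = sasa(model, probe_radius=1.4, n_points=960)
        analytic = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.005)

    def test_distant_atoms_add_independently(self):
        single = atoms([[0.0, 0.0, 0.0]])
        pair = atoms([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        _, a1 = sasa(single)
        _, a2 = sasa(pair)
        assert a2 == pytest.approx(2 * a1, rel=1e-6)

    def test_caged_atom_is_buried(self):
        """An atom inside a tight shell of neighbors has ~zero SASA."""
        shell = []
        golden = np.pi * (1 + 5 ** 0.5)
        for i in range(60):
            phi = np.arccos(1 - 2 * (i + 0.5) / 60)
            theta = golden * (i + 0.5)
            shell.append([
                3.0 * np.cos(theta) * np.sin(phi),
                3.0 * np.sin(theta) * np.sin(phi),
                3.0 * np.cos(phi),
            ])
        model = atoms([[0.0, 0.0, 0.0]] + shell)
        per_atom, _ = sasa(model, selection=np.arange(61) == 0)
        assert per_atom[0] == pytest.approx(0.0, abs=1.0)

    def test_agrees_with_independent_implementation(self):
        """Per-atom SASA matches biotite's Shrake-Rupley on a small
        cluster with identical radii and probe."""
        import biotite.structure as struc

        model = make_synthetic_subunit_structure(seed=7, n_atoms=30)
        ours, total = sasa(model, probe_radius=1.4, n_points=960)

        arr = struc.AtomArray(len(model))
        arr.coord = model.coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, len(model) + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = struc.sasa(
            arr, probe_radius=1.4, vdw_radii=model.radii.astype(float),
            point_number=960,
        )
        np.testing.assert_allclose(ours, theirs, rtol=0.03, atol=0.5)
        assert total == pytest.approx(float(theirs.sum()), rel=0.01)

    def test_sampling_convergence(self):
        """Total SASA changes by <1% from 256 to 1024 sphere points."""
        model = make_synthetic_subunit_structure(seed=3, n_atoms=80)
        _, coarse = sasa(model, n_points=256)
        _, fine = sasa(model, n_points=1024)
        assert abs(fine - coarse) / fine < 0.01


class TestBuriedArea:
    def test_disjoint_distant_selections_bury_nothing(self):
        model = atoms(
            [[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]],
        )
        res = buried_area(model, np.array([True, False]),
                          np.array([False, True]))
        assert res["two_sided_angstrom2"] == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_selection_order(self):
        model = make_synthetic_subunit_structure(seed=1, n_atoms=60)
        sel_a = np.arange(60) < 30
        ab = buried_area(model, sel_a, ~sel_a)
        ba = buried_area(model, ~sel_a, sel_a)
        assert ab["two_sided_angstrom2"] == pytest.approx(
            ba["two_sided_angstrom2"]
        )

    def test_contacting_spheres_bury_positive_area(self):
        model = atoms([[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]])
        res = buried_area(model, np.array([True, False]),
                          np.array([False, True]))
        assert res["two_sided_angstrom2"] > 10.0
        assert res["one_sided_angstrom2"] == pytest.approx(
            res["two_sided_angstrom2"] / 2
        )

    def test_overlapping_selections_rejected(self):
        model = atoms([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="overlap"):
            buried_area(model, np.array([True, True]),
                        np.array([False, True]))


class TestExpandFilament:
    def test_k_zero_is_identity(self):
        model = make_synthetic_subunit_structure(seed=0)
        ex = expand_filament(model, HelicalSymmetry(62.5, 180), [0])
        np.testing.assert_allclose(ex.coords, model.coords)
        assert list(ex.chains) == list(model.chains)

    def test_five_subunit_expansion_contact_topology(self):
        """Neighbors within |Δk| <= 2 touch; |Δk| > 2 copies do not, and
        no inter-copy clash below 1.5 Å exists."""
        from scipy.spatial import cKDTree

        model = make_synthetic_subunit_structure(seed=0)
        sym = HelicalSymmetry(62.5, 180)
        copies = {
            k: expand_filament(model, sym, [k]).coords for k in range(-3, 4)
        }
        trees = {k: cKDTree(c) for k, c in copies.items()}
        contact = 2 * VDW_RADII["C"] + 2 * 1.4  # vdW + two probe radii
        for dk in (1, 2, 3):
            d = trees[0].query(copies[dk])[0].min()
            if dk <= 2:
                assert d < contact, f"|dk|={dk} should be in contact"
            else:
                assert d > contact, f"|dk|={dk} should be separated"
            assert d > 1.5, "steric clash between symmetry copies"

    def test_chain_suffixes_identify_copies(self):
        model = make_synthetic_subunit_structure(seed=0, n_atoms=10)
        ex = expand_filament(model, HelicalSymmetry(62.5, 180), [-1, 0, 1])
        assert set(ex.chains) == {"A@-1", "A", "A@1"}


class TestBuriedFraction:
    def test_isolated_subunit_has_zero_buried_fraction(self):
        model = make_synthetic_subunit_structure(seed=0)
        ex = expand_filament(model, HelicalSymmetry(62.5, 180), [0])
        assert buried_fraction(ex, "A") == pytest.approx(0.0, abs=1e-9)

    def test_filament_context_buries_part_of_the_surface(self):
        model = make_synthetic_subunit_structure(seed=0)
        ex = expand_filament(model, HelicalSymmetry(62.5, 180), range(-2, 3))
        frac = buried_fraction(ex, "A", n_points=480)
        assert 0.05 < frac < 0.9

    def test_enclosed_sphere_cluster_fully_buried(self):
        golden = np.pi * (1 + 5 ** 0.5)
        shell = []
        for r in (3.0, 5.5):
            for i in range(80):
                phi = np.arccos(1 - 2 * (i + 0.5) / 80)
                theta = golden * (i + 0.5)
                shell.append([
                    r * np.cos(theta) * np.sin(phi),
                    r * np.sin(theta) * np.sin(phi),
                    r * np.cos(phi),
                ])
        n = 1 + len(shell)
        model = StructureModel(
            coords=np.array([[0.0, 0.0, 0.0]] + shell),
            radii=np.full(n, 1.7),
            chains=np.array(["X"] + ["S"] * len(shell)),
            resnums=np.arange(1, n + 1),
            elements=np.array(["C"] * n),
        )
        assert buried_fraction(model, "X") == pytest.approx(1.0, abs=0.02)


class TestComDistance:
    def test_same_selection_zero(self):
        model = make_synthetic_subunit_structure(seed=2, n_atoms=20)
        sel = np.arange(20) < 10
        assert com_distance(model, sel, sel) == 0.0

    def test_two_single_atoms(self):
        model = atoms([[0.0, 0.0, 0.0], [0.0, 3.0, 4.0]])
        assert com_distance(
            model, np.array([True, False]), np.array([False, True])
        ) == pytest.approx(5.0)

    def test_mass_weighting_shifts_center(self):
        model = StructureModel(
            coords=np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]]),
            radii=np.full(3, 1.7),
            chains=np.array(["A", "A", "B"]),
            resnums=np.array([1, 2, 1]),
            elements=np.array(["C", "S", "C"]),
        )
        weighted = com_distance(model, "A", "B", mass_weighted=True)
        unweighted = com_distance(model, "A", "B", mass_weighted=False)
        assert weighted < unweighted  # S outweighs C, pulls A's COM right


class TestSelectionsAndIO:
    def test_selection_parse_ranges_and_whole_chain(self):
        spec = SelectionSpec.parse("A:430-465,B")
        assert spec.ranges == {"A": [(430, 465)], "B": []}

    def test_minimal_pdb_fixture_parses(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1      11.104   6.134  -6.504"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147"
            "  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   2      10.729   6.768  -4.123"
            "  1.00  0.00           C\n"
            "END\n"
        )
        model = read_structure(str(pdb))
        assert len(model) == 3
        assert list(model.elements) == ["N", "C", "C"]
        assert model.radii[0] == VDW_RADII["N"]
        mask = SelectionSpec.parse("A:2-2").mask(model)
        assert mask.sum() == 1

    def test_empty_file_rejected(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_structure(str(empty))
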