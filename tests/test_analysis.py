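"""Structural observables: RMSD, PMF, contacts, helicity, ASA, densities."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcfold.constants import R_GAS
from mcfold.errors import InvalidParameterError, MissingRegionError
from mcfold.analysis import (
    asa,
    centroid_displacement,
    classify_contacts,
    contact_map,
    filter_bound,
    helix_assign,
    helix_content,
    min_rmsd_to_models,
    native_contact_set,
    orientation_inner_product,
    pmf_landscape,
    radial_distribution,
    rmsd_raw,
    rmsd_superposed,
    spatial_density,
)
from mcfold.structure_io import StructureModel
from mcfold.synthetic import SyntheticConfig, build_chain, make_reference_models


def _brute_force_min_rmsd(a, b, seed=0, n_coarse=4000):
    """Independent oracle: rotation search over random quaternions with
    Nelder-Mead refinement, no Kabsch."""
    from scipy.optimize import minimize

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((a - r.apply(b)) ** 2, axis=1)))

    rots = Rotation.random(n_coarse, rng=np.random.default_rng(seed))
    costs = [cost(r.as_rotvec()) for r in rots]
    best = rots[int(np.argmin(costs))].as_rotvec()
    res = minimize(cost, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.fun)


class TestRmsd:
    def test_identical_coordinates(self, rng):
        c = rng.normal(size=(8, 3))
        assert rmsd_superposed(c, c) == pytest.approx(0.0, abs=1e-7)
        assert rmsd_raw(c, c) == 0.0

    def test_superposition_removes_rigid_motion(self, rng):
        c = rng.normal(size=(10, 3))
        moved = Rotation.from_euler("z", 90, degrees=True).apply(c) + np.array([5.0, -2.0, 1.0])
        assert rmsd_superposed(c, moved) == pytest.approx(0.0, abs=1e-7)

    def test_raw_rmsd_of_uniform_translation(self, rng):
        c = rng.normal(size=(6, 3))
        assert rmsd_raw(c, c + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_against_quaternion_search_oracle(self, rng):
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        assert rmsd_superposed(a, b) == pytest.approx(
            _brute_force_min_rmsd(a, b), abs=1e-6
        )

    def test_superposed_never_exceeds_raw(self, rng):
        for _ in range(20):
            a = rng.normal(size=(7, 3))
            b = rng.normal(size=(7, 3))
            assert rmsd_superposed(a, b) <= rmsd_raw(a, b) + 1e-9

    def test_length_mismatch(self, rng):
        with pytest.raises(InvalidParameterError):
            rmsd_raw(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestMinRmsdToModels:
    def test_conformation_equal_to_one_model(self, reference_models):
        conf = reference_models[5]
        assert min_rmsd_to_models(conf, reference_models, "B", (120, 131)) == pytest.approx(
            0.0, abs=1e-7
        )

    def test_equals_explicit_loop_minimum(self, synthetic_ensemble, reference_models):
        from mcfold.structure_io import select_region

        conf = synthetic_ensemble[0][0]
        c = select_region(conf, "B", (134, 145), "CA")
        explicit = min(
            rmsd_superposed(c, select_region(m, "B", (134, 145), "CA"))
            for m in reference_models
        )
        assert min_rmsd_to_models(conf, reference_models, "B", (134, 145)) == pytest.approx(
            explicit
        )

    def test_single_model_degenerate(self, reference_models):
        from mcfold.structure_io import ModelSet, select_region

        conf = reference_models[3]
        single = ModelSet([reference_models[0]])
        expected = rmsd_superposed(
            select_region(conf, "B", (120, 131), "CA"),
            select_region(reference_models[0], "B", (120, 131), "CA"),
        )
        assert min_rmsd_to_models(conf, single, "B", (120, 131)) == pytest.approx(expected)


class TestCentroidDisplacement:
    def test_self_is_zero(self, reference_models):
        m = reference_models[0]
        assert centroid_displacement(m, m, "B", (120, 131)) == 0.0

    def test_pure_translation(self, reference_models):
        m = reference_models[0]
        moved = StructureModel(
            chain_id=m.chain_id.copy(),
            res_id=m.res_id.copy(),
            res_name=m.res_name.copy(),
            atom_name=m.atom_name.copy(),
            element=m.element.copy(),
            coord=m.coord + np.array([0.0, 0.0, 7.0]),
        )
        assert centroid_displacement(moved, m, "B", (120, 131)) == pytest.approx(7.0)

    def test_centroid_is_ca_mean(self, reference_models):
        from mcfold.structure_io import select_region

        m = reference_models[0]
        ref = reference_models[1]
        a = select_region(m, "B", (134, 145), "CA").mean(axis=0)
        b = select_region(ref, "B", (134, 145), "CA").mean(axis=0)
        assert centroid_displacement(m, ref, "B", (134, 145)) == pytest.approx(
            float(np.linalg.norm(a - b))
        )


class TestPmfLandscape:
    def test_single_occupied_bin(self):
        grid = pmf_landscape([(2.1, 3.0)] * 50, T=315.0)
        assert grid.pmf[2, 3] == 0.0
        assert np.isnan(grid.pmf[0, 0])

    def test_count_ratio_sets_free_energy_difference(self):
        """Counts N and N/e differ by exactly RT = 0.626 kcal/mol at 315 K."""
        n = 1000
        ne = int(round(n / np.e))
        values = [(0.0, 0.0)] * n + [(1.0, 0.0)] * ne
        grid = pmf_landscape(values, T=315.0)
        expected = -R_GAS * 315.0 * np.log(ne / n)
        assert grid.pmf[1, 0] - grid.pmf[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.626, abs=2e-3)

    def test_minimum_is_exactly_zero_and_probabilities_reproduce_counts(self, rng):
        values = rng.uniform(0, 8, size=(500, 2))
        grid = pmf_landscape(values, T=315.0)
        assert np.nanmin(grid.pmf) == 0.0
        occ = grid.counts > 0
        p = grid.occupied_probabilities()
        assert np.allclose(p[occ], grid.counts[occ] / grid.total, atol=1e-12)

    def test_planted_bimodal_modes(self, synthetic_ensemble, reference_models, synth_config):
        from mcfold.synthetic import planted_truth

        ens, truth = synthetic_ensemble
        ref = reference_models[0]
        poses = np.array(truth["pose"])
        R = np.array(
            [
                (
                    centroid_displacement(c, ref, "B", (120, 131)),
                    centroid_displacement(c, ref, "B", (134, 145)),
                )
                for c in ens
            ]
        )
        bound = filter_bound(R)
        grid = pmf_landscape(R[bound], T=315.0)
        tr = planted_truth(synth_config)
        tol = tr["pmf_mode_tolerance"]
        minima = np.array(grid.minima_locations(depth=0.7))
        for mode in tr["pmf_modes"]:
            d = np.linalg.norm(minima - np.asarray(mode), axis=1)
            assert d.min() <= tol, f"no PMF minimum near planted mode {mode}"


class TestOrientation:
    def test_self_is_one(self, reference_models):
        m = reference_models[0]
        assert orientation_inner_product(m, m, "B", (134, 141)) == pytest.approx(1.0)

    def test_reversed_vector(self, reference_models):
        m = reference_models[0]
        flipped = StructureModel(
            chain_id=m.chain_id.copy(),
            res_id=m.res_id.copy(),
            res_name=m.res_name.copy(),
            atom_name=m.atom_name.copy(),
            element=m.element.copy(),
            coord=-m.coord,  # inversion reverses every vector
        )
        assert orientation_inner_product(flipped, m, "B", (134, 141)) == pytest.approx(-1.0)

    def test_right_angle(self, reference_models):
        m = reference_models[0]
        a = m.atom_coord("B", 134, "CA")
        v = m.atom_coord("B", 141, "CA") - a
        axis = np.cross(v, [0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(np.pi / 2 * axis / np.linalg.norm(axis))
        turned = StructureModel(
            chain_id=m.chain_id.copy(),
            res_id=m.res_id.copy(),
            res_name=m.res_name.copy(),
            atom_name=m.atom_name.copy(),
            element=m.element.copy(),
            coord=rot.apply(m.coord - a) + a,
        )
        assert orientation_inner_product(turned, m, "B", (134, 141)) == pytest.approx(
            0.0, abs=1e-12
        )


class TestContacts:
    def _two_residue_model(self, distance):
        return StructureModel(
            chain_id=np.array(["A", "A", "B", "B"]),
            res_id=np.array([1, 1, 10, 10]),
            res_name=np.array(["ALA"] * 4),
            atom_name=np.array(["CA", "CB", "CA", "CB"]),
            element=np.array(["C"] * 4),
            coord=np.array(
                [[0, 0, 0], [1, 0, 0], [distance + 1, 5, 0], [1 + distance, 0, 0]],
                dtype=float,
            ),
        )

    def test_cutoff_is_strict(self):
        assert contact_map(self._two_residue_model(6.5), "A", "B") == set()
        assert contact_map(self._two_residue_model(6.49), "A", "B") == {(1, 10)}

    def test_symmetry_under_chain_swap(self, synthetic_ensemble):
        conf = synthetic_ensemble[0][2]
        ab = contact_map(conf, "B", "A")
        ba = contact_map(conf, "A", "B")
        assert ab == {(y, x) for x, y in ba}

    def test_support_threshold_semantics(self):
        """A pair formed in exactly 8 of 17 models is native; 7 is not."""
        cfg = SyntheticConfig(
            n_conformations=1,
            seed=5,
            support={(121, 14): 8, (124, 14): 7},
        )
        refs = make_reference_models(cfg)
        nset = native_contact_set(refs, "B", "A")
        assert (121, 14) in nset.pairs
        assert (124, 14) not in nset.pairs
        assert nset.support[(121, 14)] == 8

    def test_single_model_threshold_one(self, reference_models):
        from mcfold.structure_io import ModelSet

        single = ModelSet([reference_models[0]])
        nset = native_contact_set(single, "B", "A", support_threshold=1)
        assert nset.pairs == frozenset(contact_map(reference_models[0], "B", "A"))

    def test_classification_against_generator_truth(
        self, synthetic_ensemble, reference_models, synth_config
    ):
        ens, truth = synthetic_ensemble
        nset = native_contact_set(reference_models, "B", "A")
        expected = {
            "native": (len(synth_config.native_pairs), 0),
            "misoriented": (0, len(synth_config.nonnative_pairs)),
            "unbound": (0, 0),
        }
        for conf, pose in zip(ens, truth["pose"]):
            assert classify_contacts(conf, nset, "B", "A") == expected[pose]

    def test_contact_map_matches_direct_enumeration(self, synthetic_ensemble):
        ens, truth = synthetic_ensemble
        for conf, contacts in list(zip(ens, truth["contacts"]))[:50]:
            assert sorted(contact_map(conf, "B", "A")) == contacts


class TestHelixAssign:
    def test_ideal_helix_interior(self):
        m = build_chain(np.full(12, -57.0), np.full(12, -47.0), "A", 1)
        flags = helix_assign(m, "A")
        assert all(flags[r] for r in range(3, 11))
        assert sum(flags.values()) >= 8

    def test_extended_chain_has_no_helix(self):
        m = build_chain(np.full(12, -140.0), np.full(12, 145.0), "A", 1)
        assert not any(helix_assign(m, "A").values())

    def test_agreement_with_dssp_reference(self, synthetic_ensemble, tmp_path):
        """>= 95% per-residue agreement with mdtraj's DSSP on mixed
        helix/coil conformations."""
        mdtraj = pytest.importorskip("mdtraj")
        from mcfold.structure_io import ModelSet, write_models

        ens, _ = synthetic_ensemble
        subset = ens[:30]
        path = tmp_path / "subset.pdb"
        write_models(ModelSet(subset), path)
        traj = mdtraj.load(str(path))
        dssp = mdtraj.compute_dssp(traj, simplified=False)
        lig = [
            (r.index, r.resSeq)
            for r in traj.topology.residues
            if r.chain.index == 1
        ]
        agree = total = 0
        for f, conf in enumerate(subset):
            mine = helix_assign(conf, "B")
            for idx, resseq in lig:
                agree += (dssp[f, idx] == "H") == mine[resseq]
                total += 1
        assert agree / total >= 0.95

    def test_missing_backbone_is_error(self):
        m = StructureModel(
            chain_id=np.array(["A", "A"]),
            res_id=np.array([1, 1]),
            res_name=np.array(["ALA", "ALA"]),
            atom_name=np.array(["N", "CA"]),
            element=np.array(["N", "C"]),
            coord=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
        )
        with pytest.raises(MissingRegionError):
            helix_assign(m, "A")


class TestHelixContent:
    def test_all_helical_ensemble(self):
        m = build_chain(np.full(12, -57.0), np.full(12, -47.0), "A", 1)
        content = helix_content([m] * 5, "A", (4, 9))
        assert np.allclose(content.to_numpy(), 1.0)

    def test_counting_mixture(self):
        helical = build_chain(np.full(12, -57.0), np.full(12, -47.0), "A", 1)
        coil = build_chain(np.full(12, -140.0), np.full(12, 145.0), "A", 1)
        content = helix_content([helical] * 3 + [coil] * 7, "A", (4, 9))
        assert np.allclose(content.to_numpy(), 0.3)

    def test_bounded_in_unit_interval(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        content = helix_content(ens[:60], "B", (121, 144))
        assert (content >= 0).all() and (content <= 1).all()


class TestAsa:
    def _atom(self, name, element, xyz, res=1):
        return dict(name=name, element=element, xyz=xyz, res=res)

    def _model(self, atoms):
        return StructureModel(
            chain_id=np.array(["A"] * len(atoms)),
            res_id=np.array([a["res"] for a in atoms]),
            res_name=np.array(["ALA"] * len(atoms)),
            atom_name=np.array([a["name"] for a in atoms]),
            element=np.array([a["element"] for a in atoms]),
            coord=np.array([a["xyz"] for a in atoms], dtype=float),
        )

    def test_isolated_atom_sphere_area(self):
        m = self._model([self._atom("O", "O", (0.0, 0.0, 0.0))])
        expected = 4 * np.pi * (1.52 + 1.4) ** 2
        assert asa(m) == pytest.approx(expected, rel=0.005)

    def test_coincident_atoms_bury_symmetrically(self):
        one = self._model([self._atom("O", "O", (0.0, 0.0, 0.0))])
        two = self._model(
            [
                self._atom("O", "O", (0.0, 0.0, 0.0)),
                self._atom("O2", "O", (0.0, 0.0, 0.0), res=2),
            ]
        )
        assert asa(two) == pytest.approx(asa(one), rel=0.01)

    def test_two_sphere_overlap_against_spherical_caps(self):
        """Partial overlap vs the closed-form cap areas of two extended
        spheres R1, R2 at centre distance d: each sphere loses a cap of
        area 2 pi R h with h = R - (d^2 + R^2 - R'^2) / (2 d)."""
        d = 2.0
        m = self._model(
            [
                self._atom("O", "O", (0.0, 0.0, 0.0)),
                self._atom("N", "N", (d, 0.0, 0.0), res=2),
            ]
        )
        r1 = 1.52 + 1.4
        r2 = 1.55 + 1.4
        h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
        h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
        expected = (4 * np.pi * r1**2 - 2 * np.pi * r1 * h1) + (
            4 * np.pi * r2**2 - 2 * np.pi * r2 * h2
        )
        assert asa(m) == pytest.approx(expected, rel=0.02)

    def test_occlusion_monotonicity(self, reference_models, synthetic_ensemble):
        """Region ASA in the complex never exceeds the ligand-only ASA."""
        m = reference_models[0]
        lig_mask = m.chain_id == "B"
        lig_only = StructureModel(
            chain_id=m.chain_id[lig_mask],
            res_id=m.res_id[lig_mask],
            res_name=m.res_name[lig_mask],
            atom_name=m.atom_name[lig_mask],
            element=m.element[lig_mask],
            coord=m.coord[lig_mask],
        )
        assert asa(m, "B", (134, 145)) <= asa(lig_only, "B", (134, 145)) + 1e-6

    def test_unknown_element(self):
        m = self._model([self._atom("X", "XX", (0.0, 0.0, 0.0))])
        with pytest.raises(InvalidParameterError, match="XX"):
            asa(m)


class TestDensities:
    def test_radial_all_mass_at_reference(self):
        pts = np.zeros((40, 3))
        centers, density = radial_distribution(pts, np.zeros(3), binwidth=0.5)
        assert density[0] * 0.5 == pytest.approx(1.0)

    def test_radial_integrates_to_one(self, rng):
        pts = rng.normal(scale=3.0, size=(500, 3))
        centers, density = radial_distribution(pts, np.zeros(3), binwidth=0.25)
        assert np.sum(density) * 0.25 == pytest.approx(1.0, abs=1e-12)

    def test_radial_shell_sample(self, rng):
        u = rng.normal(size=(400, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # radius at a bin centre, so the whole shell falls in one bin
        centers, density = radial_distribution(5.5 * u, np.zeros(3), binwidth=1.0)
        assert centers[5] == pytest.approx(5.5)
        assert density[5] * 1.0 == pytest.approx(1.0)

    def test_voxel_density_units(self):
        pts = np.tile([[0.2, 0.3, 0.4]], (25, 1))
        vox = spatial_density(pts, spacing=1.0)
        assert vox.density.max() == pytest.approx(1.0)

    def test_voxel_mass_conservation(self, rng):
        pts = rng.normal(scale=2.0, size=(300, 3))
        vox = spatial_density(pts, spacing=1.0)
        assert vox.density.sum() * 1.0 == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_cloud_peak_at_mean(self, rng):
        pts = rng.normal(loc=5.0, scale=2.0, size=(20_000, 3))
        vox = spatial_density(pts, spacing=1.0)
        assert np.linalg.norm(vox.peak_position() - 5.0) < 2.0


class TestFilterBound:
    def test_inclusive_bounds(self):
        idx = filter_bound([(13.0, 7.0), (13.01, 7.0), (13.0, 7.01)])
        assert list(idx) == [0]

    def test_recovers_planted_bound_fraction(
        self, synthetic_ensemble, reference_models, synth_config
    ):
        from mcfold.synthetic import planted_truth

        ens, truth = synthetic_ensemble
        ref = reference_models[0]
        R = [
            (
                centroid_displacement(c, ref, "B", (120, 131)),
                centroid_displacement(c, ref, "B", (134, 145)),
            )
            for c in ens
        ]
        idx = filter_bound(R)
        poses = np.array(truth["pose"])
        n_bound_true = int(np.sum(poses != "unbound"))
        assert len(idx) == n_bound_true
        tr = planted_truth(synth_config)
        f = tr["expected_bound_fraction"]
        sigma = np.sqrt(f * (1 - f) / len(ens))
        assert abs(len(idx) / len(ens) - f) < 3 * sigma
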