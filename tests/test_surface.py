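import math

import numpy as np
import pytest

from calsteer import surface, synthetic
from calsteer.structure_io import AtomSite, StructureEnsemble, select
from conftest import random_rotation


def _atoms(element_positions):
    atoms, xyz = [], []
    for i, (el, pos) in enumerate(element_positions, start=1):
        atoms.append(AtomSite("A", i, "ALA", el, el))
        xyz.append(pos)
    return StructureEnsemble(atoms=atoms, coords=np.array([xyz], float),
                             chain_map={"A": "A"})


class TestShrakeRupley:
    def test_isolated_atom_area_is_analytic_sphere(self):
        ens = _atoms([("O", [0, 0, 0])])
        res = surface.shrake_rupley(ens)
        assert res.total == pytest.approx(4 * math.pi * 2.8 ** 2, rel=1e-12)

    def test_distant_atoms_unoccluded(self):
        ens = _atoms([("O", [0, 0, 0]), ("O", [20, 0, 0])])
        res = surface.shrake_rupley(ens)
        assert np.allclose(res.areas, 4 * math.pi * 2.8 ** 2)

    def test_two_spheres_in_contact_match_cap_formula(self):
        # analytic: each sphere of extended radius r loses a cap of height r - d/2
        r, d = 2.8, 2.8
        ens = _atoms([("O", [0, 0, 0]), ("O", [d, 0, 0])])
        res = surface.shrake_rupley(ens, n_points=3840)
        analytic = 4 * math.pi * r ** 2 - 2 * math.pi * r * (r - d / 2)
        assert res.areas[0] == pytest.approx(analytic, rel=0.01)
        assert res.areas[1] == pytest.approx(analytic, rel=0.01)

    def test_quadrature_convergence_under_one_percent(self, helix20):
        a = surface.shrake_rupley(helix20, n_points=960).total
        b = surface.shrake_rupley(helix20, n_points=3840).total
        assert abs(a - b) / b < 0.01

    def test_unknown_element_listed_in_error(self):
        ens = _atoms([("X", [0, 0, 0])])
        with pytest.raises(surface.SurfaceError, match="X"):
            surface.shrake_rupley(ens)

    def test_hydrogens_ignored_by_default(self, ideal_helix):
        res = surface.shrake_rupley(ideal_helix)
        elements = {ideal_helix.atoms[int(i)].element for i in res.atom_indices}
        assert "H" not in elements


class TestSurfacePoints:
    def test_isolated_atom_keeps_all_points(self):
        ens = _atoms([("O", [0, 0, 0])])
        sp = surface.surface_points(ens, n_points=240)
        assert len(sp.points) == 240
        assert sp.total_area == pytest.approx(4 * math.pi * 2.8 ** 2, rel=1e-12)

    def test_point_area_sums_to_sasa(self, helix20):
        sp = surface.surface_points(helix20, n_points=960)
        sasa = surface.shrake_rupley(helix20, n_points=960)
        assert sp.total_area == pytest.approx(sasa.total, rel=1e-9)


class TestBuriedSurface:
    def test_distant_entities_bury_nothing(self):
        far = synthetic.build_two_helix(synthetic.HelixSpec(8), synthetic.HelixSpec(8),
                                        0.0, 60.0)
        res = surface.buried_surface(far, "A", "B", models=[0])
        assert res["bsa_total"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_entity_labels(self, dimer):
        r1 = surface.buried_surface(dimer, "A", "B", models=[0])
        r2 = surface.buried_surface(dimer, "B", "A", models=[0])
        assert r1["bsa_total"] == pytest.approx(r2["bsa_total"], abs=1e-9)

    def test_matches_independent_sasa_recomputation(self, dimer):
        res = surface.buried_surface(dimer, "A", "B", models=[0])
        ia = select(dimer, "A")
        ib = select(dimer, "B")
        # brute-force oracle: rebuild three separate ensembles and re-run SASA
        sub_a, sub_b = dimer.subset(ia), dimer.subset(ib)
        sa = surface.shrake_rupley(sub_a).total
        sb = surface.shrake_rupley(sub_b).total
        sc = surface.shrake_rupley(dimer).total
        assert res["bsa_total"] == pytest.approx(sa + sb - sc, abs=1e-9)

    def test_overlapping_selections_rejected(self, dimer):
        with pytest.raises(surface.SurfaceError):
            surface.buried_surface(dimer, "A:1-10", "A:5-20")

    def test_per_entity_losses_sum_to_total(self, dimer):
        res = surface.buried_surface(dimer, "A", "B", models=[0])
        assert res["per_entity"]["A"] + res["per_entity"]["B"] == pytest.approx(
            res["bsa_total"], abs=1e-9)


class TestFractionBuried:
    def test_interface_residue_loses_most_surface(self, dimer):
        # pick the chain-B residue whose side chain loses the most area
        res = surface.buried_surface(dimer, "A", "B", models=[0])
        b_res = {r: a for (c, r), a in res["per_residue"].items() if c == "B"}
        target = max(b_res, key=b_res.get)
        frac = surface.fraction_buried(dimer, [f"B:{target}:sidechain"], "B", models=[0])
        assert frac["group_mean"] > 0.2

    def test_exposed_residue_fraction_near_zero(self, dimer):
        far_res = 1  # chain B N-terminus points away from the interface
        frac = surface.fraction_buried(dimer, [f"B:{far_res}:sidechain"], "B", models=[0])
        assert frac["group_mean"] < 0.1


class TestESP:
    def test_unit_charge_at_bjerrum_length_gives_one_kT_per_e(self):
        ens = _atoms([("N", [0, 0, 0])])
        q = np.array([1.0])
        sp = surface.esp_potential(ens, charges=q,
                                   eval_points=np.array([[7.135, 0.0, 0.0]]),
                                   ionic_strength=0.0)
        assert sp.phi[0] == pytest.approx(1.0, abs=0.01)

    def test_symmetric_dipole_midplane_is_zero(self):
        ens = _atoms([("N", [-3, 0, 0]), ("O", [3, 0, 0])])
        sp = surface.esp_potential(ens, charges=np.array([1.0, -1.0]),
                                   eval_points=np.array([[0, 5.0, 0]]),
                                   ionic_strength=0.1)
        assert sp.phi[0] == pytest.approx(0.0, abs=1e-12)

    def test_debye_length_at_physiological_salt(self):
        assert 1.0 / surface.debye_kappa(0.1) == pytest.approx(9.6, abs=0.1)

    def test_potential_linear_in_charges(self, helix20):
        idx = helix20.atom_index()
        q = np.zeros(helix20.n_atoms)
        q[idx[("A", 5, "CB")]] = -1.0
        q[idx[("A", 9, "CB")]] = -1.0
        sp1 = surface.esp_potential(helix20, charges=q, n_points=120)
        sp2 = surface.esp_potential(helix20, charges=2 * q, n_points=120)
        assert np.allclose(sp2.phi, 2 * sp1.phi)

    def test_near_charge_points_clamped_and_flagged(self):
        ens = _atoms([("N", [0, 0, 0])])
        sp = surface.esp_potential(ens, charges=np.array([1.0]),
                                   eval_points=np.array([[0.1, 0, 0]]),
                                   ionic_strength=0.0)
        assert sp.clamped[0]
        assert np.isfinite(sp.phi[0])

    def test_formal_charge_model(self, helix20):
        q = surface.formal_charges(helix20)
        # poly-Ala backbone: only the termini carry charge
        assert q.sum() == pytest.approx(0.0)
        assert (q != 0).sum() == 2


class TestBasins:
    @staticmethod
    def _charged_helix(face_residues, n_res=24):
        h = synthetic.build_helix(synthetic.HelixSpec(n_res=n_res))
        idx = h.atom_index()
        q = np.zeros(h.n_atoms)
        for r in face_residues:
            q[idx[("A", r, "CB")]] = -1.0
        return h, q, idx

    def test_single_charge_cluster_gives_one_basin_at_centroid(self):
        h, q, idx = self._charged_helix([8, 11, 15])
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        rep = surface.find_basins(sp, threshold=-1.0, link_distance=2.0)
        assert len(rep) == 1
        centroid_q = np.mean([h.coords[0, idx[("A", r, "CB")]] for r in (8, 11, 15)], axis=0)
        assert np.linalg.norm(rep.basins[0].centroid - centroid_q) < 3.0

    def test_threshold_above_all_potentials_gives_empty_report(self):
        h, q, _ = self._charged_helix([8])
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        rep = surface.find_basins(sp, threshold=-50.0)
        assert len(rep) == 0

    def test_two_distant_clusters_give_two_basins(self):
        h, q, idx = self._charged_helix([4, 7], n_res=40)
        for r in (33, 36):
            q[idx[("A", r, "CB")]] = -1.0
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        rep = surface.find_basins(sp, threshold=-1.0, link_distance=2.0)
        assert len(rep) == 2

    def test_target_distance_reported(self):
        h, q, idx = self._charged_helix([8, 11, 15])
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        target = h.coords[0, idx[("A", 11, "CB")]]
        rep = surface.find_basins(sp, threshold=-1.0, target_point=target)
        assert rep.basins[0].min_dist_to_target < 4.0

    def test_invariant_under_rigid_motion(self):
        h, q, _ = self._charged_helix([8, 11, 15])
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        rep = surface.find_basins(sp, threshold=-1.0)
        rng = np.random.default_rng(4)
        moved = h.transformed(random_rotation(rng), np.array([3.0, -8.0, 11.0]))
        rep2 = surface.find_basins(
            surface.esp_potential(moved, charges=q, ionic_strength=0.1), threshold=-1.0)
        assert len(rep) == len(rep2)
        assert rep.basins[0].area == pytest.approx(rep2.basins[0].area, rel=0.02)

    def test_positive_threshold_rejected(self):
        h, q, _ = self._charged_helix([8])
        sp = surface.esp_potential(h, charges=q, ionic_strength=0.1)
        with pytest.raises(surface.SurfaceError):
            surface.find_basins(sp, threshold=0.5)


class TestCompareESP:
    def test_identical_structures_give_zero_delta(self, helix20):
        out = surface.compare_esp(helix20, helix20, "A:5-10", n_points=120)
        assert out["delta"] == pytest.approx(0.0, abs=1e-12)

    def test_adding_acidic_charges_lowers_region_potential(self, dimer):
        # chain B with increasing numbers of acidic side-chain charges near chain A
        idx = dimer.atom_index()
        means = []
        for n_acidic in (0, 2, 4):
            q = np.zeros(dimer.n_atoms)
            for r in list(range(4, 4 + n_acidic)):
                q[idx[("B", r, "CB")]] = -1.0
            sp = surface.esp_potential(dimer, charges=q, n_points=120)
            region = set(int(i) for i in select(dimer, "A:1-10"))
            member = np.isin(sp.owner_atom, list(region))
            w = sp.point_area[member]
            means.append(float(np.sum(sp.phi[member] * w) / w.sum()))
        assert means[0] > means[1] > means[2]
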