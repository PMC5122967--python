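import numpy as np
import pytest

from calsteer import restraints as rst
from calsteer import synthetic
from calsteer.structure_io import AtomSite, StructureEnsemble


class TestParsing:
    def test_native_tsv(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "#chainA\tresA\tatomA\tchainB\tresB\tatomB\tlower\tupper\n"
            "A\t5\tH\tA\t6\tH\t1.8\t3.3\n"
            "A\t5\tHB2|HB3\tA\t9\tH\t1.8\t5.0\n"
            "A\t2\tH\tB\t7\tH\t1.8\t4.2\tnoe\n")
        rlist, rejected = rst.parse_restraints(p, "native_tsv")
        assert len(rlist) == 3 and rejected == []
        assert rlist[1].group_a == (("A", 5, "HB2"), ("A", 5, "HB3"))

    def test_xplor_assign_bounds_arithmetic(self, tmp_path):
        p = tmp_path / "r.tbl"
        p.write_text(
            "assign (segid A and resid 5 and name HN)\n"
            "       (segid A and resid 9 and name HA) 3.0 1.2 0.5\n")
        rlist, rejected = rst.parse_restraints(p, "xplor_assign")
        assert rejected == []
        (r,) = rlist
        assert (r.lower, r.upper) == (pytest.approx(1.8), pytest.approx(3.5))

    def test_xplor_or_ambiguity(self, tmp_path):
        p = tmp_path / "r.tbl"
        p.write_text(
            "assign (segid A and resid 5 and name HB2 or segid A and resid 5 and name HB3)\n"
            "       (segid B and resid 9 and name HN) 4.0 2.2 1.0\n")
        rlist, _ = rst.parse_restraints(p, "xplor_assign")
        assert len(rlist[0].group_a) == 2

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tbl"
        p.write_text("")
        with pytest.raises(rst.RestraintError):
            rst.parse_restraints(p, "native_tsv")

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("A 1 H A 2 H 1.8 3.0\n")
        with pytest.raises(rst.RestraintError):
            rst.parse_restraints(p, "cyana")

    def test_bad_lines_collected_not_dropped_silently(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("A\t5\tH\tA\t6\tH\t1.8\t3.3\nA\t5\tH\n")
        rlist, rejected = rst.parse_restraints(p, "native_tsv")
        assert len(rlist) == 1 and len(rejected) == 1

    def test_round_trip_through_tsv(self, tmp_path, ideal_helix):
        noe = synthetic.gen_noe_restraints(ideal_helix, cutoff=5.0)
        p = rst.write_restraints_tsv(noe, tmp_path / "noe.tsv")
        back, rejected = rst.parse_restraints(p, "native_tsv")
        assert rejected == []
        assert [(r.group_a, r.group_b) for r in back] == \
               [(r.group_a, r.group_b) for r in noe]


def _r(ca, ra, aa, cb, rb, ab, lo=1.8, hi=5.0, source="noe"):
    ga = tuple((ca, ra, n) for n in aa.split("|"))
    gb = tuple((cb, rb, n) for n in ab.split("|"))
    return rst.DistanceRestraint(ga, gb, lo, hi, source)


class TestCategorize:
    def test_sequence_separation_rules(self):
        counts = rst.categorize([
            _r("A", 5, "H", "A", 5, "HA"),    # |i-j| = 0
            _r("A", 5, "H", "A", 6, "H"),     # |i-j| = 1
            _r("A", 5, "H", "A", 9, "H"),     # |i-j| = 4 -> medium
            _r("A", 5, "H", "A", 10, "H"),    # |i-j| = 5 -> long
            _r("A", 5, "H", "B", 5, "H"),     # cross-chain
            _r("A", 5, "HB2|HB3", "A", 9, "H"),  # multi-atom, single residue each
        ])
        assert counts["intraresidue"] == 1
        assert counts["sequential"] == 1
        assert counts["medium"] == 2   # the OR-ambiguous pair is still |i-j|=4
        assert counts["long"] == 1
        assert counts["intermolecular"] == 1
        assert counts["ambiguous"] == 0
        assert counts["ambiguous_or_groups"] == 1

    def test_multi_residue_side_is_ambiguous(self):
        r = rst.DistanceRestraint((("A", 5, "H"), ("A", 7, "H")), (("A", 20, "H"),),
                                  1.8, 6.0)
        assert rst.categorize([r])["ambiguous"] == 1

    def test_intermolecular_takes_precedence(self):
        r = rst.DistanceRestraint((("A", 5, "H"), ("A", 7, "H")), (("B", 5, "H"),),
                                  1.8, 6.0)
        counts = rst.categorize([r])
        assert counts["intermolecular"] == 1 and counts["ambiguous"] == 0

    def test_hbond_source_tag(self):
        counts = rst.categorize([_r("A", 5, "N", "A", 9, "O", source="hbond")])
        assert counts["hbond"] == 1

    def test_counts_sum_to_total(self, dimer):
        noe = synthetic.gen_noe_restraints(dimer, cutoff=5.0)
        counts = rst.categorize(noe)
        assert sum(counts[c] for c in rst.CATEGORIES) == len(noe)


class TestViolations:
    @staticmethod
    def _pair(distance):
        atoms = [AtomSite("A", 1, "ALA", "H", "H"), AtomSite("A", 5, "ALA", "H", "H")]
        coords = np.array([[[0, 0, 0], [distance, 0, 0]]], float)
        return StructureEnsemble(atoms=atoms, coords=coords)

    def test_simple_upper_bound_violation(self):
        ens = self._pair(4.0)
        r = _r("A", 1, "H", "A", 5, "H", lo=1.8, hi=3.5)
        stats = rst.violations(ens, [r])
        assert stats.mean == pytest.approx(0.5)
        assert stats.max == pytest.approx(0.5)

    def test_lower_bound_violation(self):
        ens = self._pair(1.0)
        r = _r("A", 1, "H", "A", 5, "H", lo=1.8, hi=3.5)
        assert rst.violations(ens, [r]).mean == pytest.approx(0.8)

    def test_ambiguous_r6_sum_dominated_by_close_atom(self):
        atoms = [AtomSite("A", 1, "ALA", "HB2", "H"),
                 AtomSite("A", 1, "ALA", "HB3", "H"),
                 AtomSite("A", 5, "ALA", "H", "H")]
        coords = np.array([[[0, 0, 0], [27.0, 0, 0], [3.0, 0, 0]]], float)
        ens = StructureEnsemble(atoms=atoms, coords=coords)
        r = _r("A", 1, "HB2|HB3", "A", 5, "H", lo=1.8, hi=3.5)
        stats = rst.violations(ens, [r])
        # r_eff = (3^-6 + 24^-6)^(-1/6) ~ 3.0 -> no violation
        assert stats.mean == pytest.approx(0.0)

    def test_unresolvable_restraint_excluded_and_counted(self, ideal_helix):
        noe = synthetic.gen_noe_restraints(ideal_helix, cutoff=4.0)
        ghost = _r("Z", 99, "H", "Z", 100, "H")
        stats = rst.violations(ideal_helix, noe + [ghost])
        assert stats.n_excluded == 1
        assert stats.mean == 0.0

    def test_violations_are_nonnegative(self, jittered_ensemble, dimer):
        noe = synthetic.gen_noe_restraints(dimer, cutoff=5.0)
        stats = rst.violations(jittered_ensemble, noe)
        assert (stats.per_restraint_mean >= 0).all()
        assert stats.mean_violated_only >= stats.mean


class TestSaupe:
    def test_construction_from_da_and_rhombicity_round_trips(self):
        t = rst.SaupeTensor.from_da_rhombicity(12.0, 0.4)
        assert t.da == pytest.approx(12.0)
        assert t.rhombicity == pytest.approx(0.4)

    def test_axially_symmetric_tensor_has_zero_rhombicity(self):
        t = rst.SaupeTensor.from_da_rhombicity(8.0, 0.0)
        assert t.rhombicity == pytest.approx(0.0)

    def test_maximal_rhombicity(self):
        t = rst.SaupeTensor.from_da_rhombicity(8.0, 2.0 / 3.0)
        assert t.rhombicity == pytest.approx(2.0 / 3.0)

    def test_rotation_leaves_da_and_r_invariant(self):
        from conftest import random_rotation
        R = random_rotation(np.random.default_rng(2))
        t = rst.SaupeTensor.from_da_rhombicity(8.0, 0.3, rotation=R)
        assert t.da == pytest.approx(8.0)
        assert t.rhombicity == pytest.approx(0.3)

    def test_parallel_vectors_under_determined(self):
        atoms, coords = [], []
        for i in range(1, 8):
            atoms += [AtomSite("A", i, "ALA", "N", "N"), AtomSite("A", i, "ALA", "H", "H")]
            coords += [[3.0 * i, 0, 0], [3.0 * i, 1.0, 0]]  # all N->H along +y
        ens = StructureEnsemble(atoms=atoms, coords=np.array([coords], float))
        records = [rst.RDCRecord("A", i, 1.0) for i in range(1, 8)]
        with pytest.raises(rst.RestraintError):
            rst.fit_saupe(ens, records)

    def test_too_few_vectors_rejected(self, helix20):
        records = [rst.RDCRecord("A", i, 1.0) for i in (2, 3, 4)]
        with pytest.raises(rst.RestraintError, match="5"):
            rst.fit_saupe(helix20, records)

    def test_fit_backcalc_fit_is_a_fixed_point(self, helix20):
        t = rst.SaupeTensor.from_da_rhombicity(8.0, 0.3)
        rdc = synthetic.gen_rdc(helix20, t)
        fit1, _ = rst.fit_saupe(helix20, rdc)
        d_back = rst.backcalc_rdc(helix20, fit1, rdc)
        rdc2 = [rst.RDCRecord(r.chain_id, r.res_seq, float(d))
                for r, d in zip(rdc, d_back)]
        fit2, _ = rst.fit_saupe(helix20, rdc2)
        assert np.allclose(fit1.matrix, fit2.matrix, atol=1e-10)

    def test_noise_scales_element_errors_linearly(self, helix20):
        t = rst.SaupeTensor.from_da_rhombicity(8.0, 0.3)
        errs = []
        for sd in (0.05, 0.5):
            reps = []
            for seed in range(20):
                rdc = synthetic.gen_rdc(helix20, t, noise_sd=sd, seed=seed)
                fit, _ = rst.fit_saupe(helix20, rdc)
                reps.append(np.abs(fit.matrix - t.matrix).max())
            errs.append(np.mean(reps))
        assert errs[1] / errs[0] == pytest.approx(10.0, rel=0.4)


class TestQFactor:
    def test_exact_agreement_is_zero(self):
        d = np.array([1.0, -2.0, 3.0])
        assert rst.q_factor(d, d) == 0.0

    def test_zero_prediction_gives_one(self):
        d = np.array([1.0, -2.0, 3.0])
        assert rst.q_factor(d, np.zeros(3)) == pytest.approx(1.0)

    def test_all_zero_observed_undefined(self):
        with pytest.raises(rst.RestraintError):
            rst.q_factor(np.zeros(3), np.ones(3))
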