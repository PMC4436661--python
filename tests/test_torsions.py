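"""Dihedral geometry, pseudorotation, and MCQ."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnassess import (
    build_correspondence,
    build_helix,
    circular_diff,
    compute_torsions,
    dihedral,
    mcq_global,
    mcq_local,
    perturb,
)
from rnassess.fixtures import PerturbationSpec
from rnassess.torsions import ANGLE_NAMES, TorsionTable
from tests.conftest import random_rigid_motion


class TestDihedral:
    def test_planar_trans_chain_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_chain_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_90_degree_twist(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1]) == pytest.approx(90.0, abs=1e-9)

    def test_degenerate_geometry_is_undefined(self):
        assert dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]) is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_agrees_with_biopython_oracle(self, seed):
        from Bio.PDB.vectors import Vector, calc_dihedral

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        ours = dihedral(*pts)
        if ours is None:
            return
        theirs = math.degrees(calc_dihedral(*(Vector(*p) for p in pts)))
        assert circular_diff(ours, theirs) < 1e-6


class TestCircularDiff:
    @pytest.mark.parametrize("t1,t2,expected", [(350, 10, 20), (0, 180, 180), (-170, 170, 20)])
    def test_truth_table(self, t1, t2, expected):
        assert circular_diff(t1, t2) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(t1=st.floats(-720, 720), t2=st.floats(-720, 720))
    def test_range_and_symmetry(self, t1, t2):
        d = circular_diff(t1, t2)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(circular_diff(t2, t1), abs=1e-9)


class TestComputeTorsions:
    def test_terminal_slots_undefined(self, duplex6):
        tt = compute_torsions(duplex6)
        for cid in ("A", "B"):
            first = duplex6.chain(cid)[0].key
            last = duplex6.chain(cid)[-1].key
            assert tt.value(first, "alpha") is None
            assert tt.value(last, "epsilon") is None
            assert tt.value(last, "zeta") is None

    def test_interior_slots_all_defined(self, duplex6):
        tt = compute_torsions(duplex6)
        for r in duplex6.chain("A")[1:-1]:
            for name in ANGLE_NAMES:
                assert tt.value(r.key, name) is not None

    def test_missing_o3_prime_undefines_dependent_angles(self, duplex6):
        broken = copy.deepcopy(duplex6)
        res = broken.chain("A")[2]
        res.atoms = [a for a in res.atoms if a.name != "O3'"]
        tt = compute_torsions(broken)
        assert tt.value(res.key, "delta") is None
        assert tt.value(res.key, "epsilon") is None
        assert tt.value(res.key, "gamma") is not None

    def test_values_match_independent_dihedral_oracle(self, duplex6):
        """Recompute every backbone torsion with Biopython's dihedral."""
        from Bio.PDB.vectors import Vector, calc_dihedral

        tt = compute_torsions(duplex6)
        chain = duplex6.chain("A")
        res, nxt = chain[1], chain[2]
        quads = {
            "beta": (res.atom("P"), res.atom("O5'"), res.atom("C5'"), res.atom("C4'")),
            "gamma": (res.atom("O5'"), res.atom("C5'"), res.atom("C4'"), res.atom("C3'")),
            "delta": (res.atom("C5'"), res.atom("C4'"), res.atom("C3'"), res.atom("O3'")),
            "epsilon": (res.atom("C4'"), res.atom("C3'"), res.atom("O3'"), nxt.atom("P")),
        }
        for name, atoms in quads.items():
            oracle = math.degrees(calc_dihedral(*(Vector(*a.position) for a in atoms)))
            assert circular_diff(tt.value(res.key, name), oracle) < 1e-6

    def test_pseudorotation_is_c3_endo_for_the_ideal_helix(self, duplex6):
        tt = compute_torsions(duplex6)
        for r in duplex6.chain("A"):
            p = tt.value(r.key, "P")
            assert p is not None
            assert 0.0 <= p < 36.0 or p > 350.0  # C3'-endo north pucker


def _offset_table(tt, delta):
    out = TorsionTable(residue_keys=list(tt.residue_keys))
    for key in tt.residue_keys:
        out.angles[key] = {
            name: (None if v is None else (v + delta))
            for name, v in tt.angles[key].items()
        }
    return out


class TestMcq:
    def test_identity_is_zero(self, duplex6):
        tt = compute_torsions(duplex6)
        assert mcq_global(tt, tt).global_value == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_returns_exactly_the_offset(self, duplex6):
        tt = compute_torsions(duplex6)
        shifted = _offset_table(tt, 25.0)
        res = mcq_global(tt, shifted)
        assert res.global_value == pytest.approx(25.0, abs=1e-9)

    def test_two_known_differences_average_circularly(self):
        t1 = TorsionTable(residue_keys=[("A", 1, "")])
        t1.angles[("A", 1, "")] = {n: None for n in ANGLE_NAMES}
        t1.angles[("A", 1, "")].update({"alpha": 0.0, "beta": 0.0})
        t2 = TorsionTable(residue_keys=[("A", 1, "")])
        t2.angles[("A", 1, "")] = {n: None for n in ANGLE_NAMES}
        t2.angles[("A", 1, "")].update({"alpha": 10.0, "beta": 30.0})
        res = mcq_global(t1, t2)
        # circular mean of {10, 30} degrees
        expected = math.degrees(
            math.atan2(
                (math.sin(math.radians(10)) + math.sin(math.radians(30))) / 2,
                (math.cos(math.radians(10)) + math.cos(math.radians(30))) / 2,
            )
        )
        assert res.global_value == pytest.approx(expected, abs=1e-9)
        assert res.angles_compared == 2

    def test_symmetry(self, duplex6):
        tt = compute_torsions(duplex6)
        noisy = perturb(duplex6, PerturbationSpec(kind="noise", sigma=0.4, seed=3))
        tn = compute_torsions(noisy)
        assert mcq_global(tt, tn).global_value == pytest.approx(
            mcq_global(tn, tt).global_value, abs=1e-9
        )

    def test_rigid_motion_leaves_mcq_unchanged(self, duplex6):
        rng = np.random.default_rng(17)
        R, t = random_rigid_motion(rng)
        moved = duplex6.transformed(R, t)
        tt = compute_torsions(duplex6)
        tm = compute_torsions(moved)
        assert mcq_global(tt, tm).global_value < 1e-6

    def test_zero_comparable_slots_is_an_error(self):
        t1 = TorsionTable(residue_keys=[("A", 1, "")])
        t1.angles[("A", 1, "")] = {n: None for n in ANGLE_NAMES}
        with pytest.raises(ValueError, match="comparable"):
            mcq_global(t1, t1)

    def test_one_sided_slots_counted_not_imputed(self, duplex6):
        tt = compute_torsions(duplex6)
        broken = copy.deepcopy(duplex6)
        res = broken.chain("A")[2]
        res.atoms = [a for a in res.atoms if a.name != "O3'"]
        tb = compute_torsions(broken)
        corr = build_correspondence(duplex6, broken, mode="by-number")
        res_g = mcq_global(tt, tb, corr)
        assert res_g.angles_skipped > 0

    def test_arithmetic_aggregation_mode(self, duplex6):
        tt = compute_torsions(duplex6)
        shifted = _offset_table(tt, 40.0)
        res = mcq_global(tt, shifted, aggregation="arithmetic")
        assert res.global_value == pytest.approx(40.0, abs=1e-9)


class TestMcqLocal:
    def test_identical_tables_all_zero(self, duplex6):
        tt = compute_torsions(duplex6)
        rows, skipped = mcq_local(tt, tt)
        assert skipped == 0
        assert max(d for _, _, d in rows) < 1e-12

    def test_glycosidic_bond_rotation_moves_exactly_one_chi(self, duplex6):
        res = duplex6.chain("A")[2]
        bond = (res.key, "C1'", res.glycosidic_nitrogen)
        spun = perturb(duplex6, PerturbationSpec(kind="bond-rotation", bond=bond, delta_deg=40.0))
        t0 = compute_torsions(duplex6)
        t1 = compute_torsions(spun)
        rows, _ = mcq_local(t0, t1)
        nonzero = [(key, name, d) for key, name, d in rows if d > 1e-6]
        assert len(nonzero) == 1
        key, name, d = nonzero[0]
        assert key == res.key and name == "chi"
        assert d == pytest.approx(40.0, abs=1e-6)
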