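"""INF, DI, and the Deformation Profile."""

import copy

import numpy as np
import pytest

from rnassess import (
    Domain,
    build_correspondence,
    build_helix,
    deformation_index,
    deformation_profile,
    inf_score,
    interactions_of,
    match_interactions,
    perturb,
)
from rnassess.annotation import BasePair, InteractionSet
from rnassess.fixtures import PerturbationSpec
from tests.conftest import random_rigid_motion


def _pair(i, j, canonical=True):
    return BasePair(
        residue_i=("A", i, ""), residue_j=("A", j, ""),
        edge_i="W", edge_j="W", orientation="cis", canonical_wc=canonical,
    )


def _identity_corr(model):
    return build_correspondence(model, model, mode="by-number")


class TestInfScore:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (4, 0, 0, 1.0),
            (2, 1, 2, 0.5774),  # sqrt((2/3)(1/2))
            (0, 5, 3, 0.0),
            (3, 1, 0, np.sqrt(0.75)),
        ],
    )
    def test_matches_hand_counts(self, tp, fp, fn, expected):
        assert inf_score(tp, fp, fn) == pytest.approx(expected, abs=1e-4)

    def test_empty_reference_is_undefined_not_zero(self):
        assert inf_score(0, 4, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            inf_score(-1, 0, 0)


class TestMatchInteractions:
    def test_identical_sets_perfect(self, duplex6):
        ia = interactions_of(duplex6)
        inf = match_interactions(ia, ia, _identity_corr(duplex6))
        for cat in ("wc", "stack"):
            assert inf.counts[cat].fp == 0 and inf.counts[cat].fn == 0
        assert inf.inf_all == pytest.approx(1.0)
        assert inf.inf_wc == pytest.approx(1.0)
        assert inf.inf_nwc is None  # no non-WC pairs in an ideal duplex

    def test_empty_model_all_false_negatives(self, duplex6):
        ia = interactions_of(duplex6)
        empty = InteractionSet(source_label="empty")
        inf = match_interactions(ia, empty, _identity_corr(duplex6))
        assert inf.counts["wc"].tp == 0
        assert inf.counts["wc"].fn == len(ia.pairs)
        assert inf.inf_wc == 0.0

    def test_enumerated_sets_reproduce_hand_counts(self, duplex12):
        """reference {ab,cd,ef,gh}, model {ab,cd,xy}: TP=2 FP=1 FN=2."""
        ref = InteractionSet(pairs=[_pair(1, 24), _pair(2, 23), _pair(3, 22), _pair(4, 21)])
        mod = InteractionSet(pairs=[_pair(1, 24), _pair(2, 23), _pair(7, 18)])
        trace = build_helix("GCAUGCAUGCAUGCAUGCAUGCAU", duplex=False)
        inf = match_interactions(ref, mod, _identity_corr(trace))
        c = inf.counts["wc"]
        assert (c.tp, c.fp, c.fn) == (2, 1, 2)
        assert inf.inf_wc == pytest.approx(np.sqrt((2 / 3) * (2 / 4)), abs=1e-4)

    def test_reference_category_wins_for_matched_pairs(self, duplex12):
        trace = build_helix("GCAUGCAU", duplex=False)
        ref = InteractionSet(pairs=[_pair(1, 8, canonical=True)])
        mod = InteractionSet(pairs=[_pair(1, 8, canonical=False)])  # model calls it non-WC
        inf = match_interactions(ref, mod, _identity_corr(trace))
        assert inf.counts["wc"].tp == 1
        assert inf.counts["nwc"].fp == 0

    def test_strict_mode_requires_edge_and_orientation(self):
        trace = build_helix("GCAUGCAU", duplex=False)
        ref = InteractionSet(pairs=[_pair(1, 8)])
        flipped = BasePair(("A", 1, ""), ("A", 8, ""), "W", "H", "trans", False)
        mod = InteractionSet(pairs=[flipped])
        loose = match_interactions(ref, mod, _identity_corr(trace))
        strict = match_interactions(ref, mod, _identity_corr(trace), strict=True)
        assert loose.counts["wc"].tp == 1
        assert strict.counts["wc"].tp == 0 and strict.counts["wc"].fn == 1

    def test_interactions_outside_correspondence_become_fn_and_fp(self, duplex6):
        truncated = copy.deepcopy(duplex6)
        for cid, residues in truncated.chains:
            residues.pop()  # drop last residue of each chain
        corr = build_correspondence(duplex6, truncated, mode="by-number")
        ref_ia = interactions_of(duplex6)
        mod_ia = interactions_of(truncated)
        inf = match_interactions(ref_ia, mod_ia, corr)
        # the reference pair involving a dropped residue cannot be recovered
        assert inf.counts["wc"].fn >= 1


class TestDeformationIndex:
    @pytest.mark.parametrize("rmsd,inf,expected", [(10.0, 1.0, 10.0), (12.0, 0.5, 24.0)])
    def test_arithmetic(self, rmsd, inf, expected):
        assert deformation_index(rmsd, inf) == expected

    def test_zero_or_undefined_inf_gives_na(self):
        assert deformation_index(10.0, 0.0) is None
        assert deformation_index(10.0, None) is None


class TestDeformationProfile:
    def test_identity_is_all_zero(self, duplex6):
        dp = deformation_profile(duplex6, duplex6, _identity_corr(duplex6))
        assert np.nanmax(dp.values) < 1e-9

    def test_rigid_translation_is_all_zero(self, duplex6):
        moved = duplex6.transformed(np.eye(3), np.array([4.0, -2.0, 9.0]))
        corr = build_correspondence(duplex6, moved, mode="by-number")
        dp = deformation_profile(duplex6, moved, corr)
        assert np.nanmax(dp.values) < 1e-9

    def test_single_displaced_residue_reads_3A_everywhere(self, duplex6):
        spec = PerturbationSpec(
            kind="rigid-domain", chain="A", start=3, end=3, angle_deg=0.0,
            translation=(3.0, 0.0, 0.0),
        )
        moved = perturb(duplex6, spec)
        corr = build_correspondence(duplex6, moved, mode="by-number")
        dp = deformation_profile(duplex6, moved, corr)
        d = dp.residue_keys.index(("A", 3, ""))
        n = len(dp.residue_keys)
        for i in range(n):
            for j in range(n):
                expected = 3.0 if (i == d) != (j == d) else 0.0
                assert dp.values[i, j] == pytest.approx(expected, abs=1e-6)

    def test_rigid_motion_invariance_of_either_input(self, duplex6):
        spec = PerturbationSpec(kind="noise", sigma=0.3, seed=5)
        noisy = perturb(duplex6, spec)
        corr = build_correspondence(duplex6, noisy, mode="by-number")
        dp0 = deformation_profile(duplex6, noisy, corr).values
        rng = np.random.default_rng(9)
        R, t = random_rigid_motion(rng)
        dp1 = deformation_profile(duplex6.transformed(R, t), noisy, corr).values
        R2, t2 = random_rigid_motion(rng)
        dp2 = deformation_profile(duplex6, noisy.transformed(R2, t2), corr).values
        np.testing.assert_allclose(dp1, dp0, atol=1e-6)
        np.testing.assert_allclose(dp2, dp0, atol=1e-6)

    def test_anchor_with_too_few_atoms_gets_nan_row_and_column(self, duplex6):
        broken = copy.deepcopy(duplex6)
        res = broken.chain("A")[2]
        res.atoms = res.atoms[:2]  # < 3 usable anchor atoms
        corr = build_correspondence(duplex6, broken, mode="by-number")
        dp = deformation_profile(duplex6, broken, corr)
        d = dp.residue_keys.index(("A", 3, ""))
        assert np.isnan(dp.values[d]).all()
        assert np.isnan(dp.values[:, d]).all()

    def test_domain_summaries_isolate_the_moved_block(self, duplex12):
        spec = PerturbationSpec(
            kind="rigid-domain", chain="A", start=7, end=12,
            axis_point=(0.0, 0.0, 18.0), axis_direction=(0.0, 1.0, 0.0), angle_deg=25.0,
        )
        moved = perturb(duplex12, spec)
        corr = build_correspondence(duplex12, moved, mode="by-number")
        domains = [Domain("fixed", "A", 1, 6), Domain("moved", "A", 7, 12)]
        dp = deformation_profile(duplex12, moved, corr, domains=domains)
        # within each rigid body the anchored distances vanish
        assert dp.domain_summaries["fixed"]["max"] < 1e-6
        assert dp.domain_summaries["moved"]["max"] < 1e-6
        # but cross-block rows are elevated
        fixed_idx = [k for k, key in enumerate(dp.residue_keys) if key[0] == "A" and key[1] <= 6]
        moved_idx = [k for k, key in enumerate(dp.residue_keys) if key[0] == "A" and key[1] >= 7]
        cross = dp.values[np.ix_(fixed_idx, moved_idx)]
        assert cross.min() > 0.5

    def test_csv_round_trip_precision(self, duplex6):
        spec = PerturbationSpec(kind="noise", sigma=0.2, seed=1)
        noisy = perturb(duplex6, spec)
        corr = build_correspondence(duplex6, noisy, mode="by-number")
        dp = deformation_profile(duplex6, noisy, corr)
        lines = dp.to_csv().splitlines()
        assert len(lines) == len(dp.residue_keys) + 1
        cell = float(lines[1].split(",")[2])
        assert cell == pytest.approx(dp.values[0, 1], abs=5e-5)
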