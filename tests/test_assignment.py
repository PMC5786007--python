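"""The weighted k-NN assignment protocol and its rejection tests."""

import numpy as np
import pytest

from ntcana.assignment import (
    WEIGHT_BELOW_CUTOFF,
    AssignmentConfig,
    assign_step,
    nearest_neighbours,
)
from ntcana.assignment import test1_nn_proximity as check_nn_proximity
from ntcana.assignment import test2_esd as check_esd
from ntcana.assignment import test3_systematic_shift as check_shift
from ntcana.assignment import test4_pucker as check_pucker
from ntcana.cana import NAN
from ntcana.errors import InsufficientReferenceError
from ntcana.geometry import circular_diff, circular_mean_and_esd
from ntcana.reference import build_golden_set
from ntcana.structure_io import StepTorsions
from ntcana.synthetic import sample_candidates

from conftest import B_TEMPLATE, make_symmetric_members


def displaced(golden_class, deltas, p1=None, p2=None):
    """Candidate displaced from a class's means by per-torsion deltas."""
    angles = (golden_class.torsion_means + np.asarray(deltas)) % 360.0
    return StepTorsions.from_values(
        angles,
        golden_class.p_means[0] if p1 is None else p1,
        golden_class.p_means[1] if p2 is None else p2)


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------

def oracle_assign(candidate, golden, config=AssignmentConfig()):
    """Naive re-implementation: full distance table, direct test checks.

    Kept deliberately simple and separate from the library code paths.
    """
    def circ(a, b):
        d = (a - b) % 360.0
        return d - 360.0 if d > 180.0 else d

    cand = candidate.angles()
    table = []
    for m in golden.members:
        ref = m.torsions.angles()
        dist = np.sqrt(sum(circ(x, y) ** 2 for x, y in zip(cand, ref)))
        table.append((dist, m.member_id, m))
    table.sort(key=lambda t: (t[0], t[1]))
    top = table[:config.k_max]
    nn = top[0][2]
    cls = nn.ntc_class
    same = [(d, m) for d, _, m in top if m.ntc_class == cls]
    weight = sum(1.0 / max(d, 1e-3) ** 2 for d, _ in same)
    reasons = set()
    if weight < config.nn_cutoff:
        return NAN, {WEIGHT_BELOW_CUTOFF}
    classdef = golden.classes[cls]
    same_mean = [circular_mean_and_esd(
        [m.torsions.angles()[i] for _, m in same])[0] for i in range(9)]
    for i in range(9):
        if abs(circ(cand[i], nn.torsions.angles()[i])) > config.test1_limit:
            reasons.add("TEST1_NN_TORSION")
        if abs(circ(cand[i], same_mean[i])) > config.test1_limit:
            reasons.add("TEST1_CLASSMEAN_TORSION")
        if abs(circ(cand[i], classdef.torsion_means[i])) > \
                config.test2_esd_mult * classdef.torsion_esds[i]:
            reasons.add("TEST2_ESD")
    diffs = [circ(cand[i], classdef.torsion_means[i]) for i in range(9)]
    if abs(sum(diffs[:7])) > config.test3_limit:
        reasons.add("TEST3_BACKBONE_SUM")
    if abs(sum(diffs[7:])) > config.test3_limit:
        reasons.add("TEST3_CHI_SUM")
    for p, pm in zip((candidate.p1, candidate.p2), classdef.p_means):
        if abs(circ(p, pm)) > config.test4_limit:
            reasons.add("TEST4_PUCKER")
    if reasons:
        return NAN, reasons
    return cls, set()


# --------------------------------------------------------------------------
# nearest neighbours
# --------------------------------------------------------------------------

class TestNearestNeighbours:
    def test_identical_candidate_ranks_first_with_zero_distance(
            self, toy_golden):
        m = toy_golden.members[0]
        hits = nearest_neighbours(m.torsions, toy_golden)
        assert hits[0].member_id == m.member_id
        assert hits[0].distance == 0.0

    def test_ranked_order_matches_brute_force(self, toy_golden):
        rng = np.random.default_rng(31)
        cand = StepTorsions.from_values(
            (B_TEMPLATE + rng.uniform(-15, 15, 9)) % 360, 150, 150)
        hits = nearest_neighbours(cand, toy_golden)
        brute = sorted(
            ((np.sqrt(np.sum(circular_diff(cand.angles(),
                                           m.torsions.angles()) ** 2)),
              m.member_id) for m in toy_golden.members))
        assert [(h.distance, h.member_id) for h in hits] == [
            pytest.approx(b) for b in brute[:11]]

    def test_equidistant_tie_broken_lexicographically(self):
        golden = build_golden_set(
            make_symmetric_members("BB00", B_TEMPLATE, 155.0,
                                   offsets=(-5.0, 5.0), n_repeat=4))
        cand = StepTorsions.from_values(B_TEMPLATE, 155.0, 155.0)
        hits = nearest_neighbours(cand, golden)
        assert all(h.distance == pytest.approx(15.0) for h in hits)
        ids = [h.member_id for h in hits]
        assert ids == sorted(ids)

    def test_small_golden_set_rejected(self):
        golden = build_golden_set(
            make_symmetric_members("BB00", B_TEMPLATE, 155.0,
                                   offsets=(-3.0, 3.0), n_repeat=3))
        golden.members = golden.members[:6]
        cand = StepTorsions.from_values(B_TEMPLATE, 155.0, 155.0)
        with pytest.raises(InsufficientReferenceError):
            nearest_neighbours(cand, golden)

    def test_zero_distance_weight_capped(self, toy_golden):
        m = toy_golden.members[0]
        hits = nearest_neighbours(m.torsions, toy_golden)
        assert hits[0].weight == pytest.approx(1e6)
        finite = next(h for h in hits if h.distance > 0)
        assert finite.weight * finite.distance ** 2 == pytest.approx(1.0)


# --------------------------------------------------------------------------
# the four rejection tests, at their threshold edges
# --------------------------------------------------------------------------

class TestRejectionTests:
    def test1_pass_at_28_fail_at_29(self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        nn = single_class_golden.members[0]
        for shift, ok in ((28.0, True), (29.0, False)):
            cand = displaced(d, [0, 0, shift - 6.0, 0, 0, 0, 0, 0, 0])
            # nn member sits at template-6 on every torsion, so the zeta
            # displacement against the nn is exactly `shift`
            passed, offenders = check_nn_proximity(cand, nn, d.torsion_means)
            assert passed is ok
            if not ok:
                assert any("zeta" in o for o in offenders)

    def test1_all_torsions_at_boundary_pass(self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        cand = displaced(d, [28.0] * 9)
        nn_exact = build_golden_set(
            make_symmetric_members("BB00", B_TEMPLATE, 155.0)).members[0]
        # against the class means only (nn at -6 would be 34 away)
        passed, offenders = check_nn_proximity(
            displaced(d, [28.0] * 9), nn_exact, d.torsion_means)
        assert [o for o in offenders if "CLASSMEAN" in o] == []

    def test2_arithmetic(self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        esd = d.torsion_esds[0]  # symmetric members: same esd everywhere
        ok, _ = check_esd(displaced(d, [5 * esd - 0.01] + [0] * 8), d)
        assert ok
        bad, offenders = check_esd(displaced(d, [5 * esd + 0.01] + [0] * 8),
                                   d)
        assert not bad and offenders

    def test3_sums(self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        ok, _, back, chi = check_shift(displaced(d, [0.0] * 9), d)
        assert ok and back == pytest.approx(0) and chi == pytest.approx(0)
        # +10 on each backbone torsion: sum 70 -> fail
        bad, offenders, back, _ = check_shift(
            displaced(d, [10.0] * 7 + [0, 0]), d)
        assert not bad and back == pytest.approx(70.0)
        assert offenders == ["TEST3_BACKBONE_SUM"]
        # cancellation: +30 on delta, -30 on zeta
        ok, _, back, _ = check_shift(
            displaced(d, [30.0, 0, -30.0, 0, 0, 0, 0, 0, 0]), d)
        assert ok and back == pytest.approx(0.0)
        # edge: 60 passes, 61 fails
        for total, want in ((60.0, True), (61.0, False)):
            got, _, _, _ = check_shift(
                displaced(d, [total] + [0] * 8), d,
                AssignmentConfig(test2_esd_mult=1e9))
            assert got is want

    def test4_pucker_edges(self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        pm = float(d.p_means[0])
        for shift, ok in ((72.0, True), (73.0, False)):
            cand = displaced(d, [0.0] * 9, p1=(pm + shift) % 360)
            got, offenders = check_pucker(cand, d)
            assert got is ok
            if not ok:
                assert offenders == ["TEST4_PUCKER:sugar1"]
        # wraparound: P 350 vs mean 10 is a 20-degree difference
        cand = StepTorsions.from_values(d.torsion_means, 350.0, 10.0)
        d10 = type(d)(**{**d.__dict__, "p_means": np.array([10.0, 10.0])})
        got, _ = check_pucker(cand, d10)
        assert got


# --------------------------------------------------------------------------
# full protocol
# --------------------------------------------------------------------------

class TestAssignStep:
    def test_self_classification_zero_rejections(self, fixture_golden):
        for m in fixture_golden.members[::30]:
            a = assign_step(m.torsions, fixture_golden)
            assert a.ntc_class == m.ntc_class
            assert a.rejection_reasons == ()
            assert a.confal > 0

    def test_leave_one_out_self_classification(self, fixture_golden):
        for m in fixture_golden.members[::60]:
            rest = [x for x in fixture_golden.members
                    if x.member_id != m.member_id]
            golden = build_golden_set(rest)
            a = assign_step(m.torsions, golden)
            assert a.ntc_class == m.ntc_class

    def test_far_candidate_rejected_by_weight_cutoff(
            self, single_class_golden):
        d = single_class_golden.classes["BB00"]
        cand = displaced(d, [100.0] * 9)
        a = assign_step(cand, single_class_golden)
        assert a.ntc_class == NAN
        assert a.cana_letter == NAN
        assert a.confal == 0.0
        assert a.rejection_reasons == (WEIGHT_BELOW_CUTOFF,)
        # closed form: members sit at distance 3*(100 - off); the ranked
        # list keeps the 11 nearest of the 12 members
        dists = sorted(3.0 * (100.0 - off)
                       for off in (-6, -4, -2, 2, 4, 6) for _ in range(2))
        s = sum(1.0 / d ** 2 for d in dists[:11])
        assert s < 0.0011
        assert sum(h.weight for h in a.neighbour_trace
                   if h.ntc_class == "BB00") == pytest.approx(s, rel=1e-6)

    def test_oracle_equivalence_on_random_candidates(self, toy_golden):
        assert len(toy_golden.members) <= 50
        rng = np.random.default_rng(33)
        agree = 0
        for _ in range(1000):
            mode = rng.integers(3)
            if mode == 0:  # near a class
                base = B_TEMPLATE if rng.integers(2) else \
                    toy_golden.classes["AA00"].torsion_means
                angles = (base + rng.normal(0, 12, 9)) % 360
                p = rng.uniform(0, 360)
            elif mode == 1:  # borderline
                base = B_TEMPLATE
                angles = (base + rng.uniform(-40, 40, 9)) % 360
                p = rng.uniform(100, 220)
            else:  # anywhere
                angles = rng.uniform(0, 360, 9)
                p = rng.uniform(0, 360)
            cand = StepTorsions.from_values(angles, p, p)
            a = assign_step(cand, toy_golden)
            cls, reasons = oracle_assign(cand, toy_golden)
            assert a.ntc_class == cls
            assert set(a.rejection_reasons) == reasons
            agree += 1
        assert agree == 1000

    def test_nan_monotonic_under_tighter_thresholds(self, toy_golden):
        tight = AssignmentConfig(nn_cutoff=0.002, test1_limit=20.0,
                                 test2_esd_mult=3.0, test3_limit=40.0,
                                 test4_limit=50.0)
        rng = np.random.default_rng(34)
        for _ in range(200):
            angles = (B_TEMPLATE + rng.normal(0, 25, 9)) % 360
            cand = StepTorsions.from_values(angles, rng.uniform(0, 360),
                                            rng.uniform(0, 360))
            default = assign_step(cand, toy_golden)
            tighter = assign_step(cand, toy_golden, tight)
            if default.ntc_class == NAN:
                assert tighter.ntc_class == NAN

    def test_every_nan_carries_a_reason(self, fixture_golden):
        rng = np.random.default_rng(35)
        n_nan = n_reasons = 0
        for _ in range(100):
            cand = StepTorsions.from_values(
                rng.uniform(0, 360, 9), rng.uniform(0, 360),
                rng.uniform(0, 360))
            a = assign_step(cand, fixture_golden)
            if a.ntc_class == NAN:
                n_nan += 1
                assert len(a.rejection_reasons) >= 1
                n_reasons += 1
        assert n_nan == n_reasons


class TestParameterRecovery:
    def test_recovery_at_unit_noise(self, fixture_golden):
        classes = list(fixture_golden.classes.items())
        hits = total = 0
        for idx, (cls, d) in enumerate(classes):
            for cand in sample_candidates(d, 50, 1.0, seed=100 + idx):
                a = assign_step(cand, fixture_golden)
                hits += (a.ntc_class == cls)
                total += 1
        assert total == 500
        assert hits / total >= 0.95

    def test_majority_nan_at_tenfold_noise(self, fixture_golden):
        classes = list(fixture_golden.classes.items())
        nan = total = 0
        for idx, (cls, d) in enumerate(classes):
            for cand in sample_candidates(d, 20, 10.0, seed=200 + idx):
                a = assign_step(cand, fixture_golden)
                nan += (a.ntc_class == NAN)
                total += 1
        assert nan / total > 0.5
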