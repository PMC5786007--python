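"""Weighted k-NN assignment of steps to NtC classes.

The protocol, per candidate step:

(i)   rank the golden-set members by circular Euclidean distance over
      the nine torsions and keep the 11 nearest;
(ii)  weight each neighbour by 1/d^2;
(iii) tentatively assign the class of the single nearest neighbour; if
      the summed weight of the ranked neighbours belonging to that
      class falls below 0.0011 (= 1/30^2), declare the step NAN;
(iv)  otherwise apply four rejection tests — (1) every torsion within
      28 deg of both the nearest neighbour and the same-class
      neighbour average, (2) every torsion within 5 esd of the class
      mean, (3) signed-difference sums within +/-60 deg for the seven
      backbone torsions and for the two glycosidic torsions, and
      (4) both sugar pseudorotation phases within +/-72 deg of the
      class P averages. Any failure yields NAN with diagnostics.

All threshold comparisons are inclusive (a displacement exactly at the
limit passes). All four tests are always evaluated so the diagnostics
list every violated criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cana import NAN, ntc_to_cana
from .confal import confal_step
from .errors import InsufficientReferenceError
from .geometry import (
    BACKBONE_INDICES,
    GLYCOSIDIC_INDICES,
    TORSION_NAMES,
    circular_diff,
    circular_euclidean_distance,
    circular_mean_and_esd,
)

# rejection reason codes
WEIGHT_BELOW_CUTOFF = "WEIGHT_BELOW_CUTOFF"
TEST1_NN_TORSION = "TEST1_NN_TORSION"
TEST1_CLASSMEAN_TORSION = "TEST1_CLASSMEAN_TORSION"
TEST2_ESD = "TEST2_ESD"
TEST3_BACKBONE_SUM = "TEST3_BACKBONE_SUM"
TEST3_CHI_SUM = "TEST3_CHI_SUM"
TEST4_PUCKER = "TEST4_PUCKER"

#: Distance (degrees) below which a neighbour counts as an exact
#: duplicate; its 1/d^2 weight is capped at 1/ZERO_DISTANCE_FLOOR^2.
ZERO_DISTANCE_FLOOR = 1e-3


@dataclass(frozen=True)
class AssignmentConfig:
    """Tunable thresholds of the assignment protocol (defaults as published)."""

    nn_cutoff: float = 0.0011      # minimum summed same-class weight (1/30^2)
    test1_limit: float = 28.0      # deg, proximity to NN and same-class mean
    test2_esd_mult: float = 5.0    # multiples of the class esd
    test3_limit: float = 60.0      # deg, |sum of signed differences|
    test4_limit: float = 72.0      # deg, |P - class P mean|
    k_max: int = 11                # neighbours ranked
    k_min: int = 7                 # minimum usable golden-set size


DEFAULT_CONFIG = AssignmentConfig()


@dataclass(frozen=True)
class NeighbourHit:
    member_id: str
    ntc_class: str
    distance: float

    @property
    def weight(self) -> float:
        return 1.0 / max(self.distance, ZERO_DISTANCE_FLOOR) ** 2


@dataclass(frozen=True)
class Assignment:
    """Outcome for one step: a class or NAN, with full diagnostics."""

    step_id: str
    sequence: str
    ntc_class: str
    cana_letter: str
    confal: float
    rejection_reasons: tuple[str, ...]
    neighbour_trace: tuple[NeighbourHit, ...]

    @property
    def assigned(self) -> bool:
        return self.ntc_class != NAN

    @property
    def nn_distance(self) -> float:
        return self.neighbour_trace[0].distance if self.neighbour_trace \
            else float("nan")


def nearest_neighbours(candidate, golden, k_max: int | None = None,
                       config: AssignmentConfig = DEFAULT_CONFIG
                       ) -> list[NeighbourHit]:
    """The k_max nearest golden-set members, ascending by distance.

    Ties are broken by lexicographic member id so ranking is
    deterministic. A golden set smaller than the configured minimum
    neighbourhood is rejected outright.
    """
    if len(golden.members) < config.k_min:
        raise InsufficientReferenceError(
            f"golden set has {len(golden.members)} members; "
            f"at least {config.k_min} required")
    k_max = config.k_max if k_max is None else k_max
    cand = candidate.angles()
    hits = [NeighbourHit(m.member_id, m.ntc_class,
                         circular_euclidean_distance(cand,
                                                     m.torsions.angles()))
            for m in golden.members]
    hits.sort(key=lambda h: (h.distance, h.member_id))
    return hits[:k_max]


def test1_nn_proximity(candidate, nn_member, same_class_mean,
                       config: AssignmentConfig = DEFAULT_CONFIG
                       ) -> tuple[bool, list[str]]:
    """Every torsion within the limit of both the nearest neighbour's
    torsions and the same-class neighbour averages."""
    cand = candidate.angles()
    offenders = []
    d_nn = np.abs(circular_diff(cand, nn_member.torsions.angles()))
    d_cm = np.abs(circular_diff(cand, np.asarray(same_class_mean)))
    for i, name in enumerate(TORSION_NAMES):
        if d_nn[i] > config.test1_limit:
            offenders.append(f"{TEST1_NN_TORSION}:{name}")
        if d_cm[i] > config.test1_limit:
            offenders.append(f"{TEST1_CLASSMEAN_TORSION}:{name}")
    return not offenders, offenders


def test2_esd(candidate, classdef,
              config: AssignmentConfig = DEFAULT_CONFIG
              ) -> tuple[bool, list[str]]:
    """Every torsion within test2_esd_mult standard deviations of the
    class mean."""
    d = np.abs(circular_diff(candidate.angles(), classdef.torsion_means))
    lim = config.test2_esd_mult * classdef.torsion_esds
    offenders = [f"{TEST2_ESD}:{name}"
                 for i, name in enumerate(TORSION_NAMES) if d[i] > lim[i]]
    return not offenders, offenders


def test3_systematic_shift(candidate, classdef,
                           config: AssignmentConfig = DEFAULT_CONFIG
                           ) -> tuple[bool, list[str], float, float]:
    """Signed-difference sums over backbone and glycosidic torsions."""
    d = circular_diff(candidate.angles(), classdef.torsion_means)
    backbone_sum = float(np.sum(d[list(BACKBONE_INDICES)]))
    chi_sum = float(np.sum(d[list(GLYCOSIDIC_INDICES)]))
    offenders = []
    if abs(backbone_sum) > config.test3_limit:
        offenders.append(TEST3_BACKBONE_SUM)
    if abs(chi_sum) > config.test3_limit:
        offenders.append(TEST3_CHI_SUM)
    return not offenders, offenders, backbone_sum, chi_sum


def test4_pucker(candidate, classdef,
                 config: AssignmentConfig = DEFAULT_CONFIG
                 ) -> tuple[bool, list[str]]:
    """Both sugar pseudorotation phases within the limit of the class
    P averages."""
    offenders = []
    for sugar, (p, p_mean) in enumerate(
            zip((candidate.p1, candidate.p2), classdef.p_means), start=1):
        if abs(circular_diff(p, float(p_mean))) > config.test4_limit:
            offenders.append(f"{TEST4_PUCKER}:sugar{sugar}")
    return not offenders, offenders


def _reason_codes(offenders) -> tuple[str, ...]:
    seen: list[str] = []
    for item in offenders:
        code = item.split(":", 1)[0]
        if code not in seen:
            seen.append(code)
    return tuple(seen)


def assign_step(candidate, golden, config: AssignmentConfig = DEFAULT_CONFIG,
                step_id: str = "", sequence: str = "",
                split_ba: bool = False) -> Assignment:
    """Run the full protocol for one candidate step."""
    hits = nearest_neighbours(candidate, golden, config=config)
    nn = hits[0]
    tentative = nn.ntc_class
    same_class_hits = [h for h in hits if h.ntc_class == tentative]
    weight_sum = sum(h.weight for h in same_class_hits)

    detail: list[str] = []
    if weight_sum < config.nn_cutoff:
        detail.append(WEIGHT_BELOW_CUTOFF)
    else:
        classdef = golden.classes[tentative]
        members_by_id = {m.member_id: m for m in golden.members}
        nn_member = members_by_id[nn.member_id]
        same_class_members = [members_by_id[h.member_id]
                              for h in same_class_hits]
        neighbour_angles = np.array([m.torsions.angles()
                                     for m in same_class_members])
        same_class_mean = np.array(
            [circular_mean_and_esd(neighbour_angles[:, i])[0]
             for i in range(9)])

        _, off1 = test1_nn_proximity(candidate, nn_member, same_class_mean,
                                     config)
        _, off2 = test2_esd(candidate, classdef, config)
        _, off3, _, _ = test3_systematic_shift(candidate, classdef, config)
        _, off4 = test4_pucker(candidate, classdef, config)
        detail.extend(off1 + off2 + off3 + off4)

    reasons = _reason_codes(detail)
    if reasons:
        return Assignment(step_id=step_id, sequence=sequence, ntc_class=NAN,
                          cana_letter=NAN, confal=0.0,
                          rejection_reasons=reasons,
                          neighbour_trace=tuple(hits))
    classdef = golden.classes[tentative]
    return Assignment(
        step_id=step_id, sequence=sequence, ntc_class=tentative,
        cana_letter=ntc_to_cana(tentative, split_ba=split_ba),
        confal=confal_step(candidate, classdef),
        rejection_reasons=(), neighbour_trace=tuple(hits))


@dataclass(frozen=True)
class StructureAnnotation:
    """Ordered per-step assignments with structure-level summary."""

    assignments: tuple[Assignment, ...]
    structure_confal: float
    percentile: float | None = None
    metadata: dict = field(default_factory=dict)


def annotate_steps(candidates, golden,
                   config: AssignmentConfig = DEFAULT_CONFIG,
                   step_ids=None, sequences=None,
                   split_ba: bool = False) -> list[Assignment]:
    """Assign a list of StepTorsions, preserving order."""
    step_ids = step_ids or [f"step{i}" for i in range(len(candidates))]
    sequences = sequences or [""] * len(candidates)
    return [assign_step(c, golden, config, sid, seq, split_ba)
            for c, sid, seq in zip(candidates, step_ids, sequences)]
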