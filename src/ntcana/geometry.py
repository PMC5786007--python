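"""Torsion, circular-statistics and pseudorotation primitives.

All angles are handled in degrees. Torsions follow the IUPAC convention
(looking from the second to the third atom, clockwise rotation of the
far bond relative to the near bond is positive) and are normalized to
[0, 360), the scale on which DNA backbone torsions are conventionally
quoted (e.g. the canonical BI zeta near 260 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    DegenerateGeometryError,
    FlatRingError,
    UndefinedMeanError,
)

#: Fixed order of the nine step torsions.
TORSION_NAMES = (
    "delta",
    "epsilon",
    "zeta",
    "alpha1",
    "beta1",
    "gamma1",
    "delta1",
    "chi",
    "chi1",
)

#: The seven backbone torsions (indices into TORSION_NAMES).
BACKBONE_INDICES = tuple(range(7))
#: The two glycosidic torsions.
GLYCOSIDIC_INDICES = (7, 8)

_SIN36_PLUS_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))


def normalize_angle(x):
    """Map an angle (degrees) into [0, 360). Idempotent; vectorized."""
    r = np.mod(x, 360.0)
    # np.mod of a tiny negative value can round to exactly 360.0
    r = np.where(r >= 360.0, 0.0, r)
    return float(r) if r.ndim == 0 else r


def dihedral(a, b, c, d) -> float:
    """Dihedral angle a-b-c-d in degrees, normalized to [0, 360).

    Uses the standard atan2 formulation: positive when, looking down the
    b->c bond, the far bond c->d is rotated clockwise from the near bond
    b->a.

    Raises
    ------
    DegenerateGeometryError
        If a-b-c or b-c-d are collinear (the torsion is undefined).
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9:
        raise DegenerateGeometryError("central atoms b and c coincide")
    if np.linalg.norm(n1) < 1e-9 * max(np.linalg.norm(b1), 1.0) * nb2:
        raise DegenerateGeometryError("atoms a, b, c are collinear")
    if np.linalg.norm(n2) < 1e-9 * max(np.linalg.norm(b3), 1.0) * nb2:
        raise DegenerateGeometryError("atoms b, c, d are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    return float(normalize_angle(np.degrees(np.arctan2(y, x))))


def circular_diff(a, b):
    """Signed shortest angular difference a - b, in (-180, 180].

    The antipodal case (difference of exactly 180 deg) maps to +180 so
    that signed sums are reproducible. Vectorized over arrays.
    """
    m = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    out = np.where(m > 180.0, m - 360.0, m)
    if out.ndim == 0:
        return float(out)
    return out


def circular_euclidean_distance(t1, t2) -> float:
    """Circular Euclidean distance between two nine-torsion vectors.

    The square root of the sum of squared componentwise shortest angular
    differences; the metric used both for k-NN assignment and for
    conformer clustering.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != (9,) or t2.shape != (9,):
        raise ContractError(
            f"expected two 9-component torsion vectors, got shapes "
            f"{t1.shape} and {t2.shape}"
        )
    d = circular_diff(t1, t2)
    return float(np.sqrt(np.sum(d * d)))


def circular_mean_and_esd(values) -> tuple[float, float]:
    """Circular (directional) mean and angular standard deviation.

    The mean is the direction of the resultant of unit vectors; the
    estimated standard deviation is sqrt(-2 ln Rbar) converted to
    degrees, which reduces to the ordinary (population) standard
    deviation for tightly clustered samples.

    Raises
    ------
    UndefinedMeanError
        If the resultant length is (near) zero, e.g. perfectly uniform
        or antipodally balanced samples.
    """
    v = np.radians(np.asarray(values, dtype=float))
    if v.size == 0:
        raise UndefinedMeanError("empty sample")
    s = np.mean(np.sin(v))
    c = np.mean(np.cos(v))
    rbar = float(np.hypot(s, c))
    if rbar < 1e-12:
        raise UndefinedMeanError(
            "resultant length ~0: circular mean undefined for this sample"
        )
    mean = float(normalize_angle(np.degrees(np.arctan2(s, c))))
    # guard against rbar marginally exceeding 1 from rounding
    esd = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(min(rbar, 1.0))))))
    return mean, esd


@dataclass(frozen=True)
class SugarPucker:
    """Deoxyribose ring pucker in the pseudorotation description.

    P is the pseudorotation phase angle in [0, 360): C3'-endo (A-like)
    sugars fall near 0-60 deg and C2'-endo (B-like) sugars near
    150-180 deg. tau is the puckering amplitude in degrees (positive).
    nu holds the five endocyclic ring torsions nu0..nu4 as signed
    degrees when the pucker was derived from coordinates.
    """

    P: float
    tau: float = float("nan")
    nu: tuple[float, ...] | None = field(default=None)


def pseudorotation(nu) -> SugarPucker:
    """Pseudorotation phase P and amplitude tau from ring torsions.

    Parameters
    ----------
    nu : sequence of 5 floats
        Endocyclic torsions nu0..nu4 of the five-membered sugar ring,
        signed degrees. In the cosine parameterization
        nu_j = tau * cos(P + 144*(j-2)) so that nu2 = tau * cos(P).

    Returns
    -------
    SugarPucker
        With P in [0, 360), tau > 0 and the input torsions attached.
    """
    nu = [float(circular_diff(x, 0.0)) for x in np.asarray(nu, dtype=float)]
    if len(nu) != 5:
        raise ContractError(f"expected 5 ring torsions, got {len(nu)}")
    num = (nu[4] + nu[1]) - (nu[3] + nu[0])
    den = 2.0 * nu[2] * _SIN36_PLUS_SIN72
    if abs(num) < 1e-9 and abs(nu[2]) < 1e-9:
        raise FlatRingError("all ring torsions vanish: pucker undefined")
    # tan P = num / den with the quadrant fixed by the sign of nu2;
    # tau follows from nu2 = tau cos P and num = 2 tau sin P (sin36+sin72).
    p = float(normalize_angle(np.degrees(np.arctan2(num, den))))
    tau = float(np.hypot(nu[2], num / (2.0 * _SIN36_PLUS_SIN72)))
    return SugarPucker(P=p, tau=tau, nu=tuple(nu))


def pucker_ring_torsions(P: float, tau: float) -> np.ndarray:
    """The five ring torsions implied by (P, tau): nu_j = tau cos(P + 144(j-2))."""
    j = np.arange(5)
    return tau * np.cos(np.radians(P + 144.0 * (j - 2)))
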