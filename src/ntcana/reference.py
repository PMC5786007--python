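"""The golden set: reference members, per-class statistics, c2 calibration.

NtC classes are defined extensionally by a curated collection of
classified steps (the *golden set*). Each class definition carries the
circular means and estimated standard deviations of the nine torsions
over its members, per-torsion acceptance limits

    lim_i = min(28 deg, 5 * esd_i),

the circular mean pseudorotation phase of each sugar, and the confal
calibration coefficient c2 chosen so that the Gaussian confal score is
100 for a candidate at the class means and 1 for a candidate displaced
by lim_i on every torsion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .cana import DEFAULT_CANA_MAP, ntc_to_cana
from .errors import ReferenceFormatError, UndefinedMeanError
from .geometry import TORSION_NAMES, circular_mean_and_esd
from .structure_io import StepTorsions

logger = logging.getLogger(__name__)

#: Hard cap on the per-torsion acceptance limit, degrees.
TORSION_LIMIT_CAP = 28.0
#: Multiplier on the estimated standard deviation in the limit rule.
ESD_MULTIPLIER = 5.0

_LN100 = float(np.log(100.0))
_CLASS_ID_RE = re.compile(r"^[A-Z0-9]{4}$")

#: Columns of the member-level reference table.
REFERENCE_COLUMNS = ("member_id", "ntc_class", *TORSION_NAMES, "P1", "P2")


@dataclass(frozen=True)
class GoldenSetMember:
    """One classified step of the golden set."""

    member_id: str
    ntc_class: str
    torsions: StepTorsions


@dataclass(frozen=True)
class NtcClassDefinition:
    """Summary statistics and calibration of one NtC class."""

    ntc_class: str
    cana_letter: str
    torsion_means: np.ndarray  # (9,) circular means, degrees
    torsion_esds: np.ndarray   # (9,) circular esds, degrees
    torsion_limits: np.ndarray  # (9,) min(28, 5*esd), degrees
    p_means: np.ndarray        # (2,) circular mean P of sugar 1 and 2
    confal_c2: float
    member_count: int


@dataclass
class GoldenSet:
    """Members plus per-class definitions, with provenance metadata."""

    members: list[GoldenSetMember]
    classes: dict[str, NtcClassDefinition]
    metadata: dict = field(default_factory=dict)

    def members_of(self, ntc_class: str) -> list[GoldenSetMember]:
        return [m for m in self.members if m.ntc_class == ntc_class]

    def __len__(self) -> int:
        return len(self.members)


def calibrate_confal_c2(torsion_limits) -> float:
    """Confal coefficient c2 from the nine per-torsion limits.

    c2 = sum(lim_i^2) / ln(100), which makes the Gaussian score
    100*exp(-sum(d_i^2)/c2) equal 100 at zero displacement and exactly 1
    when every torsion sits at its limit. A degenerate class with all
    limits zero falls back to the c2 of 1-degree limits so the score
    stays defined.
    """
    lims = np.asarray(torsion_limits, dtype=float)
    total = float(np.sum(lims * lims))
    if total < 1e-9:  # incl. rounding-level esds of identical members
        total = float(len(lims))  # floor: 1 degree on every torsion
    return total / _LN100


def compute_class_statistics(members_by_class: dict[str, list[GoldenSetMember]],
                             cana_map: dict[str, str] | None = None
                             ) -> dict[str, NtcClassDefinition]:
    """Circular means/esds, limits, P-means and c2 for each class."""
    out: dict[str, NtcClassDefinition] = {}
    for ntc_class, members in members_by_class.items():
        if not members:
            raise ValueError(f"class {ntc_class} has no members")
        angles = np.array([m.torsions.angles() for m in members])
        means = np.empty(9)
        esds = np.empty(9)
        try:
            for i in range(9):
                means[i], esds[i] = circular_mean_and_esd(angles[:, i])
            p_means = np.array([
                circular_mean_and_esd([m.torsions.p1 for m in members])[0],
                circular_mean_and_esd([m.torsions.p2 for m in members])[0],
            ])
        except UndefinedMeanError as exc:
            raise UndefinedMeanError(
                f"class {ntc_class}: {exc}") from exc
        limits = np.minimum(TORSION_LIMIT_CAP, ESD_MULTIPLIER * esds)
        out[ntc_class] = NtcClassDefinition(
            ntc_class=ntc_class,
            cana_letter=ntc_to_cana(ntc_class, cana_map),
            torsion_means=means,
            torsion_esds=esds,
            torsion_limits=limits,
            p_means=p_means,
            confal_c2=calibrate_confal_c2(limits),
            member_count=len(members),
        )
    return out


def build_golden_set(members: list[GoldenSetMember],
                     cana_map: dict[str, str] | None = None,
                     metadata: dict | None = None) -> GoldenSet:
    """Group members by class, compute statistics, assemble a GoldenSet."""
    by_class: dict[str, list[GoldenSetMember]] = {}
    for m in members:
        by_class.setdefault(m.ntc_class, []).append(m)
    classes = compute_class_statistics(by_class, cana_map)
    return GoldenSet(members=list(members), classes=classes,
                     metadata=dict(metadata or {}))


def load_golden_set(path, cana_map: dict[str, str] | None = None) -> GoldenSet:
    """Load a member-level reference table (UTF-8, tab-separated).

    Expected header: member_id, ntc_class, the nine torsions in
    canonical order, P1, P2. Class statistics are recomputed from the
    members so the returned GoldenSet is self-consistent by
    construction.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ReferenceFormatError(f"cannot read reference table: {exc}")
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ReferenceFormatError(
            f"missing columns: {', '.join(missing)}", line=1)
    members = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        ntc_class = str(row["ntc_class"])
        if not _CLASS_ID_RE.match(ntc_class):
            raise ReferenceFormatError(
                f"unknown class identifier pattern {ntc_class!r}", line=line)
        try:
            angles = [float(row[n]) for n in TORSION_NAMES]
            p1, p2 = float(row["P1"]), float(row["P2"])
        except (TypeError, ValueError) as exc:
            raise ReferenceFormatError(f"malformed row: {exc}", line=line)
        if not np.all(np.isfinite(angles + [p1, p2])):
            raise ReferenceFormatError("non-finite torsion value", line=line)
        members.append(GoldenSetMember(
            member_id=str(row["member_id"]),
            ntc_class=ntc_class,
            torsions=StepTorsions.from_values(angles, p1, p2),
        ))
    return build_golden_set(members, cana_map,
                            metadata={"source": str(path)})


def write_golden_set(golden: GoldenSet, path) -> None:
    """Write the member table back out (degrees at 2 decimals)."""
    rows = []
    for m in golden.members:
        row = {"member_id": m.member_id, "ntc_class": m.ntc_class}
        row.update({n: f"{v:.2f}" for n, v in
                    zip(TORSION_NAMES, m.torsions.angles())})
        row["P1"] = f"{m.torsions.p1:.2f}"
        row["P2"] = f"{m.torsions.p2:.2f}"
        rows.append(row)
    pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def class_summary_table(golden: GoldenSet) -> pd.DataFrame:
    """One row per class: means, esds, P-means, c2, CANA letter."""
    rows = []
    for name in sorted(golden.classes):
        d = golden.classes[name]
        row = {"ntc_class": name, "cana": d.cana_letter,
               "n_members": d.member_count}
        row.update({f"mean_{n}": round(v, 2)
                    for n, v in zip(TORSION_NAMES, d.torsion_means)})
        row.update({f"esd_{n}": round(v, 2)
                    for n, v in zip(TORSION_NAMES, d.torsion_esds)})
        row["mean_P1"] = round(float(d.p_means[0]), 2)
        row["mean_P2"] = round(float(d.p_means[1]), 2)
        row["confal_c2"] = round(d.confal_c2, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _default_class_table() -> pd.DataFrame:
    path = resources.files("ntcana.data") / "ntc_classes_synthetic.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def default_golden_set(members_per_class: int = 20,
                       seed: int = 20180525) -> GoldenSet:
    """The packaged default reference, reconstituted deterministically.

    This is a *synthetic* stand-in for a curated golden set: the
    packaged class table holds constructed torsion means and esds for
    the 44-class NtC vocabulary, and members are reconstituted by
    seeded wrapped-normal sampling about those statistics. It exercises
    the full assignment machinery but does not reproduce any
    experimentally curated reference.
    """
    table = _default_class_table()
    rng = np.random.default_rng(seed)
    members: list[GoldenSetMember] = []
    for _, row in table.iterrows():
        cls = str(row["ntc_class"])
        means = np.array([float(row[f"mean_{n}"]) for n in TORSION_NAMES])
        esds = np.array([float(row[f"esd_{n}"]) for n in TORSION_NAMES])
        p_means = np.array([float(row["mean_P1"]), float(row["mean_P2"])])
        p_esd = float(row.get("esd_P", 6.0))
        for k in range(members_per_class):
            angles = np.mod(rng.normal(means, esds), 360.0)
            p1, p2 = np.mod(rng.normal(p_means, p_esd), 360.0)
            members.append(GoldenSetMember(
                member_id=f"{cls}_{k:03d}",
                ntc_class=cls,
                torsions=StepTorsions.from_values(angles, p1, p2),
            ))
    return build_golden_set(
        members, DEFAULT_CANA_MAP,
        metadata={"source": "packaged synthetic reference (reconstituted)",
                  "provenance": "reconstituted", "seed": seed,
                  "members_per_class": members_per_class})
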