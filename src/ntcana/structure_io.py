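"""Reading DNA structures and extracting dinucleotide-step torsions.

A *step* is the dinucleotide fragment running from C5' of one
nucleotide to O3' of the following one: two deoxyriboses, two bases and
the linking phosphate. Its conformation is described by nine torsions
in fixed order

    delta, epsilon, zeta, alpha1, beta1, gamma1, delta1, chi, chi1

(seven backbone torsions plus the two glycosidic torsions of the first
and second nucleotide) together with the pseudorotation puckers of both
sugars. Parsing is delegated to gemmi, which autodetects the PDB and
mmCIF dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .errors import MissingAtomError
from .geometry import (
    TORSION_NAMES,
    SugarPucker,
    dihedral,
    pseudorotation,
)

logger = logging.getLogger(__name__)

#: Standard deoxyribonucleotide residue names.
DNA_RESIDUES = frozenset({"DA", "DC", "DG", "DT"})
PURINES = frozenset({"DA", "DG"})

#: One-letter codes for sequence strings.
ONE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}

#: Maximum O3'(i)-P(i+1) distance accepted as a covalent linkage, in
#: Angstrom (~25% above the ideal bond length; tolerant of poor models).
BOND_CUTOFF = 2.0

#: Physically sensible range for the sugar torsion delta, degrees.
DELTA_RANGE = (75.0, 165.0)

_SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'")

#: Atom quadruples defining the seven backbone torsions. "1:" marks the
#: first nucleotide of the step, "2:" the second.
_BACKBONE_DEFS = {
    "delta": ("1:C5'", "1:C4'", "1:C3'", "1:O3'"),
    "epsilon": ("1:C4'", "1:C3'", "1:O3'", "2:P"),
    "zeta": ("1:C3'", "1:O3'", "2:P", "2:O5'"),
    "alpha1": ("1:O3'", "2:P", "2:O5'", "2:C5'"),
    "beta1": ("2:P", "2:O5'", "2:C5'", "2:C4'"),
    "gamma1": ("2:O5'", "2:C5'", "2:C4'", "2:C3'"),
    "delta1": ("2:C5'", "2:C4'", "2:C3'", "2:O3'"),
}

#: Ring torsions nu0..nu4 of the deoxyribose.
_NU_DEFS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


@dataclass(frozen=True)
class Nucleotide:
    """One DNA residue with its atoms resolved to single coordinates."""

    chain_id: str
    res_num: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def base_type(self) -> str:
        return "purine" if self.name in PURINES else "pyrimidine"

    @property
    def chi_atoms(self) -> tuple[str, str]:
        """Base atoms defining the glycosidic torsion with O4' and C1'."""
        return ("N9", "C4") if self.base_type == "purine" else ("N1", "C2")

    @property
    def label(self) -> str:
        return f"{self.res_num}{self.icode}".strip()

    def coord(self, atom_name: str, context: str = "") -> np.ndarray:
        try:
            return self.atoms[atom_name]
        except KeyError:
            where = f" in {context}" if context else ""
            raise MissingAtomError(
                f"missing atom {atom_name} in residue "
                f"{self.chain_id}/{self.name} {self.label}{where}"
            ) from None


@dataclass(frozen=True)
class Step:
    """Two consecutive, covalently linked nucleotides of one chain."""

    first: Nucleotide
    second: Nucleotide

    @property
    def step_id(self) -> str:
        return f"{self.first.chain_id}.{self.first.label}_{self.second.label}"

    @property
    def sequence(self) -> str:
        return ONE_LETTER[self.first.name] + ONE_LETTER[self.second.name]


@dataclass(frozen=True)
class StepTorsions:
    """The nine-torsion description of one step plus both sugar puckers."""

    delta: float
    epsilon: float
    zeta: float
    alpha1: float
    beta1: float
    gamma1: float
    delta1: float
    chi: float
    chi1: float
    pucker1: SugarPucker
    pucker2: SugarPucker
    flags: tuple[str, ...] = field(default=())

    @property
    def p1(self) -> float:
        return self.pucker1.P

    @property
    def p2(self) -> float:
        return self.pucker2.P

    def angles(self) -> np.ndarray:
        """The nine torsions as an array in canonical order."""
        return np.array([getattr(self, n) for n in TORSION_NAMES], dtype=float)

    @classmethod
    def from_values(cls, angles, p1: float, p2: float,
                    tau1: float = float("nan"),
                    tau2: float = float("nan")) -> "StepTorsions":
        """Build from a nine-vector and the two phase angles only."""
        angles = np.asarray(angles, dtype=float)
        if angles.shape != (9,):
            raise ValueError(f"expected 9 torsions, got shape {angles.shape}")
        kw = dict(zip(TORSION_NAMES, (float(a) % 360.0 for a in angles)))
        return cls(pucker1=SugarPucker(P=float(p1) % 360.0, tau=tau1),
                   pucker2=SugarPucker(P=float(p2) % 360.0, tau=tau2), **kw)

    def with_flags(self, flags) -> "StepTorsions":
        return replace(self, flags=tuple(flags))


@dataclass(frozen=True)
class SkipRecord:
    """Why a nucleotide pair did not yield a step."""

    chain_id: str
    first_label: str
    second_label: str
    reason: str


def _resolve_altlocs(residue: gemmi.Residue) -> dict[str, np.ndarray]:
    """Collapse alternative conformers: highest occupancy wins, ties go
    to the lexicographically smallest altloc identifier."""
    best: dict[str, tuple[float, str, np.ndarray]] = {}
    for atom in residue:
        name = atom.name.replace("*", "'").strip()
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        key = (-float(atom.occ), atom.altloc or "A")
        if name not in best or key < best[name][:2]:
            best[name] = (key[0], key[1], pos)
    return {name: pos for name, (_, _, pos) in best.items()}


def parse_structure(path, model_index: int = 0,
                    modified_map: dict[str, str] | None = None
                    ) -> dict[str, list[Nucleotide]]:
    """Read a PDB/mmCIF file and return its DNA residues per chain.

    Only standard deoxyribonucleotides (DA, DC, DG, DT) are kept;
    waters, ligands, protein and RNA are ignored. ``modified_map`` may
    map modified-residue names to a parent base (e.g. ``{"5MC": "DC"}``)
    to include them. ``model_index`` selects the model of multi-model
    (NMR) files, default first.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        logger.warning("no models in %s", path)
        return {}
    if model_index >= len(st):
        raise IndexError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    modified_map = modified_map or {}
    chains: dict[str, list[Nucleotide]] = {}
    for chain in model:
        residues = []
        for res in chain:
            name = modified_map.get(res.name, res.name)
            if name not in DNA_RESIDUES:
                continue
            residues.append(Nucleotide(
                chain_id=chain.name,
                res_num=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=name,
                atoms=_resolve_altlocs(res),
            ))
        if residues:
            chains[chain.name] = residues
    if not chains:
        logger.warning("no DNA residues found in %s", path)
    return chains


def _step_atom_requirements(nt: Nucleotide, role: str) -> list[str]:
    needed = list(_SUGAR_ATOMS) + list(nt.chi_atoms)
    if role == "second":
        needed += ["P", "O5'"]
    return needed


def extract_steps(nucleotides: dict[str, list[Nucleotide]]
                  ) -> tuple[list[Step], list[SkipRecord]]:
    """Pair consecutive nucleotides of each chain into steps.

    A pair becomes a step only if the O3'(i)-P(i+1) distance is within
    :data:`BOND_CUTOFF` and every atom needed for the nine torsions is
    present; otherwise the pair is skipped and recorded with a reason.
    A chain of n linked nucleotides therefore yields n-1 steps.
    """
    steps: list[Step] = []
    skips: list[SkipRecord] = []

    def skip(a: Nucleotide, b: Nucleotide, reason: str) -> None:
        skips.append(SkipRecord(a.chain_id, a.label, b.label, reason))
        logger.info("skipping %s.%s_%s: %s", a.chain_id, a.label, b.label,
                    reason)

    for chain_id, residues in nucleotides.items():
        for a, b in zip(residues, residues[1:]):
            missing = [
                name for nt, role in ((a, "first"), (b, "second"))
                for name in _step_atom_requirements(nt, role)
                if name not in nt.atoms
            ]
            if missing:
                skip(a, b, f"missing atom {missing[0]}")
                continue
            gap = float(np.linalg.norm(b.atoms["P"] - a.atoms["O3'"]))
            if gap > BOND_CUTOFF:
                skip(a, b, f"chain break: O3'-P distance {gap:.2f} A "
                           f"> {BOND_CUTOFF} A")
                continue
            steps.append(Step(first=a, second=b))
    return steps, skips


def _chi(nt: Nucleotide, context: str) -> float:
    n_atom, c_atom = nt.chi_atoms
    return dihedral(nt.coord("O4'", context), nt.coord("C1'", context),
                    nt.coord(n_atom, context), nt.coord(c_atom, context))


def _pucker(nt: Nucleotide, context: str) -> SugarPucker:
    coords = {name: nt.coord(name, context)
              for name in ("C1'", "C2'", "C3'", "C4'", "O4'")}
    nu = [dihedral(*(coords[n] for n in quad)) for quad in _NU_DEFS]
    return pseudorotation(nu)


def compute_step_torsions(step: Step) -> StepTorsions:
    """Nine torsions and both sugar puckers of one step.

    Raises :class:`MissingAtomError` naming the atom and step if a
    required coordinate is absent. Steps whose delta or delta1 falls
    outside the physically sensible 75-165 deg window are still
    processed but flagged.
    """
    ctx = f"step {step.step_id}"
    nts = {"1": step.first, "2": step.second}
    values = {}
    for name, quad in _BACKBONE_DEFS.items():
        pts = []
        for ref in quad:
            which, atom = ref.split(":")
            pts.append(nts[which].coord(atom, ctx))
        values[name] = dihedral(*pts)
    values["chi"] = _chi(step.first, ctx)
    values["chi1"] = _chi(step.second, ctx)

    flags = []
    for key in ("delta", "delta1"):
        if not (DELTA_RANGE[0] <= values[key] <= DELTA_RANGE[1]):
            flags.append(f"{key}_out_of_range")

    return StepTorsions(
        pucker1=_pucker(step.first, ctx),
        pucker2=_pucker(step.second, ctx),
        flags=tuple(flags),
        **values,
    )


def torsion_table(steps: list[Step],
                  torsions: list[StepTorsions]) -> pd.DataFrame:
    """Tabulate steps and torsions (the --dump-torsions layout)."""
    rows = []
    for step, t in zip(steps, torsions):
        row = {"step_id": step.step_id, "sequence": step.sequence}
        row.update({name: getattr(t, name) for name in TORSION_NAMES})
        row.update({"P1": t.p1, "tau1": t.pucker1.tau,
                    "P2": t.p2, "tau2": t.pucker2.tau})
        rows.append(row)
    return pd.DataFrame(rows)


def read_torsion_table(path) -> tuple[list[str], list[StepTorsions]]:
    """Read a torsion table written by :func:`torsion_table` back in."""
    df = pd.read_csv(path, sep="\t")
    ids = [str(x) for x in df["step_id"]]
    out = []
    for _, row in df.iterrows():
        out.append(StepTorsions.from_values(
            [row[n] for n in TORSION_NAMES], row["P1"], row["P2"],
            tau1=float(row.get("tau1", float("nan"))),
            tau2=float(row.get("tau2", float("nan"))),
        ))
    return ids, out
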