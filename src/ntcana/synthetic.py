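"""Synthetic fixtures: golden sets, noisy candidates and 3D coordinates.

Everything here is deterministic under (spec, seed) so that recovery
experiments and round-trip tests are reproducible without any
downloaded data.

The coordinate builder places atoms by internal-coordinate (NeRF)
chain extension with fixed ideal bond lengths and angles and
caller-supplied dihedrals. The nine step torsions and the glycosidic
geometry are honoured exactly; the deoxyribose rings are built with
their nu2 and nu3 torsions exact and the O4'-C1' ring-closure bond
implied, so the remaining ring torsions (and hence the pseudorotation
phase measured back from the coordinates) are approximate to a few
degrees. Only torsion round-tripping, not absolute geometry, is
guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import BuildError, FixtureSpecError
from .geometry import TORSION_NAMES, circular_diff, pucker_ring_torsions
from .reference import GoldenSet, GoldenSetMember, NtcClassDefinition, \
    build_golden_set
from .structure_io import Nucleotide, StepTorsions

# ---------------------------------------------------------------------------
# statistical fixtures
# ---------------------------------------------------------------------------

#: NtC identifiers used for synthetic fixture classes (all CANA-mapped).
_FIXTURE_CLASS_IDS = ("AA00", "AB01", "BA01", "BB00", "BB01",
                      "BB02", "BB04", "BB07", "BB10", "ZZ1S")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of a synthetic golden set."""

    class_count: int
    members_per_class: int
    torsion_means: np.ndarray  # (class_count, 9), degrees
    esds: np.ndarray           # (class_count, 9), positive degrees
    p_means: np.ndarray        # (class_count, 2), degrees
    seed: int
    p_esd: float = 6.0
    class_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        ids = self.class_ids or tuple(
            _FIXTURE_CLASS_IDS[i % len(_FIXTURE_CLASS_IDS)]
            for i in range(self.class_count))
        object.__setattr__(self, "class_ids", ids)


def default_fixture_spec(class_count: int = 10, members_per_class: int = 30,
                         seed: int = 1) -> FixtureSpec:
    """Well-separated classes: a B-like template rotated by 33 deg per
    class on every torsion, esds of 4 deg (backbone) / 5 deg (chi)."""
    if class_count > 10:
        raise FixtureSpecError("default spec supports at most 10 classes")
    template = np.array([135.0, 187.0, 262.0, 303.0, 179.0, 45.0, 135.0,
                         250.0, 250.0])
    means = np.mod(template[None, :]
                   + 33.0 * np.arange(class_count)[:, None], 360.0)
    esds = np.tile(np.array([4.0] * 7 + [5.0, 5.0]), (class_count, 1))
    p_means = np.mod(155.0 + 20.0 * np.arange(class_count), 360.0)
    p_means = np.stack([p_means, p_means], axis=1)
    return FixtureSpec(class_count=class_count,
                       members_per_class=members_per_class,
                       torsion_means=means, esds=esds, p_means=p_means,
                       seed=seed)


def _check_separation(spec: FixtureSpec) -> None:
    for a in range(spec.class_count):
        for b in range(a + 1, spec.class_count):
            need = 5.0 * float(max(spec.esds[a].max(), spec.esds[b].max()))
            diffs = np.abs(circular_diff(spec.torsion_means[a],
                                         spec.torsion_means[b]))
            if not np.any(diffs >= need):
                raise FixtureSpecError(
                    f"classes {a} and {b} separated by less than "
                    f"5 x largest esd ({need:.1f} deg) in every torsion")


def make_reference_fixture(spec: FixtureSpec) -> GoldenSet:
    """Sample a synthetic golden set from wrapped normals per class."""
    _check_separation(spec)
    rng = np.random.default_rng(spec.seed)
    members: list[GoldenSetMember] = []
    for c in range(spec.class_count):
        cls = spec.class_ids[c]
        for k in range(spec.members_per_class):
            angles = np.mod(rng.normal(spec.torsion_means[c], spec.esds[c]),
                            360.0)
            p1, p2 = np.mod(rng.normal(spec.p_means[c], spec.p_esd), 360.0)
            members.append(GoldenSetMember(
                member_id=f"{cls}_{k:03d}", ntc_class=cls,
                torsions=StepTorsions.from_values(angles, p1, p2)))
    return build_golden_set(members, metadata={
        "source": "synthetic fixture", "seed": spec.seed,
        "class_count": spec.class_count,
        "members_per_class": spec.members_per_class})


def sample_candidates(classdef: NtcClassDefinition, n: int,
                      noise_scale: float, seed: int,
                      p_sigma: float = 5.0) -> list[StepTorsions]:
    """Wrapped-normal candidates about a class's means.

    Torsion sigma is noise_scale times the class esd; the P values are
    sampled about the class P means with sigma = noise_scale * p_sigma.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        angles = np.mod(rng.normal(classdef.torsion_means,
                                   noise_scale * classdef.torsion_esds),
                        360.0)
        p1, p2 = np.mod(rng.normal(classdef.p_means,
                                   noise_scale * p_sigma), 360.0)
        out.append(StepTorsions.from_values(angles, p1, p2))
    return out


# ---------------------------------------------------------------------------
# the packaged 44-class synthetic reference table
# ---------------------------------------------------------------------------

#: Canonical-geometry templates per CANA family:
#: (nine torsion means, P1 mean, P2 mean).
_FAMILY_TEMPLATES = {
    "AAA": ([83, 205, 287, 295, 174, 52, 83, 203, 203], 18, 18),
    "A-B": ([85, 200, 290, 298, 176, 49, 140, 205, 248], 18, 150),
    "B-A": ([138, 185, 263, 300, 178, 48, 85, 248, 205], 152, 18),
    "BBB": ([135, 187, 262, 303, 179, 45, 135, 250, 250], 155, 155),
    "2B1": ([138, 183, 246, 306, 168, 42, 133, 253, 247], 158, 152),
    "3B1": ([134, 188, 262, 150, 178, 182, 135, 249, 251], 154, 156),
    "B12": ([136, 215, 225, 305, 177, 44, 136, 252, 250], 156, 154),
    "BB2": ([137, 250, 180, 300, 176, 43, 138, 255, 250], 158, 152),
    "miB": ([140, 195, 255, 295, 160, 50, 130, 245, 255], 160, 145),
    "SQX": ([140, 190, 260, 300, 175, 47, 140, 65, 250], 155, 155),
    "ZZZ": ([95, 240, 295, 65, 185, 175, 145, 65, 205], 45, 150),
}

#: The 44-class NtC vocabulary shipped with the package, grouped by
#: CANA letter. Eight B-A classes (the explicit enumerations of the
#: other letters total 36, so the merged B-A letter holds eight).
_DEFAULT_CLASSES = {
    "AAA": ["AA00", "AA01", "AA02", "AA03", "AA04"],
    "A-B": ["AB01", "AB02", "AB03"],
    "B-A": ["BA01", "BA05", "BA08", "BA09", "BA10",
            "BA13", "BA16", "BA17"],
    "BBB": ["BB00"],
    "2B1": ["BB01"],
    "3B1": ["BB02", "BB03"],
    "B12": ["BB04", "BB05"],
    "BB2": ["BB07", "BB08"],
    "miB": ["BB10", "BB11", "BB12", "BB13", "BB14", "BB15", "BB16"],
    "SQX": ["AB1S", "BBS1", "BB1S", "BB2S", "NS1S",
            "NS02", "NS03", "NS04", "NS05"],
    "ZZZ": ["ZZ1S", "ZZ2S", "ZZS1", "ZZS2"],
}

#: Torsion indices eligible for per-class offsets (delta and delta1
#: are excluded so sugar/backbone consistency is preserved).
_OFFSET_INDICES = (1, 2, 3, 4, 5, 7, 8)


def default_class_table():
    """The packaged synthetic class table as a DataFrame.

    Each of the 44 classes takes its family's canonical-geometry
    template plus a deterministic per-class offset on two non-sugar
    torsions, keeping classes mutually distinct while staying in the
    family's region of torsion space. Esds are set to values typical of
    tight conformer clusters (3.5-5.5 deg).
    """
    import pandas as pd

    rows = []
    for letter, classes in _DEFAULT_CLASSES.items():
        template, p1, p2 = _FAMILY_TEMPLATES[letter]
        for k, cls in enumerate(classes):
            means = np.array(template, dtype=float)
            if k > 0:
                i = _OFFSET_INDICES[(k - 1) % len(_OFFSET_INDICES)]
                j = _OFFSET_INDICES[(k + 2) % len(_OFFSET_INDICES)]
                sign = 1.0 if k % 2 else -1.0
                means[i] = (means[i] + sign * (12.0 + 3.0 * k)) % 360.0
                means[j] = (means[j] - sign * (9.0 + 2.0 * k)) % 360.0
            esds = np.array([4.0, 4.5, 4.5, 5.0, 3.5, 4.0, 4.0, 5.0, 5.0])
            row = {"ntc_class": cls, "cana": letter}
            row.update({f"mean_{n}": round(v, 2)
                        for n, v in zip(TORSION_NAMES, means)})
            row.update({f"esd_{n}": e
                        for n, e in zip(TORSION_NAMES, esds)})
            row.update({"mean_P1": float(p1), "mean_P2": float(p2),
                        "esd_P": 6.0})
            rows.append(row)
    return pd.DataFrame(rows)


def write_default_class_table(path) -> None:
    """Regenerate the packaged synthetic class table (TSV)."""
    df = default_class_table()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic NtC class table: constructed canonical-geometry"
                 " templates,\n# not curated experimental statistics\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coordinate building
# ---------------------------------------------------------------------------

# ideal bond lengths (Angstrom) and angles (degrees)
_LEN = {
    ("C1'", "C2'"): 1.521, ("C2'", "C3'"): 1.523, ("C3'", "C4'"): 1.528,
    ("C4'", "O4'"): 1.446, ("O4'", "C1'"): 1.414, ("C4'", "C5'"): 1.511,
    ("C5'", "O5'"): 1.423, ("O5'", "P"): 1.593, ("P", "O3'"): 1.607,
    ("C3'", "O3'"): 1.423, ("C1'", "N"): 1.475, ("N", "C"): 1.372,
}
_ANG = {
    "C1'-C2'-C3'": 101.5, "C2'-C3'-C4'": 102.6, "C3'-C4'-O4'": 105.6,
    "C3'-C4'-C5'": 114.7, "C4'-C3'-O3'": 110.3, "C3'-O3'-P": 119.7,
    "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.9, "O5'-C5'-C4'": 110.2,
    "C5'-C4'-C3'": 115.5, "C4'-C3'-C2'": 102.6, "C3'-C2'-C1'": 101.5,
    "O4'-C1'-N": 108.2, "C1'-N-C": 126.3,
}

#: Improper offset (deg) of C5' from O4' about the C3'->C4' axis.
_C5_OFFSET = -119.0
#: Improper offset (deg) of the base nitrogen from C2' about O4'->C1'.
_N_OFFSET = -120.0
#: Expected delta from nu3 under the builder's improper geometry.
_DELTA_FROM_NU3 = 121.0
#: Tolerated delta / sugar-pucker mismatch (deg).
_DELTA_PUCKER_TOL = 45.0

_PURINES = {"A": ("N9", "C4"), "G": ("N9", "C4")}
_PYRIMIDINES = {"C": ("N1", "C2"), "T": ("N1", "C2")}
_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

#: Physically sensible delta window, degrees.
_DELTA_WINDOW = (75.0, 165.0)


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float
          ) -> np.ndarray:
    """Place atom d such that dihedral(a, b, c, d) equals torsion_deg."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class NucleotideGeometry:
    """Per-nucleotide internal coordinates for the builder."""

    base: str       # one-letter A/C/G/T
    delta: float
    chi: float
    P: float
    tau: float = 36.0


@dataclass(frozen=True)
class JunctionGeometry:
    """Backbone torsions linking nucleotide i to i+1."""

    epsilon: float
    zeta: float
    alpha: float
    beta: float
    gamma: float


def _validate_nucleotide(spec: NucleotideGeometry, index: int) -> np.ndarray:
    nu = pucker_ring_torsions(spec.P, spec.tau)
    lo, hi = _DELTA_WINDOW
    if not (lo <= spec.delta % 360.0 <= hi):
        raise BuildError(
            f"nucleotide {index + 1}: delta {spec.delta:.1f} outside the "
            f"physically sensible {lo}-{hi} deg window")
    expected = nu[3] + _DELTA_FROM_NU3
    if abs(circular_diff(spec.delta, expected)) > _DELTA_PUCKER_TOL:
        raise BuildError(
            f"nucleotide {index + 1}: delta {spec.delta:.1f} inconsistent "
            f"with pucker P={spec.P:.1f} (expected near {expected % 360:.1f})")
    return nu


def build_chain(nucleotides: list[NucleotideGeometry],
                junctions: list[JunctionGeometry],
                chain_id: str = "A",
                origin=(0.0, 0.0, 0.0)) -> list[Nucleotide]:
    """Build Cartesian coordinates for a linked chain of nucleotides.

    ``junctions`` must have one entry fewer than ``nucleotides``. The
    result is a list of :class:`~ntcana.structure_io.Nucleotide` ready
    for torsion extraction or PDB export.
    """
    if len(junctions) != len(nucleotides) - 1:
        raise BuildError("need exactly len(nucleotides)-1 junctions")
    origin = np.asarray(origin, dtype=float)
    out: list[Nucleotide] = []
    prev: dict[str, np.ndarray] = {}
    for i, spec in enumerate(nucleotides):
        nu = _validate_nucleotide(spec, i)
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            # seed the first sugar in a local frame
            atoms["C1'"] = origin + np.zeros(3)
            atoms["C2'"] = origin + np.array([_LEN[("C1'", "C2'")], 0.0, 0.0])
            ang = np.radians(180.0 - _ANG["C1'-C2'-C3'"])
            atoms["C3'"] = atoms["C2'"] + _LEN[("C2'", "C3'")] * np.array(
                [np.cos(ang), np.sin(ang), 0.0])
            atoms["C4'"] = _nerf(atoms["C1'"], atoms["C2'"], atoms["C3'"],
                                 _LEN[("C3'", "C4'")], _ANG["C2'-C3'-C4'"],
                                 nu[2])
            atoms["C5'"] = _nerf(atoms["C2'"], atoms["C3'"], atoms["C4'"],
                                 _LEN[("C4'", "C5'")], _ANG["C3'-C4'-C5'"],
                                 nu[3] + _C5_OFFSET)
        else:
            j = junctions[i - 1]
            p_prev = out[i - 1]
            atoms["P"] = _nerf(p_prev.atoms["C4'"], p_prev.atoms["C3'"],
                               p_prev.atoms["O3'"], _LEN[("P", "O3'")],
                               _ANG["C3'-O3'-P"], j.epsilon)
            atoms["O5'"] = _nerf(p_prev.atoms["C3'"], p_prev.atoms["O3'"],
                                 atoms["P"], _LEN[("O5'", "P")],
                                 _ANG["O3'-P-O5'"], j.zeta)
            atoms["C5'"] = _nerf(p_prev.atoms["O3'"], atoms["P"],
                                 atoms["O5'"], _LEN[("C5'", "O5'")],
                                 _ANG["P-O5'-C5'"], j.alpha)
            atoms["C4'"] = _nerf(atoms["P"], atoms["O5'"], atoms["C5'"],
                                 _LEN[("C4'", "C5'")], _ANG["O5'-C5'-C4'"],
                                 j.beta)
            atoms["C3'"] = _nerf(atoms["O5'"], atoms["C5'"], atoms["C4'"],
                                 _LEN[("C3'", "C4'")], _ANG["C5'-C4'-C3'"],
                                 j.gamma)
            atoms["C2'"] = _nerf(atoms["C5'"], atoms["C4'"], atoms["C3'"],
                                 _LEN[("C2'", "C3'")], _ANG["C4'-C3'-C2'"],
                                 nu[3] + _C5_OFFSET)
            atoms["C1'"] = _nerf(atoms["C4'"], atoms["C3'"], atoms["C2'"],
                                 _LEN[("C1'", "C2'")], _ANG["C3'-C2'-C1'"],
                                 nu[2])
        atoms["O4'"] = _nerf(atoms["C2'"], atoms["C3'"], atoms["C4'"],
                             _LEN[("C4'", "O4'")], _ANG["C3'-C4'-O4'"],
                             nu[3])
        atoms["O3'"] = _nerf(atoms["C5'"], atoms["C4'"], atoms["C3'"],
                             _LEN[("C3'", "O3'")], _ANG["C4'-C3'-O3'"],
                             spec.delta)
        n_name, c_name = (_PURINES.get(spec.base)
                          or _PYRIMIDINES[spec.base])
        atoms[n_name] = _nerf(atoms["C4'"], atoms["O4'"], atoms["C1'"],
                              _LEN[("C1'", "N")], _ANG["O4'-C1'-N"],
                              nu[0] + _N_OFFSET)
        atoms[c_name] = _nerf(atoms["O4'"], atoms["C1'"], atoms[n_name],
                              _LEN[("N", "C")], _ANG["C1'-N-C"], spec.chi)
        out.append(Nucleotide(chain_id=chain_id, res_num=i + 1, icode="",
                              name=_RESNAME[spec.base], atoms=atoms))
    return out


def _specs_from_step(torsions: StepTorsions, sequence: str
                     ) -> tuple[list[NucleotideGeometry],
                                list[JunctionGeometry]]:
    tau1 = torsions.pucker1.tau
    tau2 = torsions.pucker2.tau
    nts = [
        NucleotideGeometry(base=sequence[0], delta=torsions.delta,
                           chi=torsions.chi, P=torsions.p1,
                           tau=36.0 if np.isnan(tau1) else tau1),
        NucleotideGeometry(base=sequence[1], delta=torsions.delta1,
                           chi=torsions.chi1, P=torsions.p2,
                           tau=36.0 if np.isnan(tau2) else tau2),
    ]
    junctions = [JunctionGeometry(epsilon=torsions.epsilon,
                                  zeta=torsions.zeta, alpha=torsions.alpha1,
                                  beta=torsions.beta1, gamma=torsions.gamma1)]
    return nts, junctions


def build_step_coordinates(torsions: StepTorsions, sequence: str = "AT",
                           chain_id: str = "A") -> list[Nucleotide]:
    """Coordinates of one dinucleotide step realizing the given torsions.

    The nine torsions round-trip through torsion extraction to within
    numerical precision. Raises :class:`BuildError` for delta values
    outside 75-165 deg or delta/pucker combinations that no deoxyribose
    can realize (e.g. delta near 80 with a C2'-endo ring).
    """
    if len(sequence) != 2:
        raise BuildError("sequence must name exactly two bases")
    nts, junctions = _specs_from_step(torsions, sequence)
    return build_chain(nts, junctions, chain_id=chain_id)


def chain_from_steps(steps: list[StepTorsions], sequence: str,
                     chain_id: str = "A",
                     origin=(0.0, 0.0, 0.0)) -> list[Nucleotide]:
    """Build an n-nucleotide chain from n-1 step torsion vectors.

    Consecutive steps share their middle nucleotide, so step i's
    (delta1, chi1, P2) must agree with step i+1's (delta, chi, P1)
    within 0.5 deg.
    """
    n = len(steps) + 1
    if len(sequence) != n:
        raise BuildError(f"sequence length {len(sequence)} != {n}")
    for i in range(len(steps) - 1):
        for a, b, label in ((steps[i].delta1, steps[i + 1].delta, "delta"),
                            (steps[i].chi1, steps[i + 1].chi, "chi"),
                            (steps[i].p2, steps[i + 1].p1, "P")):
            if abs(circular_diff(a, b)) > 0.5:
                raise BuildError(
                    f"steps {i} and {i + 1} disagree on shared {label}")
    nts = []
    junctions = []
    for i, s in enumerate(steps):
        s_nts, s_junctions = _specs_from_step(
            s, sequence[i:i + 2])
        if i == 0:
            nts.append(s_nts[0])
        nts.append(s_nts[1])
        junctions.extend(s_junctions)
    return build_chain(nts, junctions, chain_id=chain_id, origin=origin)


def write_pdb(path, chains: list[list[Nucleotide]]) -> None:
    """Write built nucleotides as a minimal PDB file."""
    st = gemmi.Structure()
    st.name = "ntcana-synthetic"
    model = gemmi.Model(1)
    for residues in chains:
        if not residues:
            continue
        chain = gemmi.Chain(residues[0].chain_id)
        for nt in residues:
            res = gemmi.Residue()
            res.name = nt.name
            res.seqid = gemmi.SeqId(nt.res_num, " ")
            for name, pos in nt.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                atom.element = gemmi.Element(name[0])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_mmcif(path, chains: list[list[Nucleotide]],
                precision: int = 6) -> None:
    """Write built nucleotides as a minimal mmCIF _atom_site loop.

    Unlike the fixed-column PDB format (3 decimals, which limits
    torsion round-trips to ~0.05 deg), coordinates are written with
    enough precision for sub-0.01-deg round-trips.
    """
    from gemmi import cif

    doc = cif.Document()
    block = doc.add_new_block("ntcana_synthetic")
    loop = block.init_loop("_atom_site.", [
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_seq_id", "auth_seq_id",
        "auth_asym_id", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
        "B_iso_or_equiv", "pdbx_PDB_model_num",
    ])
    serial = 0
    for residues in chains:
        for nt in residues:
            for name, pos in nt.atoms.items():
                serial += 1
                loop.add_row([
                    "ATOM", str(serial), name[0], cif.quote(name), ".",
                    nt.name, nt.chain_id, str(nt.res_num), str(nt.res_num),
                    nt.chain_id,
                    f"{pos[0]:.{precision}f}", f"{pos[1]:.{precision}f}",
                    f"{pos[2]:.{precision}f}", "1.00", "0.00", "1",
                ])
    doc.write_file(str(path))


def make_duplex_pdb(path, step_torsions: StepTorsions | None = None,
                    n_nt: int = 12) -> None:
    """Write a two-chain synthetic duplex-like fixture (12+12 nt).

    Both chains repeat a single homogeneous step conformation (default:
    a canonical BI-like geometry); the second chain is a translated
    copy, not a base-paired partner — base pairing is out of scope for
    these fixtures.
    """
    if step_torsions is None:
        step_torsions = StepTorsions.from_values(
            [135.0, 187.0, 262.0, 303.0, 179.0, 45.0, 135.0, 250.0, 250.0],
            155.0, 155.0)
    steps = [step_torsions] * (n_nt - 1)
    seq = ("CGCGAATTCGCG" * ((n_nt // 12) + 1))[:n_nt]
    chain_a = chain_from_steps(steps, seq, chain_id="A")
    chain_b = chain_from_steps(steps, seq, chain_id="B",
                               origin=(30.0, 0.0, 0.0))
    write_pdb(path, [chain_a, chain_b])
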