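"""The CANA structural alphabet: grouping NtC classes into 12 letters.

CANA (Conformational Alphabet of Nucleic Acids) compresses the NtC
dinucleotide conformer classes into eleven structural letters — A-form
(AAA), the A/B bridges (A-B, B-A), canonical BI (BBB), minor BI
variants (2B1, 3B1), the BI/BII bridge (B12), BII (BB2), minor B forms
(miB), syn/quadruplex-associated conformers (SQX) and Z-forms (ZZZ) —
plus NAN for unassigned steps.
"""

from __future__ import annotations

from .errors import UnmappedClassError

NAN = "NAN"

#: The eleven structural letters (NAN excluded).
CANA_LETTERS = ("AAA", "A-B", "B-A", "BBB", "2B1", "3B1", "B12", "BB2",
                "miB", "SQX", "ZZZ")


def _expand() -> dict[str, str]:
    groups: dict[str, list[str]] = {
        "AAA": [f"AA{i:02d}" for i in range(5)],
        "A-B": ["AB01", "AB02", "AB03"],
        "B-A": [f"BA{i:02d}" for i in range(1, 11)]
               + [f"BA{i:02d}" for i in range(13, 18)],
        "BBB": ["BB00"],
        "2B1": ["BB01"],
        "3B1": ["BB02", "BB03"],
        "B12": ["BB04", "BB05"],
        "BB2": ["BB07", "BB08"],
        "miB": [f"BB{i:02d}" for i in range(10, 17)],
        "SQX": ["AB1S", "BBS1", "BB1S", "BB2S", "NS1S",
                "NS02", "NS03", "NS04", "NS05"],
        "ZZZ": ["ZZ1S", "ZZ2S", "ZZS1", "ZZS2"],
    }
    return {cls: letter for letter, classes in groups.items()
            for cls in classes}


#: Default NtC -> CANA mapping covering every identifier the grouped
#: class-range notation spans.
DEFAULT_CANA_MAP: dict[str, str] = _expand()

#: Finer split of the B-A letter by class number.
_B1A_CLASSES = frozenset(f"BA{i:02d}" for i in range(1, 11))
_B2A_CLASSES = frozenset(f"BA{i:02d}" for i in range(13, 18))


def ntc_to_cana(ntc_class: str, mapping: dict[str, str] | None = None,
                split_ba: bool = False) -> str:
    """CANA letter for an NtC class identifier; NAN maps to NAN.

    Raises :class:`UnmappedClassError` for identifiers absent from the
    mapping (never silently NAN). With ``split_ba`` the merged B-A
    letter is reported as B1A (BA01-BA10) or B2A (BA13-BA17).
    """
    if ntc_class == NAN:
        return NAN
    mapping = DEFAULT_CANA_MAP if mapping is None else mapping
    try:
        letter = mapping[ntc_class]
    except KeyError:
        raise UnmappedClassError(
            f"NtC class {ntc_class!r} has no CANA letter") from None
    if split_ba and letter == "B-A":
        if ntc_class in _B1A_CLASSES:
            return "B1A"
        if ntc_class in _B2A_CLASSES:
            return "B2A"
    return letter


def load_cana_map(path) -> dict[str, str]:
    """Read a two-column (ntc_class, cana) tab-separated mapping file."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return {str(r["ntc_class"]): str(r["cana"]) for _, r in df.iterrows()}


def cana_string(assignments) -> str:
    """Space-separated CANA tokens for an ordered list of assignments."""
    return " ".join(a.cana_letter for a in assignments)


def cana_strings_by_chain(assignments) -> dict[str, str]:
    """Per-chain CANA strings; chain inferred from the step-id prefix."""
    by_chain: dict[str, list] = {}
    for a in assignments:
        chain = a.step_id.split(".", 1)[0] if "." in a.step_id else ""
        by_chain.setdefault(chain, []).append(a)
    return {chain: cana_string(items) for chain, items in by_chain.items()}
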