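"""Exception hierarchy for ntcana."""


class NtcanaError(Exception):
    """Base class for all ntcana errors."""


class DegenerateGeometryError(NtcanaError):
    """Three consecutive points defining a dihedral are collinear."""


class UndefinedMeanError(NtcanaError):
    """Circular mean requested for a sample with (near-)zero resultant."""


class FlatRingError(NtcanaError):
    """Pseudorotation undefined: all ring torsions vanish."""


class ContractError(NtcanaError):
    """A caller violated an interface contract (e.g. wrong dimensionality)."""


class MissingAtomError(NtcanaError):
    """An atom required for a torsion is absent from a nucleotide."""


class ReferenceFormatError(NtcanaError):
    """A golden-set reference table is malformed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InsufficientReferenceError(NtcanaError):
    """Golden set too small for k-NN assignment."""


class UnmappedClassError(NtcanaError):
    """An NtC class identifier has no CANA letter in the mapping."""


class FixtureSpecError(NtcanaError):
    """A synthetic fixture specification violates its preconditions."""


class BuildError(NtcanaError):
    """Coordinate building from internal coordinates failed."""


class NoStepsError(NtcanaError):
    """A structure-level quantity was requested for an empty step list."""
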