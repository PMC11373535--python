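"""Exception types shared across the package."""


class CsensError(Exception):
    """Base class for all package-specific errors."""


class StructureMismatchError(CsensError):
    """Models of a multi-model structure disagree in atom count or ordering."""


class SelectionError(CsensError):
    """An atom/residue selection is empty, unknown or otherwise invalid."""


class CappingError(CsensError):
    """A chain break cannot be capped (missing donor atoms)."""


class ReferencingError(CsensError):
    """Shielding-to-shift conversion is impossible (wrong element, missing reference)."""


class CoverageError(CsensError):
    """A residue is covered zero or more than one time as a central unit."""


class JoinError(CsensError):
    """Tables cannot be joined on atom identity."""
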