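"""Exception hierarchy.

All package errors derive from :class:`MDShiftError` so callers can catch
one base class; subclasses mirror the failure domains (file format,
selection resolution, geometry, window arithmetic, spec validation).
"""


class MDShiftError(Exception):
    """Base class for all errors raised by mdshift."""


class FormatError(MDShiftError):
    """A file could not be parsed or is internally inconsistent."""


class SelectionError(MDShiftError):
    """A residue/atom selection resolved to nothing or is ambiguous."""


class GeometryError(MDShiftError):
    """A geometric operation received a degenerate configuration."""


class WindowError(MDShiftError):
    """A frame window is empty or out of range."""


class SpecValidationError(MDShiftError):
    """A synthetic-ensemble or pocket specification is invalid."""


class AlignmentError(MDShiftError):
    """Two per-residue profiles or topologies could not be aligned."""


class StageError(MDShiftError):
    """A pipeline stage failed or an unknown stage was requested."""
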