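"""Exception hierarchy for cdftpep.

All package errors derive from :class:`CdftpepError` so callers can catch a
single base class at pipeline boundaries.
"""


class CdftpepError(Exception):
    """Base class for all cdftpep errors."""


class UnitError(CdftpepError, ValueError):
    """An energy unit name is not recognised."""


class SchemaError(CdftpepError, ValueError):
    """An input table violates the documented energetics schema."""


class ConflictError(SchemaError):
    """Two rows claim the same (molecule, functional, solvent, charge) slot."""


class MissingSpeciesError(CdftpepError, ValueError):
    """An operation needs a charged species that a partial triad lacks."""


class MissingDataError(CdftpepError, ValueError):
    """A required field (orbital energy, SOMO, ...) is absent."""


class CubeFormatError(CdftpepError, ValueError):
    """A volumetric file does not conform to the Gaussian cube convention."""


class GridMismatchError(CdftpepError, ValueError):
    """Two density grids do not share origin, axes and shape."""


class UndefinedValueError(CdftpepError, ZeroDivisionError):
    """A descriptor is undefined for the given input (e.g. zero gap)."""


class CoverageError(CdftpepError, ValueError):
    """A synthetic grid extent does not cover the requested density."""


class VocabularyError(CdftpepError, ValueError):
    """A property or target name is outside the fixed reporting vocabulary."""
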