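"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors -> 1, data/validation
errors -> 2, numerical failures -> 3.
"""


class RenodiffError(Exception):
    """Base class for all package errors."""


class FormatError(RenodiffError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(RenodiffError):
    """In-memory data violates a documented invariant or precondition."""


class FitError(RenodiffError):
    """A voxel-wise fit could not be carried out (rank deficiency,
    too few usable measurements after outlier rejection, ...)."""


class DegenerateDataError(RenodiffError):
    """Statistical input carries no usable information (e.g. all paired
    differences are zero)."""
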