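"""Exception hierarchy for rbfseg.

All rbfseg-specific failures derive from :class:`RbfsegError` so callers can
catch the package's errors with one clause.  Input/contract violations are
also ``ValueError`` subclasses; numerical degeneracies get their own types so
the CLI can map them to distinct exit codes.
"""


class RbfsegError(Exception):
    """Base class for all rbfseg errors."""


class InputError(RbfsegError, ValueError):
    """Malformed or out-of-contract user input (bad shapes, coords, counts)."""


class FormatError(InputError):
    """Unsupported or malformed image/file format."""


class DegenerateCentersError(RbfsegError, ValueError):
    """Center set unusable: fewer than two centers, or all centers coincide
    (the shared Gaussian width is undefined when the maximum pairwise
    distance is zero)."""


class SingularActivationsError(RbfsegError, ValueError):
    """Rank-deficient hidden-activation matrix with ridge = 0; the
    least-squares weight solve has no unique solution.  Retry with a small
    positive ridge."""


class SamplingError(InputError):
    """A class does not have enough eligible pixels to sample."""


class TrainingError(RbfsegError, RuntimeError):
    """Training could not produce a usable network."""


class ModelError(InputError):
    """Model/feature mismatch at inference time."""


class RenderError(InputError):
    """Palette does not cover every class present in a label image."""


class ArchiveError(RbfsegError, RuntimeError):
    """Archive manifest problems (duplicate ids, failed hash verification)."""
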