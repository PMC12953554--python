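"""Exception hierarchy shared across the package.

Every anticipated failure mode gets its own class so callers (and the CLI,
which maps them to distinct exit codes) can react specifically.
"""


class EduKineticsError(Exception):
    """Base class for all package errors."""


class ValidationError(EduKineticsError):
    """An input violates a documented invariant; the message names it."""


class InsufficientDataError(EduKineticsError):
    """Too few timepoints / replicates for the requested fit."""


class NoSaturationError(EduKineticsError):
    """The curve never reaches a detectable plateau (still rising at the end),
    or has no rise segment at all, so Tc cannot be located."""


class NoGrowthError(EduKineticsError):
    """The fitted rise has non-positive slope; the linear-rise inversion
    Tc = GF/slope is undefined."""


class UnstableFitError(EduKineticsError):
    """More than the allowed fraction of bootstrap replicates failed to fit."""
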