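"""Exception hierarchy for envregimes.

All errors raised by the library derive from :class:`EnvRegimesError`, so
callers (and the CLI) can catch one base class.
"""


class EnvRegimesError(Exception):
    """Base class for all envregimes errors."""


class FormatError(EnvRegimesError):
    """A file could not be parsed (bad date, missing header, wrong layout)."""


class ValidationError(EnvRegimesError):
    """An input violates a structural invariant (ordering, duplicates, bounds)."""


class GapError(ValidationError):
    """A series has calendar gaps under the strict regularity policy."""


class WindowError(EnvRegimesError):
    """A realized window is unusable (e.g. contains no non-missing values)."""
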