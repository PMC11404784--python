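"""Exception hierarchy shared across the toolkit.

All anticipated failure modes raise a subclass of :class:`PathkitError` so
that callers (and the CLI) can distinguish data problems (exit code 1) from
usage problems (exit code 2, handled by click itself).
"""


class PathkitError(Exception):
    """Base class for all errors raised by pathkit."""


class FormatError(PathkitError):
    """A file did not conform to its expected on-disk format."""


class AmbiguousDialectError(FormatError):
    """A DEG table header matched more than one known dialect."""


class ValidationError(PathkitError):
    """Input data violated an invariant (duplicates, out-of-range values...)."""
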