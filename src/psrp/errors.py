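"""Exception hierarchy.

Validation problems (bad inputs, contract violations, failed sample QC) and
I/O problems are kept distinct so the command-line layer can map them to
separate exit codes (2 and 3 respectively).
"""


class PsrpError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PsrpError):
    """Input violates a documented contract (bad value, missing gene, ...)."""


class ParseError(ValidationError):
    """A file does not conform to its dialect; message names the offending
    row, gene or cell."""


class QCError(ValidationError):
    """A sample failed quality control and is unusable (e.g. an undetected
    housekeeping gene)."""


class ConfigError(ValidationError):
    """A configuration object is internally inconsistent."""
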