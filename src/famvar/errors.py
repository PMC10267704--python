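"""Exception hierarchy shared across the package.

``FamvarError`` is the base for everything the pipeline raises on its own
authority; callers that want a single except-clause around a whole run can
catch it. Subclasses distinguish *what kind* of problem occurred so the CLI
can map them onto exit codes and name the offending file/record.
"""


class FamvarError(Exception):
    """Base class for all errors raised by famvar."""


class ParseError(FamvarError):
    """A file could not be parsed (malformed VCF/TSV record)."""


class FormatError(FamvarError):
    """A file parsed but violates the expected format contract (e.g. no GT)."""


class ValidationError(FamvarError):
    """Parsed data violates a domain invariant (duplicate sample id, ...)."""


class DataError(FamvarError):
    """A record is internally inconsistent (non-missing genotype, zero reads)."""


class ConfigError(FamvarError):
    """A configuration value is out of range or self-contradictory."""
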