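"""Exception hierarchy for haplopred.

All exceptions derive from :class:`HaplopredError` so callers can catch the
package's failures with a single ``except`` clause; each subclass maps to one
failure family (bad configuration, malformed input files, undefined
statistics, structural pedigree problems).
"""


class HaplopredError(Exception):
    """Base class for all haplopred errors."""


class ConfigurationError(HaplopredError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(HaplopredError, ValueError):
    """Inconsistent or out-of-range in-memory inputs (dimension mismatches,
    bad indices, unknown modes)."""


class ParseError(HaplopredError, ValueError):
    """A file could not be parsed under the package's format contracts
    (e.g. unphased or multi-allelic VCF records)."""


class MonomorphicLocusError(HaplopredError, ValueError):
    """LD is undefined because one locus carries a single allele."""


class PedigreeCycleError(HaplopredError, ValueError):
    """The pedigree graph contains a cycle; the message lists it."""


class UndefinedCorrelationError(HaplopredError, ValueError):
    """A correlation-based statistic was requested on a constant vector."""
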