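"""Exception hierarchy for devocompare."""


class DevocompareError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DevocompareError):
    """An invalid configuration value; the message names the offending field."""


class ConsistencyError(DevocompareError):
    """Inputs that should have come from the same generation/run disagree."""


class MissingDataError(DevocompareError):
    """A gene, chromosome, replicate or marker required by an operation is absent."""
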