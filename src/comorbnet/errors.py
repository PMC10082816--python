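"""Exception hierarchy shared across the pipeline stages."""


class ComorbnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ComorbnetError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(ComorbnetError):
    """An input table is missing required columns or contains illegal values."""


class IntegrityError(ComorbnetError):
    """Cross-table referential integrity violated (unknown ids, overlaps)."""


class GenerationError(ComorbnetError):
    """The synthetic cohort generator cannot honour its inputs."""


class MatchingError(ComorbnetError):
    """Propensity-score estimation or matching cannot proceed."""


class ContractError(ComorbnetError):
    """A stage received input that violates an upstream contract."""
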