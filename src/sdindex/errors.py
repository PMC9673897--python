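"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config 2, input 3, stage 4).
"""


class SDIndexError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SDIndexError):
    """Invalid configuration (bad thresholds, infeasible generator targets...)."""


class InputError(SDIndexError):
    """Unreadable, malformed or schema-violating input data."""


class StageError(SDIndexError):
    """A pipeline stage failed on structurally valid input."""
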