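"""Exception hierarchy shared across the pipeline stages."""


class SeedscapeError(Exception):
    """Base class for all package errors."""


class ConfigError(SeedscapeError):
    """A configuration value is missing or inconsistent with the inputs."""


class InputError(SeedscapeError):
    """An input file violates its format contract."""


class ContractError(SeedscapeError):
    """A function precondition or internal invariant was violated."""


class PipelineError(SeedscapeError):
    """A pipeline stage produced an unusable result (e.g. empty gene list)."""
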