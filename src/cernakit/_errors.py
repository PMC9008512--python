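"""Exception hierarchy shared across the toolkit."""


class CernakitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CernakitError, ValueError):
    """Invalid input data or parameters."""


class GenerationError(CernakitError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""


class PipelineError(CernakitError, RuntimeError):
    """A pipeline stage failed; message names the stage and offending inputs."""
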