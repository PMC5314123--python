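"""Exception hierarchy shared by all pipeline stages."""


class CrossmethError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CrossmethError, ValueError):
    """A study or run configuration is invalid; the message names the field."""


class InputError(CrossmethError, ValueError):
    """An input table violates a precondition (shape, sign, domain, alignment)."""


class PipelineError(CrossmethError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
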