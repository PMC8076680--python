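"""Exception types shared across the package."""


class IrgpiError(Exception):
    """Base class for all errors raised by irgpi."""


class FormatError(IrgpiError):
    """A file could not be parsed (bad cell, short line, duplicate name...)."""


class ValidationError(IrgpiError):
    """Inputs violate a documented precondition (missing genes, empty group...)."""


class PipelineError(IrgpiError):
    """A pipeline stage failed; the message is prefixed with the stage name."""
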