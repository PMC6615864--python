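"""Exception hierarchy for the pipeline."""


class DropscreenError(ValueError):
    """Base class for all pipeline errors."""


class ValidationError(DropscreenError):
    """A domain-type invariant was violated (duplicate ids, bad alphabet...)."""


class FormatError(DropscreenError):
    """A file could not be parsed under the documented dialect."""


class DesignError(DropscreenError):
    """The experimental design is unusable (e.g. a tF group with no t0)."""
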