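"""Exception hierarchy shared across the pipeline."""


class FamdivergeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FamdivergeError, ValueError):
    """An input file violates its declared format or dialect."""


class ValidationError(FamdivergeError, ValueError):
    """An in-memory object or configuration violates an invariant."""
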