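"""Exception types shared across the package."""


class DreamPPLError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DreamPPLError, ValueError):
    """An argument violates a documented precondition."""


class ContractError(DreamPPLError):
    """A language-model or windowing contract was violated."""


class AdapterLoadError(DreamPPLError):
    """A pretrained-model adapter could not resolve its backend or weights."""


class EmptyOverlapError(DreamPPLError):
    """Range-matched sampling found no pool item inside the target range."""
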