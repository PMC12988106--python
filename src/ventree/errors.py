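"""Exception hierarchy for the ventree pipeline."""


class VentreeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(VentreeError):
    """An invalid parameter, design, or unknown compound-class label."""


class MalformedRunError(VentreeError):
    """A raw run violates its invariants (e.g. non-monotone retention times)."""


class UndefinedSimilarityError(VentreeError):
    """Spectral similarity requested for an empty spectrum."""


class InternalConsistencyError(VentreeError):
    """A structural invariant that should hold by construction was violated."""


class NewickParseError(VentreeError):
    """Malformed Newick input; carries the approximate character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (near position {position})"
        super().__init__(message)
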