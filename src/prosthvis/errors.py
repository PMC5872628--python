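"""Exception hierarchy shared by every pipeline stage."""


class ProsthvisError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ProsthvisError, ValueError):
    """An input raster/mask/graph violates a precondition (shape, emptiness, range)."""


class InvalidParameterError(ProsthvisError, ValueError):
    """A tunable parameter is outside its documented range."""


class DegenerateInputError(ProsthvisError, ValueError):
    """The input is formally valid but carries no usable signal (e.g. a constant map)."""


class NumericalError(ProsthvisError, ArithmeticError):
    """A linear solve or other numeric step failed; the message carries diagnostics."""
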