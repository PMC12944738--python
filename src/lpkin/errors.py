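"""Exception hierarchy for the lpkin pipeline."""


class LpkinError(Exception):
    """Base class for all lpkin errors."""


class ParseError(LpkinError):
    """A detection file or table could not be parsed (names file and line)."""


class ValidationError(LpkinError):
    """An input record violates a structural invariant (e.g. corner count)."""


class DegenerateGeometryError(LpkinError):
    """A box or trajectory has no usable geometry (zero area, zero radius)."""


class InsufficientDataError(LpkinError):
    """Too few frames or pairs to carry out the requested computation."""


class ConfigurationError(LpkinError):
    """A configuration value is out of its valid range."""


class DegenerateDataError(LpkinError):
    """The data admit no well-defined estimate (e.g. zero-variance differences)."""
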