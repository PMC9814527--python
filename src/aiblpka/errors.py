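"""Exception hierarchy for the aiblpka package."""


class AiblError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AiblError):
    """A structure or table file could not be parsed."""


class UnsupportedDialectError(ParseError):
    """A recognised format in an unsupported dialect (e.g. MOL V3000)."""


class FragmentNotFoundError(AiblError):
    """No keto-enol fragment could be located in a molecule."""


class DegenerateFitError(AiblError):
    """A regression fit is degenerate (e.g. zero variance in x)."""


class NumericalError(AiblError):
    """A numerical routine failed beyond recovery (e.g. non-PD kernel)."""
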