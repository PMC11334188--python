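"""Exception hierarchy for platecal."""


class PlatecalError(Exception):
    """Base class for all platecal errors."""


class ConfigurationError(PlatecalError):
    """A scheme/simulation parameter combination is inconsistent."""


class InstructionError(PlatecalError):
    """A transfer list cannot realize the requested plate map."""


class SimulationError(PlatecalError):
    """Execution of an instruction list reached an unphysical state."""


class FitError(PlatecalError):
    """A model fit is degenerate or rank deficient."""


class InversionError(PlatecalError):
    """A response model cannot be inverted for the given value."""


class ParseError(PlatecalError):
    """An input file does not conform to the expected dialect."""
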