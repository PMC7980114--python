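"""Exception hierarchy shared across the toolkit."""


class PulsemanError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(PulsemanError, ValueError):
    """A configuration or argument value is out of its admissible range."""


class ContractError(PulsemanError, ValueError):
    """Inputs violate an interface contract (schema/length mismatch etc.)."""


class DegenerateSignalError(PulsemanError, ValueError):
    """The signal carries no usable information (e.g. zero variance)."""


class UndefinedFeatureError(PulsemanError, ValueError):
    """A feature is undefined for this input (e.g. flat cardiac cycle)."""


class InsufficientContextError(PulsemanError, ValueError):
    """Not enough surrounding signal to compute a windowed quantity."""


class InsufficientDataError(PulsemanError, ValueError):
    """Too few observations for the requested estimate."""


class FormatError(PulsemanError, ValueError):
    """An input file does not match the documented format."""


class SpecError(PulsemanError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
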