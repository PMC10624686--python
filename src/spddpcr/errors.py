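"""Exception hierarchy for spddpcr."""


class SpddpcrError(Exception):
    """Base class for all package errors."""


class InputError(SpddpcrError, ValueError):
    """Invalid argument value (bad sequence, counts, thresholds...)."""


class StrategyParseError(SpddpcrError, ValueError):
    """Primer-strategy notation could not be parsed."""


class StrategyError(SpddpcrError, ValueError):
    """Strategy is syntactically valid but semantically impossible."""


class GeometryError(SpddpcrError, ValueError):
    """Primer segments do not fit on the template around the variant."""


class DesignError(SpddpcrError, RuntimeError):
    """No primer satisfying the design constraints could be found."""


class FormatError(SpddpcrError, ValueError):
    """A file does not conform to its documented schema."""
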