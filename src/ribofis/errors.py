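"""Exception hierarchy for ribofis."""


class RibofisError(Exception):
    """Base class for all ribofis-specific errors."""


class FuzzyDefinitionError(RibofisError):
    """Invalid membership function, variable, rule or model geometry."""


class OutOfRangeError(RibofisError):
    """A crisp value lies outside the universe of discourse of its variable."""


class MissingInputError(RibofisError):
    """A rule antecedent references a variable with no supplied crisp value."""


class NoRuleFiredError(RibofisError):
    """Every rule fired at strength zero; the prediction is undefined."""


class DataError(RibofisError):
    """Malformed or inconsistent dose-response data."""


class InsufficientCoverageError(RibofisError):
    """Dose-response data activates fewer than two input terms; no usable rule base."""
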