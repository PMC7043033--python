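"""Exception hierarchy for leafskew."""


class LeafSkewError(Exception):
    """Base class for all leafskew errors."""


class InputError(LeafSkewError):
    """Unreadable, malformed or inconsistent input."""


class ConfigurationError(LeafSkewError):
    """An option combination that cannot be honoured (e.g. alpha rule on an RGB file)."""


class DegenerateInputError(LeafSkewError):
    """Structurally valid input on which the operation is undefined (empty mask, zero variance)."""


class FitError(LeafSkewError):
    """A model fit failed to converge or the design is rank deficient."""
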