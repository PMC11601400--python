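"""Package exception hierarchy."""


class FacdisError(Exception):
    """Base class for all facdis errors."""


class ValidationError(FacdisError, ValueError):
    """Invalid input values (negative rates, bad units, malformed tables)."""


class IdentifiabilityError(FacdisError):
    """The requested fit is structurally under-determined by the data."""


class NonDissociatingError(FacdisError):
    """The kinetic network has no pathway for the partner to leave the chip."""
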