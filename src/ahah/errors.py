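"""Exception hierarchy for the AHAH pipeline.

Every contract violation raises a subclass of :class:`AHAHError` carrying a
one-line actionable message; the CLI maps these to nonzero exit codes.
"""


class AHAHError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(AHAHError):
    """Invalid or infeasible configuration (names the violated constraint)."""


class ValidationError(AHAHError):
    """Input data violates a structural precondition."""


class ParseError(AHAHError):
    """A file could not be parsed against its declared schema."""


class UnreachableError(AHAHError):
    """One or more origins cannot reach any facility on the road network."""

    def __init__(self, postcodes: list[str], category: str):
        self.postcodes = list(postcodes)
        self.category = category
        super().__init__(
            f"{len(self.postcodes)} postcode(s) cannot reach any "
            f"'{category}' facility: {', '.join(self.postcodes[:10])}"
            + ("..." if len(self.postcodes) > 10 else "")
        )
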