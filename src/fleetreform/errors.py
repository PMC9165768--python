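"""Exception hierarchy.

Every error raised by the library derives from :class:`FleetReformError`
so callers (and the CLI) can catch one base class.
"""

from __future__ import annotations


class FleetReformError(Exception):
    """Base class for all library errors."""


class ConfigurationError(FleetReformError):
    """An input configuration is invalid; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DomainError(FleetReformError):
    """A numeric argument is outside the domain of an operation."""


class MissingRateError(FleetReformError, KeyError):
    """An allocation rate is missing for a (flag_state, region) or flag_state key."""

    def __init__(self, key):
        self.key = key
        super().__init__(f"no allocation rate for {key!r}")


class UnknownSubsidyTypeError(FleetReformError, KeyError):
    """A subsidy type has no effective-subsidy multiplier."""

    def __init__(self, subsidy_type: str):
        self.subsidy_type = subsidy_type
        super().__init__(f"no effective-subsidy multiplier for type {subsidy_type!r}")


class SimulationError(FleetReformError):
    """The projection produced a non-finite state; carries a diagnostic dump."""

    def __init__(self, message: str, state: dict | None = None):
        self.state = state or {}
        detail = f"{message}; state: {self.state}" if state else message
        super().__init__(detail)
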