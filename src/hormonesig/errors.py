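"""Exception hierarchy shared across the toolkit."""


class HormonesigError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(HormonesigError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(HormonesigError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class BedParseError(DataError):
    """Malformed BED record; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class CapacityError(ConfigError):
    """Genome too small to place the requested sites disjointly."""
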