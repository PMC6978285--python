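"""Exception hierarchy shared across the package."""


class InterraiError(Exception):
    """Base class for all package errors."""


class RegistryError(InterraiError):
    """Raised when an instrument registry violates its structural contract."""


class ConfigError(InterraiError):
    """Raised when a scale / CAP / simulation configuration is malformed."""


class RecordParseError(InterraiError):
    """Raised for malformed assessment files; carries line and item context."""

    def __init__(self, message: str, line: int | None = None, item: str | None = None):
        self.line = line
        self.item = item
        context = []
        if line is not None:
            context.append(f"line {line}")
        if item is not None:
            context.append(f"item {item!r}")
        suffix = f" ({', '.join(context)})" if context else ""
        super().__init__(message + suffix)


class UndefinedStatisticError(InterraiError):
    """Raised when a statistic is undefined for the given data (e.g. zero variance)."""
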