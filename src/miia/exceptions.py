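"""Exception hierarchy for the miia package."""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple


class MiiaError(Exception):
    """Base class for all errors raised by miia."""


class MembershipError(MiiaError):
    """A species was queried outside the membership of a culture."""


class ParseError(MiiaError):
    """A file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataCompletenessError(MiiaError):
    """Required cultures are missing from an observation set."""

    def __init__(self, missing: Sequence[str], what: str = "cultures"):
        self.missing = tuple(missing)
        super().__init__(
            f"missing required {what}: {', '.join(self.missing)}"
        )


class UnidentifiableError(MiiaError):
    """A coefficient cannot be estimated from the available data."""

    def __init__(self, message: str, pairs: Iterable[Tuple[str, str]] = ()):
        self.pairs = tuple(pairs)
        if self.pairs:
            listed = ", ".join(f"{i}<-{j}" for i, j in self.pairs)
            message = f"{message}: {listed}"
        super().__init__(message)


class DegenerateConstraintError(MiiaError):
    """All partner abundances vanish so the focal constraint is ill-posed."""


class InconsistentConstraintError(MiiaError):
    """A vanished constraint demands a nonzero abundance change."""


class GenerationError(MiiaError):
    """A synthetic dataset could not be generated from the given truth."""


class ConfigError(MiiaError):
    """A run configuration is invalid."""
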