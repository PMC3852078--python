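"""Exception types shared across the package."""


class CrossnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CrossnetError, ValueError):
    """A parameter is outside its documented range."""


class InsufficientReplicatesError(CrossnetError, ValueError):
    """A statistical test was asked to run with fewer than two replicates."""


class DegenerateInputError(CrossnetError, ValueError):
    """The input is structurally valid but too small/empty for the operation."""


class ParseError(CrossnetError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")


class ConfigError(CrossnetError, ValueError):
    """Pipeline configuration is invalid; aggregates all violations."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
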