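"""Errors and warning categories used across the package."""


class RailPatternError(Exception):
    """Base class for all package errors."""


class DomainError(RailPatternError, ValueError):
    """A physical quantity is outside its valid domain (e.g. D <= 0)."""


class ConfigError(RailPatternError, ValueError):
    """An options/config object is internally inconsistent."""


class NoSolutionError(RailPatternError, ValueError):
    """A design boundary has no positive solution for the given inputs."""


class DeviceValidationError(RailPatternError, ValueError):
    """A device spec failed validation; carries all violations at once."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"{len(self.violations)} violation(s): {lines}")


class DeviceParseError(RailPatternError, ValueError):
    """A device JSON file failed schema checks; carries all messages."""

    def __init__(self, messages, path=None):
        self.messages = list(messages)
        self.path = path
        prefix = f"{path}: " if path else ""
        super().__init__(prefix + "; ".join(self.messages))


class BoundaryWarning(UserWarning):
    """Two critical pressures are exactly equal: the geometry sits on a
    design boundary and the classification is resolved by convention."""


class TieWarning(UserWarning):
    """Two interfaces share an identical threshold; event order falls
    back to the deterministic lexicographic tie-break."""


class FilmTrapWarning(UserWarning):
    """A lane with two equal open ports traps a liquid film and will not
    clear at any modelled pressure."""
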