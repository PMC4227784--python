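"""Exception hierarchy.

``InputError`` covers malformed user data (CLI exit code 1); everything
else raised by the package derives from :class:`MagscanError`.
"""


class MagscanError(Exception):
    """Base class for all magscan errors."""


class InputError(MagscanError):
    """Malformed or inconsistent user-supplied data."""


class SchemaError(InputError):
    """A tabular input is missing required columns/fields."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing required fields: {', '.join(self.missing)}")


class ParameterError(MagscanError):
    """Invalid model or algorithm parameter."""


class FitError(MagscanError):
    """A curve or model fit failed or the data are degenerate."""


class StateError(MagscanError):
    """An operation was called before its prerequisites were computed."""
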