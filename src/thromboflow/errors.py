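"""Exception hierarchy.

All errors derive from :class:`ThromboflowError` so callers can catch the
package's failures with one clause; each subclass also derives from the
built-in it most resembles (ValueError for bad inputs) so idiomatic
``except ValueError`` code keeps working.
"""


class ThromboflowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ThromboflowError, ValueError):
    """A model or operation parameter violates its precondition."""


class TraceInputError(ThromboflowError, ValueError):
    """A sensor trace is unusable (too short, empty, non-finite...)."""


class TraceParseError(ThromboflowError, ValueError):
    """A trace or manifest file could not be parsed."""


class ConfigError(ThromboflowError, ValueError):
    """A simulation configuration is inconsistent or uncalibratable."""
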