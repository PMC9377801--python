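"""Exception hierarchy shared across the package."""


class PremoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PremoError, ValueError):
    """A model parameter is outside its mathematical domain."""


class ScheduleError(PremoError, ValueError):
    """A trial schedule is malformed or internally inconsistent."""


class RegimeError(PremoError, ValueError):
    """A closed form was requested outside its regime of validity."""


class TrialTableError(PremoError, ValueError):
    """A trial table violates the canonical file contract."""


class FitError(PremoError, RuntimeError):
    """Estimation cannot proceed (degenerate data or empty free set)."""
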