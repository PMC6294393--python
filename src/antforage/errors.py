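"""Package-wide exception types.

All user-facing errors derive from :class:`AntforageError` so callers can
catch one base class; the subclasses mirror the failure modes of the model
components (bad parameters, out-of-domain evaluation, degenerate dynamical
regimes, numerical integration failure).
"""


class AntforageError(Exception):
    """Base class for all antforage errors."""


class InvalidParameterError(AntforageError, ValueError):
    """A model or operation parameter violates its contract (e.g. tau <= 0)."""


class DomainError(AntforageError, ValueError):
    """An evaluation point lies outside the operation's domain."""


class DegenerateRegimeError(AntforageError, ValueError):
    """Parameters place the oscillator in a degenerate regime (c*eps2 >= 1,
    or c = 0 where the recovery equilibrium is unconstrained)."""


class IntegrationFailureError(AntforageError, RuntimeError):
    """The numerical integration diverged or produced non-finite state."""


class ConfigError(AntforageError, ValueError):
    """A run-configuration file failed schema validation."""
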