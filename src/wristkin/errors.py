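"""Exception hierarchy for wristkin.

Input/format problems derive from :class:`WristkinInputError`; failures of a
computation on otherwise well-formed input derive from
:class:`WristkinComputationError`.  The CLI maps the former to exit code 2 and
the latter to exit code 1.
"""


class WristkinError(Exception):
    """Base class for all wristkin errors."""


class WristkinInputError(WristkinError, ValueError):
    """Malformed, missing, or schema-violating input."""


class WristkinComputationError(WristkinError, RuntimeError):
    """A pipeline stage failed on well-formed input."""


class InvalidInputError(WristkinInputError):
    """Non-finite or structurally invalid numeric input."""


class FormatError(WristkinInputError):
    """A file does not match its documented CSV/JSON layout."""


class ConfigError(WristkinInputError):
    """A run configuration failed schema validation."""


class DegenerateGeometryError(WristkinComputationError):
    """Observation geometry does not determine a unique solution
    (e.g. magnetic field parallel to gravity)."""


class NonStaticError(WristkinComputationError):
    """A window assumed static shows too much motion/acceleration."""


class IllConditionedFitError(WristkinComputationError):
    """A least-squares fit is rank deficient or numerically singular."""


class InsufficientRestError(WristkinComputationError):
    """Rest window too short to seed the orientation filter."""


class InsufficientExcursionError(WristkinComputationError):
    """Calibration movement covers too little rotation to be usable."""


class UnstableBaselineError(WristkinComputationError):
    """The baseline window contains motion; cannot define the limb axis."""


class InsufficientDataError(WristkinComputationError):
    """Too few samples for the requested operation."""


class NoValidDataError(WristkinComputationError):
    """A stream contains no valid samples at all."""


class SynchronizationError(WristkinComputationError):
    """Two trajectories are not on the same timeline."""


class SegmentationError(WristkinComputationError):
    """Hold/rest intervals overlap or fall outside the recording."""


class TargetLookupError(WristkinComputationError, KeyError):
    """A requested target label has no data."""


class UndefinedMetricError(WristkinComputationError):
    """A metric's denominator (or other prerequisite) is degenerate."""


class ReachabilityError(WristkinComputationError):
    """A requested wrist target lies outside the reachable workspace."""
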