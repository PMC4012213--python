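"""Exception hierarchy for rewardnet.

All package errors derive from :class:`RewardNetError` so callers can catch
one base class at the CLI boundary.
"""


class RewardNetError(Exception):
    """Base class for all rewardnet errors."""


class ParameterError(RewardNetError, ValueError):
    """A scalar parameter is outside its admissible range."""


class BoundsError(RewardNetError, ValueError):
    """A time index (onset/offset) is outside the template window."""


class UnsupportedTemplateError(RewardNetError, ValueError):
    """Unknown stimulus-template or kernel kind."""


class ShapeError(RewardNetError, ValueError):
    """Array shapes are inconsistent with the network dimension."""


class EmptyMemoriesError(RewardNetError, ValueError):
    """A memory set with no patterns was supplied."""


class NumericalStateError(RewardNetError, FloatingPointError):
    """Non-finite values entered the network state."""


class InstabilityError(RewardNetError, RuntimeError):
    """The rate vector exceeded the divergence guard during integration."""

    def __init__(self, t: int, norm: float, bound: float):
        self.t = t
        self.norm = norm
        self.bound = bound
        super().__init__(
            f"rate dynamics diverged at step {t}: ||v||_inf = {norm:.3g} "
            f"exceeds guard {bound:.3g}"
        )


class EnumerationTooLargeError(RewardNetError, ValueError):
    """Exact state enumeration was requested beyond the size bound."""


class InsufficientRecordError(RewardNetError, ValueError):
    """A trace lacks the weight snapshots needed for re-analysis."""


class StagedError(RewardNetError, RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")
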