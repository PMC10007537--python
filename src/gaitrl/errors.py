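"""Exception hierarchy for gaitrl.

All package-raised errors derive from :class:`GaitRLError` so callers can
catch one base class at tool boundaries (CLI, run_experiment).
"""


class GaitRLError(Exception):
    """Base class for all gaitrl errors."""


class ValidationError(GaitRLError, ValueError):
    """Invalid numeric input (NaN kinematics, negative temperature, ...)."""


class ShapeError(GaitRLError, ValueError):
    """Dimension or length mismatch between coupled arrays."""


class AlignmentError(GaitRLError, ValueError):
    """Two time series that must share a time base do not."""


class FormatError(GaitRLError, ValueError):
    """A file on disk does not conform to the expected tabular schema."""


class ContractError(GaitRLError, ValueError):
    """A call violates an interface contract (bad id, exhausted store, ...)."""


class ConfigError(GaitRLError, ValueError):
    """Run configuration is inconsistent or out of range."""
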