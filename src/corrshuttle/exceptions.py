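"""Exception hierarchy shared across the package.

All errors derive from :class:`CorrShuttleError` so callers can catch the
package's failures with one clause; subclasses mirror the failure domains
(parameter validation, file formats, site selection, frame alignment, ...).
"""


class CorrShuttleError(Exception):
    """Base class for all corrshuttle errors."""


class ParameterError(CorrShuttleError, ValueError):
    """A numeric or structural parameter is out of its valid domain."""


class FormatError(CorrShuttleError, ValueError):
    """A trajectory file has an unknown or unsupported format."""


class StructureError(CorrShuttleError, ValueError):
    """Frames within one trajectory disagree on site count or ordering."""


class SelectionError(CorrShuttleError, ValueError):
    """A site selector matched zero or more than the expected sites."""


class AlignmentError(CorrShuttleError, ValueError):
    """Two frame-aligned inputs differ in length or timestamps."""


class LabelError(CorrShuttleError, ValueError):
    """Series with incompatible pair labels were combined."""


class EmptyTrajectoryError(CorrShuttleError, ValueError):
    """An operation removed every frame of a trajectory."""


class DataError(CorrShuttleError, ValueError):
    """Input data are empty or otherwise unusable for the computation."""


class DegenerateFitError(CorrShuttleError, ValueError):
    """A superposition was requested on too few or collinear sites."""


class NoPathError(CorrShuttleError, ValueError):
    """The requested endpoints are disconnected in the graph."""


class ConfigError(CorrShuttleError, ValueError):
    """A pipeline configuration failed validation."""
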