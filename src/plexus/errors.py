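"""Exception hierarchy for the plexus package.

Every failure mode the pipeline can hit deliberately (degenerate mixture
fits, infeasible phantom geometry, empty masks, malformed configs) raises a
distinct subclass of :class:`PlexusError` so callers can react per stage.
"""


class PlexusError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PlexusError, ValueError):
    """An argument is outside its documented domain (e.g. sigma <= 0)."""


class FitError(PlexusError):
    """A mixture fit could not be completed (too few samples, non-finite
    values, or variance collapse below the configured floor)."""


class GeometryError(PlexusError):
    """Phantom geometry is infeasible, e.g. a choroid-plexus blob cannot be
    placed fully inside the ventricle interior."""


class CalibrationError(PlexusError):
    """A cohort-simulation target (partial correlation) is unattainable."""


class MaskError(PlexusError):
    """A mask precondition failed (empty initial mask, out-of-grid edit)."""


class FormatError(PlexusError):
    """A file does not satisfy the expected on-disk format contract."""


class ConfigError(PlexusError, ValueError):
    """A pipeline configuration is invalid; the message names the field."""


class SegmentationError(PlexusError):
    """A pipeline stage failed; carries the stage tag for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
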