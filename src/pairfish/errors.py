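"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PairfishError`, so callers (and the
plate runner, which skips failing wells rather than aborting the run) can
catch pipeline failures without masking programming errors.
"""


class PairfishError(Exception):
    """Base class for all pipeline errors."""


class ChannelError(PairfishError):
    """An operation received an image plane of the wrong channel."""


class DegenerateHistogramError(PairfishError):
    """Thresholding a histogram with fewer than two occupied intensities."""


class DegenerateNucleusError(PairfishError):
    """A nucleus too small to compute per-nucleus statistics."""


class AlignmentError(PairfishError):
    """Channel raster does not match the segmentation frame."""


class PlacementError(PairfishError):
    """The simulator could not place the requested nuclei."""


class LayoutError(PairfishError):
    """Invalid or inconsistent plate layout."""


class GroupingError(PairfishError):
    """Foci from different nuclei were mixed in a per-nucleus operation."""


class EmptyWellError(PairfishError):
    """A well with no scoreable nuclei."""


class InsufficientControlsError(PairfishError):
    """Too few control nuclei/wells to derive a control-based cutoff."""


class DegeneratePlateError(PairfishError):
    """Plate statistics cannot be formed (too few wells or zero spread)."""


class ReplicateError(PairfishError):
    """Replicate plates do not share a layout."""


class SampleSizeError(PairfishError):
    """A statistical test was given too few observations."""


class DegenerateVarianceError(PairfishError):
    """Both samples constant with unequal values: no variance to test against."""


class ConfigError(PairfishError):
    """Invalid configuration file or parameter set."""


class FormatError(PairfishError):
    """Unreadable or inconsistent input file."""
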