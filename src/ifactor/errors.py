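"""Exception hierarchy.

``DataError`` subclasses mark problems with the *input* (empty channels,
degenerate images, unusable ROIs) as opposed to internal failures; the CLI
maps them to a distinct exit code.
"""


class IFactorError(Exception):
    """Base class for all package-specific errors."""


class DataError(IFactorError):
    """Input data is unusable (empty, degenerate, wrong shape)."""


class NoClustersError(DataError):
    """An operation that needs at least one cluster got an empty channel.

    Raised instead of silently returning 0 so that "no interaction" and
    "nothing to measure" stay distinguishable.
    """


class DegenerateImageError(DataError):
    """Image content does not support the requested operation
    (e.g. constant intensities inside the ROI for Otsu thresholding,
    zero variance for the Pearson coefficient)."""


class PlacementError(IFactorError):
    """A cluster cannot be placed (no valid anchor inside the ROI)."""


class NonInvertibleProfileError(IFactorError):
    """The random-overlap profile does not determine a unique IF for the
    observed overlap fraction (every per-cluster probability is 0 or 1)."""
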