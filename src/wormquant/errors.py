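"""Exception hierarchy.

Every pipeline stage raises a subclass of :class:`WormQuantError` so batch
drivers can catch one type, attach the stage identity, and keep going.
"""


class WormQuantError(Exception):
    """Base class for all wormquant errors."""


class SegmentationError(WormQuantError):
    """Segmentation failed: no worm, clipped worm, or coiled/overlapping worm."""


class MidlineError(WormQuantError):
    """Skeleton has no usable tip-to-tip path."""


class TransectError(WormQuantError):
    """A perpendicular width transect failed to exit the mask."""


class LumenBandError(WormQuantError):
    """No dark luminal band detected on a transect."""


class EventLogError(WormQuantError):
    """Behavioral event log is malformed or too short for the requested statistic."""


class PlateError(WormQuantError):
    """Plate-reader table is malformed or missing required wells."""


class GeometryError(WormQuantError):
    """A synthetic worm specification is unrenderable (self-intersecting or out of bounds)."""
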