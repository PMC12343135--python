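"""Exception hierarchy for the myomorph pipeline.

Every stage raises a subclass of :class:`MyomorphError` so callers can
distinguish quality-control rejections from programming errors.
"""


class MyomorphError(Exception):
    """Base class for all myomorph errors."""


# --- simulation ---------------------------------------------------------
class InvalidSpec(MyomorphError):
    """A myofibril specification violates its geometric invariants."""


class SpecOutOfCanvas(MyomorphError):
    """A myofibril does not fit inside the requested canvas."""


# --- segmentation -------------------------------------------------------
class EmptyStack(MyomorphError):
    """An image stack with no z-planes."""


class NothingSegmented(MyomorphError):
    """No connected component passed the segmentation filters."""


class BranchedSkeleton(MyomorphError):
    """The mask skeleton has more than two endpoints; no unique centerline."""


class TooShort(MyomorphError):
    """Centerline shorter than the minimum analysable length after trimming."""


# --- profiles -----------------------------------------------------------
class OutOfBounds(MyomorphError):
    """A profile ROI leaves the image."""


# --- model fitting ------------------------------------------------------
class NoPeaks(MyomorphError):
    """No peaks found in the profile."""


class FitDiverged(MyomorphError):
    """The least-squares optimiser failed to converge."""


class TooFewPeaks(MyomorphError):
    """Not enough fitted peaks to form the requested distances."""


class DegenerateProfile(MyomorphError):
    """Profile carries too little signal for a disc fit."""


class TooFewConverged(MyomorphError):
    """Fewer than half of the per-position disc fits converged."""


# --- morphometrics ------------------------------------------------------
class NegativeLength(MyomorphError):
    """Band widths imply a non-positive filament length."""


class EmptyInput(MyomorphError):
    """Summary requested over zero measurements."""


# --- lattice ------------------------------------------------------------
class InvalidCount(MyomorphError):
    """Filament count outside the valid range."""


class NoInteriorSites(MyomorphError):
    """Lattice too small to contain a fully coordinated thick filament."""


class NotInterior(MyomorphError):
    """Requested site is on the lattice boundary."""


class NonPositiveGrowth(MyomorphError):
    """Filament count did not increase over the interval."""


class GeometryError(MyomorphError):
    """Three-dimensional sarcomere model has inverted filament spans."""


# --- I/O ----------------------------------------------------------------
class MissingPixelSize(MyomorphError):
    """No physical pixel size in metadata and no override given."""


class ChannelCountError(MyomorphError):
    """Image file does not provide the two required channels."""
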