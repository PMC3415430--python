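"""Exception types shared across the pipeline stages."""


class SosError(Exception):
    """Base class for all pipeline errors."""


class OutOfArenaError(SosError):
    """A synthetic body extends beyond the arena ("out_of_arena")."""


class DegenerateHistogramError(SosError):
    """Automatic thresholding on a constant image ("degenerate_histogram")."""


class NoObjectError(SosError):
    """No foreground object in a binary mask ("no_object" / "no_animal")."""


class BackgroundIncompleteError(SosError):
    """The animal never vacated its initial box ("background_incomplete")."""

    def __init__(self, message: str, background=None):
        super().__init__(message)
        self.background = background


class BranchedSkeletonError(SosError):
    """Skeleton has more than two endpoints ("branched")."""


class AmbiguousSeedError(SosError):
    """Head and tail hints select the same endpoint ("ambiguous_seed")."""


class FlatFieldError(SosError):
    """Zero stimulus gradient where a bearing was requested ("flat_field")."""


class ZeroBaselineError(SosError):
    """Relative change against a zero baseline ("zero_baseline")."""


class IncompatibleUnitsError(SosError):
    """Trials with different stimulus units cannot be merged."""
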