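"""Exception hierarchy shared by all vfinger modules."""


class VFError(Exception):
    """Base class for all vfinger errors."""


class FormatError(VFError):
    """A file could not be read or written in a supported volume format."""


class NoPathError(VFError):
    """Fast marching exhausted the search region without reaching a sink."""


class NoPointError(VFError):
    """A pinpoint operation had no usable ray samples."""


class NoCurveError(VFError):
    """Curve generation failed (bad first ray or an unreachable ray)."""


class EmptyStrokeError(VFError):
    """Every ray of a stroke missed the volume."""


class MetricError(VFError):
    """A curve metric was asked to compare degenerate (zero-length) curves."""


class PhantomError(VFError):
    """A phantom specification does not fit the requested volume dims."""


class IntegrityError(VFError):
    """An octree store is missing or inconsistent on disk."""
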