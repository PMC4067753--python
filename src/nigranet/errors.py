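"""Exception hierarchy for nigranet.

All package-specific failures derive from :class:`NigranetError` so callers
can catch one base class. Analysis routines raise rather than silently
returning sentinel values; "no event detected" style outcomes that are part
of normal operation are represented in return values, not exceptions, except
where a quantity is genuinely undefined (e.g. FWHM of a flat histogram).
"""


class NigranetError(Exception):
    """Base class for all nigranet errors."""


class InvalidSpecError(NigranetError, ValueError):
    """A generator or simulation spec violates its invariants."""


class ResolutionError(NigranetError, ValueError):
    """Sampling interval too coarse for the requested kinetics."""


class DegenerateKernelError(NigranetError, ValueError):
    """Rise and decay time constants coincide; the dual-exponential form
    is degenerate and an alpha function is NOT silently substituted."""


class AccuracyError(NigranetError, ValueError):
    """Integration step too coarse for a reliable simulation."""


class IntegrationError(NigranetError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class EventNotDetectedError(NigranetError, RuntimeError):
    """No synaptic event onset found within the search window."""


class NoThresholdError(NigranetError, RuntimeError):
    """Phase-plot dV/dt never reaches the threshold criterion."""


class UndefinedFWHMError(NigranetError, RuntimeError):
    """PSTH has no bin above baseline; width at half maximum undefined."""


class UndefinedCorrelationError(NigranetError, RuntimeError):
    """Zero variance in one coordinate; Pearson r undefined."""


class WindowCollisionError(NigranetError, ValueError):
    """Stimulus rate too high for non-overlapping measurement windows."""


class DegenerateBaselineError(NigranetError, ValueError):
    """Baseline SD is zero; z-score based classification undefined."""


class InsufficientDataError(NigranetError, ValueError):
    """Too few samples/pairs to compute the requested statistic."""


class FitNotIdentifiableError(NigranetError, RuntimeError):
    """Too few retained bins (or degenerate geometry) to fit the model."""


class AnnotationError(NigranetError, ValueError):
    """Grid edge annotations are inconsistent (e.g. non-perpendicular)."""


class ResampleRequiredError(NigranetError, ValueError):
    """Two images are not on the same raster; resample before comparing."""
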