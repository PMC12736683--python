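"""Exception hierarchy for gaitevents.

All package errors derive from :class:`GaitEventsError` so callers can catch
one base class; the subclasses mirror the failure modes of the individual
stages (configuration, signal geometry, detector degeneracies, statistics,
file I/O).
"""


class GaitEventsError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(GaitEventsError):
    """A configuration object violates one of its documented invariants."""


class ParameterError(GaitEventsError):
    """An operation parameter is outside its valid range (cutoff >= Nyquist,
    even median order, wavelet scale too large for the signal, ...)."""


class SignalTooShortError(GaitEventsError):
    """The input signal has too few samples for the requested operation."""


class AlignmentError(GaitEventsError):
    """Two signals that must share sampling rate / start time / length do not."""


class DomainError(GaitEventsError):
    """A closed-form profile was evaluated outside its domain."""


class DegenerateThresholdError(GaitEventsError):
    """An adaptive velocity threshold computed to exactly zero (zero-mean,
    zero-variance quiet window).  Configure ``threshold_floor`` on
    :class:`~gaitevents.omc.Omc2Params` to proceed on noise-free signals."""


class NormalizationDegenerateError(GaitEventsError):
    """Amplitude normalization requested on an all-zero axis."""


class UndefinedStatisticError(GaitEventsError):
    """A summary statistic was requested on an input for which it is
    undefined (empty error list, non-positive mean, fewer than two values)."""


class PairingError(GaitEventsError):
    """Paired statistics received sequences of unequal length."""


class ManifestError(GaitEventsError):
    """A trial manifest is malformed, references missing files, or declares
    sampling rates inconsistent with the channel files."""
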