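"""Exception types shared across the pipeline."""


class HRVStreamError(Exception):
    """Base class for all package-specific errors."""


class MalformedPacketError(HRVStreamError, ValueError):
    """A heart-rate-measurement payload violates the characteristic layout."""


class InsufficientDataError(HRVStreamError, ValueError):
    """Too few intervals/samples for the requested computation.

    Distinct from a *withheld* metric: raised only when a caller asks for a
    quantity that is mathematically undefined at the given sample size (for
    example RMSSD of a single interval). Gated outcomes (the >=10-NN rule,
    the HF-power floor) are represented as ``None`` values, never as errors.
    """


class OrderingError(HRVStreamError, ValueError):
    """Beat times pushed out of order into a rolling buffer."""
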