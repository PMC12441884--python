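"""Exception hierarchy for the mrcyt package."""


class MrcytError(Exception):
    """Base class for all package-specific errors."""


class InvalidTimingError(MrcytError, ValueError):
    """Waveform timing does not fit inside the echo time."""


class HardwareLimitError(MrcytError, ValueError):
    """Requested gradient amplitude exceeds the hardware cap."""


class InvalidWaveformError(MrcytError, ValueError):
    """Waveform violates a physical invariant (e.g. not refocused)."""


class ProtocolError(MrcytError, ValueError):
    """Acquisition protocol is inconsistent (missing waveform, no b=0 anchor, ...)."""


class DegenerateBalanceError(MrcytError, ValueError):
    """Exchange model requested with v_in = 1 and k_in > 0 (no extracellular pool)."""


class NumericalError(MrcytError, RuntimeError):
    """A numerical routine failed to converge within its caps."""


class DataError(MrcytError, ValueError):
    """Input signal data violate preconditions (non-positive, NaN, wrong length)."""


class FormatError(MrcytError, ValueError):
    """On-disk data do not match the declared protocol/layout."""
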