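"""Exception hierarchy.

Every failure mode documented by the pipeline raises a subclass of
:class:`TdiError` with a stable, descriptive message so callers (and the CLI)
can distinguish bad inputs from bugs.
"""


class TdiError(ValueError):
    """Base class for all tdiquant errors."""


class CalibrationError(TdiError):
    """Layout, zero-axis or scale read-out failed."""


class EnvelopeError(TdiError):
    """Thresholding, filtering or trace extraction failed."""


class BeatError(TdiError):
    """Cycle-length estimation or beat detection failed."""


class AgreementError(TdiError):
    """Agreement statistics undefined for the given input."""


class SyntheticError(TdiError):
    """Synthetic waveform/render parameters are inconsistent."""
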