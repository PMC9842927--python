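"""Exception hierarchy for the hopfec package."""

from __future__ import annotations


class HopfecError(Exception):
    """Base class for all package-specific errors."""


class NumericalDivergenceError(HopfecError):
    """Integration produced non-finite values (reduce ``dt`` or the coupling).

    Attributes
    ----------
    volume_index : int
        Index of the first retained sample at which a non-finite value
        was observed.
    """

    def __init__(self, volume_index: int, message: str | None = None):
        self.volume_index = volume_index
        super().__init__(
            message
            or f"non-finite state at retained sample {volume_index}; "
            "reduce dt or the coupling strength"
        )


class DegenerateSignalError(HopfecError):
    """One or more regions carry a constant (zero-variance) signal."""

    def __init__(self, regions, message: str | None = None):
        self.regions = list(regions)
        super().__init__(
            message or f"constant signal in region(s): {', '.join(map(str, self.regions))}"
        )


class MatrixFormatError(HopfecError):
    """A delimited matrix/timeseries file violates the expected layout."""


class FitDivergenceError(HopfecError):
    """The fit metric decreased persistently; carries the metric history."""

    def __init__(self, history, message: str | None = None):
        self.history = history
        super().__init__(message or "fit metric decreased persistently; fit diverged")
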