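"""Acquisition geometry: volumes, TR, and the analyzed timepoint window.

All TR indices in this package are 1-based and inclusive, matching the
convention of reporting analysis windows as "TRs 11:168". The first
``discarded_leading`` volumes (rest + opening logos of the movie) are never
analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass


class ConfigurationError(ValueError):
    """A parameter set that cannot describe a valid run."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Scan timing for one functional run.

    Parameters
    ----------
    tr_seconds : float
        Repetition time in seconds (one volume per TR).
    n_volumes : int
        Number of volumes acquired in the run.
    discarded_leading : int
        Leading volumes excluded from all analyses (pre-stimulus rest and
        opening logos).
    """

    tr_seconds: float = 2.0
    n_volumes: int = 168
    discarded_leading: int = 10

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.n_volumes <= 0:
            raise ConfigurationError("n_volumes must be positive")
        if not 0 <= self.discarded_leading < self.n_volumes:
            raise ConfigurationError(
                "discarded_leading must be in [0, n_volumes)"
            )

    @property
    def analysis_window(self) -> tuple[int, int]:
        """Inclusive 1-based TR range that is analyzed."""
        return (self.discarded_leading + 1, self.n_volumes)

    @property
    def n_analyzed(self) -> int:
        """Number of analyzed TRs (window length)."""
        return self.n_volumes - self.discarded_leading

    @property
    def analysis_slice(self) -> slice:
        """0-based slice selecting the analyzed TRs from a full-run array."""
        return slice(self.discarded_leading, self.n_volumes)

    @property
    def run_seconds(self) -> float:
        return self.tr_seconds * self.n_volumes


def window_slice(window: tuple[int, int]) -> slice:
    """0-based slice for an inclusive 1-based TR ``(start, end)`` window."""
    start, end = window
    if start < 1 or end < start:
        raise ConfigurationError(f"invalid TR window {window!r}")
    return slice(start - 1, end)
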