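"""Uniformly sampled time-series container.

Heart-period (R-R interval) series are treated as uniformly sampled in *beat
time*: the nominal sampling period is the mean R-R interval in seconds, which
maps the beat-domain frequency axis to Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A finite, uniformly indexed sample sequence.

    Parameters
    ----------
    values
        Signal samples (e.g. R-R intervals in ms). Must be finite, length >= 2.
    sampling_period
        Nominal sampling period in seconds (> 0). For R-R series this is the
        mean heart period, so spectra are expressed on a Hz axis.
    label
        Free-text identifier.
    """

    values: np.ndarray
    sampling_period: float = 1.0
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must all be finite")
        if not (self.sampling_period > 0):
            raise ValueError("sampling_period must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sampling_period", float(self.sampling_period))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total span in seconds."""
        return len(self) * self.sampling_period

    def centered(self) -> np.ndarray:
        """Samples with the sample mean removed."""
        return self.values - self.values.mean()
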