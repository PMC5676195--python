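"""Shared container for directed frequency-domain measures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .var_models import FrequencyGrid

__all__ = ["CausalitySpectrum"]


@dataclass(frozen=True)
class CausalitySpectrum:
    """A directed frequency-domain measure on a grid for one ordered pair.

    ``kind`` is one of ``"GGC"`` (Granger–Geweke causality, nonnegative,
    unbounded), ``"DC"`` or ``"PDC"`` (squared-magnitude coherences in
    [0, 1]). ``provenance`` records whether the curve is theoretical (from
    exact model parameters) or estimated, which estimator produced it, and
    the model orders involved; estimators also record the number of
    frequencies at which the log-ratio argument was clamped to preserve
    nonnegativity.
    """

    kind: str
    source: str
    target: str
    cond: tuple[str, ...]
    grid: FrequencyGrid
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_freq,):
            raise ValueError(
                f"values shape {values.shape} does not match grid ({self.grid.n_freq},)"
            )

    @property
    def freqs(self) -> np.ndarray:
        return self.grid.freqs

    def grid_average(self) -> float:
        """Trapezoidal average of the spectrum over the grid (equals the
        full-circle spectral average for symmetric grids on [0, fs/2])."""
        f = self.grid.freqs
        return float(np.trapezoid(self.values, f) / (f[-1] - f[0]))
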