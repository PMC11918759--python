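"""Vector-based hemodynamic response indicators.

From the oxygenated / deoxygenated hemoglobin concentration changes
(ΔHbO, ΔHbR) a vector analysis in the (ΔCBV, ΔCOE) plane yields four more
indicators of oxygen metabolism:

    ΔCBV = (ΔHbO + ΔHbR) / 2      cerebral blood-volume change
    ΔCOE = (ΔHbO − ΔHbR) / 2      cerebral oxygen-exchange change
    |L|  = sqrt(ΔCBV² + ΔCOE²)    vector magnitude
    k    = atan2(ΔCOE, ΔCBV)      vector angle, radians in (−π, π]

The six indicators (ΔHbO, ΔHbR, ΔCBV, ΔCOE, |L|, k) stacked in this fixed
order form the input tensor of the classifiers.  Note the exact algebraic
identities ΔCBV + ΔCOE = ΔHbO and ΔCBV − ΔCOE = ΔHbR, and that
|L|² = (ΔHbO² + ΔHbR²)/2.

Convention notes: |L| is taken as the Euclidean magnitude in the
(ΔCBV, ΔCOE) plane, so the first five indicators scale linearly with the
input while k is scale-invariant; k at the origin is defined as 0 (the
atan2 zero convention) so degenerate samples do not propagate NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

INDICATOR_NAMES: tuple[str, ...] = ("dHbO", "dHbR", "dCBV", "dCOE", "absL", "k")

__all__ = ["INDICATOR_NAMES", "IndicatorTensor", "compute_indicators"]


@dataclass(frozen=True)
class IndicatorTensor:
    """Six hemodynamic indicators, stacked as ``(indicator, time, channel)``.

    Units are µM for the first five indicators and radians for ``k``.
    """

    values: np.ndarray  # (6, n_times, n_channels)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[0] != len(INDICATOR_NAMES):
            raise ValueError(
                f"expected shape (6, time, channel), got {self.values.shape}"
            )

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def get(self, name: str) -> np.ndarray:
        return self.values[INDICATOR_NAMES.index(name)]


def compute_indicators(dhbo: np.ndarray, dhbr: np.ndarray) -> IndicatorTensor:
    """Compute the six-indicator tensor from ΔHbO / ΔHbR arrays.

    Parameters
    ----------
    dhbo, dhbr
        Arrays of identical shape ``(time, channel)`` (any common shape is
        accepted), finite everywhere, in µM.

    Returns
    -------
    IndicatorTensor
        ``values[i]`` holds indicator ``INDICATOR_NAMES[i]``.
    """
    dhbo = np.asarray(dhbo, dtype=float)
    dhbr = np.asarray(dhbr, dtype=float)
    if dhbo.shape != dhbr.shape:
        raise ValueError(f"shape mismatch: {dhbo.shape} vs {dhbr.shape}")
    if not (np.isfinite(dhbo).all() and np.isfinite(dhbr).all()):
        raise ValueError("non-finite values in input")
    dcbv = (dhbo + dhbr) / 2.0
    dcoe = (dhbo - dhbr) / 2.0
    mag = np.hypot(dcbv, dcoe)
    angle = np.arctan2(dcoe, dcbv)
    return IndicatorTensor(np.stack([dhbo, dhbr, dcbv, dcoe, mag, angle]))


def reconstruct_hb(dcbv: np.ndarray, dcoe: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert the vector transform: returns (ΔHbO, ΔHbR) exactly."""
    return dcbv + dcoe, dcbv - dcoe
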