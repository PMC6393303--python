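"""Quantification of gel-lane band intensities into product-length
distributions: peak normalization, modal length, and fractional extension."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanism import LengthDistribution, ParameterError

__all__ = ["LaneProfile", "normalize_to_peak", "modal_length", "fraction_extended"]


@dataclass(frozen=True)
class LaneProfile:
    """Band intensities of one denaturing-gel lane, indexed by product length
    (primer+0 ... primer+n, contiguous from 0); arbitrary units >= 0."""

    band_intensity: np.ndarray
    time: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        b = np.asarray(self.band_intensity, dtype=float)
        object.__setattr__(self, "band_intensity", b)
        if b.ndim != 1 or b.size < 1:
            raise ParameterError("band_intensity must be a 1-D array")
        if np.any(b < 0):
            raise ParameterError("band intensities must be >= 0")
        if not np.any(b > 0):
            raise ParameterError("lane has no positive band")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.band_intensity.size)


def normalize_to_peak(lane: LaneProfile) -> np.ndarray:
    """Divide all bands by the lane maximum so the tallest band is exactly 1.

    Idempotent and scale invariant: the same output for ``c * lane``, c > 0.
    """
    return lane.band_intensity / lane.band_intensity.max()


def modal_length(dist: LengthDistribution | LaneProfile | np.ndarray) -> tuple[int, bool]:
    """Argmax product length; ties broken toward the shorter length.

    Returns ``(length, tied)`` where ``tied`` flags a non-unique maximum.
    """
    if isinstance(dist, LengthDistribution):
        p = dist.probabilities
    elif isinstance(dist, LaneProfile):
        p = dist.band_intensity
    else:
        p = np.asarray(dist, dtype=float)
    mode = int(np.argmax(p))
    tied = bool(np.sum(np.isclose(p, p[mode], rtol=1e-12, atol=0.0)) > 1)
    return mode, tied


def fraction_extended(lane: LaneProfile) -> float:
    """1 minus the unextended-primer band's share of total lane intensity."""
    total = lane.band_intensity.sum()
    return float(1.0 - lane.band_intensity[0] / total)
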