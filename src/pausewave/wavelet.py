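"""Haar wavelet transforms for kinetic signal tracks.

Two transforms are provided.

The *decimated* transform recursively splits a power-of-two-length signal
into smooth (low-pass) and detail (high-pass) coefficients.  With the Haar
filter, h = (1/sqrt(2), 1/sqrt(2)) and g = (1/sqrt(2), -1/sqrt(2)), the
scale-2 coefficients of a pair (a, b) are (a + b)/sqrt(2) and
(a - b)/sqrt(2); higher scales apply the same filters to the smooths of the
previous scale.  Scales are labelled by the width of the region a
coefficient summarizes, in positions (2, 4, 8, ...), not by the dyadic
level index.  The basis is orthonormal: energy is conserved (Parseval) and
for white-noise input the detail coefficients at every scale have mean 0
and second moment 1.

The *causal smooth* is the non-decimated (stationary) smooth evaluated on
the reversed signal, so that the coefficient attributed to position i is a
weighted sum of position i and its trailing context only:

    s_i^(w) = w^(-1/2) * (x_{i-w+1} + ... + x_i)

For polymerase kinetics this attributes a pause to the nucleotide at which
it occurs and the positions already synthesized, never to bases the
polymerase has not yet reached.  Leading positions without a full trailing
window are undefined (NaN) rather than padded: padding would fabricate
kinetics across the start of a read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateEnergyError, ValidationError

__all__ = [
    "HAAR_LOW",
    "HAAR_HIGH",
    "WaveletDecomposition",
    "CausalSmoothTrack",
    "haar_decompose",
    "haar_reconstruct",
    "power_by_scale",
    "causal_smooth",
]

_SQRT2 = np.sqrt(2.0)

#: Haar analysis filters (low-pass h, high-pass g); orthonormal pair.
HAAR_LOW: tuple[float, float] = (1.0 / _SQRT2, 1.0 / _SQRT2)
HAAR_HIGH: tuple[float, float] = (1.0 / _SQRT2, -1.0 / _SQRT2)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def _as_signal(x, name: str = "signal") -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise ValidationError(f"{name} must have length >= 1")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class WaveletDecomposition:
    """Decimated Haar decomposition of a length-``n`` signal.

    ``smooth[w]`` and ``detail[w]`` hold the n/w coefficients at scale
    ``w`` (region width in positions), for w in {2, 4, ..., n}.  The final
    smooth coefficient ``smooth[n][0]`` completes the orthonormal basis:

        sum(x**2) == sum_w sum(detail[w]**2) + smooth[n][0]**2
    """

    n: int
    smooth: dict[int, np.ndarray] = field(repr=False)
    detail: dict[int, np.ndarray] = field(repr=False)

    @property
    def scales(self) -> list[int]:
        return sorted(self.detail)

    @property
    def final_smooth(self) -> float:
        return float(self.smooth[self.n][0])

    def validate(self) -> None:
        """Check the coefficient-count structure; raise on inconsistency."""
        if not _is_power_of_two(self.n) or self.n < 2:
            raise ValidationError(f"decomposition length {self.n} is not a power of two >= 2")
        expected = [2 ** j for j in range(1, int(np.log2(self.n)) + 1)]
        if self.scales != expected or sorted(self.smooth) != expected:
            raise ValidationError("decomposition scales are inconsistent with its length")
        for w in expected:
            if len(self.detail[w]) != self.n // w or len(self.smooth[w]) != self.n // w:
                raise ValidationError(
                    f"scale {w} should have {self.n // w} coefficients, "
                    f"got {len(self.detail[w])} detail / {len(self.smooth[w])} smooth"
                )


def haar_decompose(x) -> WaveletDecomposition:
    """Full decimated Haar decomposition of a power-of-two-length signal.

    Raises :class:`ValidationError` if the length is not a power of two
    (callers must trim first; silently truncating kinetics would
    desynchronize tracks).
    """
    arr = _as_signal(x)
    n = arr.size
    if not _is_power_of_two(n) or n < 2:
        raise ValidationError(
            f"signal length {n} is not a power of two >= 2; trim before decomposing"
        )
    smooth: dict[int, np.ndarray] = {}
    detail: dict[int, np.ndarray] = {}
    cur = arr
    w = 2
    while w <= n:
        a, b = cur[0::2], cur[1::2]
        smooth[w] = (a + b) / _SQRT2
        detail[w] = (a - b) / _SQRT2
        cur = smooth[w]
        w *= 2
    return WaveletDecomposition(n=n, smooth=smooth, detail=detail)


def haar_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`haar_decompose` exactly (up to rounding)."""
    dec.validate()
    cur = dec.smooth[dec.n]
    for w in reversed(dec.scales):
        d = dec.detail[w]
        prev = np.empty(2 * cur.size, dtype=np.float64)
        prev[0::2] = (cur + d) / _SQRT2
        prev[1::2] = (cur - d) / _SQRT2
        cur = prev
    return cur


def power_by_scale(dec: WaveletDecomposition) -> dict[int, float]:
    """Fraction of total detail energy at each scale.

    Power_w = sum_i d_i^(w)**2 / sum_w sum_i d_i^(w)**2.  Fractions are
    non-negative and sum to 1.  A signal with zero detail energy (e.g. a
    constant) has no defined power spectrum: raises
    :class:`DegenerateEnergyError` rather than returning NaNs.
    """
    energies = {w: float(np.sum(d * d)) for w, d in dec.detail.items()}
    total = sum(energies.values())
    if total == 0.0:
        raise DegenerateEnergyError(
            "all detail coefficients are zero; power fractions are undefined"
        )
    return {w: e / total for w, e in sorted(energies.items())}


@dataclass
class CausalSmoothTrack:
    """Per-position causal smooth at one scale.

    ``values[i]`` (0-based) is w^(-1/2) times the sum of the trailing
    window x[i-w+1..i]; positions without a full trailing window hold NaN.
    """

    scale: int
    values: np.ndarray = field(repr=False)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of positions with a defined coefficient."""
        return ~np.isnan(self.values)


def causal_smooth(x, scale: int) -> CausalSmoothTrack:
    """Non-decimated trailing-window Haar smooth at one dyadic scale.

    Equivalent to reversing the signal, applying the standard
    start-anchored non-decimated smooth, and reversing back; implemented
    directly as a trailing-window sum.  No coefficient mixes values beyond
    the given signal.
    """
    arr = _as_signal(x)
    if not _is_power_of_two(scale) or scale < 2:
        raise ValidationError(f"scale must be a power of two >= 2, got {scale}")
    if scale > arr.size:
        raise ValidationError(f"scale {scale} exceeds signal length {arr.size}")
    csum = np.concatenate([[0.0], np.cumsum(arr)])
    values = np.full(arr.size, np.nan)
    values[scale - 1:] = (csum[scale:] - csum[:-scale]) / np.sqrt(scale)
    return CausalSmoothTrack(scale=scale, values=values)
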