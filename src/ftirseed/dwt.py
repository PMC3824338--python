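"""Multilevel dyadic discrete wavelet decomposition of 1-D spectra.

Thin, bookkeeping-heavy layer over PyWavelets: a spectrum is cascaded
through complementary low/high-pass filter-and-downsample steps; detail
level ``j`` holds the high-frequency output at scale ``2^j`` and the final
approximation the residual low-frequency trend.  Besides the transform
itself this module tracks which wavenumber interval each coefficient
dominates, which the feature-region definitions need.

The default wavelet is Daubechies-4 with periodized boundaries: with an
orthogonal filter pair and a signal length divisible by ``2^levels`` the
transform is an orthonormal change of basis, so total energy (sum of squared
coefficients) equals the signal's energy exactly; for other lengths the
periodization pads one sample at odd-length stages and perfect
reconstruction still holds while the energy identity is only approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .errors import CorruptDecompositionError, InsufficientLengthError
from .synth import WavenumberGrid


@dataclass(frozen=True)
class WaveletSpec:
    """Daubechies analysis wavelet and boundary handling."""

    family: str = "db"
    order: int = 4
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.family != "db":
            raise ValueError("only the Daubechies ('db') family is supported")
        if not 1 <= self.order <= 10:
            raise ValueError("Daubechies order must be between 1 and 10")

    @property
    def name(self) -> str:
        return f"{self.family}{self.order}"

    def pywt_wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.name)


@dataclass
class WaveletDecomposition:
    """Approximation + details 1..levels with provenance.

    ``details[j]`` is the detail coefficient vector at level ``j`` (scale
    ``2^j``); ``approximation`` is the level-``levels`` approximation.
    """

    approximation: np.ndarray
    details: dict[int, np.ndarray]
    levels: int
    source_length: int
    wavelet: WaveletSpec
    grid: WavenumberGrid | None = field(default=None, repr=False)

    def coeff_list(self) -> list[np.ndarray]:
        """PyWavelets-ordered coefficient list [cA_L, cD_L, ..., cD_1]."""
        return [self.approximation] + [
            self.details[j] for j in range(self.levels, 0, -1)
        ]

    def total_energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.coeff_list()))

    def detail_energy(self, level: int) -> float:
        return float(np.sum(self.details[level] ** 2))


def dwt_multilevel(
    signal: np.ndarray,
    wavelet: WaveletSpec | None = None,
    levels: int = 5,
    grid: WavenumberGrid | None = None,
) -> WaveletDecomposition:
    """Decompose a 1-D signal into ``levels`` dyadic scales."""
    wavelet = wavelet or WaveletSpec()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if levels < 1:
        raise ValueError("levels must be at least 1")
    if signal.size < 2**levels:
        raise InsufficientLengthError(
            f"signal of length {signal.size} cannot support {levels} levels "
            f"(needs at least {2**levels} samples)"
        )
    coeffs = pywt.wavedec(
        signal, wavelet.pywt_wavelet(), mode=wavelet.boundary_mode, level=levels
    )
    details = {levels - i + 1: c for i, c in enumerate(coeffs[1:], start=1)}
    return WaveletDecomposition(
        approximation=coeffs[0],
        details=details,
        levels=levels,
        source_length=signal.size,
        wavelet=wavelet,
        grid=grid,
    )


def idwt_multilevel(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert a decomposition back to a signal of the original length."""
    _check_consistent(decomp)
    rec = pywt.waverec(
        decomp.coeff_list(),
        decomp.wavelet.pywt_wavelet(),
        mode=decomp.wavelet.boundary_mode,
    )
    return rec[: decomp.source_length]


def _expected_lengths(decomp: WaveletDecomposition) -> list[int]:
    lengths = []
    n = decomp.source_length
    wav = decomp.wavelet.pywt_wavelet()
    for _ in range(decomp.levels):
        n = pywt.dwt_coeff_len(n, wav.dec_len, mode=decomp.wavelet.boundary_mode)
        lengths.append(n)
    return lengths  # level 1 first


def _check_consistent(decomp: WaveletDecomposition) -> None:
    expected = _expected_lengths(decomp)
    for j in range(1, decomp.levels + 1):
        if j not in decomp.details:
            raise CorruptDecompositionError(f"missing detail level {j}")
        if decomp.details[j].size != expected[j - 1]:
            raise CorruptDecompositionError(
                f"detail {j} has {decomp.details[j].size} coefficients, "
                f"expected {expected[j - 1]}"
            )
    if decomp.approximation.size != expected[-1]:
        raise CorruptDecompositionError(
            f"approximation has {decomp.approximation.size} coefficients, "
            f"expected {expected[-1]}"
        )


def coeff_to_wavenumber(
    decomp: WaveletDecomposition, level: int, index: int
) -> tuple[float, float]:
    """Half-open wavenumber interval dominated by one detail coefficient.

    Coefficient ``index`` at level ``j`` is anchored to source samples
    ``[index · 2^j, (index + 1) · 2^j)`` (clipped to the signal), returned as
    a descending ``(wn_high, wn_low)`` pair of interval edges on the grid.
    """
    if decomp.grid is None:
        raise ValueError("decomposition carries no wavenumber grid")
    if level < 1 or level > decomp.levels:
        raise IndexError(f"level {level} outside 1..{decomp.levels}")
    n_coeff = decomp.details[level].size
    if index < 0 or index >= n_coeff:
        raise IndexError(f"index {index} outside 0..{n_coeff - 1} at level {level}")
    span = 2**level
    i_start = index * span
    i_end = min((index + 1) * span, decomp.source_length)
    if i_start >= decomp.source_length:
        raise IndexError(
            f"coefficient {index} at level {level} lies beyond the signal"
        )
    g = decomp.grid
    return (g.start - g.step * i_start, g.start - g.step * i_end)


def decomposition_frame(decomp: WaveletDecomposition) -> pd.DataFrame:
    """Long-format export (level, index, coefficient, wn_start, wn_end);
    level 0 rows hold the final approximation (no wavenumber mapping)."""
    rows = []
    for level in range(1, decomp.levels + 1):
        coeffs = decomp.details[level]
        for k, c in enumerate(coeffs):
            if decomp.grid is not None and k * 2**level < decomp.source_length:
                wn_hi, wn_lo = coeff_to_wavenumber(decomp, level, k)
            else:
                wn_hi = wn_lo = np.nan
            rows.append(dict(level=level, index=k, coefficient=c,
                             wn_start=wn_hi, wn_end=wn_lo))
    for k, c in enumerate(decomp.approximation):
        rows.append(dict(level=0, index=k, coefficient=c,
                         wn_start=np.nan, wn_end=np.nan))
    return pd.DataFrame(rows)
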