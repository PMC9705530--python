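"""Bleach correction and the spatial-Fourier temporal-variance filter.

Light-sheet recordings of dense 3D cultures carry two characteristic
artifacts on top of photobleaching: horizontal stripes (shadows of optically
dense objects in the static sheet) and out-of-focus haze.  Both live at low
spatial frequencies and, because the stripes flicker and the background
drifts, their Fourier coefficients have large *temporal* variance — whereas
a nearly point-like neuron spreads its energy over many coefficients.  The
filter therefore zeroes, for all time points, the spatial-frequency
coefficients whose temporal variance is at or above a high quantile
(default the 99th).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .errors import DegenerateFrameError, DimensionError, ParameterError
from .io import Movie4D

__all__ = ["FourierMask", "bleach_correct", "fourier_filter"]


@dataclass
class FourierMask:
    """Keep/remove decision per non-redundant spatial-frequency coefficient."""

    keep: np.ndarray  # bool, rfftn coefficient layout
    variance: np.ndarray  # temporal variance per coefficient, same shape
    quantile: float  # quantile level used
    threshold: float  # variance value at that quantile

    @property
    def n_removed(self) -> int:
        return int(self.keep.size - self.keep.sum())


def bleach_correct(movie: Movie4D) -> Movie4D:
    """Divide every volume by its own spatial median.

    Removes the slow multiplicative intensity loss from photobleaching; the
    spatial median of every output volume is exactly 1.
    """
    data = movie.data.astype(np.float64, copy=False)
    medians = np.median(data.reshape(movie.n_volumes, -1), axis=1)
    bad = np.flatnonzero(medians <= 0)
    if bad.size:
        raise DegenerateFrameError(
            f"frame {bad[0]} has non-positive spatial median ({medians[bad[0]]})"
        )
    out = data / medians[:, None, None, None]
    return movie.with_data(out)


def fourier_filter(
    movie: Movie4D, quantile: float = 0.99
) -> tuple[Movie4D, FourierMask]:
    """Zero high-temporal-variance spatial-frequency coefficients.

    For each volume the real-input FFT over (z, y, x) is taken; for each
    coefficient the temporal variance ``E|f - E_t f|^2`` is computed; the
    coefficients at or above the requested variance quantile (linear
    interpolation estimator) are zeroed at every time point; the inverse
    transform restores a real movie of the original shape.  Zero-variance
    coefficients are always kept, and the kept set is invariant under any
    monotone rescaling of the variance (quantiles commute with monotone maps).
    """
    if not 0.0 < quantile <= 1.0:
        raise ParameterError(f"quantile must be in (0, 1], got {quantile}")
    if movie.n_volumes < 2:
        raise DimensionError("temporal variance needs at least 2 time points")
    data = movie.data.astype(np.float64, copy=False)
    f = scipy.fft.rfftn(data, axes=(1, 2, 3))
    mean = f.mean(axis=0)
    var = np.mean(np.abs(f - mean) ** 2, axis=0)
    # Variances at float round-off level are genuine zeros (temporally
    # constant coefficients) and must always be kept; round-off scales with
    # each coefficient's own magnitude.
    floor = (np.abs(mean) * np.finfo(np.float64).eps * 64.0) ** 2
    var[var <= floor] = 0.0
    thr = float(np.quantile(var, quantile))
    # "<" keeps: coefficients exactly at the quantile are removed.
    keep = (var < thr) | (var == 0)
    f *= keep
    out = scipy.fft.irfftn(f, s=movie.volume_shape, axes=(1, 2, 3))
    mask = FourierMask(keep=keep, variance=var, quantile=quantile, threshold=thr)
    return movie.with_data(out), mask


def apply_fourier_mask(movie: Movie4D, mask: FourierMask) -> Movie4D:
    """Re-apply a previously computed mask (idempotent on its own output)."""
    f = scipy.fft.rfftn(movie.data.astype(np.float64, copy=False), axes=(1, 2, 3))
    if f.shape[1:] != mask.keep.shape:
        raise DimensionError("mask shape does not match movie coefficient layout")
    f *= mask.keep
    out = scipy.fft.irfftn(f, s=movie.volume_shape, axes=(1, 2, 3))
    return movie.with_data(out)
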