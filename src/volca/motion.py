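"""Rigid 3D motion correction by cross-correlation against a median template.

The sample drifts slowly on its mount; before factorization every volume is
aligned to a template (voxelwise median of the first volumes).  Shifts are
found at the integer-voxel cross-correlation peak within a bounded search
window and refined to sub-voxel precision by separable quadratic
interpolation around the peak.  Only rigid translation is corrected;
piecewise-rigid patch parameters (strides/overlaps/max deviation) are
recorded in the pipeline configuration for provenance but not applied, since
residual non-rigid motion in these recordings is sub-cellular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy.ndimage import shift as nd_shift

from .errors import DegenerateInputError, DimensionError
from .io import Movie4D

__all__ = ["ShiftSeries", "estimate_shifts", "apply_shifts"]

# Default clamp, (z, y, x) voxels; mirrors a recorded (x, y, z) = (4, 4, 2).
DEFAULT_MAX_SHIFTS = (2, 4, 4)


@dataclass
class ShiftSeries:
    """Per-volume rigid shifts (dz, dy, dx) in voxels, sub-voxel precision."""

    shifts: np.ndarray  # (t, 3)
    max_shifts: tuple[int, int, int]
    template: np.ndarray  # (z, y, x)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.shifts, columns=["dz", "dy", "dx"])
        df.insert(0, "t", np.arange(len(df)))
        df.to_csv(path, index=False)


def _quadratic_peak_offset(m1: float, m0: float, p1: float) -> float:
    """Sub-voxel offset of a parabola through three points around a maximum."""
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0:  # flat or degenerate: keep the integer peak
        return 0.0
    return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))


def estimate_shifts(
    movie: Movie4D,
    max_shifts: tuple[int, int, int] = DEFAULT_MAX_SHIFTS,
    template_frames: int = 30,
) -> ShiftSeries:
    """Estimate per-volume rigid shifts against a median template.

    The template is the voxelwise median of the first ``template_frames``
    volumes (all volumes if fewer).  For each volume the circular spatial
    cross-correlation with the template is computed in the Fourier domain,
    the peak is located within ``max_shifts`` of zero lag, refined by
    quadratic interpolation per axis, and clamped to ``max_shifts``.

    Shifts are reported relative to the first volume (the sample's position
    at recording start): the median template carries an arbitrary offset of
    its own, so the first volume's estimate is subtracted from the series.
    """
    data = movie.data.astype(np.float64, copy=False)
    n = min(template_frames, movie.n_volumes)
    template = np.median(data[:n], axis=0)
    if not np.any(template):
        raise DegenerateInputError("all-zero template: movie carries no signal")
    shape = movie.volume_shape
    ft_conj = np.conj(scipy.fft.fftn(template - template.mean()))

    mz, my, mx = (int(m) for m in max_shifts)
    # Wrap-around lag grid: index -m..m via np.roll of the correlation volume.
    shifts = np.zeros((movie.n_volumes, 3))
    for t in range(movie.n_volumes):
        vol = data[t]
        cc = scipy.fft.ifftn(scipy.fft.fftn(vol - vol.mean()) * ft_conj).real
        # Restrict the peak search to the allowed window around zero lag.
        window = cc[
            np.arange(-mz, mz + 1)[:, None, None],
            np.arange(-my, my + 1)[None, :, None],
            np.arange(-mx, mx + 1)[None, None, :],
        ]
        iz, iy, ix = np.unravel_index(np.argmax(window), window.shape)
        ipeak = np.array([iz - mz, iy - my, ix - mx], dtype=int)
        # Quadratic refinement per axis around the fixed integer peak.
        peak = ipeak.astype(float)
        m0 = cc[tuple(np.mod(ipeak, shape))]
        for ax in range(3):
            lag = ipeak.copy()
            lag[ax] = ipeak[ax] - 1
            m1 = cc[tuple(np.mod(lag, shape))]
            lag[ax] = ipeak[ax] + 1
            p1 = cc[tuple(np.mod(lag, shape))]
            peak[ax] = ipeak[ax] + _quadratic_peak_offset(m1, m0, p1)
        shifts[t] = peak
    shifts -= shifts[0]
    shifts = np.clip(shifts, [-mz, -my, -mx], [mz, my, mx])
    return ShiftSeries(shifts=shifts, max_shifts=(mz, my, mx), template=template)


def apply_shifts(movie: Movie4D, shifts: ShiftSeries, order: int = 3) -> Movie4D:
    """Translate every volume by minus its estimated shift.

    Interpolation is cubic-spline by default: linear interpolation of
    sub-voxel shifts leaves flicker at sharp intensity edges (static somata)
    that downstream source extraction can mistake for activity.  Voxels
    shifted in from outside the field of view are filled with the volume's
    median intensity.
    """
    if len(shifts.shifts) != movie.n_volumes:
        raise DimensionError(
            f"{len(shifts.shifts)} shifts for {movie.n_volumes} volumes"
        )
    out = np.empty_like(movie.data, dtype=np.float64)
    for t in range(movie.n_volumes):
        vol = movie.data[t].astype(np.float64, copy=False)
        s = shifts.shifts[t]
        if np.any(s != 0):
            out[t] = nd_shift(vol, -s, order=order, mode="constant", cval=float(np.median(vol)))
        else:
            out[t] = vol
    return movie.with_data(out)
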