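"""Optical characterization: Gaussian fits, beam-waist hyperbola, PSF, shifts.

A light-sheet's axial resolution is governed by the illumination beam: an
elliptical Gaussian beam of waist ``w0`` (sheet thickness ``2 w0``) that
stays thin over twice its Rayleigh length ``xR = n pi w0^2 / lambda``.  The
sheet is characterized by fitting transversal profile images with a 2D
Gaussian and fitting the collected 1/e^2 widths ``w(x) = 2 sigma_x(x)``
with the Gaussian-beam hyperbola.  The system PSF is measured from
sub-resolution bead stacks: line profiles through each bead centre are fit
with a 1D Gaussian and the fitted sigma (the 1/e radius measure used
throughout) is aggregated per axis.

All fitters are nonlinear least squares (Levenberg-Marquardt via
``scipy.optimize.curve_fit``) with moment-based initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import center_of_mass, gaussian_filter, maximum_filter
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, DetectionError, FitError, ParameterError
from .io import MovieMeta

__all__ = [
    "Gaussian1DFit",
    "Gaussian2DFit",
    "BeamProfileSeries",
    "PSFMeasurement",
    "fit_gaussian_1d",
    "fit_gaussian_2d",
    "profile_series_widths",
    "fit_beam_waist",
    "rayleigh_length",
    "measure_psf",
    "chromatic_shift",
]

_MAXFEV = 500 * 10  # generous LM budget; fits are low-dimensional


@dataclass
class Gaussian1DFit:
    """Parameters of ``y = d + A exp(-(x - x0)^2 / (2 sigma^2))``."""

    d: float
    A: float
    x0: float
    sigma: float
    residual: float  # RMS of fit residuals

    def __call__(self, x):
        return self.d + self.A * np.exp(-((x - self.x0) ** 2) / (2 * self.sigma**2))


@dataclass
class Gaussian2DFit:
    """Parameters of the (optionally rotated) 2D Gaussian.

    ``f(x, y) = d + A exp(-(a (x-x0)^2 + 2 b (x-x0)(y-y0) + c (y-y0)^2))``
    with ``a``, ``b``, ``c`` tied to (sigma_x, sigma_y, theta) by the usual
    rotation identities; ``theta = 0`` reduces to the axis-aligned form.
    """

    d: float
    A: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float
    residual: float

    @property
    def abc(self) -> tuple[float, float, float]:
        ct2, st2 = np.cos(self.theta) ** 2, np.sin(self.theta) ** 2
        s2 = np.sin(2 * self.theta)
        sx2, sy2 = 2 * self.sigma_x**2, 2 * self.sigma_y**2
        a = ct2 / sx2 + st2 / sy2
        b = -s2 / (2 * sx2) + s2 / (2 * sy2)
        c = st2 / sx2 + ct2 / sy2
        return a, b, c

    def __call__(self, x, y):
        a, b, c = self.abc
        dx, dy = x - self.x0, y - self.y0
        return self.d + self.A * np.exp(-(a * dx**2 + 2 * b * dx * dy + c * dy**2))


@dataclass
class BeamProfileSeries:
    """Fitted sheet half-widths along the propagation axis."""

    positions: np.ndarray  # um, strictly increasing
    sigma_x: np.ndarray  # fitted thin-axis sigma, um
    wavelength: float | None = None  # um
    refractive_index: float = 1.33

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.sigma_x = np.asarray(self.sigma_x, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")

    @property
    def widths(self) -> np.ndarray:
        """1/e^2 beam width w = 2 sigma_x."""
        return 2.0 * self.sigma_x


@dataclass
class PSFMeasurement:
    """Per-bead Gaussian widths and their per-axis aggregate (um)."""

    sigma_per_bead: np.ndarray  # (n_beads, 3) as (sigma_z, sigma_y, sigma_x)
    mean: np.ndarray  # (3,)
    sd: np.ndarray  # (3,); zero with a single bead
    n_beads: int


def _moment_init_1d(x, y):
    d = float(y.min())
    A = float(y.max() - d)
    x0 = float(x[np.argmax(y)])
    w = np.clip(y - d, 0, None)
    tot = w.sum()
    if tot > 0:
        mu = (w * x).sum() / tot
        sigma = float(np.sqrt((w * (x - mu) ** 2).sum() / tot))
    else:
        sigma = 0.0
    if sigma <= 0:
        sigma = (x.max() - x.min()) / 6 or 1.0
    return d, A, x0, sigma


def fit_gaussian_1d(x: np.ndarray, y: np.ndarray) -> Gaussian1DFit:
    """Least-squares fit of a 1D Gaussian with offset.

    Initialization: offset = min, amplitude = max - min, centre = argmax,
    width from the second moment of the offset-subtracted profile.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ParameterError("need at least 5 samples for a 4-parameter fit")
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant profile cannot constrain a Gaussian")
    p0 = _moment_init_1d(x, y)

    def model(x, d, A, x0, sigma):
        return d + A * np.exp(-((x - x0) ** 2) / (2 * sigma**2))

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=_MAXFEV, xtol=1e-10, ftol=1e-10)
    except RuntimeError as exc:
        raise FitError(f"1D Gaussian fit did not converge (init {p0}): {exc}") from exc
    d, A, x0, sigma = popt
    res = float(np.sqrt(np.mean((model(x, *popt) - y) ** 2)))
    return Gaussian1DFit(d=float(d), A=float(A), x0=float(x0), sigma=abs(float(sigma)), residual=res)


def fit_gaussian_2d(
    image: np.ndarray,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    fix_theta_zero: bool = True,
) -> Gaussian2DFit:
    """Least-squares fit of a 2D Gaussian, rotated or axis-aligned.

    ``image`` is indexed ``[y, x]``; coordinate vectors default to pixel
    indices.  With ``fix_theta_zero`` the axis-aligned form is fit (6
    parameters), otherwise the rotation angle is free.
    """
    image = np.asarray(image, dtype=float)
    if image.size < 7:
        raise ParameterError("need at least 7 samples")
    if np.ptp(image) == 0:
        raise DegenerateFitError("constant image cannot constrain a Gaussian")
    ny, nx = image.shape
    x = np.arange(nx, dtype=float) if x is None else np.asarray(x, dtype=float)
    y = np.arange(ny, dtype=float) if y is None else np.asarray(y, dtype=float)
    xx, yy = np.meshgrid(x, y)

    d0 = float(image.min())
    A0 = float(image.max() - d0)
    iy, ix = np.unravel_index(np.argmax(image), image.shape)
    w = np.clip(image - d0, 0, None)
    tot = w.sum()
    mx = (w * xx).sum() / tot
    my = (w * yy).sum() / tot
    sx0 = float(np.sqrt((w * (xx - mx) ** 2).sum() / tot)) or (x.max() - x.min()) / 6
    sy0 = float(np.sqrt((w * (yy - my) ** 2).sum() / tot)) or (y.max() - y.min()) / 6

    coords = np.vstack([xx.ravel(), yy.ravel()])
    data = image.ravel()

    def model(coords, d, A, x0, y0, sx, sy, theta):
        xd = coords[0] - x0
        yd = coords[1] - y0
        ct2, st2 = np.cos(theta) ** 2, np.sin(theta) ** 2
        s2 = np.sin(2 * theta)
        a = ct2 / (2 * sx**2) + st2 / (2 * sy**2)
        b = -s2 / (4 * sx**2) + s2 / (4 * sy**2)
        c = st2 / (2 * sx**2) + ct2 / (2 * sy**2)
        return d + A * np.exp(-(a * xd**2 + 2 * b * xd * yd + c * yd**2))

    try:
        if fix_theta_zero:
            popt, _ = curve_fit(
                lambda co, d, A, x0, y0, sx, sy: model(co, d, A, x0, y0, sx, sy, 0.0),
                coords, data,
                p0=(d0, A0, float(x[ix]), float(y[iy]), sx0, sy0),
                maxfev=_MAXFEV, xtol=1e-10, ftol=1e-10,
            )
            popt = (*popt, 0.0)
        else:
            popt, _ = curve_fit(
                model, coords, data,
                p0=(d0, A0, float(x[ix]), float(y[iy]), sx0, sy0, 0.0),
                maxfev=_MAXFEV, xtol=1e-10, ftol=1e-10,
            )
    except RuntimeError as exc:
        raise FitError(f"2D Gaussian fit did not converge: {exc}") from exc
    d, A, x0, y0, sx, sy, theta = popt
    res = float(np.sqrt(np.mean((model(coords, *popt) - data) ** 2)))
    return Gaussian2DFit(
        d=float(d), A=float(A), x0=float(x0), y0=float(y0),
        sigma_x=abs(float(sx)), sigma_y=abs(float(sy)), theta=float(theta), residual=res,
    )


def profile_series_widths(
    images: list[np.ndarray],
    positions_um: np.ndarray,
    pixel_size_um: float = 1.0,
    wavelength_um: float | None = None,
    refractive_index: float = 1.33,
) -> BeamProfileSeries:
    """Fit each transversal profile image (theta = 0) and collect sigma_x.

    A failed fit is recorded as missing and excluded, together with its
    position, from the series.
    """
    positions_um = np.asarray(positions_um, dtype=float)
    if len(images) != len(positions_um):
        raise ParameterError("one position per image required")
    if len(images) < 3:
        raise ParameterError("need at least 3 propagation positions")
    pos_ok, sig_ok = [], []
    for img, pos in zip(images, positions_um):
        try:
            fit = fit_gaussian_2d(np.asarray(img), fix_theta_zero=True)
        except (FitError, ParameterError) as exc:
            warnings.warn(f"profile at x={pos} um excluded: {exc}")
            continue
        pos_ok.append(pos)
        sig_ok.append(fit.sigma_x * pixel_size_um)
    if len(pos_ok) < 3:
        raise FitError("fewer than 3 profiles could be fit")
    return BeamProfileSeries(
        positions=np.array(pos_ok), sigma_x=np.array(sig_ok),
        wavelength=wavelength_um, refractive_index=refractive_index,
    )


def fit_beam_waist(series: BeamProfileSeries) -> tuple[float, float, float]:
    """Fit the Gaussian-beam hyperbola to measured 1/e^2 widths.

    ``w(x) = w0 sqrt(1 + ((x - x0)/xR)^2)``; returns (w0, xR, x0) with
    w0, xR > 0.  Identities ``w(x0) = w0`` and ``w(x0 + xR) = w0 sqrt(2)``
    hold by construction, and the fit is invariant to reversing the
    position axis.
    """
    x = series.positions
    w = series.widths
    if len(x) < 3:
        raise ParameterError("need at least 3 width samples")
    w0_init = float(w.min())
    x0_init = float(x[np.argmin(w)])
    if series.wavelength:
        xr_init = rayleigh_length(w0_init / 2 * 2, series.wavelength, series.refractive_index)
    else:
        xr_init = float(np.ptp(x)) / 2 or 1.0

    def model(x, w0, xr, x0):
        return w0 * np.sqrt(1.0 + ((x - x0) / xr) ** 2)

    try:
        popt, _ = curve_fit(
            model, x, w, p0=(w0_init, xr_init, x0_init),
            maxfev=_MAXFEV, xtol=1e-12, ftol=1e-12,
        )
    except RuntimeError as exc:
        raise FitError(f"beam-waist fit did not converge: {exc}") from exc
    w0, xr, x0 = popt
    return abs(float(w0)), abs(float(xr)), float(x0)


def rayleigh_length(w0_um: float, wavelength_um: float, n: float = 1.33) -> float:
    """Rayleigh length xR = n pi w0^2 / lambda, in micrometres."""
    if w0_um <= 0 or wavelength_um <= 0 or n <= 0:
        raise ParameterError("w0, wavelength and n must all be positive")
    return n * np.pi * w0_um**2 / wavelength_um


def _detect_beads(stack: np.ndarray, n_beads: int, min_sep_vox: int = 5):
    """Brightest local maxima above background, at least ``min_sep_vox`` apart."""
    smoothed = gaussian_filter(stack.astype(float), 1.0)
    bg = np.median(smoothed)
    thr = bg + 0.2 * (smoothed.max() - bg)
    local_max = (maximum_filter(smoothed, size=3) == smoothed) & (smoothed > thr)
    coords = np.array(np.nonzero(local_max)).T
    if len(coords) == 0:
        raise DetectionError("no beads detected above background")
    vals = smoothed[tuple(coords.T)]
    order = np.argsort(-vals)
    picked = []
    for idx in order:
        c = coords[idx]
        if all(np.max(np.abs(c - p)) >= min_sep_vox for p in picked):
            picked.append(c)
        if len(picked) == n_beads:
            break
    return picked


def measure_psf(
    stack: np.ndarray, n_beads: int, meta: MovieMeta, profile_halfwidth_um: float = 6.0
) -> PSFMeasurement:
    """Per-axis Gaussian widths of the PSF from a bead z-stack.

    For each detected bead, line profiles along the three axes through the
    bead centre are extracted (the lateral x/y profiles appear in two of the
    three central planes each, the axial z profile in both the xz and yz
    planes; the duplicated lines carry the same data and are fit once).  Each
    profile is fit with a 1D Gaussian in physical coordinates, so anisotropic
    voxels are converted to micrometres before fitting.  Aggregates are the
    mean and standard deviation over beads per axis (sd = 0 with one bead).
    """
    stack = np.asarray(stack, dtype=float)
    beads = _detect_beads(stack, n_beads)
    vs = np.asarray(meta.voxel_size)  # (dz, dy, dx)
    sigmas = []
    for c in beads:
        per_axis = []
        for ax in range(3):
            half = max(3, int(round(profile_halfwidth_um / vs[ax])))
            lo = max(0, c[ax] - half)
            hi = min(stack.shape[ax], c[ax] + half + 1)
            sl = [int(c[0]), int(c[1]), int(c[2])]
            sl[ax] = slice(lo, hi)
            profile = stack[tuple(sl)]
            coords = np.arange(lo, hi) * vs[ax]
            per_axis.append(fit_gaussian_1d(coords, profile).sigma)
        sigmas.append(per_axis)
    sigmas = np.array(sigmas)  # (n, 3) in (z, y, x)
    return PSFMeasurement(
        sigma_per_bead=sigmas,
        mean=sigmas.mean(axis=0),
        sd=sigmas.std(axis=0, ddof=0) if len(sigmas) > 1 else np.zeros(3),
        n_beads=len(sigmas),
    )


def chromatic_shift(
    stack_a: np.ndarray,
    stack_b: np.ndarray,
    meta: MovieMeta,
    n_beads: int = 10,
    max_match_um: float = 5.0,
) -> np.ndarray:
    """Mean (dz, dy, dx) displacement of matched beads, b relative to a, in um.

    Bead centres are refined by intensity-weighted centroids in a local
    window; beads are matched to their nearest counterpart within
    ``max_match_um``.  Raises if no bead pair matches.
    """
    vs = np.asarray(meta.voxel_size)

    def centers(stack):
        pts = []
        for c in _detect_beads(np.asarray(stack, float), n_beads):
            win = tuple(
                slice(max(0, int(ci) - 4), min(s, int(ci) + 5))
                for ci, s in zip(c, stack.shape)
            )
            local = np.clip(stack[win] - np.median(stack), 0, None)
            com = center_of_mass(local)
            pts.append([w.start + o for w, o in zip(win, com)])
        return np.array(pts) * vs

    pa, pb = centers(stack_a), centers(stack_b)
    deltas = []
    for p in pa:
        d = np.linalg.norm(pb - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_match_um:
            deltas.append(pb[j] - p)
    if not deltas:
        raise DetectionError("no bead pairs matched between the two stacks")
    return np.mean(deltas, axis=0)
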