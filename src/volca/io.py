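"""Movie container, acquisition metadata, and TIFF hyperstack I/O.

A 4D recording is stored as a nonnegative array indexed ``(t, z, y, x)``
together with the physical acquisition metadata (voxel size, volume rate).
The physical position of voxel ``(z, y, x)`` is ``index * voxel_size``.

Hyperstacks are plain multi-page TIFFs whose pages are single planes in
t-major, z-minor order; a directory of single-volume stacks (one file per
time point) is accepted as an alternate dialect.  Metadata travels in a JSON
sidecar so that a movie on disk is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import DimensionError, FormatError, ParameterError

__all__ = [
    "MovieMeta",
    "Movie4D",
    "read_hyperstack",
    "read_volume_series",
    "write_hyperstack",
    "reorder_bidirectional",
]


@dataclass(frozen=True)
class MovieMeta:
    """Physical acquisition metadata for a volumetric recording.

    Parameters
    ----------
    voxel_size : (dz, dy, dx) in micrometres.
    frame_interval : seconds per volume.
    plane_exposure : seconds per plane.
    n_planes : planes per volume.
    wavelength : illumination wavelength in nm (optional).
    bidirectional : whether the z-scan alternated direction between volumes.
    """

    voxel_size: tuple[float, float, float] = (3.0, 1.3, 1.3)
    frame_interval: float = 0.2
    plane_exposure: float = 0.01
    n_planes: int = 20
    wavelength: float | None = 561.0
    bidirectional: bool = False

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.frame_interval <= 0 or self.plane_exposure <= 0 or self.n_planes <= 0:
            raise ParameterError("frame_interval, plane_exposure and n_planes must be positive")
        if self.wavelength is not None and self.wavelength <= 0:
            raise ParameterError("wavelength must be positive")
        # A volume cannot be acquired faster than its planes are exposed.
        if self.frame_interval < self.n_planes * self.plane_exposure - 1e-12:
            raise ParameterError(
                f"frame_interval {self.frame_interval} s shorter than "
                f"{self.n_planes} planes x {self.plane_exposure} s exposure"
            )

    @classmethod
    def from_acquisition(
        cls,
        n_planes: int,
        plane_exposure: float,
        fov_xy_um: float,
        n_pixels_xy: int,
        dz: float,
        wavelength: float | None = None,
        bidirectional: bool = False,
    ) -> "MovieMeta":
        """Derive voxel geometry and volume rate from acquisition settings.

        The lateral voxel size is ``fov_xy_um / n_pixels_xy`` and the volume
        period is ``n_planes * plane_exposure`` (stepwise scan, one exposure
        per plane).
        """
        dxy = fov_xy_um / n_pixels_xy
        return cls(
            voxel_size=(dz, dxy, dxy),
            frame_interval=n_planes * plane_exposure,
            plane_exposure=plane_exposure,
            n_planes=n_planes,
            wavelength=wavelength,
            bidirectional=bidirectional,
        )

    @property
    def volume_rate(self) -> float:
        """Volumetric scanning rate in Hz."""
        return 1.0 / self.frame_interval

    @property
    def axial_extent(self) -> float:
        """Axial coverage of one volume in micrometres."""
        return self.n_planes * self.voxel_size[0]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "MovieMeta":
        d = json.loads(Path(path).read_text())
        d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)


@dataclass
class Movie4D:
    """A 4D fluorescence recording indexed ``(t, z, y, x)``.

    Raw acquisitions are nonnegative photon counts; linear-filter
    intermediates (Fourier-filtered, motion-interpolated) may dip slightly
    below zero and are accepted as-is so that those operators stay exactly
    linear and idempotent.
    """

    data: np.ndarray
    meta: MovieMeta = field(default_factory=MovieMeta)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionError(f"movie must be 4D (t,z,y,x), got ndim={self.data.ndim}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Movie4D":
        """Same metadata, new array."""
        return Movie4D(data=data, meta=self.meta)

    def copy(self) -> "Movie4D":
        return Movie4D(data=self.data.copy(), meta=self.meta)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_hyperstack(path, meta: MovieMeta | None = None) -> Movie4D:
    """Read a multi-page TIFF whose pages are planes in t-major, z-minor order.

    If ``meta`` is omitted, a JSON sidecar (``<name>.tif.meta.json``) written
    by :func:`write_hyperstack` is required.
    """
    path = Path(path)
    if meta is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"no metadata given and no sidecar at {sidecar}")
        meta = MovieMeta.from_json(sidecar)
    try:
        pages = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim == 4:
        # Writer emitted a true 4D hyperstack; trust its plane count.
        if pages.shape[1] != meta.n_planes:
            raise DimensionError(
                f"hyperstack has {pages.shape[1]} planes/volume, metadata says {meta.n_planes}"
            )
        return Movie4D(pages, meta)
    if pages.ndim != 3:
        raise FormatError(f"unexpected TIFF dimensionality {pages.ndim}")
    n_pages = pages.shape[0]
    if n_pages % meta.n_planes:
        raise DimensionError(
            f"{n_pages} pages not divisible by n_planes={meta.n_planes}"
        )
    t = n_pages // meta.n_planes
    return Movie4D(pages.reshape(t, meta.n_planes, *pages.shape[1:]), meta)


def read_volume_series(directory, meta: MovieMeta, pattern: str = "*.tif*") -> Movie4D:
    """Read a directory of single-volume TIFF stacks, sorted by file name.

    Each file holds the ``n_planes`` planes of one time point.
    """
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FormatError(f"no TIFF files matching {pattern!r} in {directory}")
    volumes = []
    for f in files:
        v = np.asarray(tifffile.imread(f))
        if v.ndim != 3 or v.shape[0] != meta.n_planes:
            raise DimensionError(
                f"{f.name}: expected a ({meta.n_planes},Y,X) volume, got shape {v.shape}"
            )
        volumes.append(v)
    return Movie4D(np.stack(volumes), meta)


def write_hyperstack(movie: Movie4D, path) -> None:
    """Write a movie as a plane-per-page TIFF plus a JSON metadata sidecar.

    Integer data round-trips bit-exactly through :func:`read_hyperstack`.
    """
    path = Path(path)
    t, z, y, x = movie.shape
    try:
        tifffile.imwrite(path, movie.data.reshape(t * z, y, x))
    except OSError as exc:
        raise OSError(f"cannot write hyperstack to {path}: {exc}") from exc
    meta = movie.meta
    if meta.n_planes != z:
        meta = replace(meta, n_planes=z)
    meta.to_json(_sidecar_path(path))


def reorder_bidirectional(movie: Movie4D, reverse_odd: bool = True) -> Movie4D:
    """Undo bidirectional z-scanning by flipping every other volume in z.

    With ``reverse_odd=True`` (default) volumes 1, 3, 5, ... are flipped,
    otherwise volumes 0, 2, 4, ...  The operation is an involution: applying
    it twice with the same flag returns the original movie.
    """
    data = movie.data.copy()
    start = 1 if reverse_odd else 0
    data[start::2] = data[start::2, ::-1]
    return Movie4D(data, replace(movie.meta, bidirectional=False))
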