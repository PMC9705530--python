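"""Accepted-neuron container shared by extraction, post-filtering and graphs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import MovieMeta

__all__ = ["ComponentSet"]


@dataclass
class ComponentSet:
    """Extracted neurons: 3D footprints, traces and geometry.

    ``footprints`` is ``(n, z, y, x)`` with nonnegative weights of compact
    support; ``traces`` are the denoised (factorization) traces and
    ``raw_traces`` the movie averaged over each footprint's support, both
    ``(n, t)``.  Centroids are footprint-weighted and expressed in
    micrometres via the shared metadata.
    """

    footprints: np.ndarray
    traces: np.ndarray
    raw_traces: np.ndarray
    meta: MovieMeta
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ids is None:
            self.ids = np.arange(len(self.footprints))
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return len(self.footprints)

    @property
    def voxel_counts(self) -> np.ndarray:
        """Nonzero voxels per footprint."""
        if len(self) == 0:
            return np.zeros(0, dtype=int)
        return np.count_nonzero(self.footprints.reshape(len(self), -1), axis=1)

    @property
    def volumes_um3(self) -> np.ndarray:
        if self.meta is None:
            raise ConfigurationError("voxel volume unknown: ComponentSet has no metadata")
        return self.voxel_counts * self.meta.voxel_volume

    @property
    def centroids_um(self) -> np.ndarray:
        """Weighted centroid of each footprint, (n, 3) in (z, y, x) um."""
        n = len(self)
        out = np.zeros((n, 3))
        vs = np.asarray(self.meta.voxel_size)
        for i in range(n):
            w = self.footprints[i]
            tot = w.sum()
            if tot <= 0:
                continue
            idx = np.array(np.nonzero(w))
            out[i] = (idx * w[tuple(idx)]).sum(axis=1) / tot * vs
        return out

    def select(self, indices) -> "ComponentSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            footprints=self.footprints[idx],
            traces=self.traces[idx],
            raw_traces=self.raw_traces[idx],
            ids=self.ids[idx],
        )

    def summary(self) -> pd.DataFrame:
        cen = self.centroids_um
        return pd.DataFrame(
            {
                "id": self.ids,
                "z_um": cen[:, 0],
                "y_um": cen[:, 1],
                "x_um": cen[:, 2],
                "voxels": self.voxel_counts,
                "volume_um3": self.volumes_um3,
            }
        )

    def to_npz(self, path) -> None:
        """Serialize with footprints in coordinate-list (sparse) form."""
        n = len(self)
        comp_idx, zz, yy, xx, ww = [], [], [], [], []
        for i in range(n):
            nz = np.nonzero(self.footprints[i])
            comp_idx.append(np.full(len(nz[0]), i))
            zz.append(nz[0]); yy.append(nz[1]); xx.append(nz[2])
            ww.append(self.footprints[i][nz])
        cat = lambda xs: np.concatenate(xs) if xs else np.array([], dtype=int)
        np.savez_compressed(
            path,
            shape=np.array(self.footprints.shape),
            comp=cat(comp_idx), z=cat(zz), y=cat(yy), x=cat(xx), w=cat(ww),
            traces=self.traces,
            raw_traces=self.raw_traces,
            ids=self.ids,
            voxel_size=np.array(self.meta.voxel_size),
            frame_interval=self.meta.frame_interval,
            plane_exposure=self.meta.plane_exposure,
            n_planes=self.meta.n_planes,
        )

    @classmethod
    def from_npz(cls, path) -> "ComponentSet":
        with np.load(path) as z:
            shape = tuple(z["shape"])
            fp = np.zeros(shape)
            fp[z["comp"], z["z"], z["y"], z["x"]] = z["w"]
            meta = MovieMeta(
                voxel_size=tuple(z["voxel_size"]),
                frame_interval=float(z["frame_interval"]),
                plane_exposure=float(z["plane_exposure"]),
                n_planes=int(z["n_planes"]),
            )
            return cls(
                footprints=fp,
                traces=z["traces"],
                raw_traces=z["raw_traces"],
                meta=meta,
                ids=z["ids"],
            )
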