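"""Lightweight 3D constrained nonnegative matrix factorization (CNMF).

The preprocessed movie is decomposed as ``Y = AC + B + E``: nonnegative
spatial footprints ``A`` (one compact 3D map per neuron), nonnegative
temporal traces ``C``, a low-rank background ``B = b f`` capturing slow
drifts and residual out-of-focus fluorescence, and noise ``E``.

The solver is hierarchical alternating least squares (HALS): footprints and
traces are updated by exact nonnegative one-dimensional least-squares steps
restricted to a per-component support box, and the background is refit as a
rank-``nb`` factorization of ``Y - AC``; every step is non-increasing in
``||Y - AC - B||^2``.  Components are seeded at local maxima of a
neighborhood correlation image, screened by peak SNR and spatial
correlation, refit seeded with the survivors, and merged when their
footprints overlap and their traces are near-duplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .components import ComponentSet
from .errors import DegenerateInputError, ParameterError
from .io import Movie4D

__all__ = [
    "ExtractParams",
    "FactorModel",
    "correlation_image",
    "seed_components",
    "fit_model",
    "evaluate_components",
    "merge_components",
    "run_extraction",
]


@dataclass(frozen=True)
class ExtractParams:
    """CNMF configuration.

    ``K`` seeds per patch, ``gSig`` the expected neuron half-width in voxels
    per (z, y, x) axis, ``rf``/``stride`` the patch geometry used for
    seeding (``rf=None`` seeds the whole volume as one patch), ``nb`` the
    background rank.  ``p`` (autoregressive order of the calcium dynamics)
    is recorded for provenance; temporal deconvolution is not performed and
    the denoised traces are the constrained least-squares solutions.
    """

    K: int = 10
    gSig: tuple[int, int, int] = (2, 2, 2)
    merge_thresh: float = 0.8
    nb: int = 2
    p: int = 2
    min_snr: float = 1.0
    min_spatial_corr: float = 0.5
    rf: int | None = 10
    stride: int = 10
    seed_min_corr: float = 0.1
    footprint_threshold: float = 0.02
    spatial_significance: float = 4.0

    def __post_init__(self):
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if not 0 < self.merge_thresh <= 1:
            raise ParameterError("merge_thresh must be in (0, 1]")
        if self.nb < 0:
            raise ParameterError("nb must be >= 0")


@dataclass
class FactorModel:
    """State of the factorization ``Y = AC + B + E``."""

    A: np.ndarray  # (K, z, y, x), nonnegative, compact support
    C: np.ndarray  # (K, t), nonnegative
    b: np.ndarray  # (n_voxels, nb) spatial background maps
    f: np.ndarray  # (nb, t) background time courses
    volume_shape: tuple[int, int, int]
    objective: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.A)

    def background(self) -> np.ndarray:
        """B as a (t, z, y, x) array."""
        t = self.C.shape[1] if self.n_components else self.f.shape[1]
        B = (self.b @ self.f).T if self.b.size else np.zeros((t, int(np.prod(self.volume_shape))))
        return B.reshape(t, *self.volume_shape)

    def reconstruction(self) -> np.ndarray:
        """AC + B as a (t, z, y, x) array."""
        t = self.C.shape[1]
        rec = np.zeros((t, int(np.prod(self.volume_shape))))
        for i in range(self.n_components):
            a = self.A[i].ravel()
            idx = np.flatnonzero(a)
            rec[:, idx] += np.outer(self.C[i], a[idx])
        if self.b.size:
            rec += (self.b @ self.f).T
        return rec.reshape(t, *self.volume_shape)

    def residual(self, movie: Movie4D) -> np.ndarray:
        """E = Y - AC - B."""
        return movie.data - self.reconstruction()

    def select(self, indices) -> "FactorModel":
        idx = np.asarray(indices, dtype=int)
        return FactorModel(
            A=self.A[idx],
            C=self.C[idx],
            b=self.b,
            f=self.f,
            volume_shape=self.volume_shape,
            objective=list(self.objective),
        )


def correlation_image(movie: Movie4D) -> np.ndarray:
    """Mean temporal Pearson correlation of each voxel with its 6-neighbors.

    Voxels with zero temporal variance contribute correlation 0.  Values lie
    in [-1, 1]; active somata light up as connected high-correlation blobs.
    """
    if movie.n_volumes < 2:
        raise DegenerateInputError("correlation image needs >= 2 time points")
    data = movie.data.astype(np.float64, copy=False)
    t = movie.n_volumes
    mean = data.mean(axis=0)
    sd = data.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(sd > 0, (data - mean) / sd, 0.0)
    corr_sum = np.zeros(movie.volume_shape)
    counts = np.zeros(movie.volume_shape)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = np.einsum("t...,t...->...", v[(slice(None), *sl_lo)], v[(slice(None), *sl_hi)]) / t
        corr_sum[tuple(sl_lo)] += pair
        corr_sum[tuple(sl_hi)] += pair
        counts[tuple(sl_lo)] += 1
        counts[tuple(sl_hi)] += 1
    return corr_sum / counts


def seed_components(corr: np.ndarray, params: ExtractParams) -> list[tuple[int, int, int]]:
    """Seed centers: local maxima of the smoothed correlation image.

    The map is smoothed at scale ``gSig``; maxima closer than ``2*gSig`` are
    suppressed and maxima below ``seed_min_corr`` are ignored.  With patch
    geometry (``rf``/``stride``) the top-``K`` maxima are kept per patch;
    otherwise the top-``K`` overall.  Seeds are returned in descending
    smoothed-correlation order, ties broken lexicographically in (z, y, x).
    """
    if not np.all(np.isfinite(corr)):
        raise ParameterError("correlation image contains non-finite values")
    smoothed = gaussian_filter(corr, sigma=params.gSig)
    candidates = peak_local_max(
        smoothed,
        min_distance=1,
        threshold_abs=params.seed_min_corr,
        exclude_border=False,
    )
    if len(candidates) == 0:
        return []
    cand_vals = smoothed[tuple(candidates.T)]
    # Deterministic order: descending value, then lexicographic coordinates.
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0], -cand_vals))
    candidates, cand_vals = candidates[order], cand_vals[order]
    # Greedy suppression at separation 2*gSig, normalized per axis so that
    # anisotropic voxel geometry does not merge axially adjacent somata.
    sep = 2.0 * np.asarray(params.gSig, dtype=float)
    peaks_list: list[np.ndarray] = []
    vals_list: list[float] = []
    for c, v in zip(candidates, cand_vals):
        if all(np.sum(((c - k) / sep) ** 2) >= 1.0 for k in peaks_list):
            peaks_list.append(c)
            vals_list.append(float(v))
    peaks = np.array(peaks_list)
    vals = np.array(vals_list)

    if params.rf is None:
        keep = peaks[: params.K]
        return [tuple(int(c) for c in p) for p in keep]

    size = 2 * params.rf
    selected: dict[tuple, float] = {}
    dims = corr.shape
    for oz in range(0, dims[0], params.stride):
        for oy in range(0, dims[1], params.stride):
            for ox in range(0, dims[2], params.stride):
                inside = (
                    (peaks[:, 0] >= oz) & (peaks[:, 0] < oz + size)
                    & (peaks[:, 1] >= oy) & (peaks[:, 1] < oy + size)
                    & (peaks[:, 2] >= ox) & (peaks[:, 2] < ox + size)
                )
                for p, v in list(zip(peaks[inside], vals[inside]))[: params.K]:
                    selected[tuple(int(c) for c in p)] = float(v)
    ordered = sorted(selected.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ordered]


def _bbox_slices(
    mask: np.ndarray, margin: tuple[int, int, int] | None = None
) -> tuple[slice, slice, slice] | None:
    """Bounding box of the nonzero support, optionally dilated per axis."""
    nz = np.nonzero(mask)
    if len(nz[0]) == 0:
        return None
    margin = margin or (0, 0, 0)
    return tuple(
        slice(max(0, int(ax.min()) - m), min(s, int(ax.max()) + 1 + m))
        for ax, m, s in zip(nz, margin, mask.shape)
    )


def _support_box(
    a: np.ndarray, gSig: tuple[int, int, int], anchor: tuple[int, int, int]
) -> tuple[slice, slice, slice] | None:
    """Dilated bounding box of a footprint, confined to a fixed local window.

    The window has side ``8*gSig + 1`` per axis around the component's
    anchor (its seed), twice the seed patch: large enough for a soma wider
    than the seed patch, small enough to keep components local and updates
    cheap.  Because the box always stays inside the window, footprints can
    grow by the ``gSig`` dilation margin but never creep across the volume.
    """
    box = _bbox_slices(a, margin=gSig)
    if box is None:
        return None
    out = []
    for sl, c, g, s in zip(box, anchor, gSig, a.shape):
        half = 4 * g
        lo = max(sl.start, int(c) - half)
        hi = min(sl.stop, int(c) + half + 1)
        out.append(slice(max(0, lo), min(s, hi)))
    return tuple(out)


def _box_indices(box: tuple[slice, slice, slice], shape) -> np.ndarray:
    """Flat voxel indices of a box within a (z, y, x) volume."""
    zz = np.arange(box[0].start, box[0].stop)
    yy = np.arange(box[1].start, box[1].stop)
    xx = np.arange(box[2].start, box[2].stop)
    return (
        (zz[:, None, None] * shape[1] + yy[None, :, None]) * shape[2] + xx[None, None, :]
    ).ravel()


def _seeded_init(Y, seeds, params, vshape, t_len):
    """Gaussian-bump footprints at the seeds with projected initial traces."""
    K = len(seeds)
    A = np.zeros((K, *vshape))
    C = np.zeros((K, t_len))
    boxes = []
    half = tuple(2 * g for g in params.gSig)
    for i, seed_pos in enumerate(seeds):
        box = tuple(
            slice(max(0, c - h), min(s, c + h + 1))
            for c, h, s in zip(seed_pos, half, vshape)
        )
        boxes.append(box)
        grids = np.ogrid[box]
        bump = np.exp(
            -sum(
                ((g - c) ** 2) / (2.0 * max(g_sig, 0.5) ** 2)
                for g, c, g_sig in zip(grids, seed_pos, params.gSig)
            )
        )
        A[i][box] = bump
        a = A[i].ravel()
        idx = np.flatnonzero(a)
        C[i] = np.clip(Y[:, idx] @ a[idx] / (a[idx] @ a[idx]), 0.0, None)
        C[i] -= C[i].min()
    return A, C, boxes


def fit_model(
    movie: Movie4D,
    seeds: list[tuple[int, int, int]] | None,
    params: ExtractParams,
    n_iter: int = 30,
    init_model: FactorModel | None = None,
    tol: float = 1e-4,
    seed: int = 0,
) -> FactorModel:
    """Alternating constrained updates of A, C and the background.

    Each component's footprint is confined to a support box of side
    ``4*gSig + 1`` around its seed, shrunk to the footprint's bounding box as
    iterations proceed.  Stops after ``n_iter`` iterations or when the
    relative change of the reconstruction error falls below ``tol``; the
    objective ``||Y - AC - B||^2`` is non-increasing across iterations.
    """
    data = movie.data
    if np.any(~np.isfinite(data)):
        raise ParameterError("movie contains NaN or infinite values")
    t_len = movie.n_volumes
    vshape = movie.volume_shape
    n_vox = int(np.prod(vshape))
    Y = data.reshape(t_len, n_vox).astype(np.float64)
    rng = np.random.default_rng(seed)

    # --- initialization -------------------------------------------------
    if init_model is not None:
        A = init_model.A.copy()
        C = init_model.C.copy()
        anchors = []
        for a in A:
            nz = np.nonzero(a)
            w = a[nz]
            if w.size:
                anchors.append(tuple(int(round((ax * w).sum() / w.sum())) for ax in nz))
            else:
                anchors.append((0, 0, 0))
        boxes = [_support_box(a, params.gSig, anc) for a, anc in zip(A, anchors)]
        if seeds:
            # Augment a warm start with freshly seeded components.
            extra = _seeded_init(Y, seeds, params, vshape, t_len)
            A = np.concatenate([A, extra[0]])
            C = np.concatenate([C, extra[1]])
            anchors.extend(list(seeds))
            boxes.extend(extra[2])
        K = len(A)
    elif seeds:
        K = len(seeds)
        A, C, boxes = _seeded_init(Y, seeds, params, vshape, t_len)
        anchors = list(seeds)
        K = len(A)
    else:
        raise ParameterError("fit_model needs seeds or an initial model")

    nb = params.nb
    b = np.zeros((n_vox, nb))
    f = np.zeros((nb, t_len))

    def model_AC(R_out):
        """Write Y - AC into R_out (in place over a copy of Y)."""
        np.copyto(R_out, Y)
        for i in range(K):
            a = A[i].ravel()
            idx = np.flatnonzero(a)
            if idx.size:
                R_out[:, idx] -= np.outer(C[i], a[idx])

    YmAC = np.empty_like(Y)
    objective: list[float] = []
    prev_err = None
    for it in range(n_iter):
        # Background update: best rank-nb approximation of Y - AC
        # (randomized SVD with a monotonicity guard).
        model_AC(YmAC)
        if nb > 0:
            old_obj = float(np.linalg.norm(YmAC - (b @ f).T) ** 2)
            k = min(nb + 4, t_len, n_vox)
            omega = rng.standard_normal((n_vox, k))
            G = YmAC @ omega
            G = YmAC @ (YmAC.T @ G)
            Q, _ = np.linalg.qr(G)
            small = Q.T @ YmAC  # (k, n_vox)
            u, s, vt = np.linalg.svd(small, full_matrices=False)
            f_new = ((Q @ u)[:, :nb] * s[:nb]).T  # (nb, t)
            b_new = vt[:nb].T  # (n_vox, nb)
            new_obj = float(np.linalg.norm(YmAC - (b_new @ f_new).T) ** 2)
            if new_obj <= old_obj:
                b, f = b_new, f_new

        # Residual R = Y - AC - B, maintained through the HALS sweeps.
        R = YmAC - (b @ f).T if nb > 0 else YmAC

        # Temporal HALS.
        for i in range(K):
            a = A[i].ravel()
            idx = np.flatnonzero(a)
            if idx.size == 0:
                continue
            aa = a[idx] @ a[idx]
            c_new = np.clip(C[i] + (R[:, idx] @ a[idx]) / aa, 0.0, None)
            delta = c_new - C[i]
            if np.any(delta):
                R[:, idx] -= np.outer(delta, a[idx])
                C[i] = c_new

        # Spatial HALS within each support box; boxes shrink to the
        # footprint's bounding box.
        for i in range(K):
            if boxes[i] is None:
                continue
            cc = C[i] @ C[i]
            if cc == 0:
                continue
            idx = _box_indices(boxes[i], vshape)
            a_old = A[i].ravel()[idx]
            a_new = np.clip(a_old + (C[i] @ R[:, idx]) / cc, 0.0, None)
            delta = a_new - a_old
            if np.any(delta):
                R[:, idx] -= np.outer(C[i], delta)
                A[i].ravel()[idx] = a_new
            # Support follows the footprint: bounding box dilated by gSig so
            # somata larger than the seed patch can be captured, but capped
            # at side 8*gSig+1 around the footprint's weighted centre to keep
            # every component local.
            boxes[i] = _support_box(A[i], params.gSig, anchors[i])

        err = float(np.linalg.norm(R))
        objective.append(err**2)
        if prev_err is not None and prev_err > 0 and abs(prev_err - err) / prev_err < tol:
            break
        prev_err = err

    alive = [i for i in range(K) if A[i].any() and C[i].any()]
    model = FactorModel(
        A=A[alive], C=C[alive], b=b, f=f, volume_shape=vshape, objective=objective
    )
    return model


def _robust_noise_sd(trace: np.ndarray) -> float:
    """Noise level from first differences: 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(trace)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def peak_snr(trace: np.ndarray) -> float:
    """(max - median) / robust noise; 0 for a flat trace."""
    amp = float(trace.max() - np.median(trace))
    sd = _robust_noise_sd(trace)
    if sd == 0:
        return np.inf if amp > 0 else 0.0
    return amp / sd


def spatial_correlation(model: FactorModel, movie: Movie4D, i: int) -> float:
    """Pearson correlation of footprint i with the movie's active-frame mean.

    The movie is averaged over the frames where the component's trace is in
    its top decile and compared to the footprint on its bounding box.
    """
    c = model.C[i]
    thr = np.quantile(c, 0.9)
    frames = np.flatnonzero(c >= thr)
    if frames.size == 0:
        return 0.0
    box = _bbox_slices(model.A[i])
    if box is None:
        return 0.0
    data_box = movie.data[(slice(None), *box)]
    avg = data_box[frames].mean(axis=0).ravel()
    a = model.A[i][box].ravel()
    if np.std(a) == 0 or np.std(avg) == 0:
        return 0.0
    return float(np.corrcoef(a, avg)[0, 1])


def evaluate_components(
    model: FactorModel,
    movie: Movie4D,
    min_snr: float = 1.0,
    min_spatial_corr: float = 0.5,
) -> np.ndarray:
    """Accept flags: peak SNR >= min_snr AND spatial correlation >= min_spatial_corr."""
    flags = np.zeros(model.n_components, dtype=bool)
    for i in range(model.n_components):
        if peak_snr(model.C[i]) >= min_snr and spatial_correlation(model, movie, i) >= min_spatial_corr:
            flags[i] = True
    return flags


def merge_components(model: FactorModel, merge_thresh: float = 0.8) -> FactorModel:
    """Merge transitively all components that overlap and share their trace.

    Pairs with spatially overlapping footprints AND trace Pearson
    correlation >= ``merge_thresh`` are grouped by transitive closure; each
    group's footprints are summed and its trace refit by a nonnegative
    least-squares projection of the group's reconstruction onto the merged
    footprint.
    """
    K = model.n_components
    if K <= 1:
        return model
    supports = [model.A[i] > 0 for i in range(K)]
    parent = list(range(K))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(K):
        for j in range(i + 1, K):
            if not np.any(supports[i] & supports[j]):
                continue
            ci, cj = model.C[i], model.C[j]
            if np.std(ci) == 0 or np.std(cj) == 0:
                continue
            if np.corrcoef(ci, cj)[0, 1] >= merge_thresh:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(K):
        groups.setdefault(find(i), []).append(i)
    if len(groups) == K:
        return model

    A_new, C_new = [], []
    for members in groups.values():
        if len(members) == 1:
            i = members[0]
            A_new.append(model.A[i].copy())
            C_new.append(model.C[i].copy())
            continue
        a_m = np.sum(model.A[members], axis=0)
        # Group reconstruction restricted to the merged support.
        idx = np.flatnonzero(a_m.ravel())
        rec = np.zeros((model.C.shape[1], idx.size))
        for i in members:
            ai = model.A[i].ravel()[idx]
            rec += np.outer(model.C[i], ai)
        am_flat = a_m.ravel()[idx]
        c_m = np.clip(rec @ am_flat / (am_flat @ am_flat), 0.0, None)
        A_new.append(a_m)
        C_new.append(c_m)
    return FactorModel(
        A=np.stack(A_new),
        C=np.stack(C_new),
        b=model.b,
        f=model.f,
        volume_shape=model.volume_shape,
        objective=list(model.objective),
    )


def refine_footprints(
    movie: Movie4D, model: FactorModel, params: ExtractParams
) -> np.ndarray:
    """Final voxelwise nonnegative LS estimate of each footprint's activity.

    The trace-baseline x footprint direction of the factorization is
    degenerate with the static background, so converged HALS footprints can
    carry static local structure.  This step resolves the degeneracy the way
    the model intends (all static fluorescence belongs to ``B``): each
    footprint is re-estimated by regressing the temporally mean-subtracted
    movie on the baseline-subtracted trace, restricted to the footprint's
    dilated bounding box.  Voxel weights below ``spatial_significance``
    standard errors of their per-voxel noise level are set to zero, which
    keeps the expected number of false voxels per support window below one.
    """
    t_len = movie.n_volumes
    Y = movie.data.reshape(t_len, -1).astype(np.float64)
    Yd = Y - Y.mean(axis=0)
    d = np.diff(Y, axis=0)
    noise_sd = 1.4826 * np.median(np.abs(d - np.median(d, axis=0)), axis=0) / np.sqrt(2.0)
    out = np.zeros_like(model.A)
    for i in range(model.n_components):
        box = _bbox_slices(model.A[i], margin=(2, 2, 2))
        c = model.C[i]
        ct = c - np.median(c)
        nrm = ct @ ct
        if box is None or nrm == 0:
            continue
        mask = np.zeros(model.volume_shape, dtype=bool)
        mask[box] = True
        idx = np.flatnonzero(mask.ravel())
        a = ct @ Yd[:, idx] / nrm
        gate = params.spatial_significance * noise_sd[idx] / np.sqrt(nrm)
        a = np.where(a > gate, a, 0.0)
        out[i].ravel()[idx] = np.clip(a, 0.0, None)
    return out


def _raw_traces(movie: Movie4D, A: np.ndarray) -> np.ndarray:
    """Movie averaged over each footprint's support (unweighted mean)."""
    t = movie.n_volumes
    Y = movie.data.reshape(t, -1)
    out = np.zeros((len(A), t))
    for i, a in enumerate(A):
        idx = np.flatnonzero(a.ravel())
        if idx.size:
            out[i] = Y[:, idx].mean(axis=1)
    return out


def run_extraction(
    movie: Movie4D, params: ExtractParams = ExtractParams(), n_iter: int = 30
) -> ComponentSet:
    """Two-pass extraction: seed, fit, screen; refit with survivors; merge.

    Pass 1 seeds components at correlation-image maxima, fits the
    factorization and screens components by peak SNR and spatial
    correlation.  Pass 2 refits the whole volume seeded only with the
    accepted components, merges near-duplicates and screens again.  Returns
    the accepted components with footprints, denoised and raw traces.
    """
    empty = ComponentSet(
        footprints=np.zeros((0, *movie.volume_shape)),
        traces=np.zeros((0, movie.n_volumes)),
        raw_traces=np.zeros((0, movie.n_volumes)),
        meta=movie.meta,
    )
    corr = correlation_image(movie)
    seeds = seed_components(corr, params)
    if not seeds:
        warnings.warn("no seeds found; returning an empty component set")
        return empty
    model = fit_model(movie, seeds, params, n_iter=n_iter)
    # Residual seeding: somata hidden behind a stronger neighbour at the
    # first seeding round reappear as correlated blobs in Y - AC - B.
    resid = Movie4D(movie.data - model.reconstruction(), movie.meta)
    resid_seeds = seed_components(correlation_image(resid), params)
    if resid_seeds:
        centers = []
        for i in range(model.n_components):
            nz = np.nonzero(model.A[i])
            w = model.A[i][nz]
            centers.append(np.array([(ax * w).sum() / w.sum() for ax in nz]))
        sep = 2.0 * np.asarray(params.gSig, dtype=float)
        new = [
            s for s in resid_seeds
            if all(np.sum(((np.asarray(s) - c) / sep) ** 2) >= 1.0 for c in centers)
        ]
        if new:
            model = fit_model(movie, new, params, n_iter=n_iter, init_model=model)
    flags = evaluate_components(model, movie, params.min_snr, params.min_spatial_corr)
    if not flags.any():
        warnings.warn("no components accepted in pass 1; returning an empty component set")
        return empty
    model = fit_model(
        movie, None, params, n_iter=n_iter, init_model=model.select(np.flatnonzero(flags))
    )
    model = merge_components(model, params.merge_thresh)
    flags = evaluate_components(model, movie, params.min_snr, params.min_spatial_corr)
    if not flags.any():
        warnings.warn("no components accepted after refit; returning an empty component set")
        return empty
    model = model.select(np.flatnonzero(flags))
    # Resolve the footprint/background degeneracy and trim insignificant or
    # sub-threshold weights before morphological filtering downstream.
    A = refine_footprints(movie, model, params)
    for i in range(len(A)):
        m = A[i].max()
        if m > 0:
            A[i][A[i] < params.footprint_threshold * m] = 0.0
    keep = [i for i in range(len(A)) if A[i].any()]
    A = A[keep]
    return ComponentSet(
        footprints=A,
        traces=model.C[keep],
        raw_traces=_raw_traces(movie, A),
        meta=movie.meta,
    )
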