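"""Morphological and statistical filtering of extracted components.

Two filters separate genuine neurons from factorization artifacts:

* a volume filter keeps components whose physical volume lies inside the
  morphological range of a soma (defaults 710-7605 um^3, i.e. 141-1500
  voxels at the (3 x 1.3 x 1.3) um voxel geometry, bounds inclusive);
* a variance filter discards components whose min-max-normalized trace has
  temporal variance above a threshold (default 0.06).  A slow residual
  background drift normalized to [0, 1] has variance near 1/12 ~ 0.083,
  whereas a sparse-transient calcium trace spends most samples near its
  baseline and scores p(1-p) << 0.06 — so high variance flags
  drift-dominated false positives.  The direction is exposed as a switch.

Trace normalization offers the two standard dF/F conventions:
``(F - Fmin)/(Fmax - Fmin)`` (amplitudes homogenized to [0, 1]) and
``(F - Fmin)/Fmin`` (event counts remain comparable across neurons).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .components import ComponentSet
from .errors import ConfigurationError, DegenerateTraceError, ParameterError

__all__ = ["volume_filter", "normalize_trace", "variance_filter"]

# Relative tolerance for the inclusive volume bounds: 1500 voxels at the 20x
# geometry must land exactly on the 7605 um^3 ceiling despite float rounding.
_REL_TOL = 1e-9


def volume_filter(
    cset: ComponentSet, vmin: float = 710.0, vmax: float = 7605.0
) -> ComponentSet:
    """Keep components with vmin <= voxel_count * voxel_volume <= vmax (inclusive)."""
    if cset.meta is None:
        raise ConfigurationError("volume filter needs voxel geometry metadata")
    if len(cset) == 0:
        return cset
    v = cset.volumes_um3
    keep = (v >= vmin * (1 - _REL_TOL)) & (v <= vmax * (1 + _REL_TOL))
    return cset.select(np.flatnonzero(keep))


def normalize_trace(trace: np.ndarray, mode: str = "minmax") -> np.ndarray:
    """dF/F normalization of a fluorescence trace.

    ``minmax``: (F - Fmin)/(Fmax - Fmin), mapped onto [0, 1].
    ``baseline``: (F - Fmin)/Fmin, zero at baseline and unbounded above.
    """
    trace = np.asarray(trace, dtype=np.float64)
    fmin = trace.min()
    if mode == "minmax":
        fmax = trace.max()
        if fmax == fmin:
            raise DegenerateTraceError("constant trace cannot be min-max normalized")
        return (trace - fmin) / (fmax - fmin)
    if mode == "baseline":
        if fmin <= 0:
            raise DegenerateTraceError(f"baseline normalization needs Fmin > 0, got {fmin}")
        return (trace - fmin) / fmin
    raise ParameterError(f"unknown normalization mode {mode!r}")


def variance_filter(
    cset: ComponentSet,
    threshold: float = 0.06,
    discard_high: bool = True,
) -> tuple[ComponentSet, pd.DataFrame]:
    """Filter components by the variance of their min-max-normalized trace.

    With ``discard_high`` (default) components whose normalized-trace
    variance exceeds ``threshold`` are removed (drift-dominated traces);
    constant traces are discarded as degenerate.  Returns the filtered set
    and a report listing every component's variance, kept flag and reason.
    """
    records = []
    keep_idx = []
    for k in range(len(cset)):
        try:
            norm = normalize_trace(cset.traces[k], "minmax")
        except DegenerateTraceError:
            records.append((cset.ids[k], np.nan, False, "degenerate"))
            continue
        var = float(np.var(norm))
        high = var > threshold
        kept = not high if discard_high else high
        reason = "kept" if kept else ("high variance" if high else "low variance")
        records.append((cset.ids[k], var, kept, reason))
        if kept:
            keep_idx.append(k)
    report = pd.DataFrame(records, columns=["id", "variance", "kept", "reason"])
    return cset.select(keep_idx), report
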