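"""Segmentation scoring against annotations and trace-recovery scoring.

Voxel-level precision/recall/F1 against a consensus (voxelwise AND) of
independent manual annotations, plus ground-truth-based scoring for
synthetic recordings: greedy Jaccard matching of footprints and per-match
Pearson correlation between recovered and planted traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ComponentSet
from .errors import DimensionError
from .synth import GroundTruth

__all__ = [
    "AnnotationSet",
    "consensus_annotation",
    "segmentation_metrics",
    "binarize_footprints",
    "match_and_score_traces",
    "snr_gain",
    "trace_snr",
]


@dataclass
class AnnotationSet:
    """Per-annotator binary masks over the same (selected) slices."""

    masks: list[np.ndarray]
    slice_indices: list[int] | None = None

    def __post_init__(self):
        if not self.masks:
            raise DimensionError("annotation set needs at least one annotator")
        shape = self.masks[0].shape
        for m in self.masks[1:]:
            if m.shape != shape:
                raise DimensionError("annotator masks must share one shape")


def consensus_annotation(annos: AnnotationSet) -> np.ndarray:
    """Voxelwise logical AND across annotators.

    Adding an annotator can only shrink the consensus (monotone).  A single
    annotator returns its own mask.
    """
    out = np.asarray(annos.masks[0], dtype=bool)
    for m in annos.masks[1:]:
        out = out & np.asarray(m, dtype=bool)
    return out


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Voxel-level (precision, recall, F1) of a binary prediction.

    Vanishing denominators follow the zero convention.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise DimensionError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def binarize_footprints(footprints: np.ndarray, rel_threshold: float = 0.1) -> np.ndarray:
    """Union mask of footprints, each kept above ``rel_threshold`` of its max."""
    out = np.zeros(footprints.shape[1:], dtype=bool)
    for fp in footprints:
        m = fp.max()
        if m > 0:
            out |= fp > rel_threshold * m
    return out


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    return inter / union if union else 0.0


def match_and_score_traces(
    cset: ComponentSet,
    gt: GroundTruth,
    jaccard_threshold: float = 0.1,
    rel_threshold: float = 0.1,
) -> pd.DataFrame:
    """Greedy one-to-one matching of components to planted neurons.

    Pairs are matched in descending footprint Jaccard order (binarized at
    ``rel_threshold`` of each footprint's max) down to ``jaccard_threshold``;
    each match is scored by the Pearson correlation between the denoised
    trace and the planted clean trace.  Rows report matches, misses
    (unmatched truths) and false positives (unmatched components); the
    result is invariant to component order.
    """
    n_pred = len(cset)
    n_true = len(gt.footprints)
    pred_masks = [
        (cset.footprints[i] > rel_threshold * cset.footprints[i].max())
        if cset.footprints[i].max() > 0
        else np.zeros(cset.footprints[i].shape, dtype=bool)
        for i in range(n_pred)
    ]
    true_masks = [gt.footprints[j] > 0 for j in range(n_true)]

    pairs = []
    for i in range(n_pred):
        for j in range(n_true):
            jac = _jaccard(pred_masks[i], true_masks[j])
            if jac >= jaccard_threshold:
                pairs.append((jac, i, j))
    # Deterministic greedy: best overlap first, ties by (truth, component) id.
    pairs.sort(key=lambda p: (-p[0], p[2], p[1]))

    used_pred, used_true = set(), set()
    rows = []
    for jac, i, j in pairs:
        if i in used_pred or j in used_true:
            continue
        used_pred.add(i)
        used_true.add(j)
        c, g = cset.traces[i], gt.clean_traces[j]
        if np.std(c) > 0 and np.std(g) > 0:
            r = float(np.corrcoef(c, g)[0, 1])
        else:
            r = np.nan
        rows.append(("match", int(cset.ids[i]), j, jac, r))
    for j in range(n_true):
        if j not in used_true:
            rows.append(("miss", None, j, 0.0, np.nan))
    for i in range(n_pred):
        if i not in used_pred:
            rows.append(("false_positive", int(cset.ids[i]), None, 0.0, np.nan))
    return pd.DataFrame(
        rows, columns=["kind", "component_id", "truth_id", "jaccard", "trace_r"]
    )


def trace_snr(trace: np.ndarray) -> float:
    """(peak - median) / robust noise, noise from first differences.

    The noise level is 1.4826 * MAD of the first differences divided by
    sqrt(2) (differencing doubles the noise variance).  Returns inf when the
    noise estimate vanishes but the trace has amplitude, 0 for a flat trace.
    """
    trace = np.asarray(trace, dtype=np.float64)
    amp = float(trace.max() - np.median(trace))
    d = np.diff(trace)
    mad = np.median(np.abs(d - np.median(d))) if d.size else 0.0
    sd = 1.4826 * mad / np.sqrt(2.0)
    if sd == 0:
        return np.inf if amp > 0 else 0.0
    return amp / sd


def snr_gain(raw_traces: np.ndarray, denoised_traces: np.ndarray) -> np.ndarray:
    """Per-component SNR_denoised / SNR_raw.

    Infinite denoised SNR (noise-free trace with signal) is reported as inf;
    a flat denoised trace gives gain 0.
    """
    raw_traces = np.atleast_2d(raw_traces)
    denoised_traces = np.atleast_2d(denoised_traces)
    if raw_traces.shape != denoised_traces.shape:
        raise DimensionError("raw and denoised trace arrays must have equal shape")
    out = np.empty(len(raw_traces))
    for i, (r, d) in enumerate(zip(raw_traces, denoised_traces)):
        s_r, s_d = trace_snr(r), trace_snr(d)
        if s_d == 0:
            out[i] = 0.0
        elif not np.isfinite(s_d):
            out[i] = np.inf
        elif s_r == 0 or not np.isfinite(s_r):
            out[i] = np.inf if s_d > 0 else 0.0
        else:
            out[i] = s_d / s_r
    return out
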