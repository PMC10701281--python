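"""Fluorescence-intensity preprocessing.

Raw relative fluorescence units are log2 transformed, quantile
normalized across samples, and smoothed along each protein with a
sliding mean over probe start positions within +/-8 aa.  The stages are
applied in that order; smoothing operates on occurrence-level rows
(``accession:start``) so a peptide shared between proteins is smoothed
in each protein context separately.

Matrices are plain :class:`pandas.DataFrame` objects (rows: probes or
occurrences, columns: samples) with the processing stage recorded in
``df.attrs["stage"]`` (``raw | log2 | quantile | smoothed``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .arrays import ProbeLibrary, parse_occurrence_id

logger = logging.getLogger("episcope")

STAGES = ("raw", "log2", "quantile", "smoothed")


def _stage(m: pd.DataFrame) -> str:
    return m.attrs.get("stage", "raw")


def log2_transform(m: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Elementwise log2 of raw fluorescence.

    Nonpositive values are an error unless a ``pseudocount`` is given,
    in which case it is added to every cell first.
    """
    values = m.to_numpy(dtype=float)
    if pseudocount is not None:
        values = values + pseudocount
    if (values <= 0).any():
        rows, cols = np.nonzero(values <= 0)
        cells = [
            f"({m.index[r]}, {m.columns[c]})" for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(
            f"nonpositive intensities at {len(rows)} cells "
            f"(e.g. {', '.join(cells)}); enable a pseudocount"
        )
    out = pd.DataFrame(np.log2(values), index=m.index, columns=m.columns)
    out.attrs.update(m.attrs)
    out.attrs["stage"] = "log2"
    return out


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common rank-mean distribution.

    Each column's sorted values are replaced by the across-column means
    of the order statistics; within-column rank order is preserved.
    Ties within a column receive the mean of the rank means they span.
    """
    if m.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returning as-is")
        out = m.copy()
        out.attrs["stage"] = "quantile"
        return out
    values = m.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        # mean rank-mean over each run of tied values
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            assigned[i : k + 1] = rank_means[i : k + 1].mean()
            i = k + 1
        out[order[:, j], j] = assigned
    res = pd.DataFrame(out, index=m.index, columns=m.columns)
    res.attrs.update(m.attrs)
    res.attrs["stage"] = "quantile"
    return res


def sliding_mean_smooth(
    m: pd.DataFrame,
    library: ProbeLibrary | None = None,
    half_window_aa: int = 8,
) -> pd.DataFrame:
    """Sliding mean over probe start positions within each protein.

    For an occurrence starting at ``s`` the smoothed value is the mean
    over all occurrences of the same protein with start in
    ``[s - w, s + w]`` (w = ``half_window_aa``), truncated at protein
    ends; smoothing never crosses protein boundaries.  Rows must be
    occurrence-level ``accession:start`` ids (restore redundant
    peptides to their proteins first).
    """
    if m.attrs.get("row_level") not in (None, "occurrence"):
        raise ValueError(
            "matrix rows are unique peptides; apply "
            "ProbeLibrary.restore_matrix before smoothing"
        )
    try:
        parsed = [parse_occurrence_id(i) for i in m.index]
    except (ValueError, TypeError) as exc:
        raise ValueError(
            "rows must be occurrence ids 'accession:start'; apply "
            "ProbeLibrary.restore_matrix first"
        ) from exc
    accs = np.array([a for a, _ in parsed])
    starts = np.array([s for _, s in parsed])
    values = m.to_numpy(dtype=float)
    out = np.empty_like(values)
    for acc in pd.unique(accs):
        mask = accs == acc
        idx = np.nonzero(mask)[0]
        s = starts[idx]
        order = np.argsort(s, kind="stable")
        s_sorted = s[order]
        v = values[idx[order]]
        csum = np.vstack([np.zeros(v.shape[1]), np.cumsum(v, axis=0)])
        lo = np.searchsorted(s_sorted, s_sorted - half_window_aa, side="left")
        hi = np.searchsorted(s_sorted, s_sorted + half_window_aa, side="right")
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
        out[idx[order]] = smoothed
    res = pd.DataFrame(out, index=m.index, columns=m.columns)
    res.attrs.update(m.attrs)
    res.attrs["stage"] = "smoothed"
    return res


def preprocess(
    raw: pd.DataFrame,
    library: ProbeLibrary,
    half_window_aa: int = 8,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Full pipeline: log2 -> quantile normalize -> restore -> smooth.

    ``raw`` is a unique-peptide-level matrix (rows ``probe_seq``); the
    result is an occurrence-level smoothed matrix ready for binding
    calls, with the pre-smoothing normalized matrix attached under
    ``attrs["normalized"]`` (per-chip probe values, used for
    replicate-scatter views).
    """
    m = log2_transform(raw, pseudocount=pseudocount)
    m = quantile_normalize(m)
    m = library.restore_matrix(m)
    smoothed = sliding_mean_smooth(m, library, half_window_aa=half_window_aa)
    smoothed.attrs["normalized"] = m
    return smoothed
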