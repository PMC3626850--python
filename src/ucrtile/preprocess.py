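"""Probe-level normalization, smoothing, and T-UCR summarization.

The tiling-array preprocessing chain is: log2 transform, quantile
normalization across arrays, window-3 median smoothing along each
region/strand probe track, then per-transcript summarization as the mean of
core-zone probe values.  A transcript is called expressed when its summary
exceeds the array background (the median expression of the array) in all
three cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["array_id", "cell_line", "treatment", "repeat"]
TREATMENTS = ("untreated", "ATRA")


def transcript_id(region: str, container: str) -> str:
    return f"{region}:{container}"


@dataclass
class IntensityMatrix:
    """Probe x array intensities plus the sample sheet and processing state.

    ``values`` is indexed by probe_id with one column per array; ``samples``
    is indexed by array_id with columns cell_line, treatment, repeat.  State
    flags accumulate as {"raw"} -> +"log2" -> +"quantile_normalized" ->
    +"smoothed".
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    state: frozenset[str] = frozenset({"raw"})

    def __post_init__(self) -> None:
        missing = [c for c in ("cell_line", "treatment", "repeat")
                   if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns {missing}")
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        if "log2" not in self.state and (self.values.to_numpy() < 0).any():
            raise ValueError("raw intensities must be non-negative")

    def with_values(self, values: pd.DataFrame, *add_state: str) -> "IntensityMatrix":
        return IntensityMatrix(values, self.samples, self.state | set(add_state))


@dataclass
class TUCRMatrix:
    """Transcript x array summary matrix (log2 scale).

    One row per (region, strand container) transcript; ``missing`` lists
    transcripts that had no core probes.  ``expressed`` is filled by
    :func:`call_expressed` (transcripts x cell lines, boolean).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    missing: list[str] = field(default_factory=list)
    expressed: pd.DataFrame | None = None


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    if "log2" in matrix.state:
        return matrix
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        # tiling intensities are strictly positive in practice; guard anyway
        raise ValueError("cannot log2-transform non-positive intensities")
    return matrix.with_values(
        pd.DataFrame(np.log2(vals), index=matrix.values.index,
                     columns=matrix.values.columns),
        "log2",
    )


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to their common mean distribution.

    After normalization every column holds the same multiset of values (the
    row-wise mean of the sorted columns) and within-column ranks are
    preserved.  Ties receive the mean of the reference values across the tied
    rank span.  A constant column has no ranks and raises.
    """
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    X = df.to_numpy(dtype=float)
    for j, col in enumerate(df.columns):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"array {col!r} is constant; ranks are undefined")
    reference = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        rmin = rankdata(X[:, j], method="min").astype(np.int64)
        rmax = rankdata(X[:, j], method="max").astype(np.int64)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    return matrix.with_values(
        quantile_normalize_frame(matrix.values), "quantile_normalized"
    )


def median_smooth(values, window: int = 3) -> np.ndarray:
    """Median-smooth an ordered probe track with a centered window.

    ``values`` may be 1-D (one array) or 2-D (positions x arrays).  At track
    boundaries the window is truncated to the available positions; the median
    of an even truncated window is the midpoint average.  Empty input returns
    an empty track.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[:, None]
    n = v.shape[0]
    out = np.empty_like(v)
    if n == 0:
        return out[:, 0] if squeeze else out
    half = window // 2
    if n >= window:
        windows = sliding_window_view(v, window, axis=0)
        out[half:n - half] = np.median(windows, axis=-1)
    edges = set(range(min(half, n))) | set(range(max(n - half, 0), n))
    for i in sorted(edges):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(v[lo:hi], axis=0)
    return out[:, 0] if squeeze else out


def smooth_tracks(matrix: IntensityMatrix, probes: pd.DataFrame,
                  window: int = 3) -> IntensityMatrix:
    """Median-smooth every (region, container) probe track in genomic order."""
    probes = (probes.set_index("probe_id").loc[matrix.values.index]
              .rename_axis("probe_id").reset_index())
    order = probes.sort_values(["region", "container", "start", "probe_id"])
    vals = matrix.values.to_numpy(dtype=float).copy()
    pos = {pid: i for i, pid in enumerate(matrix.values.index)}
    for _, grp in order.groupby(["region", "container"], sort=False):
        idx = [pos[pid] for pid in grp["probe_id"]]
        vals[idx, :] = median_smooth(vals[idx, :], window=window)
    return matrix.with_values(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        "smoothed",
    )


def summarize_tucrs(matrix: IntensityMatrix, probes: pd.DataFrame) -> TUCRMatrix:
    """Summarize each transcript as the mean of its core-zone probe values.

    Flank probes are excluded from transcript summaries (they remain in the
    probe matrix for host-gene exon use).  Transcripts whose region has no
    core probes in a container are flagged missing and excluded.
    """
    probes = (probes.set_index("probe_id").loc[matrix.values.index]
              .rename_axis("probe_id").reset_index())
    core = probes[probes["zone"] == "core"]
    tids = [transcript_id(r, c) for r, c in zip(probes["region"], probes["container"])]
    all_tids = sorted(set(tids))
    grouped = matrix.values.loc[core["probe_id"]].groupby(
        [transcript_id(r, c) for r, c in zip(core["region"], core["container"])]
    ).mean()
    missing = sorted(set(all_tids) - set(grouped.index))
    if missing:
        logger.warning("%d transcripts have no core probes and are dropped", len(missing))
    return TUCRMatrix(values=grouped, samples=matrix.samples, missing=missing)


def call_expressed(tucrs: TUCRMatrix,
                   background: str = "transcript",
                   per_line_rule: str = "any",
                   probe_matrix: IntensityMatrix | None = None) -> TUCRMatrix:
    """Flag transcripts as expressed and keep those expressed in all lines.

    The array background is the median expression of the array: by default
    the median over transcript summaries, optionally (``background="probe"``)
    the median over probe-level values.  A transcript is expressed in a cell
    line when its summary exceeds the background in at least one
    (``per_line_rule="any"``) or in all (``"all"``) arrays of that line, and
    is retained only when expressed in all three cell lines.
    """
    lines = tucrs.samples["cell_line"].unique()
    if len(lines) < 3:
        raise ValueError(f"expression calling expects >=3 cell lines, got {len(lines)}")
    if per_line_rule not in ("any", "all"):
        raise ValueError(f"unknown per_line_rule {per_line_rule!r}")
    if background == "transcript":
        bg = tucrs.values.median(axis=0)
    elif background == "probe":
        if probe_matrix is None:
            raise ValueError("probe-level background needs the probe matrix")
        bg = probe_matrix.values.median(axis=0)
    else:
        raise ValueError(f"unknown background mode {background!r}")
    above = tucrs.values.gt(bg, axis=1)
    grouped = above.T.groupby(tucrs.samples["cell_line"])
    agg = (grouped.any() if per_line_rule == "any" else grouped.all()).T
    keep = agg.all(axis=1)
    filtered = TUCRMatrix(
        values=tucrs.values.loc[keep],
        samples=tucrs.samples,
        missing=list(tucrs.missing),
        expressed=agg,
    )
    return filtered


def preprocess_matrix(matrix: IntensityMatrix, probes: pd.DataFrame,
               window: int = 3) -> tuple[IntensityMatrix, TUCRMatrix]:
    """Full chain: log2 -> quantile normalize -> median smooth -> summarize.

    Returns the smoothed probe-level matrix (needed for host-gene exon
    expression) and the transcript summary matrix.
    """
    m = log2_transform(matrix)
    m = quantile_normalize(m)
    m = smooth_tracks(m, probes, window=window)
    return m, summarize_tucrs(m, probes)
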