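"""ATRA differential-expression calling for T-UCR transcripts.

The filter cascade mirrors the tiling-array analysis it re-implements:
per-repeat treated/untreated fold changes within each cell line, per-line
folds as the geometric mean of the two repeat folds, a 1.5-fold cut in at
least 2 of 3 cell lines with at least 4 of 6 repeat folds in the same
direction, and a two-tailed Student's t-test across the six matched
biological sample pairs (p < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import TUCRMatrix
from .probes import CONTAINER_STRAND
from .regions import UCRegion

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    fold_threshold: float = 1.5
    min_lines: int = 2
    min_repeats: int = 4
    alpha: float = 0.05
    paired: bool = True          # unpaired equal-variance t available as option
    bh_correction: bool = False  # Benjamini-Hochberg, off to match raw p < alpha

    def validate(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not 1 <= self.min_lines <= 3:
            raise ValueError("min_lines must be between 1 and 3")
        if not 0 <= self.min_repeats <= 6:
            raise ValueError("min_repeats must be between 0 and 6")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")


def _matched_pairs(samples: pd.DataFrame) -> list[tuple[str, int, str, str]]:
    """(line, repeat, treated array, untreated array) for every matched pair."""
    pairs = []
    for (line, rep), grp in samples.groupby(["cell_line", "repeat"], sort=True):
        tr = grp.index[grp["treatment"] == "ATRA"]
        un = grp.index[grp["treatment"] == "untreated"]
        if len(tr) != 1 or len(un) != 1:
            raise ValueError(
                f"cell line {line!r} repeat {rep}: expected exactly one treated and "
                f"one untreated array, got {len(tr)} treated / {len(un)} untreated"
            )
        pairs.append((line, rep, tr[0], un[0]))
    return pairs


def per_repeat_folds(tucrs: TUCRMatrix) -> pd.DataFrame:
    """Linear fold change per transcript per matched (line, repeat) pair.

    fold = 2**(log2 treated - log2 untreated) within the matched repeat.
    Columns are a (cell_line, repeat) MultiIndex.
    """
    pairs = _matched_pairs(tucrs.samples)
    data = {
        (line, rep): np.exp2(tucrs.values[t] - tucrs.values[u])
        for line, rep, t, u in pairs
    }
    out = pd.DataFrame(data, index=tucrs.values.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_line", "repeat"])
    return out


def per_line_folds(repeat_folds: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-line fold as the geometric mean of the line's repeat folds."""
    if (repeat_folds.to_numpy() <= 0).any():
        raise ValueError("fold changes must be positive")
    log = np.log2(repeat_folds)
    return np.exp2(log.T.groupby(level="cell_line").mean().T)


def de_filter(line_folds, config: DEConfig | None = None,
              repeat_folds=None) -> dict:
    """Apply the fold-change filter cascade to one transcript.

    A line passes "up" when its fold >= threshold, "down" when its fold
    <= 1/threshold; the call direction is the majority direction among
    passing lines (a tie is ambiguous and fails).  When ``repeat_folds`` is
    given, at least ``min_repeats`` of the repeat-level folds must also pass
    in the call direction.
    """
    config = config or DEConfig()
    config.validate()
    folds = np.asarray(line_folds, dtype=float)
    if (folds <= 0).any():
        raise ValueError("fold changes must be positive")
    thr = config.fold_threshold
    up_lines = int((folds >= thr).sum())
    down_lines = int((folds <= 1.0 / thr).sum())
    ambiguous = up_lines == down_lines and up_lines > 0
    if up_lines > down_lines:
        direction = "up"
    elif down_lines > up_lines:
        direction = "down"
    else:
        direction = "up" if folds.prod() >= 1.0 else "down"  # cosmetic for reporting
    lines_passing = max(up_lines, down_lines)
    repeats_passing = 0
    repeats_ok = True
    if repeat_folds is not None:
        rf = np.asarray(repeat_folds, dtype=float)
        up_reps = int((rf >= thr).sum())
        down_reps = int((rf <= 1.0 / thr).sum())
        repeats_passing = up_reps if direction == "up" else down_reps
        repeats_ok = repeats_passing >= config.min_repeats
    passes = (not ambiguous) and lines_passing >= config.min_lines and repeats_ok
    return {
        "direction": direction,
        "lines_passing": lines_passing,
        "repeats_passing": repeats_passing,
        "passes": bool(passes),
        "ambiguous": bool(ambiguous),
    }


def ttest_treated_vs_untreated(tucrs: TUCRMatrix,
                               paired: bool = True) -> pd.Series:
    """Two-tailed Student's t-test on the six matched log2 sample pairs.

    Paired by default (treated vs untreated within each line and repeat);
    an unpaired equal-variance test is available.  Degenerate transcripts
    (zero variance of differences) report p = 1 when treated equals
    untreated everywhere and p = 0 otherwise, with a warning.
    """
    pairs = _matched_pairs(tucrs.samples)
    T = tucrs.values[[t for _, _, t, _ in pairs]].to_numpy(dtype=float)
    U = tucrs.values[[u for _, _, _, u in pairs]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            res = stats.ttest_rel(T, U, axis=1)
        else:
            res = stats.ttest_ind(T, U, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    diffs = T - U
    degenerate = np.isclose(diffs.std(axis=1), 0.0)
    if degenerate.any():
        zero = np.isclose(diffs, 0.0).all(axis=1)
        n_warn = int(degenerate.sum())
        logger.warning("%d transcripts have zero-variance differences", n_warn)
        p[degenerate & zero] = 1.0
        p[degenerate & ~zero] = 0.0
    return pd.Series(p, index=tucrs.values.index, name="p_value")


def build_de_table(tucrs: TUCRMatrix,
                   regions: list[UCRegion],
                   config: DEConfig | None = None,
                   correlation_flags: pd.Series | None = None) -> pd.DataFrame:
    """Rank significantly altered transcripts in the published table layout.

    Rows pass when the fold-filter cascade holds and the t-test p-value is
    below alpha; the table lists the up-regulated block then the
    down-regulated block, each sorted by ascending p.
    """
    config = config or DEConfig()
    config.validate()
    rf = per_repeat_folds(tucrs)
    lf = per_line_folds(rf)
    p = ttest_treated_vs_untreated(tucrs, paired=config.paired)
    if config.bh_correction:
        order = np.argsort(p.to_numpy())
        n = len(p)
        adj = np.empty(n)
        ranked = p.to_numpy()[order] * n / (np.arange(n) + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        p = pd.Series(np.minimum(adj, 1.0), index=p.index, name="p_value")

    by_region = {r.id: r for r in regions}
    rows = []
    for tid in tucrs.values.index:
        rid, container = tid.rsplit(":", 1)
        region = by_region[rid]
        verdict = de_filter(lf.loc[tid], config, repeat_folds=rf.loc[tid])
        orientation = "n/a"
        if region.is_intragenic:
            orientation = ("sense" if CONTAINER_STRAND[container] == region.host_strand
                           else "anti-sense")
        rows.append({
            "transcript": tid,
            **{f"fold_{line}": lf.loc[tid, line] for line in lf.columns},
            "direction": verdict["direction"],
            "lines_passing": verdict["lines_passing"],
            "repeats_passing": verdict["repeats_passing"],
            "p_value": p.loc[tid],
            "region_class": region.region_class,
            "orientation": orientation,
            "host_gene": region.host_gene or "0",
            "correlation_flag": (correlation_flags.get(tid, "n/a")
                                 if correlation_flags is not None else "n/a"),
            "passes": verdict["passes"] and p.loc[tid] < config.alpha,
        })
    table = pd.DataFrame(rows)
    table = table[table["passes"]].drop(columns="passes")
    up = table[table["direction"] == "up"].sort_values("p_value")
    down = table[table["direction"] == "down"].sort_values("p_value")
    return pd.concat([up, down], ignore_index=True)


def evaluate_de_calls(de_table: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Recall and false-discovery proportion of calls against planted truth."""
    planted = truth[truth["de_label"] != "null"].set_index("transcript")["de_label"]
    called = de_table.set_index("transcript")["direction"]
    tp = sum(1 for t, d in called.items() if planted.get(t) == d)
    fp = len(called) - tp
    fn = len(planted) - tp
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    fdp = fp / (tp + fp) if (tp + fp) else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "recall": recall, "fdp": fdp}
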