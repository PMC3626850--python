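"""Intragenic T-UCR vs host-gene expression correlation.

For every intragenic transcript whose tiled window covers host-gene exons,
the Pearson correlation between the T-UCR summary (mean core probe value)
and the host expression (mean of exonic probe values) is computed over the
experimental arrays, with significance from the exact t transform of r.
Class-wise summaries (median r, fraction significant) and the
anti-correlation screen for transcriptional interference sit on top.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import IntensityMatrix, TUCRMatrix
from .probes import CONTAINER_STRAND
from .regions import UCRegion
from .simulate import corr_class

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["transcript", "host_gene", "corr_class", "r", "n", "p", "flag"]

FLAGS = ("sig_correlated", "sig_anticorrelated", "not_correlated", "no_data")


def host_exon_expression(matrix: IntensityMatrix,
                         probe_gene_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene, per-array mean of exonic probe values (log2 scale).

    Genes without exon probes in any tiled window are simply absent from the
    result; downstream they carry the ``no_data`` flag.
    """
    pids = [p for p in matrix.values.index if p in probe_gene_map]
    if not pids:
        return pd.DataFrame(columns=matrix.values.columns)
    genes = [probe_gene_map[p] for p in pids]
    return matrix.values.loc[pids].groupby(genes).mean()


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its exact two-tailed significance.

    p is derived from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom,
    the closed form behind the classical critical-value tables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("series lengths differ")
    if n < 3:
        raise ValueError("Pearson significance needs n >= 3")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("constant series: correlation undefined")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def correlation_screen(tucrs: TUCRMatrix,
                       host_expression: pd.DataFrame,
                       regions: Iterable[UCRegion],
                       alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every intragenic transcript with its host gene.

    Returns the per-transcript result table and per-class summaries (median
    r, fraction significant at ``alpha``, n).  Intergenic transcripts are
    excluded; intragenic transcripts without host exon data are flagged
    ``no_data`` and excluded from the summaries.
    """
    by_region = {r.id: r for r in regions}
    rows = []
    for tid in tucrs.values.index:
        rid, container = tid.rsplit(":", 1)
        region = by_region[rid]
        if not region.is_intragenic:
            continue
        orientation = ("sense" if CONTAINER_STRAND[container] == region.host_strand
                       else "anti-sense")
        cls = corr_class(region.region_class, orientation)
        if region.host_gene not in host_expression.index:
            rows.append({"transcript": tid, "host_gene": region.host_gene,
                         "corr_class": cls, "r": np.nan, "n": 0, "p": np.nan,
                         "flag": "no_data"})
            continue
        x = tucrs.values.loc[tid].to_numpy()
        y = host_expression.loc[region.host_gene].to_numpy()
        r, p = pearson_with_p(x, y)
        if p < alpha:
            flag = "sig_correlated" if r > 0 else "sig_anticorrelated"
        else:
            flag = "not_correlated"
        rows.append({"transcript": tid, "host_gene": region.host_gene,
                     "corr_class": cls, "r": r, "n": len(x), "p": p, "flag": flag})
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    scored = results[results["flag"] != "no_data"]
    summaries = []
    for cls, grp in scored.groupby("corr_class", sort=True):
        summaries.append({
            "corr_class": cls,
            "n": len(grp),
            "median_r": float(grp["r"].median()),
            "frac_significant": float((grp["p"] < alpha).mean()),
        })
    return results, pd.DataFrame(summaries,
                                 columns=["corr_class", "n", "median_r",
                                          "frac_significant"])


def anticorrelation_screen(results: pd.DataFrame) -> pd.DataFrame:
    """Transcripts significantly anti-correlated with their host gene,
    sorted by ascending r (most negative first)."""
    if results.empty:
        return results.copy()
    hits = results[results["flag"] == "sig_anticorrelated"]
    return hits.sort_values("r").reset_index(drop=True)
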