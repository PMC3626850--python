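"""Host-gene reorientation, Spearman-distance Ward clustering, enrichment.

Strand-level expression is arbitrary with respect to the host gene, so each
region's two strand profiles are relabelled sense (S, transcribed with the
host gene) and anti-sense (A, against it) and concatenated, turning a 2R x F
transcript matrix into an R x 2F region matrix.  Regions are then clustered
hierarchically with Ward linkage on the 1 - Spearman-rho distance, and
cluster membership is tested for annotation over-/under-representation with
one-sided hypergeometric tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, rankdata

from .preprocess import transcript_id
from .regions import UCRegion

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ["cluster", "annotation", "cluster_size", "n_annotated",
                  "overlap", "p_over", "p_under"]


def reorient_merge(values: pd.DataFrame,
                   regions: Iterable[UCRegion]) -> pd.DataFrame:
    """Merge each region's two strand profiles into host-relative S/A blocks.

    ``values`` is a transcript (2R) x array (F) matrix with transcript ids
    ``region:container``.  The S block takes the container transcribed with
    the host gene (the + container for intergenic regions), the A block the
    other; output columns are ``S:<array>`` then ``A:<array>`` (shape R x 2F).
    Every input value appears exactly once in the output.  Only regions with
    both strand transcripts present are kept.
    """
    arrays = list(values.columns)
    rows, index = [], []
    for region in regions:
        plus = transcript_id(region.id, "plus")
        minus = transcript_id(region.id, "minus")
        if plus not in values.index or minus not in values.index:
            continue
        if region.region_class != "intergenic" and region.host_strand is None:
            raise ValueError(f"region {region.id}: intragenic without host strand")
        sense_first = region.host_strand != "-"  # intergenic: + container is S
        s_row = values.loc[plus if sense_first else minus]
        a_row = values.loc[minus if sense_first else plus]
        rows.append(np.concatenate([s_row.to_numpy(), a_row.to_numpy()]))
        index.append(region.id)
    columns = [f"S:{a}" for a in arrays] + [f"A:{a}" for a in arrays]
    return pd.DataFrame(rows, index=index, columns=columns)


def spearman_distance(reoriented: pd.DataFrame) -> pd.DataFrame:
    """Region x region distance d = 1 - Spearman rank correlation.

    Symmetric with zero diagonal, values in [0, 2].  A constant row has no
    ranks and raises.
    """
    if len(reoriented) < 2:
        raise ValueError("distance needs at least 2 regions")
    X = reoriented.to_numpy(dtype=float)
    const = np.isclose(X.std(axis=1), 0.0)
    if const.any():
        bad = list(reoriented.index[const])
        raise ValueError(f"constant expression rows (rank-undefined): {bad}")
    ranks = np.apply_along_axis(rankdata, 1, X)
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=reoriented.index, columns=reoriented.index)


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage table (merge order, heights)
    labels: pd.Series            # region -> cluster label in 1..k
    leaf_order: list             # dendrogram leaf order (region ids)


def ward_cluster(distance: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    Ward's objective is applied directly to the supplied (1 - rho)
    distances, cut into ``k`` clusters.  Deterministic for a given input.
    """
    n = len(distance)
    if k > n:
        raise ValueError(f"cannot cut {n} regions into {k} clusters")
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = [distance.index[i] for i in leaves_list(Z)]
    return ClusterResult(
        linkage=Z,
        labels=pd.Series(labels, index=distance.index, name="cluster"),
        leaf_order=order,
    )


def euclidean_rank_cluster(reoriented: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Alternative: Ward on Euclidean distances between row ranks."""
    X = np.apply_along_axis(rankdata, 1, reoriented.to_numpy(dtype=float))
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = [reoriented.index[i] for i in leaves_list(Z)]
    return ClusterResult(Z, pd.Series(labels, index=reoriented.index,
                                      name="cluster"), order)


def cluster_enrichment(labels: pd.Series,
                       annotation_sets: Mapping[str, set]) -> pd.DataFrame:
    """Hypergeometric over-/under-representation of annotations per cluster.

    Urn model: the universe is the set of clustered regions (N), each
    cluster is a draw of its size (n), annotated regions are the successes
    (K).  ``p_over`` = P(X >= k), ``p_under`` = P(X <= k) for the observed
    overlap k.  Annotations disjoint from the universe are skipped.
    """
    universe = set(labels.index)
    N = len(universe)
    rows = []
    for name, members in annotation_sets.items():
        K = len(members & universe)
        if K == 0:
            logger.warning("annotation %r does not intersect the region universe", name)
            continue
        for cluster in sorted(labels.unique()):
            in_cluster = set(labels.index[labels == cluster])
            n = len(in_cluster)
            k = len(in_cluster & members)
            rows.append({
                "cluster": cluster,
                "annotation": name,
                "cluster_size": n,
                "n_annotated": K,
                "overlap": k,
                "p_over": float(hypergeom.sf(k - 1, N, K, n)),
                "p_under": float(hypergeom.cdf(k, N, K, n)),
            })
    return pd.DataFrame(rows, columns=ENRICH_COLUMNS)
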