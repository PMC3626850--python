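"""Gene-level differential expression and gene-list overlap analysis.

Gene arrays use a stricter repeat rule than the tiling arrays: a gene is
called only when it changes at least 1.5-fold *in both* biological repeats.
The overlap stage intersects the up/up and down/down calls of two
experiments (e.g. a transcript knockdown vs ATRA treatment), optionally with
a hypergeometric enrichment p against a stated gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .simulate import GeneExperiment

GENE_DE_COLUMNS = ["gene", "fold_rep1", "fold_rep2", "mean_fold", "direction", "passes"]


def gene_de(experiment: GeneExperiment, threshold: float = 1.5,
            mean: str = "geometric") -> pd.DataFrame:
    """Call per-gene differential expression from a 2-repeat experiment.

    Per matched repeat, fold = test/ctrl on linear intensities; a gene is
    called up when both repeat folds are >= threshold, down when both are
    <= 1/threshold.  The summary fold is the geometric (default) or
    arithmetic mean of the two repeat folds.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    samples = experiment.samples
    folds = {}
    for rep, grp in samples.groupby("repeat", sort=True):
        ctrl = grp.index[grp["condition"] == "ctrl"]
        test = grp.index[grp["condition"] == "test"]
        if len(ctrl) != 1 or len(test) != 1:
            raise ValueError(f"repeat {rep}: need exactly one ctrl and one test array")
        folds[rep] = experiment.values[test[0]] / experiment.values[ctrl[0]]
    if len(folds) != 2:
        raise ValueError(f"expected 2 matched repeats, got {len(folds)}")
    f1, f2 = (folds[r] for r in sorted(folds))
    if mean == "geometric":
        mf = np.sqrt(f1 * f2)
    elif mean == "arithmetic":
        mf = (f1 + f2) / 2.0
    else:
        raise ValueError(f"unknown mean {mean!r}")
    up = (f1 >= threshold) & (f2 >= threshold)
    down = (f1 <= 1.0 / threshold) & (f2 <= 1.0 / threshold)
    out = pd.DataFrame({
        "gene": experiment.values.index,
        "fold_rep1": f1.to_numpy(),
        "fold_rep2": f2.to_numpy(),
        "mean_fold": mf.to_numpy(),
        "direction": np.where(up, "up", np.where(down, "down", "none")),
        "passes": (up | down).to_numpy(),
    }, columns=GENE_DE_COLUMNS)
    return out


@dataclass
class OverlapResult:
    """Direction-matched intersection of two gene DE call tables."""

    n_a_up: int
    n_b_up: int
    n_a_down: int
    n_b_down: int
    up_overlap: list[str] = field(default_factory=list)
    down_overlap: list[str] = field(default_factory=list)
    p_up: float | None = None
    p_down: float | None = None

    @property
    def n_up_overlap(self) -> int:
        return len(self.up_overlap)

    @property
    def n_down_overlap(self) -> int:
        return len(self.down_overlap)


def _called(table: pd.DataFrame, direction: str) -> set[str]:
    mask = table["passes"] & (table["direction"] == direction)
    return {g.casefold() for g in table.loc[mask, "gene"]}


def overlap_lists(a: pd.DataFrame, b: pd.DataFrame,
                  universe: int | None = None) -> OverlapResult:
    """Intersect the up/up and down/down calls of two gene DE tables.

    Gene symbols are matched exactly after case-folding.  When ``universe``
    (total number of assayable genes) is given, a one-sided hypergeometric
    enrichment p-value is attached per direction.
    """
    a_up, b_up = _called(a, "up"), _called(b, "up")
    a_down, b_down = _called(a, "down"), _called(b, "down")
    result = OverlapResult(
        n_a_up=len(a_up), n_b_up=len(b_up),
        n_a_down=len(a_down), n_b_down=len(b_down),
        up_overlap=sorted(a_up & b_up),
        down_overlap=sorted(a_down & b_down),
    )
    if universe is not None:
        union = len(a_up | b_up | a_down | b_down)
        if universe < union:
            raise ValueError(
                f"universe of {universe} genes is smaller than the union "
                f"of the call lists ({union})"
            )
        result.p_up = float(hypergeom.sf(result.n_up_overlap - 1, universe,
                                         len(a_up), len(b_up)))
        result.p_down = float(hypergeom.sf(result.n_down_overlap - 1, universe,
                                           len(a_down), len(b_down)))
    return result
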