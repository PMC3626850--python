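"""Packaged fixtures: the published table of ATRA-responsive T-UCRs.

The fixture ships the 32-row result table (per-cell-line fold changes,
region type, orientation to the host gene, host-gene correlation flag and
t-test p-value) exactly as printed, and :func:`verify_fixture` recomputes
the summary statistics that characterize it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diffexpr import DEConfig, de_filter

FOLD_COLUMNS = ["fold_sk_n_be", "fold_lan_5", "fold_sh_sy5y"]


def load_atra_table() -> pd.DataFrame:
    """Load the packaged 32-transcript result table."""
    with resources.files("ucrtile.data").joinpath("atra_tucr_table.tsv").open("rb") as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[])
    df[FOLD_COLUMNS] = df[FOLD_COLUMNS].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    return df


def verify_fixture(table: pd.DataFrame | None = None,
                   config: DEConfig | None = None) -> dict:
    """Recompute the fixture's summary statistics under the default DE filter.

    Directions are derived from the three per-cell-line folds with the
    1.5-fold / 2-of-3-lines rule (repeat-level folds are not printed, so the
    repeat criterion does not apply here).  The "independent transcripts"
    arithmetic counts intergenic rows, intragenic anti-sense rows, and sense
    rows whose expression is not significantly correlated with the host.
    """
    table = table if table is not None else load_atra_table()
    config = config or DEConfig()
    directions, passes = [], []
    for _, row in table.iterrows():
        verdict = de_filter([row[c] for c in FOLD_COLUMNS], config)
        directions.append(verdict["direction"])
        passes.append(verdict["passes"])
    table = table.assign(direction=directions, passes_de_filter=passes)

    corr = table["ucr_host_correlation"].str.strip().str.casefold()
    orientation = table["orientation"].str.strip().str.casefold()
    intergenic = table["type"].str.casefold() == "intergenic"
    antisense = orientation == "anti-sense"
    sense_uncorrelated = (orientation == "sense") & (corr == "not correlated")

    up = table["direction"] == "up"
    passing = table["passes_de_filter"]
    stats = {
        "n_rows": int(len(table)),
        "n_passing": int(passing.sum()),
        "n_up": int((up & passing).sum()),
        "n_down": int((~up & passing).sum()),
        "n_intergenic": int(intergenic.sum()),
        "n_intragenic_antisense": int(antisense.sum()),
        "n_sense_uncorrelated": int(sense_uncorrelated.sum()),
        "n_sig_correlated": int((corr == "sig. correlated").sum()),
        "all_p_below_alpha": bool((table["p_value"] < config.alpha).all()),
        "min_up_p": float(table.loc[up, "p_value"].min()),
        "min_down_p": float(table.loc[~up, "p_value"].min()),
    }
    stats["n_independent"] = (stats["n_intergenic"]
                              + stats["n_intragenic_antisense"]
                              + stats["n_sense_uncorrelated"])
    return stats
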