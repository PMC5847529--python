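"""Replicate reproducibility: distance-stratified Spearman correlation.

Counts for every fragment-pair combination are compared between the two
biological replicates of a cell line, per ligation class, within half-open
distance strata (defaults 0-500 kb, 500 kb-1 Mb, 1-1.5 Mb, >1.5 Mb). Pairs
with zero di-tags in both replicates are excluded; ties get average ranks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEFAULT_STRATA", "spearman_by_stratum"]

DEFAULT_STRATA: list[tuple[float, float]] = [
    (0, 500_000),
    (500_000, 1_000_000),
    (1_000_000, 1_500_000),
    (1_500_000, np.inf),
]


def _stratum_label(lo: float, hi: float) -> str:
    def fmt(x: float) -> str:
        if x == 0:
            return "0"
        if np.isinf(x):
            return "inf"
        if x >= 1_000_000 and x % 1_000_000 == 0:
            return f"{int(x / 1_000_000)}Mb"
        return f"{int(x / 1000)}kb"

    return f"{fmt(lo)}-{fmt(hi)}" if np.isfinite(hi) else f">{fmt(lo)}"


def spearman_by_stratum(
    pair_counts: pd.DataFrame,
    rep1,
    rep2,
    strata: list[tuple[float, float]] | None = None,
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Spearman rho between two replicates, per pair class and distance stratum.

    ``pair_counts`` is the long aggregated table (frag_lo, frag_hi,
    replicate_id, count, pair_class, distance). For each pair class and
    half-open stratum [lo, hi), rho is computed over pairs observed (count
    > 0) in at least one replicate; absent counts are 0. Strata with < 2
    usable pairs report rho = NaN.
    """
    strata = strata if strata is not None else DEFAULT_STRATA
    columns = ["cell_line", "pair_class", "stratum", "rho", "n_pairs"]
    if pair_counts.empty or "replicate_id" not in pair_counts.columns:
        return pd.DataFrame(columns=columns)
    sub = pair_counts[pair_counts["replicate_id"].isin([rep1, rep2])]
    wide = (
        sub.pivot_table(
            index=["frag_lo", "frag_hi", "pair_class", "distance"],
            columns="replicate_id",
            values="count",
            fill_value=0,
            aggfunc="sum",
        )
        .reindex(columns=[rep1, rep2], fill_value=0)
        .reset_index()
    )
    wide = wide[(wide[rep1] > 0) | (wide[rep2] > 0)]
    rows = []
    for pair_class, class_sub in wide.groupby("pair_class"):
        for lo, hi in strata:
            mask = (class_sub["distance"] >= lo) & (class_sub["distance"] < hi)
            x = class_sub.loc[mask, rep1].to_numpy()
            y = class_sub.loc[mask, rep2].to_numpy()
            if len(x) >= 2 and (np.std(x) > 0 and np.std(y) > 0):
                rho = float(stats.spearmanr(x, y).statistic)
            else:
                rho = np.nan
            rows.append(
                {
                    "cell_line": cell_line,
                    "pair_class": pair_class,
                    "stratum": _stratum_label(lo, hi),
                    "rho": rho,
                    "n_pairs": int(len(x)),
                }
            )
    return pd.DataFrame(rows)
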