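"""Valid di-tag ingestion: classification, pair-count aggregation, trans totals.

Di-tags arrive already cleaned (unique mapping, artefact and PCR-duplicate
removal are upstream concerns). Each di-tag is assigned exactly one class:

``within_capture``
    both ends in captured fragments, same chromosome, mid-point distance
    within ``max_dist`` (ends may lie in two different capture regions)
``capture_to_cis``
    exactly one end captured, same chromosome, distance within ``max_dist``
``trans``
    at least one end captured, ends on different chromosomes; retained only
    to count per-fragment trans-ligation totals N_T (interactability)
``off_target``
    neither end captured; discarded
``out_of_range``
    >= 1 end captured, same chromosome, distance beyond ``max_dist``;
    discarded from peak calling and NOT counted toward N_T

Same-fragment di-tags are invalid upstream; if present they are dropped with
a warning.
"""

from __future__ import annotations

import enum
import warnings

import numpy as np
import pandas as pd

from chicpeaks.genome import FragmentMap

__all__ = [
    "DiTagClass",
    "classify_ditag",
    "classify_ditags",
    "aggregate_pair_counts",
    "compute_trans_counts",
    "pivot_pair_counts",
]

DEFAULT_MAX_DIST = 5_000_000


class DiTagClass(str, enum.Enum):
    WITHIN_CAPTURE = "within_capture"
    CAPTURE_TO_CIS = "capture_to_cis"
    TRANS = "trans"
    OFF_TARGET = "off_target"
    OUT_OF_RANGE = "out_of_range"
    SAME_FRAGMENT = "same_fragment"


def classify_ditags(
    ditags: pd.DataFrame,
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Vectorised classification of a di-tag table.

    ``ditags`` has columns replicate_id, chromA, posA, chromB, posB with
    1-based positions. Returns the table with added columns frag_a, frag_b,
    distance (midpoint distance, NaN for trans) and ditag_class.
    """
    df = ditags.copy()
    frag_a = fragment_map.locate_many(
        df["chromA"].to_numpy(), df["posA"].to_numpy() - 1
    )
    frag_b = fragment_map.locate_many(
        df["chromB"].to_numpy(), df["posB"].to_numpy() - 1
    )
    fdf = fragment_map.df.set_index("frag_id")
    cap = fdf["captured"].to_numpy()
    pos = fdf.index.get_indexer(frag_a)
    posb = fdf.index.get_indexer(frag_b)
    cap_a = cap[pos]
    cap_b = cap[posb]
    chrom_a = fdf["chrom"].to_numpy()[pos]
    chrom_b = fdf["chrom"].to_numpy()[posb]
    mid = ((fdf["start"] + fdf["end"]) / 2).to_numpy()
    cis = chrom_a == chrom_b
    dist = np.where(cis, np.abs(mid[pos] - mid[posb]), np.nan)

    cls = np.full(len(df), DiTagClass.OFF_TARGET.value, dtype=object)
    any_cap = cap_a | cap_b
    both_cap = cap_a & cap_b
    same_frag = frag_a == frag_b
    in_range = cis & (dist <= max_dist)
    cls[any_cap & ~cis] = DiTagClass.TRANS.value
    cls[any_cap & cis & ~in_range] = DiTagClass.OUT_OF_RANGE.value
    cls[cap_a != cap_b] = np.where(
        in_range[cap_a != cap_b],
        DiTagClass.CAPTURE_TO_CIS.value,
        cls[cap_a != cap_b],
    )
    cls[both_cap & in_range] = DiTagClass.WITHIN_CAPTURE.value
    cls[~any_cap] = DiTagClass.OFF_TARGET.value
    if same_frag.any():
        warnings.warn(
            f"dropping {int(same_frag.sum())} same-fragment di-tags "
            "(invalid; expected to be removed upstream)",
            stacklevel=2,
        )
        cls[same_frag] = DiTagClass.SAME_FRAGMENT.value

    df["frag_a"] = frag_a
    df["frag_b"] = frag_b
    df["distance"] = dist
    df["ditag_class"] = cls
    return df


def classify_ditag(
    replicate_id,
    endA: tuple[str, int],
    endB: tuple[str, int],
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
) -> DiTagClass:
    """Classify a single di-tag (ends as (chrom, 1-based pos))."""
    df = pd.DataFrame(
        {
            "replicate_id": [replicate_id],
            "chromA": [endA[0]],
            "posA": [endA[1]],
            "chromB": [endB[0]],
            "posB": [endB[1]],
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = classify_ditags(df, fragment_map, max_dist)
    return DiTagClass(out["ditag_class"].iloc[0])


def aggregate_pair_counts(
    ditags: pd.DataFrame,
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Aggregate classified di-tags into canonical unordered pair counts.

    Only within_capture and capture_to_cis di-tags enter the table. Returns a
    long DataFrame with columns frag_lo, frag_hi (frag_lo < frag_hi),
    replicate_id, count, pair_class, distance. Invariant to the order of the
    input rows and to swapping endA/endB.
    """
    if "ditag_class" not in ditags.columns:
        ditags = classify_ditags(ditags, fragment_map, max_dist)
    keep = ditags[
        ditags["ditag_class"].isin(
            [DiTagClass.WITHIN_CAPTURE.value, DiTagClass.CAPTURE_TO_CIS.value]
        )
    ]
    if keep.empty:
        return pd.DataFrame(
            columns=["frag_lo", "frag_hi", "replicate_id", "count", "pair_class", "distance"]
        )
    lo = np.minimum(keep["frag_a"], keep["frag_b"])
    hi = np.maximum(keep["frag_a"], keep["frag_b"])
    tmp = pd.DataFrame(
        {
            "frag_lo": lo,
            "frag_hi": hi,
            "replicate_id": keep["replicate_id"].to_numpy(),
            "pair_class": keep["ditag_class"].to_numpy(),
            "distance": keep["distance"].to_numpy(),
        }
    )
    out = (
        tmp.groupby(["frag_lo", "frag_hi", "replicate_id"], as_index=False)
        .agg(count=("pair_class", "size"), pair_class=("pair_class", "first"),
             distance=("distance", "first"))
        .sort_values(["frag_lo", "frag_hi", "replicate_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def compute_trans_counts(
    ditags: pd.DataFrame,
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
    replicate_ids: list | None = None,
) -> pd.DataFrame:
    """Per-captured-fragment, per-replicate trans-ligation totals N_T.

    Every captured fragment receives a row for every replicate; fragments
    with no trans di-tags get N_T = 0. Trans means a different chromosome
    only — long-range same-chromosome pairs do not contribute.
    """
    if "ditag_class" not in ditags.columns:
        ditags = classify_ditags(ditags, fragment_map, max_dist)
    if replicate_ids is None:
        replicate_ids = sorted(ditags["replicate_id"].unique())
    trans = ditags[ditags["ditag_class"] == DiTagClass.TRANS.value]
    cap_ids = fragment_map.captured_frag_ids()
    cap_set = set(int(i) for i in cap_ids)
    rows = []
    for end in ("frag_a", "frag_b"):
        sub = trans[trans[end].isin(cap_set)]
        rows.append(sub[[end, "replicate_id"]].rename(columns={end: "frag_id"}))
    stacked = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    counts = (
        stacked.groupby(["frag_id", "replicate_id"]).size()
        if len(stacked)
        else pd.Series(dtype=int)
    )
    idx = pd.MultiIndex.from_product(
        [cap_ids, replicate_ids], names=["frag_id", "replicate_id"]
    )
    out = counts.reindex(idx, fill_value=0).rename("n_trans").reset_index()
    out["n_trans"] = out["n_trans"].astype(int)
    return out


def pivot_pair_counts(pair_counts: pd.DataFrame) -> pd.DataFrame:
    """Long pair counts -> wide table with one count column per replicate.

    Adds ``combined_count`` (sum over replicates). Count columns are named
    ``count_<replicate_id>``.
    """
    if pair_counts.empty:
        return pd.DataFrame(
            columns=["frag_lo", "frag_hi", "pair_class", "distance", "combined_count"]
        )
    wide = pair_counts.pivot_table(
        index=["frag_lo", "frag_hi", "pair_class", "distance"],
        columns="replicate_id",
        values="count",
        fill_value=0,
        aggfunc="sum",
    )
    wide.columns = [f"count_{c}" for c in wide.columns]
    wide = wide.reset_index()
    count_cols = [c for c in wide.columns if c.startswith("count_")]
    wide["combined_count"] = wide[count_cols].sum(axis=1).astype(int)
    return wide
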