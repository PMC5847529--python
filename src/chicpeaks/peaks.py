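"""Interaction-peak calling against a negative-binomial background model.

For every kept captured (bait) fragment, all cis partner fragments with
mid-point distance in [min_dist, max_dist] are candidate pairs; pairs never
observed contribute y = 0. The two ligation classes — within_capture (both
ends captured) and capture_to_cis (one end captured) — are analysed
separately throughout. Within equal-count distance bins we fit an NB
regression of the combined (replicate-summed) count on interactability and
distance covariates with a log link:

* capture_to_cis:   1 + ln N_T(bait, rep)  for each replicate        + ln D
* within_capture:   1 + [ln N_T(lo,rep) + ln N_T(hi,rep)]            + ln D
                      + [ln N_T(lo,rep) * ln N_T(hi,rep)]  per replicate

The within_capture encoding is symmetric in the two fragments, so results
are invariant to fragment order. Upper-tail p-values P(Y >= y) under the
fitted NB are Benjamini-Hochberg adjusted within (locus, cell line,
pair_class), and a pair is a peak when p_adj < alpha inside the distance
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from chicpeaks.genome import FragmentMap, Locus

__all__ = [
    "BackgroundFit",
    "enumerate_candidate_pairs",
    "assign_distance_bins",
    "fit_background_model",
    "score_candidates",
    "pair_pvalue",
    "adjust_fdr",
    "call_peaks",
    "write_bedpe",
    "read_bedpe",
    "write_longrange",
    "read_longrange",
]

DEFAULT_MIN_DIST = 10_000
DEFAULT_MAX_DIST = 5_000_000
DEFAULT_ALPHA = 0.01
POISSON_SIZE_SENTINEL = 1e8

WITHIN_CAPTURE = "within_capture"
CAPTURE_TO_CIS = "capture_to_cis"


@dataclass
class BackgroundFit:
    bin_id: int
    pair_class: str
    coefficients: pd.Series
    size: float
    n_pairs: int
    converged: bool
    dropped_terms: tuple[str, ...] = ()


def _region_to_locus(loci: list[Locus]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for locus in loci:
        for rid in locus.member_region_ids:
            mapping[rid] = locus.locus_id
    return mapping


def enumerate_candidate_pairs(
    fragment_map: FragmentMap,
    loci: list[Locus],
    kept_frag_ids: np.ndarray,
    pair_counts_wide: pd.DataFrame,
    trans_counts: pd.DataFrame,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Enumerate all candidate pairs for the kept baits, zeros included.

    Returns one row per canonical pair (frag_lo < frag_hi) with columns
    locus_id, pair_class, y (combined count), distance, ln_d, and the
    class-appropriate interactability covariates (``ln_nt_bait_<rep>`` or
    ``sum_ln_nt_<rep>`` / ``prod_ln_nt_<rep>``). Pairs whose partner is a
    captured-but-excluded fragment are dropped; a kept bait with N_T = 0 in
    any replicate is excluded with a warning (its ln N_T is undefined).
    Within-capture pairs spanning two loci are assigned the locus of the
    lower fragment.
    """
    fdf = fragment_map.df
    reps = sorted(trans_counts["replicate_id"].unique())
    nt = trans_counts.pivot_table(
        index="frag_id", columns="replicate_id", values="n_trans", fill_value=0
    ).reindex(columns=reps, fill_value=0)

    kept = np.asarray(sorted(set(int(k) for k in kept_frag_ids)))
    nt_kept = nt.reindex(kept, fill_value=0)
    bad = nt_kept[(nt_kept <= 0).any(axis=1)].index.to_numpy()
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} kept fragments with zero trans count in a replicate",
            stacklevel=2,
        )
        kept = np.setdiff1d(kept, bad)
    kept_set = set(int(k) for k in kept)

    region_locus = _region_to_locus(loci)
    frag_region = fdf.set_index("frag_id")["region_id"]
    cap_all = set(int(i) for i in fragment_map.captured_frag_ids())
    excluded_cap = cap_all - kept_set

    lo_list, hi_list, bait_list = [], [], []
    for chrom, sub in fdf.groupby("chrom", sort=False):
        ids = sub["frag_id"].to_numpy()
        mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
        bait_mask = np.isin(ids, kept)
        bait_idx = np.flatnonzero(bait_mask)
        for bi in bait_idx:
            m = mids[bi]
            left = np.searchsorted(mids, m - max_dist, side="left")
            lstop = np.searchsorted(mids, m - min_dist, side="right")
            rstart = np.searchsorted(mids, m + min_dist, side="left")
            right = np.searchsorted(mids, m + max_dist, side="right")
            partners = np.concatenate([np.arange(left, lstop), np.arange(rstart, right)])
            partners = partners[partners != bi]
            if len(partners) == 0:
                continue
            b_id = ids[bi]
            p_ids = ids[partners]
            lo_list.append(np.minimum(b_id, p_ids))
            hi_list.append(np.maximum(b_id, p_ids))
            bait_list.append(np.full(len(p_ids), b_id))
    if not lo_list:
        return pd.DataFrame(
            columns=["frag_lo", "frag_hi", "locus_id", "pair_class", "y", "distance", "ln_d"]
        )
    cand = pd.DataFrame(
        {
            "frag_lo": np.concatenate(lo_list),
            "frag_hi": np.concatenate(hi_list),
            "bait": np.concatenate(bait_list),
        }
    )
    # drop pairs whose partner is an excluded captured fragment
    partner = np.where(cand["bait"] == cand["frag_lo"], cand["frag_hi"], cand["frag_lo"])
    cand = cand[~pd.Series(partner).isin(excluded_cap).to_numpy()]
    partner = np.where(cand["bait"] == cand["frag_lo"], cand["frag_hi"], cand["frag_lo"])
    partner_captured = pd.Series(partner).isin(kept_set).to_numpy()
    cand["pair_class"] = np.where(partner_captured, WITHIN_CAPTURE, CAPTURE_TO_CIS)
    # within-capture pairs are generated from both baits: canonicalise and dedupe
    cand = cand.drop_duplicates(subset=["frag_lo", "frag_hi"]).reset_index(drop=True)

    mids = ((fdf["start"] + fdf["end"]) / 2).set_axis(fdf["frag_id"])
    cand["distance"] = (
        mids.reindex(cand["frag_hi"]).to_numpy() - mids.reindex(cand["frag_lo"]).to_numpy()
    )
    cand["distance"] = np.abs(cand["distance"])
    cand["ln_d"] = np.log(cand["distance"])

    # observed combined counts (0 where never seen)
    if len(pair_counts_wide):
        obs = pair_counts_wide.set_index(["frag_lo", "frag_hi"])["combined_count"]
        cand["y"] = (
            obs.reindex(pd.MultiIndex.from_frame(cand[["frag_lo", "frag_hi"]]))
            .fillna(0)
            .astype(int)
            .to_numpy()
        )
    else:
        cand["y"] = 0

    # locus of the bait end (lower fragment for within-capture pairs)
    anchor = np.where(cand["pair_class"] == WITHIN_CAPTURE, cand["frag_lo"], cand["bait"])
    regions = frag_region.reindex(anchor).to_numpy()
    cand["locus_id"] = [region_locus.get(r, "non_risk") for r in regions]

    # interactability covariates
    lnt = np.log(nt.clip(lower=1))
    for rep in reps:
        ln_rep = lnt[rep]
        ln_lo = ln_rep.reindex(cand["frag_lo"]).to_numpy()
        ln_hi = ln_rep.reindex(cand["frag_hi"]).to_numpy()
        ln_bait = ln_rep.reindex(cand["bait"]).to_numpy()
        wc = cand["pair_class"] == WITHIN_CAPTURE
        cand[f"ln_nt_bait_{rep}"] = np.where(wc, np.nan, ln_bait)
        cand[f"sum_ln_nt_{rep}"] = np.where(wc, ln_lo + ln_hi, np.nan)
        cand[f"prod_ln_nt_{rep}"] = np.where(wc, ln_lo * ln_hi, np.nan)
    return cand.drop(columns=["bait"]).reset_index(drop=True)


def assign_distance_bins(
    candidates: pd.DataFrame,
    n_bins: int = 100,
    min_bin_pairs: int = 200,
) -> pd.DataFrame:
    """Equal-count quantile distance bins, per pair class.

    Ties share a bin (binning is on distance values). Bins smaller than
    ``min_bin_pairs`` are merged into their nearest (adjacent) neighbour;
    when there are fewer candidates than bins the bin count is reduced to
    floor(n / min_bin_pairs), minimum 1. Adds an integer ``bin_id`` column
    (ids are unique across pair classes).
    """
    out = candidates.copy()
    out["bin_id"] = -1
    offset = 0
    for _, idx in out.groupby("pair_class").groups.items():
        d = out.loc[idx, "distance"]
        n = len(d)
        k = min(n_bins, max(1, n // min_bin_pairs)) if n < n_bins * min_bin_pairs else n_bins
        k = max(1, k)
        if d.nunique() == 1 or k == 1:
            codes = np.zeros(n, dtype=int)
        else:
            binned = pd.qcut(d, q=k, duplicates="drop")
            codes = binned.cat.codes.to_numpy().astype(int)
        codes = _merge_small_bins(codes, min_bin_pairs)
        out.loc[idx, "bin_id"] = codes + offset
        offset = int(out.loc[idx, "bin_id"].max()) + 1
    out["bin_id"] = out["bin_id"].astype(int)
    return out


def _merge_small_bins(codes: np.ndarray, min_bin_pairs: int) -> np.ndarray:
    """Merge adjacent distance bins until all have >= min_bin_pairs members."""
    codes = codes.copy()
    while True:
        uniq, counts = np.unique(codes, return_counts=True)
        if len(uniq) <= 1 or counts.min() >= min_bin_pairs:
            break
        i = int(np.argmin(counts))
        if i == 0:
            target = uniq[1]
        elif i == len(uniq) - 1:
            target = uniq[i - 1]
        else:
            target = uniq[i - 1] if counts[i - 1] <= counts[i + 1] else uniq[i + 1]
        codes[codes == uniq[i]] = target
    # re-label to consecutive ids preserving distance order
    uniq = np.unique(codes)
    relabel = {u: j for j, u in enumerate(uniq)}
    return np.vectorize(relabel.get)(codes)


def _design_columns(pair_class: str, replicates: list) -> list[str]:
    if pair_class == CAPTURE_TO_CIS:
        return [f"ln_nt_bait_{r}" for r in replicates] + ["ln_d"]
    return (
        [f"sum_ln_nt_{r}" for r in replicates]
        + [f"prod_ln_nt_{r}" for r in replicates]
        + ["ln_d"]
    )


def fit_background_model(
    bin_candidates: pd.DataFrame,
    pair_class: str,
    replicates: list,
) -> BackgroundFit:
    """NB regression (log link, ML dispersion) for one distance bin.

    Collinear or constant covariates are dropped with a note in
    ``dropped_terms``. On NB non-convergence the fit falls back to Poisson
    with a large-dispersion sentinel; an all-zero bin gets a degenerate fit
    whose expected means are ~0 (so every p-value is 1).
    """
    cols = _design_columns(pair_class, replicates)
    y = bin_candidates["y"].to_numpy(dtype=float)
    bin_id = int(bin_candidates["bin_id"].iloc[0]) if "bin_id" in bin_candidates else -1
    if y.sum() == 0:
        coef = pd.Series(0.0, index=["const"] + cols)
        coef["const"] = -20.0
        return BackgroundFit(bin_id, pair_class, coef, POISSON_SIZE_SENTINEL, len(y), True)

    X = bin_candidates[cols].copy()
    dropped: list[str] = []
    for c in cols:
        if np.nanstd(X[c].to_numpy()) < 1e-12:
            dropped.append(c)
    X = X.drop(columns=dropped)
    # drop exactly collinear columns (keep earlier terms)
    keep_cols = list(X.columns)
    M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in keep_cols])
    rank = np.linalg.matrix_rank(M)
    while rank < M.shape[1] and keep_cols:
        c = keep_cols.pop()
        dropped.append(c)
        M = np.column_stack([np.ones(len(X))] + [X[k].to_numpy() for k in keep_cols])
        rank = np.linalg.matrix_rank(M)
    exog = sm.add_constant(X[keep_cols], has_constant="add")

    converged = True
    size = POISSON_SIZE_SENTINEL
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, exog)
            res = model.fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        alpha = float(params[-1])
        if not np.all(np.isfinite(params)) or alpha <= 1e-8:
            raise RuntimeError("NB fit degenerate")
        coef = pd.Series(params[:-1], index=exog.columns)
        size = 1.0 / alpha
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            raise RuntimeError("NB fit did not converge")
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        coef = pd.Series(res.params, index=exog.columns)
        size = POISSON_SIZE_SENTINEL
        converged = True
    full = pd.Series(0.0, index=["const"] + cols)
    full.update(coef)
    return BackgroundFit(bin_id, pair_class, full, float(size), len(y), converged, tuple(dropped))


def score_candidates(
    candidates: pd.DataFrame,
    replicates: list,
    two_pass: bool = True,
) -> tuple[pd.DataFrame, list[BackgroundFit]]:
    """Fit per-bin background models and score every candidate pair.

    Adds ``mu_hat`` (expected count), ``size`` and ``p`` columns; returns the
    scored table and the per-bin fits. With ``two_pass`` (default), each bin
    is refit excluding extreme first-pass outliers (upper-tail p below
    0.5 / bin size, i.e. an expected half an exclusion per bin under the
    null) so that genuine interaction peaks do not inflate the background
    mean and dispersion they are tested against; all pairs, including the
    excluded outliers, are then rescored against the refit background.
    """
    out = candidates.copy()
    out["mu_hat"] = np.nan
    out["size"] = np.nan
    fits: list[BackgroundFit] = []
    groups = out.groupby(["pair_class", "bin_id"]).groups
    for (pair_class, bin_id), idx in groups.items():
        sub = out.loc[idx]
        fit = fit_background_model(sub, pair_class, replicates)
        cols = [c for c in fit.coefficients.index if c != "const"]
        X = sub[cols].to_numpy(dtype=float)
        eta = fit.coefficients["const"] + X @ fit.coefficients[cols].to_numpy()
        mu = np.exp(eta)
        if two_pass:
            p1 = pair_pvalue(sub["y"].to_numpy(), mu, fit.size)
            keep = p1 >= 0.5 / len(sub)
            if (~keep).any() and keep.sum() >= 2:
                fit = fit_background_model(sub.loc[np.asarray(idx)[keep]], pair_class, replicates)
                fit.bin_id = int(bin_id)
                fit.n_pairs = len(sub)
                cols = [c for c in fit.coefficients.index if c != "const"]
                X = sub[cols].to_numpy(dtype=float)
                eta = fit.coefficients["const"] + X @ fit.coefficients[cols].to_numpy()
                mu = np.exp(eta)
        fits.append(fit)
        out.loc[idx, "mu_hat"] = mu
        out.loc[idx, "size"] = fit.size
    out["p"] = pair_pvalue(
        out["y"].to_numpy(), out["mu_hat"].to_numpy(), out["size"].to_numpy()
    )
    return out, fits


def pair_pvalue(y, mu_hat, size):
    """Upper-tail probability P(Y >= y) under NB(mean mu_hat, size).

    y = 0 gives p = 1 exactly. Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu_hat, dtype=float)
    size_arr = np.broadcast_to(np.asarray(size, dtype=float), y.shape) if y.shape else np.asarray(size, dtype=float)
    p = np.asarray(size_arr / (size_arr + mu))
    out = stats.nbinom.sf(y - 1, size_arr, p)
    out = np.where(y <= 0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def adjust_fdr(pvalues: np.ndarray, groups: pd.Series | np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, optionally per group.

    Within each group: p_adj(i) = min_{j: p_(j) >= p_(i)} m * p_(j) / j,
    capped at 1 (step-up from the largest p).
    """
    p = np.asarray(pvalues, dtype=float)
    if groups is None:
        return _bh(p)
    groups = np.asarray(groups)
    out = np.empty_like(p)
    df = pd.DataFrame({"g": groups})
    for _, idx in df.groupby("g").groups.items():
        ii = np.asarray(idx)
        out[ii] = _bh(p[ii])
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_peaks(
    scored: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
    cell_line: str | None = None,
) -> pd.DataFrame:
    """BH-adjust per (locus, pair_class) and flag significant peaks.

    Returns the scored table with ``p_adj`` and ``significant`` columns,
    sorted by (locus_id, p_adj). With ``cell_line`` set, a column is added
    (the FDR grouping is per cell line by construction: one table per line).
    """
    out = scored.copy()
    grouping = out["locus_id"].astype(str) + "::" + out["pair_class"].astype(str)
    out["p_adj"] = adjust_fdr(out["p"].to_numpy(), grouping)
    out["significant"] = (
        (out["p_adj"] < alpha)
        & (out["distance"] >= min_dist)
        & (out["distance"] <= max_dist)
    )
    if cell_line is not None:
        out["cell_line"] = cell_line
    return out.sort_values(["locus_id", "p_adj"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# peak export / import


def _peak_coords(peaks: pd.DataFrame, fragment_map: FragmentMap) -> pd.DataFrame:
    fdf = fragment_map.df.set_index("frag_id")
    out = peaks.copy()
    for side in ("lo", "hi"):
        ids = out[f"frag_{side}"]
        out[f"chrom{side}"] = fdf["chrom"].reindex(ids).to_numpy()
        out[f"start{side}"] = fdf["start"].reindex(ids).to_numpy()
        out[f"end{side}"] = fdf["end"].reindex(ids).to_numpy()
    return out


def write_bedpe(peaks: pd.DataFrame, fragment_map: FragmentMap, path: str | Path) -> None:
    """Significant peaks as BEDPE with observed/expected/p columns appended."""
    sig = _peak_coords(peaks[peaks["significant"]], fragment_map)
    p_adj = sig["p_adj"].clip(lower=1e-300)
    rows = pd.DataFrame(
        {
            "chrom1": sig["chromlo"],
            "start1": sig["startlo"],
            "end1": sig["endlo"],
            "chrom2": sig["chromhi"],
            "start2": sig["starthi"],
            "end2": sig["endhi"],
            "name": sig["frag_lo"].astype(str) + "_" + sig["frag_hi"].astype(str),
            "score": np.round(-np.log2(p_adj)).astype(int),
            "strand1": ".",
            "strand2": ".",
            "observed": sig["y"],
            "expected": sig["mu_hat"],
            "p": sig["p"],
            "p_adj": sig["p_adj"],
            "pair_class": sig["pair_class"],
            "cell_line": sig.get("cell_line", "."),
        }
    )
    rows.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    cols = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
        "strand1", "strand2", "observed", "expected", "p", "p_adj", "pair_class",
        "cell_line",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom1": str, "chrom2": str})
    parts = df["name"].str.split("_", expand=True)
    df["frag_lo"] = parts[0].astype(int)
    df["frag_hi"] = parts[1].astype(int)
    return df


def write_longrange(peaks: pd.DataFrame, fragment_map: FragmentMap, path: str | Path) -> None:
    """WashU longrange text: one reciprocal line per anchor, score = -log2(p_adj)."""
    sig = _peak_coords(peaks[peaks["significant"]], fragment_map)
    score = -np.log2(sig["p_adj"].clip(lower=1e-300))
    lines = []
    for (_, row), s in zip(sig.iterrows(), score):
        a = (row["chromlo"], int(row["startlo"]), int(row["endlo"]))
        b = (row["chromhi"], int(row["starthi"]), int(row["endhi"]))
        lines.append(f"{a[0]}\t{a[1]}\t{a[2]}\t{b[0]}:{b[1]}-{b[2]},{s:.6g}")
        lines.append(f"{b[0]}\t{b[1]}\t{b[2]}\t{a[0]}:{a[1]}-{a[2]},{s:.6g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_longrange(path: str | Path, fragment_map: FragmentMap) -> pd.DataFrame:
    """Re-read a longrange file into canonical fragment pairs (deduplicated)."""
    rows = []
    text = Path(path).read_text()
    for line in text.strip().splitlines():
        if not line:
            continue
        chrom1, s1, e1, rest = line.split("\t")
        target, score = rest.rsplit(",", 1)
        chrom2, span = target.split(":")
        s2, e2 = span.split("-")
        fa = fragment_map.locate(chrom1, int(s1))
        fb = fragment_map.locate(chrom2, int(s2))
        rows.append((min(fa, fb), max(fa, fb), float(score)))
    df = pd.DataFrame(rows, columns=["frag_lo", "frag_hi", "score"])
    return df.drop_duplicates(subset=["frag_lo", "frag_hi"]).reset_index(drop=True)
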