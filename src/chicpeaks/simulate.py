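"""Synthetic Capture Hi-C data with known ground truth.

The generator mirrors the statistical structure the peak caller assumes:

* restriction fragments with geometric inter-cut spacing (HindIII-like
  ~4 kb mean), capture regions placed without overlap, one risk SNP per
  region at its midpoint;
* bimodal bait interactability — a ``noise_fraction`` of captured fragments
  are failed baits whose trans counts are Poisson with a small mean, the
  rest carry a gamma-distributed propensity G_i (so trans counts are
  marginally negative binomial) with the interactability factor
  B_i ∝ G_i normalised to mean 1 over working baits;
* pair counts per replicate drawn from NB(mu_ij, size_c) with
  mu_ij = k * replicate_scale * B_i * B_j * D_ij^(-alpha) * E_ij,
  where B_j = 1 for non-captured partners and E_ij >= 1 is the planted
  enrichment (1 everywhere except planted peaks).

Ground truth (planted pairs, B factors, noise/signal labels) is exported for
false-discovery and power evaluation. All stages derive their RNG streams
deterministically from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from chicpeaks.genome import (
    CaptureRegion,
    FragmentMap,
    GenomicInterval,
    Locus,
    RiskSNP,
    define_loci,
    mark_captured,
)
from chicpeaks.peaks import CAPTURE_TO_CIS, WITHIN_CAPTURE

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_fragment_map",
    "simulate_interactability",
    "simulate_ditags",
    "simulate_cell_line",
    "truth_evaluation",
    "preset_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generator (defaults = desk-scale
    emulation of a two-replicate capture design)."""

    n_chroms: int = 10
    chrom_length: int = 2_000_000
    mean_frag_size: int = 4_000
    n_capture_regions: int = 20
    region_width: int = 40_000
    noise_fraction: float = 0.2
    noise_trans_mean: float = 5.0
    signal_trans_mu: float = 300.0
    signal_trans_size: float = 8.0
    decay_exponent: float = 1.0
    base_rate: float = 400_000.0
    count_dispersion: float = 6.0
    replicate_scales: tuple[float, ...] = (1.0, 1.0)
    max_dist: int = 5_000_000
    # planted-peak policy: n pairs per class, eligibility by combined
    # background mean and the detectable distance window
    n_planted_cis: int = 0
    n_planted_within: int = 0
    planted_enrichment: float = 8.0
    planted_min_mean: float = 20.0
    planted_window: tuple[int, int] = (10_000, 5_000_000)

    def __post_init__(self) -> None:
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.decay_exponent <= 0 or self.base_rate < 0:
            raise ValueError("decay_exponent must be > 0 and base_rate >= 0")
        if self.planted_enrichment < 1:
            raise ValueError("planted enrichment must be >= 1")


@dataclass
class SimTruth:
    planted: pd.DataFrame  # frag_lo, frag_hi, pair_class, distance, enrichment
    B: pd.Series  # per captured fragment interactability factor
    labels: pd.Series  # per captured fragment: "noise" | "signal"


def preset_config(name: str) -> SimConfig:
    """Named study conditions: ``null`` (no planted peaks), ``default``
    (a handful of planted peaks for smoke runs), ``power`` (the power-
    evaluation configuration: enrichment 8 at combined background mean >= 20,
    both ligation classes planted)."""
    base = SimConfig()
    if name == "null":
        return base
    if name == "default":
        return replace(base, n_planted_cis=20, n_planted_within=5)
    if name == "power":
        return replace(base, n_planted_cis=40, n_planted_within=10)
    raise ValueError(f"unknown preset {name!r}")


def simulate_fragment_map(
    config: SimConfig, seed: int
) -> tuple[FragmentMap, list[CaptureRegion], list[RiskSNP], list[Locus]]:
    """Fragment map, capture design, risk SNPs and loci for one genome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    intervals: dict[str, list[GenomicInterval]] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    for chrom in chrom_names:
        cuts = []
        pos = 0
        while pos < config.chrom_length:
            step = rng.geometric(1.0 / config.mean_frag_size)
            pos += int(step)
            if pos < config.chrom_length:
                cuts.append(pos)
        bounds = [0] + cuts + [config.chrom_length]
        intervals[chrom] = [
            GenomicInterval(chrom, a, b) for a, b in zip(bounds[:-1], bounds[1:])
        ]
    fm = FragmentMap.from_intervals(intervals)

    # round-robin region placement, random offset within per-chrom slots
    per_chrom: dict[str, int] = {c: 0 for c in chrom_names}
    for i in range(config.n_capture_regions):
        per_chrom[chrom_names[i % config.n_chroms]] += 1
    regions: list[CaptureRegion] = []
    snps: list[RiskSNP] = []
    rid = 0
    for chrom in chrom_names:
        k = per_chrom[chrom]
        if k == 0:
            continue
        slot = config.chrom_length // k
        if config.region_width >= slot:
            raise ValueError("capture regions cannot be placed without overlap")
        for j in range(k):
            lo = j * slot
            start = int(lo + rng.integers(0, slot - config.region_width))
            iv = GenomicInterval(chrom, start, start + config.region_width)
            rsid = f"rs{rid}"
            mid = (iv.start + iv.end) // 2
            regions.append(CaptureRegion(f"region_{rid}", iv, (rsid,)))
            snps.append(RiskSNP(rsid, chrom, mid + 1))
            rid += 1
    fm = mark_captured(fm, regions)
    loci = define_loci(regions, snps, merge_gap=0)
    return fm, regions, snps, loci


def simulate_interactability(
    fragment_map: FragmentMap, config: SimConfig, seed: int
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Bait propensities, noise/signal labels, and per-replicate trans counts.

    Returns (B, labels, trans_counts) where trans_counts is the long table
    (frag_id, replicate_id, n_trans) over all captured fragments.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    cap = fragment_map.captured_frag_ids()
    if len(cap) == 0:
        empty = pd.DataFrame(columns=["frag_id", "replicate_id", "n_trans"])
        return pd.Series(dtype=float), pd.Series(dtype=object), empty
    noise = rng.random(len(cap)) < config.noise_fraction
    G = rng.gamma(
        shape=config.signal_trans_size,
        scale=config.signal_trans_mu / config.signal_trans_size,
        size=len(cap),
    )
    labels = pd.Series(np.where(noise, "noise", "signal"), index=cap)
    signal_mean = G[~noise].mean() if (~noise).any() else config.signal_trans_mu
    B = np.where(noise, config.noise_trans_mean / signal_mean, G / signal_mean)
    B = pd.Series(B, index=cap)
    rows = []
    for r, scale in enumerate(config.replicate_scales, start=1):
        lam = np.where(noise, config.noise_trans_mean, G) * scale
        counts = rng.poisson(lam)
        rows.append(
            pd.DataFrame({"frag_id": cap, "replicate_id": f"rep{r}", "n_trans": counts})
        )
    return B, labels, pd.concat(rows, ignore_index=True)


def _cis_candidate_pairs(
    fragment_map: FragmentMap, max_dist: int
) -> pd.DataFrame:
    """Canonical (frag_lo, frag_hi) pairs with >=1 captured end, cis, within max_dist."""
    fdf = fragment_map.df
    lo_l, hi_l = [], []
    for chrom, sub in fdf.groupby("chrom", sort=False):
        ids = sub["frag_id"].to_numpy()
        cap = sub["captured"].to_numpy()
        mids = ((sub["start"] + sub["end"]) / 2).to_numpy()
        for bi in np.flatnonzero(cap):
            m = mids[bi]
            left = np.searchsorted(mids, m - max_dist, side="left")
            right = np.searchsorted(mids, m + max_dist, side="right")
            partners = np.arange(left, right)
            partners = partners[partners != bi]
            lo_l.append(np.minimum(ids[bi], ids[partners]))
            hi_l.append(np.maximum(ids[bi], ids[partners]))
    pairs = pd.DataFrame(
        {"frag_lo": np.concatenate(lo_l), "frag_hi": np.concatenate(hi_l)}
    ).drop_duplicates()
    mids = ((fdf["start"] + fdf["end"]) / 2).set_axis(fdf["frag_id"])
    cap = fdf.set_index("frag_id")["captured"]
    pairs["distance"] = np.abs(
        mids.reindex(pairs["frag_hi"]).to_numpy() - mids.reindex(pairs["frag_lo"]).to_numpy()
    )
    both_cap = (
        cap.reindex(pairs["frag_lo"]).to_numpy() & cap.reindex(pairs["frag_hi"]).to_numpy()
    )
    pairs["pair_class"] = np.where(both_cap, WITHIN_CAPTURE, CAPTURE_TO_CIS)
    return pairs.reset_index(drop=True)


def simulate_ditags(
    fragment_map: FragmentMap,
    B: pd.Series,
    labels: pd.Series,
    config: SimConfig,
    seed: int,
    planted_pairs: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicate pair counts for every cis candidate pair, with planted peaks.

    Returns the long pair-count table (frag_lo, frag_hi, replicate_id,
    count, pair_class, distance; zero-count rows omitted) and the ground
    truth. By default planted pairs are drawn among signal-bait pairs inside
    the detectable window whose combined background mean is >=
    ``planted_min_mean``; a requested plant that cannot be satisfied raises.
    ``planted_pairs`` (frag_lo/frag_hi columns) overrides the policy with an
    explicit selection, e.g. to share true peaks across simulated cell
    lines; explicit plants outside the detectable window only warn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    pairs = _cis_candidate_pairs(fragment_map, config.max_dist)
    pairs = pairs[pairs["distance"] > 0].reset_index(drop=True)

    b_lo = B.reindex(pairs["frag_lo"]).fillna(1.0).to_numpy()
    b_hi = B.reindex(pairs["frag_hi"]).fillna(1.0).to_numpy()
    decay = pairs["distance"].to_numpy() ** (-config.decay_exponent)
    base_mu = config.base_rate * b_lo * b_hi * decay
    combined_mean = base_mu * sum(config.replicate_scales)

    # eligibility for planting: both ends signal (non-captured partners count
    # as signal), detectable window, background mean floor
    lab_lo = labels.reindex(pairs["frag_lo"]).fillna("signal").to_numpy()
    lab_hi = labels.reindex(pairs["frag_hi"]).fillna("signal").to_numpy()
    w_lo, w_hi = config.planted_window
    eligible = (
        (lab_lo == "signal")
        & (lab_hi == "signal")
        & (pairs["distance"] >= w_lo)
        & (pairs["distance"] <= w_hi)
        & (combined_mean >= config.planted_min_mean)
    )
    E = np.ones(len(pairs))
    planted_idx: list[int] = []
    if planted_pairs is not None:
        idx = pairs.reset_index().merge(
            planted_pairs[["frag_lo", "frag_hi"]], on=["frag_lo", "frag_hi"]
        )["index"].to_numpy()
        outside = (
            (pairs.loc[idx, "distance"] < w_lo) | (pairs.loc[idx, "distance"] > w_hi)
        ).sum()
        if outside:
            import warnings

            warnings.warn(
                f"{int(outside)} planted pairs fall outside the detectable window",
                stacklevel=2,
            )
        E[idx] = config.planted_enrichment
        planted_idx.extend(idx.tolist())
    else:
        for cls, n_req in (
            (CAPTURE_TO_CIS, config.n_planted_cis),
            (WITHIN_CAPTURE, config.n_planted_within),
        ):
            if n_req == 0:
                continue
            pool = np.flatnonzero(eligible & (pairs["pair_class"] == cls).to_numpy())
            if len(pool) < n_req:
                raise ValueError(
                    f"cannot plant {n_req} {cls} peaks; only {len(pool)} eligible pairs"
                )
            chosen = rng.choice(pool, size=n_req, replace=False)
            E[chosen] = config.planted_enrichment
            planted_idx.extend(chosen.tolist())

    size_c = config.count_dispersion
    rows = []
    for r, scale in enumerate(config.replicate_scales, start=1):
        mu = base_mu * scale * E
        p = size_c / (size_c + mu)
        counts = rng.negative_binomial(size_c, p)
        nz = counts > 0
        rows.append(
            pd.DataFrame(
                {
                    "frag_lo": pairs.loc[nz, "frag_lo"].to_numpy(),
                    "frag_hi": pairs.loc[nz, "frag_hi"].to_numpy(),
                    "replicate_id": f"rep{r}",
                    "count": counts[nz],
                    "pair_class": pairs.loc[nz, "pair_class"].to_numpy(),
                    "distance": pairs.loc[nz, "distance"].to_numpy(),
                }
            )
        )
    table = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["frag_lo", "frag_hi", "replicate_id"], kind="stable")
        .reset_index(drop=True)
    )
    planted = pairs.loc[sorted(planted_idx), ["frag_lo", "frag_hi", "pair_class", "distance"]].copy()
    planted["enrichment"] = config.planted_enrichment
    truth = SimTruth(planted=planted.reset_index(drop=True), B=B, labels=labels)
    return table, truth


def simulate_cell_line(
    config: SimConfig,
    fragment_map: FragmentMap,
    seed: int,
    planted_pairs: pd.DataFrame | None = None,
) -> dict:
    """Interactability + pair counts for one cell line on a shared genome.

    ``seed`` should differ between cell lines; the fragment map (geometry)
    is simulated once upstream so lines share coordinates. ``planted_pairs``
    forces a specific set of enriched pairs (shared biology across lines).
    """
    B, labels, trans = simulate_interactability(fragment_map, config, seed)
    pair_counts, truth = simulate_ditags(
        fragment_map, B, labels, config, seed, planted_pairs=planted_pairs
    )
    return {
        "B": B,
        "labels": labels,
        "trans_counts": trans,
        "pair_counts": pair_counts,
        "truth": truth,
    }


def truth_evaluation(
    calls: pd.DataFrame,
    truth: SimTruth,
    window: tuple[int, int] = (10_000, 5_000_000),
) -> dict:
    """False-discovery proportion and sensitivity of a called peak table.

    FDP = called-and-unplanted / max(1, called); sensitivity = called-and-
    planted / planted-within-detectable-window.
    """
    sig = calls[calls["significant"]] if "significant" in calls else calls
    called = set(zip(sig["frag_lo"], sig["frag_hi"]))
    detectable = truth.planted[
        (truth.planted["distance"] >= window[0]) & (truth.planted["distance"] <= window[1])
    ]
    planted = set(zip(detectable["frag_lo"], detectable["frag_hi"]))
    n_called = len(called)
    tp = len(called & planted)
    fdp = (n_called - tp) / max(1, n_called)
    sens = tp / len(planted) if planted else 0.0
    return {
        "n_called": n_called,
        "n_planted_detectable": len(planted),
        "true_positives": tp,
        "fdp": fdp,
        "sensitivity": sens,
    }
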