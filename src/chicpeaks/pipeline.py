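"""End-to-end orchestration: qc -> filter -> call -> compare -> targets.

The pipeline is a pure function of (inputs, config, seed). Inputs arrive
either as per-cell-line di-tag TSVs (classification and aggregation happen
here) or as pre-aggregated pair-count + trans-count TSVs (the simulator's
output format). Every stage's numbers are written as plain TSV so summary
reports are recomputable from the stage outputs they summarise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from chicpeaks import io as cio
from chicpeaks.comparison import (
    PeakSet,
    jaccard_dendrogram,
    locus_count_tests,
    peak_overlap_sets,
    permutation_sharing_test,
)
from chicpeaks.ditags import aggregate_pair_counts, classify_ditags, compute_trans_counts, pivot_pair_counts
from chicpeaks.genome import FragmentMap, Locus, define_loci
from chicpeaks.interactability import filter_fragments, fit_interactability_filters
from chicpeaks.peaks import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_DIST,
    DEFAULT_MIN_DIST,
    assign_distance_bins,
    call_peaks,
    enumerate_candidate_pairs,
    score_candidates,
    write_bedpe,
    write_longrange,
)
from chicpeaks.replicate_qc import spearman_by_stratum
from chicpeaks.targets import (
    assign_adjacent_locus_targets,
    assign_target_genes,
    compare_chic_vs_nearest,
    map_tss_to_fragments,
    nearest_gene,
)

logger = logging.getLogger("chicpeaks")

__all__ = ["RunConfig", "call_cell_line", "run_pipeline", "summarize_loci"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end run (paper defaults throughout)."""

    fragments_bed: str
    regions_bed: str
    snps_tsv: str
    # per cell line: either {"ditags": path} or
    # {"pair_counts": path, "trans_counts": path}
    cell_lines: dict = field(default_factory=dict)
    genes_tsv: str | None = None
    groups: dict = field(default_factory=dict)  # cell line -> label (e.g. ER status)
    alpha: float = DEFAULT_ALPHA
    min_dist: int = DEFAULT_MIN_DIST
    max_dist: int = DEFAULT_MAX_DIST
    n_bins: int = 100
    min_bin_pairs: int = 200
    merge_gap: int = 0
    n_perm: int = 10_000
    seed: int = 1
    manual_truncation: dict = field(default_factory=dict)  # line -> {rep: t}

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.min_dist < self.max_dist:
            raise ValueError("min_dist must be < max_dist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _load_cell_line(
    spec: dict, fragment_map: FragmentMap, max_dist: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (pair_counts long, trans_counts long) for one cell line."""
    if "ditags" in spec:
        ditags = classify_ditags(cio.read_ditag_tsv(spec["ditags"]), fragment_map, max_dist)
        counts = aggregate_pair_counts(ditags, fragment_map, max_dist)
        trans = compute_trans_counts(ditags, fragment_map, max_dist)
        return counts, trans
    pc = cio.read_pair_counts_tsv(spec["pair_counts"]).rename(
        columns={"frag_id_a": "frag_lo", "frag_id_b": "frag_hi"}
    )
    lo = np.minimum(pc["frag_lo"], pc["frag_hi"])
    hi = np.maximum(pc["frag_lo"], pc["frag_hi"])
    pc["frag_lo"], pc["frag_hi"] = lo, hi
    mids = ((fragment_map.df["start"] + fragment_map.df["end"]) / 2).set_axis(
        fragment_map.df["frag_id"]
    )
    cap = fragment_map.df.set_index("frag_id")["captured"]
    pc["distance"] = np.abs(
        mids.reindex(pc["frag_hi"]).to_numpy() - mids.reindex(pc["frag_lo"]).to_numpy()
    )
    both = cap.reindex(pc["frag_lo"]).to_numpy() & cap.reindex(pc["frag_hi"]).to_numpy()
    pc["pair_class"] = np.where(both, "within_capture", "capture_to_cis")
    trans = cio.read_trans_counts_tsv(spec["trans_counts"])
    return pc, trans


def call_cell_line(
    fragment_map: FragmentMap,
    loci: list[Locus],
    pair_counts: pd.DataFrame,
    trans_counts: pd.DataFrame,
    cell_line: str = "cell_line",
    alpha: float = DEFAULT_ALPHA,
    min_dist: int = DEFAULT_MIN_DIST,
    max_dist: int = DEFAULT_MAX_DIST,
    n_bins: int = 100,
    min_bin_pairs: int = 200,
    manual_t: dict | None = None,
) -> dict:
    """Interactability filter + background model + peak calls for one cell line."""
    fits = fit_interactability_filters(trans_counts, manual_t=manual_t)
    filt = filter_fragments(trans_counts, fits)
    kept = filt.loc[filt["kept"], "frag_id"].to_numpy()
    pct_excluded = 100.0 * (1 - len(kept) / max(1, len(filt)))
    logger.info(
        "%s: %d/%d captured fragments kept (%.1f%% excluded)",
        cell_line, len(kept), len(filt), pct_excluded,
    )
    wide = pivot_pair_counts(pair_counts)
    cand = enumerate_candidate_pairs(
        fragment_map, loci, kept, wide, trans_counts, min_dist, max_dist
    )
    reps = sorted(trans_counts["replicate_id"].unique())
    cand = assign_distance_bins(cand, n_bins=n_bins, min_bin_pairs=min_bin_pairs)
    scored, bg_fits = score_candidates(cand, reps)
    calls = call_peaks(scored, alpha, min_dist, max_dist, cell_line=cell_line)
    logger.info("%s: %d candidates, %d peaks", cell_line, len(calls), int(calls["significant"].sum()))
    return {
        "calls": calls,
        "filter": filt,
        "interactability_fits": fits,
        "background_fits": bg_fits,
        "pct_excluded": pct_excluded,
    }


def summarize_loci(
    calls_by_cell_line: dict[str, pd.DataFrame], loci: list[Locus]
) -> pd.DataFrame:
    """Per-locus, per-cell-line peak count, median peak distance and count of
    peaks > 2 Mb; a locus is informative if any cell line has >= 1 peak."""
    rows = []
    risk = [l for l in loci if l.risk]
    for locus in risk:
        counts = {}
        for cell_line, calls in calls_by_cell_line.items():
            sig = calls[(calls["significant"]) & (calls["locus_id"] == locus.locus_id)]
            counts[cell_line] = sig
        informative = any(len(s) > 0 for s in counts.values())
        for cell_line, sig in counts.items():
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "cell_line": cell_line,
                    "n_peaks": int(len(sig)),
                    "median_distance": float(sig["distance"].median()) if len(sig) else np.nan,
                    "n_peaks_gt_2mb": int((sig["distance"] > 2_000_000).sum()),
                    "informative": informative,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute qc -> filter -> call -> compare -> targets, writing TSV reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fm = cio.read_fragment_bed(config.fragments_bed)
    regions = cio.read_capture_bed(config.regions_bed)
    snps = cio.read_snp_tsv(config.snps_tsv)
    from chicpeaks.genome import mark_captured

    fm = mark_captured(fm, regions)
    # attach SNPs to regions by position for locus definition
    regions = [
        type(r)(
            r.region_id,
            r.interval,
            tuple(
                s.rsid
                for s in snps
                if s.chrom == r.interval.chrom and r.interval.start <= s.pos - 1 < r.interval.end
            ),
        )
        for r in regions
    ]
    loci = define_loci(regions, snps, merge_gap=config.merge_gap)

    results: dict[str, dict] = {}
    qc_tables = []
    filter_rows = []
    for cell_line, spec in config.cell_lines.items():
        pair_counts, trans = _load_cell_line(dict(spec), fm, config.max_dist)
        reps = sorted(trans["replicate_id"].unique())
        if len(reps) < 2:
            raise ValueError(f"{cell_line}: peak calling needs >= 2 replicates")
        qc = spearman_by_stratum(pair_counts, reps[0], reps[1], cell_line=cell_line)
        qc_tables.append(qc)
        res = call_cell_line(
            fm,
            loci,
            pair_counts,
            trans,
            cell_line=cell_line,
            alpha=config.alpha,
            min_dist=config.min_dist,
            max_dist=config.max_dist,
            n_bins=config.n_bins,
            min_bin_pairs=config.min_bin_pairs,
            manual_t=config.manual_truncation.get(cell_line),
        )
        results[cell_line] = res
        for rep, fit in res["interactability_fits"].items():
            filter_rows.append(
                {
                    "cell_line": cell_line,
                    "replicate": rep,
                    "t": fit.truncation_point,
                    "mu": fit.mu,
                    "size": fit.size,
                    "threshold": fit.threshold,
                    "n_fitted": fit.n_fitted,
                    "pct_excluded": res["pct_excluded"],
                }
            )
        write_bedpe(res["calls"], fm, outdir / f"peaks_{cell_line}.bedpe")
        write_longrange(res["calls"], fm, outdir / f"peaks_{cell_line}.longrange.txt")

    pd.concat(qc_tables, ignore_index=True).to_csv(
        outdir / "replicate_qc.tsv", sep="\t", index=False
    )
    pd.DataFrame(filter_rows).to_csv(
        outdir / "interactability_filter.tsv", sep="\t", index=False
    )

    calls_by_line = {cl: res["calls"] for cl, res in results.items()}
    summary = summarize_loci(calls_by_line, loci)
    summary.to_csv(outdir / "locus_summary.tsv", sep="\t", index=False)

    outputs: dict = {
        "fragment_map": fm,
        "loci": loci,
        "results": results,
        "locus_summary": summary,
    }

    if len(results) >= 2:
        peaksets = [PeakSet.from_calls(res["calls"], cl) for cl, res in results.items()]
        venn = peak_overlap_sets(peaksets)
        pd.DataFrame(
            [
                {"cell_lines": "+".join(sorted(k)), "n_peaks_exact": v}
                for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))
            ]
        ).to_csv(outdir / "peak_overlap.tsv", sep="\t", index=False)
        sharing = permutation_sharing_test(
            peaksets, n_perm=config.n_perm, seed=config.seed, mode="all_shared"
        )
        pd.DataFrame(
            [
                {
                    "cell_lines": "+".join(sharing.cell_lines),
                    "mode": sharing.mode,
                    "observed_shared": sharing.observed_shared,
                    "null_mean": sharing.null_mean,
                    "p": sharing.permutation_p,
                    "n_perm": sharing.n_permutations,
                }
            ]
        ).to_csv(outdir / "peak_sharing.tsv", sep="\t", index=False)
        dm, newick = jaccard_dendrogram(peaksets)
        dm.to_csv(outdir / "jaccard_dissimilarity.tsv", sep="\t")
        (outdir / "jaccard_dendrogram.nwk").write_text(newick + "\n")
        contrasts = []
        if config.groups:
            labels = sorted(set(config.groups.values()))
            by_label = {
                lab: [cl for cl, g in config.groups.items() if g == lab] for lab in labels
            }
            contrasts = [
                (by_label[a], by_label[b])
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            ]
        tests = locus_count_tests(summary, contrasts=contrasts, value_col="n_peaks")
        tests.to_csv(outdir / "locus_count_tests.tsv", sep="\t", index=False)
        outputs["sharing"] = sharing
        outputs["jaccard"] = dm
        outputs["tests"] = tests

    if config.genes_tsv:
        genes = cio.read_gene_tsv(config.genes_tsv)
        tss_frag = map_tss_to_fragments(genes, fm)
        direct = assign_target_genes(calls_by_line, loci, tss_frag, genes, fm, config.max_dist)
        adjacent = assign_adjacent_locus_targets(loci, calls_by_line, direct, fm, config.max_dist)
        assignments = direct + adjacent
        pd.DataFrame(
            [
                {
                    "locus_id": a.locus_id,
                    "gene": a.gene,
                    "mode": a.mode,
                    "supporting_cell_lines": ",".join(sorted(a.supporting_cell_lines)),
                    "mediating_locus": a.mediating_locus or ".",
                }
                for a in assignments
            ]
        ).to_csv(outdir / "target_genes.tsv", sep="\t", index=False)
        snp_by_locus = {}
        for locus in loci:
            if locus.risk and locus.snp_ids:
                snp = next(s for s in snps if s.rsid == locus.snp_ids[0])
                snp_by_locus[locus.locus_id] = nearest_gene(snp, genes)
        agreement = compare_chic_vs_nearest(assignments, snp_by_locus, loci)
        agreement.to_csv(outdir / "agreement.tsv", sep="\t", index=False)
        outputs["assignments"] = assignments
        outputs["agreement"] = agreement
    return outputs
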