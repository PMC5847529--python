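"""Putative target-gene assignment at GWAS risk loci, and the nearest-gene baseline.

A gene is a *direct* target of a locus when its TSS lies within (or in cis,
<= 5 Mb of) the locus's capture region and the TSS fragment is an end of a
significant interaction peak anchored in that locus in at least two cell
lines. A locus additionally gains the direct targets of an *adjacent* locus
(<= 5 Mb away) when a significant inter-locus peak connects the two in at
least one cell line. The nearest-gene baseline assigns the gene containing
the risk SNP (UTR/exon/intron), else the gene with the closest TSS; when
that gene is non-coding the nearest protein-coding gene is also reported.
Per-locus agreement categories compare the two approaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from chicpeaks.genome import FragmentMap, Locus, RiskSNP

__all__ = [
    "TargetAssignment",
    "NearestGeneCall",
    "map_tss_to_fragments",
    "assign_target_genes",
    "assign_adjacent_locus_targets",
    "nearest_gene",
    "compare_chic_vs_nearest",
    "enrichment_hypergeometric",
]

DEFAULT_MAX_DIST = 5_000_000


@dataclass(frozen=True)
class TargetAssignment:
    locus_id: str
    gene: str
    supporting_cell_lines: frozenset
    mode: str  # "direct" | "adjacent"
    mediating_locus: str | None = None


@dataclass(frozen=True)
class NearestGeneCall:
    rsid: str
    nearest_gene: str
    rule: str  # "within_gene" | "nearest_tss"
    nearest_coding_gene: str | None = None


def gene_tss(genes: pd.DataFrame) -> pd.Series:
    """1-based TSS per gene: txStart for + strand, txEnd for - strand."""
    return pd.Series(
        np.where(genes["strand"] == "+", genes["txStart"], genes["txEnd"]),
        index=genes["name"],
    )


def map_tss_to_fragments(genes: pd.DataFrame, fragment_map: FragmentMap) -> pd.Series:
    """Map each gene's TSS to the containing restriction fragment.

    Genes whose TSS falls outside the fragment map are skipped with a
    warning. Several genes may share one fragment (the method's resolution
    limit). Returns a Series gene name -> frag_id.
    """
    import warnings

    tss = gene_tss(genes)
    out = {}
    for row in genes.itertuples(index=False):
        pos0 = int(tss[row.name]) - 1
        try:
            out[row.name] = fragment_map.locate(row.chrom, pos0)
        except (KeyError, ValueError):
            warnings.warn(f"TSS of {row.name} outside fragment map; gene skipped", stacklevel=2)
    return pd.Series(out, dtype="int64")


def _locus_fragments(locus: Locus, fragment_map: FragmentMap) -> set[int]:
    """Captured fragments belonging to a locus (by member capture region)."""
    fdf = fragment_map.df
    mask = fdf["region_id"].isin(locus.member_region_ids)
    return set(int(i) for i in fdf.loc[mask, "frag_id"])


def assign_target_genes(
    peaks_by_cell_line: dict[str, pd.DataFrame],
    loci: list[Locus],
    tss_fragments: pd.Series,
    genes: pd.DataFrame,
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
    min_cell_lines: int = 2,
) -> list[TargetAssignment]:
    """Direct target assignment from significant peaks.

    ``peaks_by_cell_line`` maps cell line -> called peak table (the output
    of :func:`chicpeaks.peaks.call_peaks`); only rows with
    ``significant == True`` are used. A gene is assigned to a locus when its
    TSS is within ``max_dist`` of the locus hull and its TSS fragment is a
    peak end anchored in the locus (other end in a locus capture-region
    fragment) in >= ``min_cell_lines`` cell lines — not necessarily via the
    same partner fragment.
    """
    tss = gene_tss(genes)
    gene_chrom = genes.set_index("name")["chrom"]
    assignments: list[TargetAssignment] = []
    for locus in loci:
        if not locus.risk:
            continue
        locus_frags = _locus_fragments(locus, fragment_map)
        support: dict[str, set[str]] = {}
        for cell_line, calls in peaks_by_cell_line.items():
            sig = calls[calls["significant"]]
            # peak ends anchored in this locus
            lo_in = sig["frag_lo"].isin(locus_frags)
            hi_in = sig["frag_hi"].isin(locus_frags)
            anchored = sig[lo_in | hi_in]
            ends = set(anchored["frag_lo"]) | set(anchored["frag_hi"])
            for gene, frag in tss_fragments.items():
                if frag in ends:
                    support.setdefault(gene, set()).add(cell_line)
        for gene, lines in sorted(support.items()):
            if len(lines) < min_cell_lines:
                continue
            if gene_chrom.get(gene) != locus.hull.chrom:
                continue
            pos0 = int(tss[gene]) - 1
            dist = 0 if locus.hull.start <= pos0 < locus.hull.end else min(
                abs(pos0 - locus.hull.start), abs(pos0 - (locus.hull.end - 1))
            )
            if dist > max_dist:
                continue
            assignments.append(
                TargetAssignment(locus.locus_id, gene, frozenset(lines), "direct")
            )
    return assignments


def assign_adjacent_locus_targets(
    loci: list[Locus],
    peaks_by_cell_line: dict[str, pd.DataFrame],
    direct_assignments: list[TargetAssignment],
    fragment_map: FragmentMap,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[TargetAssignment]:
    """Indirect assignment through a significant peak to an adjacent locus.

    Locus X gains gene G (mode "adjacent", mediator Y) when X and Y are
    <= ``max_dist`` apart on one chromosome, a significant peak joins a
    fragment of X to a fragment of Y in >= 1 cell line, and G is a direct
    target of Y. Genes X already targets directly are not duplicated.
    """
    risk_loci = [l for l in loci if l.risk]
    frags = {l.locus_id: _locus_fragments(l, fragment_map) for l in risk_loci}
    direct_by_locus: dict[str, list[TargetAssignment]] = {}
    for a in direct_assignments:
        direct_by_locus.setdefault(a.locus_id, []).append(a)
    out: list[TargetAssignment] = []
    for X in risk_loci:
        have = {a.gene for a in direct_by_locus.get(X.locus_id, [])}
        for Y in risk_loci:
            if Y.locus_id == X.locus_id or Y.hull.chrom != X.hull.chrom:
                continue
            gap = max(X.hull.start, Y.hull.start) - min(X.hull.end, Y.hull.end)
            if gap > max_dist:
                continue
            connected = False
            for calls in peaks_by_cell_line.values():
                sig = calls[calls["significant"]]
                lo = sig["frag_lo"]
                hi = sig["frag_hi"]
                xy = (lo.isin(frags[X.locus_id]) & hi.isin(frags[Y.locus_id])) | (
                    lo.isin(frags[Y.locus_id]) & hi.isin(frags[X.locus_id])
                )
                if xy.any():
                    connected = True
                    break
            if not connected:
                continue
            for a in direct_by_locus.get(Y.locus_id, []):
                if a.gene in have:
                    continue
                out.append(
                    TargetAssignment(
                        X.locus_id,
                        a.gene,
                        a.supporting_cell_lines,
                        "adjacent",
                        mediating_locus=Y.locus_id,
                    )
                )
                have.add(a.gene)
    return out


def nearest_gene(snp: RiskSNP, genes: pd.DataFrame) -> NearestGeneCall:
    """Nearest-gene baseline for one risk SNP.

    A SNP inside a transcript span ([txStart, txEnd], 1-based inclusive)
    takes that gene (ties broken by distance to TSS, then name); otherwise
    the gene with the closest TSS. A non-coding nearest gene is accompanied
    by the nearest protein-coding gene.
    """
    sub = genes[genes["chrom"] == snp.chrom]
    if sub.empty:
        raise ValueError(f"no genes on chromosome {snp.chrom}")
    tss = gene_tss(sub)
    tss_dist = (tss - snp.pos).abs()
    within = sub[(sub["txStart"] <= snp.pos) & (snp.pos <= sub["txEnd"])]
    if len(within):
        ranked = sorted(within["name"], key=lambda g: (tss_dist[g], g))
        name, rule = ranked[0], "within_gene"
    else:
        ranked = sorted(sub["name"], key=lambda g: (tss_dist[g], g))
        name, rule = ranked[0], "nearest_tss"
    biotype = sub.set_index("name")["biotype"]
    coding = None
    if biotype[name] != "coding":
        coding_sub = sub[sub["biotype"] == "coding"]
        if len(coding_sub):
            coding = sorted(coding_sub["name"], key=lambda g: (tss_dist[g], g))[0]
    return NearestGeneCall(snp.rsid, name, rule, coding)


def compare_chic_vs_nearest(
    assignments: list[TargetAssignment],
    nearest_calls: dict[str, NearestGeneCall],
    loci: list[Locus],
) -> pd.DataFrame:
    """Per-locus agreement between CHi-C targets and the nearest gene.

    Categories: ``uninformative`` (no targets), ``sole`` (nearest gene is the
    unique target), ``one_of_several`` (nearest gene among several targets),
    ``other`` (targets exclude the nearest gene). ``nearest_calls`` maps
    locus_id -> NearestGeneCall for the locus's (lead) risk SNP.
    """
    targets_by_locus: dict[str, set[str]] = {}
    for a in assignments:
        targets_by_locus.setdefault(a.locus_id, set()).add(a.gene)
    rows = []
    for locus in loci:
        if not locus.risk:
            continue
        targets = targets_by_locus.get(locus.locus_id, set())
        call = nearest_calls.get(locus.locus_id)
        nearest = call.nearest_gene if call else None
        if not targets:
            cat = "uninformative"
        elif nearest in targets:
            cat = "sole" if len(targets) == 1 else "one_of_several"
        else:
            cat = "other"
        rows.append(
            {
                "locus_id": locus.locus_id,
                "category": cat,
                "n_targets": len(targets),
                "targets": ",".join(sorted(targets)),
                "nearest_gene": nearest,
            }
        )
    return pd.DataFrame(rows)


def enrichment_hypergeometric(
    target_genes, reference_list, universe_size: int
) -> tuple[float, int]:
    """Upper-tail hypergeometric enrichment of targets in a reference list.

    Returns (p, overlap) with p = P(X >= k) for X ~ Hypergeom(universe_size,
    |reference|, |targets|) and k the observed overlap.
    """
    targets = set(target_genes)
    reference = set(reference_list)
    if len(targets) > universe_size or len(reference) > universe_size:
        raise ValueError("gene sets larger than the universe")
    k = len(targets & reference)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(reference), len(targets)))
    return p, k
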