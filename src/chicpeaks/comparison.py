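"""Cross-cell-line comparison of interaction-peak sets.

Peaks are compared as canonical fragment pairs on a shared fragment map
(exact identity, no fuzzy matching). The permutation test for excess
sharing draws, for each cell line, a uniform random subset of its tested
candidate-pair universe of the same size as its observed peak set, and
counts pairs shared by every line (or exclusive to a focal line).

The sampler exploits a stepwise identity: the intersection of a uniform
k-subset of an N-set with any fixed m-subset is Hypergeometric(N, m, k).
Chaining this across cell lines (and across universe-membership strata for
the exclusive statistic) reproduces the exact distribution of the overlap
statistic with O(n_lines) random draws per permutation instead of
materialising the subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "PeakSet",
    "peak_overlap_sets",
    "permutation_sharing_test",
    "jaccard",
    "jaccard_dendrogram",
    "locus_count_tests",
]


@dataclass
class PeakSet:
    """A cell line's significant peaks and the universe of pairs it tested."""

    cell_line: str
    peaks: frozenset
    universe: frozenset

    def __post_init__(self) -> None:
        self.peaks = frozenset(self.peaks)
        self.universe = frozenset(self.universe)
        if not self.peaks <= self.universe:
            raise ValueError(f"{self.cell_line}: peaks must be a subset of the universe")

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, cell_line: str) -> "PeakSet":
        keys = list(zip(calls["frag_lo"], calls["frag_hi"]))
        sig = calls["significant"].to_numpy()
        return cls(
            cell_line,
            frozenset(k for k, s in zip(keys, sig) if s),
            frozenset(keys),
        )


def peak_overlap_sets(peaksets: list[PeakSet]) -> dict[frozenset, int]:
    """Venn counts: for every non-empty cell-line subset S, the number of
    peaks present in exactly the lines of S."""
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    names = [ps.cell_line for ps in peaksets]
    membership: dict = {}
    for ps in peaksets:
        for key in ps.peaks:
            membership.setdefault(key, set()).add(ps.cell_line)
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            counts[frozenset(combo)] = 0
    for key, lines in membership.items():
        counts[frozenset(lines)] += 1
    return counts


@dataclass
class SharingResult:
    cell_lines: tuple[str, ...]
    mode: str
    observed_shared: int
    permutation_p: float
    n_permutations: int
    null_mean: float = np.nan


def _chained_intersection(rng, N: int, sizes: list[int]) -> int:
    """Size of the intersection of independent uniform subsets of a common N-set."""
    x = sizes[0]
    for k in sizes[1:]:
        if x == 0:
            return 0
        x = int(rng.hypergeometric(x, N - x, k))
    return x


def permutation_sharing_test(
    peaksets: list[PeakSet],
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: str = "all_shared",
    focal: str | None = None,
) -> SharingResult:
    """Permutation test for an excess of shared (or exclusive) peaks.

    Each permutation redraws every cell line's peaks as a uniform subset of
    its own universe, preserving the per-line peak count. The statistic is
    the number of pairs present in all lines (``all_shared``) or present in
    the focal line and no other (``exclusive``).
    p = (1 + #{permutation statistic >= observed}) / (n_perm + 1).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the permutation test")
    if mode not in ("all_shared", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    for ps in peaksets:
        if len(ps.peaks) > len(ps.universe):
            raise ValueError("universe smaller than peak set")
    rng = np.random.default_rng(seed)
    names = [ps.cell_line for ps in peaksets]

    if mode == "all_shared":
        observed = len(frozenset.intersection(*[ps.peaks for ps in peaksets]))
        core = frozenset.intersection(*[ps.universe for ps in peaksets])
        M = len(core)
        stats_null = np.zeros(n_perm, dtype=int)
        n_sizes = [(len(ps.universe), len(ps.peaks)) for ps in peaksets]
        for b in range(n_perm):
            # peaks of each line falling in the common universe core
            m = [
                int(rng.hypergeometric(M, N - M, k)) if M < N else k
                for (N, k) in n_sizes
            ]
            stats_null[b] = _chained_intersection(rng, M, m) if M > 0 else 0
    else:
        if focal is None:
            focal = names[0]
        focal_ps = next(ps for ps in peaksets if ps.cell_line == focal)
        others = [ps for ps in peaksets if ps.cell_line != focal]
        observed = len(
            focal_ps.peaks.difference(*[ps.peaks for ps in others])
            if others
            else focal_ps.peaks
        )
        # stratify the focal universe by which other lines can hit each pair
        strata: dict[frozenset, int] = {}
        universes = {ps.cell_line: ps.universe for ps in others}
        for key in focal_ps.universe:
            pat = frozenset(n for n, u in universes.items() if key in u)
            strata[pat] = strata.get(pat, 0) + 1
        pats = list(strata)
        sizes = np.array([strata[p] for p in pats], dtype=int)
        kf = len(focal_ps.peaks)
        # per other line: the strata it participates in, plus the remainder of
        # its universe outside the focal strata (so its allocation over strata
        # is a single joint multivariate-hypergeometric draw)
        other_alloc_spec = {}
        for ps in others:
            idx = [i for i, pat in enumerate(pats) if ps.cell_line in pat]
            inside = int(sizes[idx].sum())
            rest = len(ps.universe) - inside
            other_alloc_spec[ps.cell_line] = (idx, np.append(sizes[idx], rest), len(ps.peaks))
        stats_null = np.zeros(n_perm, dtype=int)
        for b in range(n_perm):
            focal_alloc = (
                rng.multivariate_hypergeometric(sizes, kf) if len(sizes) else np.array([], dtype=int)
            )
            picks = {}  # (line, stratum index) -> picks in stratum
            for name, (idx, colors, k_o) in other_alloc_spec.items():
                alloc = rng.multivariate_hypergeometric(colors, k_o)
                for i, c in zip(idx, alloc[:-1]):
                    picks[(name, i)] = int(c)
            total = 0
            for i, (pat, M_g, f_g) in enumerate(zip(pats, sizes, focal_alloc)):
                x = int(f_g)
                if x == 0:
                    continue
                for name in pat:
                    c = picks[(name, i)]
                    # focal picks avoided by the line's c picks in this stratum
                    x = int(rng.hypergeometric(x, M_g - x, M_g - c)) if c < M_g else 0
                    if x == 0:
                        break
                total += x
            stats_null[b] = total
    p = (1 + int(np.sum(stats_null >= observed))) / (n_perm + 1)
    return SharingResult(
        cell_lines=tuple(names),
        mode=mode,
        observed_shared=int(observed),
        permutation_p=float(p),
        n_permutations=int(n_perm),
        null_mean=float(stats_null.mean()),
    )


def jaccard(setA, setB) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B|; two empty sets give 1 (warning)."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 1", stacklevel=2)
        return 1.0
    return len(A & B) / len(union)


def jaccard_dendrogram(
    peaksets: list[PeakSet], linkage_method: str = "average"
) -> tuple[pd.DataFrame, str]:
    """Hierarchical clustering of cell lines on Jaccard dissimilarity (1 - J).

    Returns the pairwise dissimilarity matrix and a Newick string with
    branch lengths from the linkage heights (default UPGMA/average linkage).
    """
    names = [ps.cell_line for ps in peaksets]
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard(peaksets[i].peaks, peaksets[j].peaks)
            D[i, j] = D[j, i] = d
    dm = pd.DataFrame(D, index=names, columns=names)
    if n < 2:
        return dm, f"({names[0]});" if names else ";"
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    tree = hierarchy.to_tree(Z)

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        children = ",".join(newick(c, node.dist) for c in (node.left, node.right))
        return f"({children}):{length:.6g}"

    return dm, newick(tree, tree.dist).rsplit(":", 1)[0] + ";"


def locus_count_tests(
    locus_counts: pd.DataFrame,
    contrasts: list[tuple[list[str], list[str]]] | None = None,
    value_col: str = "n_peaks",
) -> pd.DataFrame:
    """Non-parametric tests on per-locus values across cell lines.

    ``locus_counts`` is long-form with columns locus_id, cell_line and
    ``value_col`` (peak counts, or peak distances for distance comparisons).
    Reports a Kruskal-Wallis test across all cell lines plus two-sided
    Mann-Whitney U tests for each requested contrast (lists of cell-line
    names per side); the exact U distribution is used when both sides have
    n <= 8 and no ties, scipy's tie-corrected normal approximation otherwise.
    """
    groups = {
        cl: sub[value_col].to_numpy() for cl, sub in locus_counts.groupby("cell_line")
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 cell lines")
    for cl, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"cell line {cl} has no loci")
    rows = []
    H, p = stats.kruskal(*groups.values())
    rows.append(
        {"test": "kruskal_wallis", "groups": ",".join(sorted(groups)), "statistic": float(H), "p": float(p)}
    )
    for a_lines, b_lines in contrasts or []:
        a = np.concatenate([groups[cl] for cl in a_lines])
        b = np.concatenate([groups[cl] for cl in b_lines])
        n_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not n_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "test": "mann_whitney",
                "groups": "+".join(a_lines) + " vs " + "+".join(b_lines),
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
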