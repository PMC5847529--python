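"""Genome model: restriction fragments, capture regions, risk SNPs and loci.

Coordinates are 0-based half-open internally (BED convention). SNP and gene
positions are 1-based on disk and converted at the I/O boundary. Restriction
fragments tile each chromosome without gaps or overlaps and carry a global
``frag_id`` that strictly increases in genome order, so fragment identity is
a plain integer throughout the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RestrictionFragment",
    "CaptureRegion",
    "RiskSNP",
    "Locus",
    "FragmentMap",
    "digest_sequence",
    "mark_captured",
    "define_loci",
    "midpoint_distance",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RestrictionFragment:
    frag_id: int
    interval: GenomicInterval
    captured: bool = False
    region_id: str | None = None


@dataclass(frozen=True)
class CaptureRegion:
    region_id: str
    interval: GenomicInterval
    snp_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class RiskSNP:
    """GWAS risk SNP; ``pos`` is 1-based as published."""

    rsid: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("SNP positions are 1-based; pos must be >= 1")


@dataclass(frozen=True)
class Locus:
    """A risk locus: one or more merged capture regions annotated by risk SNPs.

    Loci without any annotating SNP are flagged ``risk=False`` and are
    excluded from locus-level reporting.
    """

    locus_id: str
    member_region_ids: tuple[str, ...]
    hull: GenomicInterval
    snp_ids: tuple[str, ...]
    risk: bool = True


def digest_sequence(
    sequence: str,
    recognition_site: str = "AAGCTT",
    cut_offset: int = 1,
) -> list[GenomicInterval]:
    """In-silico restriction digestion of one chromosome sequence.

    The default site/offset is HindIII (A^AGCTT). Fragment boundaries fall at
    ``site_start + cut_offset`` for every exact occurrence of the recognition
    site; a sequence with no site yields a single fragment covering it.

    Parameters
    ----------
    sequence
        Nucleotide string over {A, C, G, T, N} (case-insensitive).
    recognition_site
        Enzyme recognition sequence.
    cut_offset
        Cut position within the site, 0 <= cut_offset <= len(site).
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if not 0 <= cut_offset <= len(recognition_site):
        raise ValueError("cut_offset must lie within the recognition site")
    seq = sequence.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    site = recognition_site.upper()
    # overlapping occurrences via lookahead so e.g. palindromic runs all cut
    cuts = [m.start() + cut_offset for m in re.finditer(f"(?={re.escape(site)})", seq)]
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    bounds = sorted(set(bounds))
    return [
        GenomicInterval("chr", a, b) for a, b in zip(bounds[:-1], bounds[1:])
    ]


class FragmentMap:
    """Genome-ordered restriction fragments with capture annotation.

    Backed by a DataFrame with columns ``frag_id, chrom, start, end,
    captured, region_id`` sorted by (chrom, start); frag_id is the row
    index into genome order. Provides O(log n) position-to-fragment lookup
    per chromosome via searchsorted.
    """

    COLUMNS = ["frag_id", "chrom", "start", "end", "captured", "region_id"]

    def __init__(self, df: pd.DataFrame):
        required = {"frag_id", "chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"fragment table needs columns {sorted(required)}")
        df = df.copy()
        if "captured" not in df.columns:
            df["captured"] = False
        if "region_id" not in df.columns:
            df["region_id"] = None
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._validate_tiling(df)
        self.df = df[self.COLUMNS]
        self._by_chrom = {
            chrom: sub for chrom, sub in self.df.groupby("chrom", sort=False)
        }
        self._frag_index = self.df.set_index("frag_id")

    @staticmethod
    def _validate_tiling(df: pd.DataFrame) -> None:
        for chrom, sub in df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts >= ends).any():
                raise ValueError(f"empty fragment on {chrom}")
            if len(sub) > 1 and not (starts[1:] == ends[:-1]).all():
                raise ValueError(f"fragments do not tile {chrom} without gaps")
        ids = df.sort_values(["chrom", "start"])["frag_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("frag_id values must be unique")
        if not (np.diff(ids) > 0).all():
            raise ValueError("frag_id must strictly increase in genome order")

    @classmethod
    def from_intervals(cls, intervals_by_chrom: dict[str, list[GenomicInterval]]) -> "FragmentMap":
        rows = []
        fid = 0
        for chrom in sorted(intervals_by_chrom):
            for iv in sorted(intervals_by_chrom[chrom], key=lambda i: i.start):
                rows.append((fid, chrom, iv.start, iv.end, False, None))
                fid += 1
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def fragment(self, frag_id: int) -> RestrictionFragment:
        row = self._frag_index.loc[frag_id]
        return RestrictionFragment(
            frag_id=int(frag_id),
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            captured=bool(row["captured"]),
            region_id=row["region_id"] if pd.notna(row["region_id"]) else None,
        )

    def chrom_of(self, frag_id) -> "pd.Series | str":
        res = self._frag_index.loc[frag_id, "chrom"]
        return res

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id containing 0-based position ``pos``."""
        if chrom not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        sub = self._by_chrom[chrom]
        starts = sub["start"].to_numpy()
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        if idx < 0 or pos >= int(sub["end"].iloc[idx]):
            raise ValueError(f"position {chrom}:{pos} outside fragment map extent")
        return int(sub["frag_id"].iloc[idx])

    def locate_many(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Vectorised 0-based position -> frag_id lookup."""
        out = np.empty(len(pos), dtype=np.int64)
        chroms = np.asarray(chroms)
        pos = np.asarray(pos)
        for chrom in np.unique(chroms):
            if chrom not in self._by_chrom:
                raise KeyError(f"unknown chromosome {chrom!r}")
            sub = self._by_chrom[chrom]
            mask = chroms == chrom
            idx = np.searchsorted(sub["start"].to_numpy(), pos[mask], side="right") - 1
            if (idx < 0).any():
                raise ValueError(f"position before start of {chrom}")
            if (pos[mask] >= sub["end"].to_numpy()[idx]).any():
                raise ValueError(f"position beyond extent of {chrom}")
            out[mask] = sub["frag_id"].to_numpy()[idx]
        return out

    def captured_frag_ids(self) -> np.ndarray:
        return self.df.loc[self.df["captured"], "frag_id"].to_numpy()

    def midpoints(self) -> pd.Series:
        return ((self.df["start"] + self.df["end"]) / 2).set_axis(self.df["frag_id"])


def mark_captured(
    fragments: FragmentMap, capture_regions: list[CaptureRegion]
) -> FragmentMap:
    """Flag fragments overlapping a capture region (>= 1 bp, half-open).

    A fragment spanning two regions is assigned the first region in
    coordinate order. Idempotent: flags are recomputed from scratch.
    """
    df = fragments.df.copy()
    df["captured"] = False
    df["region_id"] = None
    regions = sorted(capture_regions, key=lambda r: (r.interval.chrom, r.interval.start))
    for reg in regions:
        iv = reg.interval
        if iv.chrom not in fragments._by_chrom:
            raise KeyError(f"capture region {reg.region_id} on unknown chromosome {iv.chrom}")
        hit = (df["chrom"] == iv.chrom) & (df["start"] < iv.end) & (df["end"] > iv.start)
        newly = hit & ~df["captured"]
        df.loc[hit, "captured"] = True
        df.loc[newly, "region_id"] = reg.region_id
    return FragmentMap(df)


def define_loci(
    capture_regions: list[CaptureRegion],
    risk_snps: list[RiskSNP],
    merge_gap: int = 0,
) -> list[Locus]:
    """Collapse nearby capture regions into analysis loci.

    Regions on the same chromosome whose gap is <= ``merge_gap`` bp are merged
    into one locus (default 0: merge only overlapping or book-ended regions).
    A locus inherits every SNP falling inside a member region; loci with no
    SNP are flagged non-risk (captured but not part of locus-level reporting).
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    snps_by_chrom: dict[str, list[RiskSNP]] = {}
    for snp in risk_snps:
        snps_by_chrom.setdefault(snp.chrom, []).append(snp)
    loci: list[Locus] = []
    regions = sorted(capture_regions, key=lambda r: (r.interval.chrom, r.interval.start))
    cluster: list[CaptureRegion] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0].interval.chrom
        hull = GenomicInterval(
            chrom,
            min(r.interval.start for r in cluster),
            max(r.interval.end for r in cluster),
        )
        snp_ids = [s for r in cluster for s in r.snp_ids]
        # also pick up SNPs located inside the hull but not annotated on a region
        for snp in snps_by_chrom.get(chrom, []):
            if hull.start <= snp.pos - 1 < hull.end and snp.rsid not in snp_ids:
                snp_ids.append(snp.rsid)
        loci.append(
            Locus(
                locus_id=f"locus_{len(loci)}",
                member_region_ids=tuple(r.region_id for r in cluster),
                hull=hull,
                snp_ids=tuple(snp_ids),
                risk=len(snp_ids) > 0,
            )
        )

    for reg in regions:
        if (
            cluster
            and reg.interval.chrom == cluster[-1].interval.chrom
            and reg.interval.start - max(r.interval.end for r in cluster) <= merge_gap
        ):
            cluster.append(reg)
        else:
            flush()
            cluster = [reg]
    flush()
    return loci


def midpoint_distance(
    fragA: RestrictionFragment | GenomicInterval,
    fragB: RestrictionFragment | GenomicInterval,
) -> float | None:
    """Distance in bp between fragment mid-points; None for trans pairs.

    Midpoints are exact halves ((start+end)/2), so distances are multiples
    of 0.5 bp and no rounding rule is needed.
    """
    ivA = fragA.interval if isinstance(fragA, RestrictionFragment) else fragA
    ivB = fragB.interval if isinstance(fragB, RestrictionFragment) else fragB
    if ivA.chrom != ivB.chrom:
        return None
    return abs(ivA.midpoint() - ivB.midpoint())
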