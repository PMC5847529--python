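"""Readers and writers for the pipeline's plain-text interchange formats.

Formats:

* fragment map — BED4 ``chrom  start  end  frag_id`` (captured flag and
  region id re-derivable from the capture-region BED; an extended 6-column
  variant with ``captured``/``region_id`` is written for convenience and
  accepted on read)
* capture regions — BED4 ``chrom  start  end  region_id``
* risk SNPs — TSV with header ``rsid  chrom  pos  locus_label`` (pos 1-based)
* di-tags — TSV with header ``replicate_id  chromA  posA  chromB  posB``
  (positions 1-based)
* pre-aggregated pair counts — TSV ``frag_id_a  frag_id_b  replicate_id  count``
* trans counts — TSV ``frag_id  replicate_id  n_trans``
* gene models — refFlat-like TSV ``name  chrom  strand  txStart  txEnd  biotype``
  (txStart/txEnd 1-based inclusive)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from chicpeaks.genome import CaptureRegion, FragmentMap, GenomicInterval, RiskSNP

__all__ = [
    "read_fragment_bed",
    "write_fragment_bed",
    "read_capture_bed",
    "write_capture_bed",
    "read_snp_tsv",
    "write_snp_tsv",
    "read_ditag_tsv",
    "read_pair_counts_tsv",
    "write_pair_counts_tsv",
    "read_trans_counts_tsv",
    "write_trans_counts_tsv",
    "read_gene_tsv",
    "write_gene_tsv",
]


def read_fragment_bed(path: str | Path) -> FragmentMap:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    df.columns = FragmentMap.COLUMNS[1:2] + FragmentMap.COLUMNS[2:4] + ["frag_id"] + (
        ["captured", "region_id"] if df.shape[1] == 6 else []
    )
    if "captured" in df.columns:
        df["captured"] = df["captured"].astype(int).astype(bool)
        df["region_id"] = df["region_id"].where(df["region_id"] != ".", None)
    return FragmentMap(df)


def write_fragment_bed(fm: FragmentMap, path: str | Path, extended: bool = True) -> None:
    df = fm.df[["chrom", "start", "end", "frag_id"]].copy()
    if extended:
        df["captured"] = fm.df["captured"].astype(int)
        df["region_id"] = fm.df["region_id"].fillna(".")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_capture_bed(path: str | Path) -> list[CaptureRegion]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    return [
        CaptureRegion(row[3], GenomicInterval(row[0], int(row[1]), int(row[2])))
        for row in df.itertuples(index=False)
    ]


def write_capture_bed(regions: list[CaptureRegion], path: str | Path) -> None:
    rows = [
        (r.interval.chrom, r.interval.start, r.interval.end, r.region_id)
        for r in sorted(regions, key=lambda r: (r.interval.chrom, r.interval.start))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_snp_tsv(path: str | Path) -> list[RiskSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [RiskSNP(r.rsid, r.chrom, int(r.pos)) for r in df.itertuples(index=False)]


def write_snp_tsv(snps: list[RiskSNP], path: str | Path, labels: dict[str, str] | None = None) -> None:
    rows = [
        (s.rsid, s.chrom, s.pos, (labels or {}).get(s.rsid, "."))
        for s in snps
    ]
    pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "locus_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_ditag_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromA": str, "chromB": str})
    required = {"replicate_id", "chromA", "posA", "chromB", "posB"}
    if not required.issubset(df.columns):
        raise ValueError(f"di-tag TSV needs columns {sorted(required)}")
    return df


def read_pair_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"frag_id_a", "frag_id_b", "replicate_id", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair-count TSV needs columns {sorted(required)}")
    return df


def write_pair_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["frag_id_a", "frag_id_b", "replicate_id", "count"]].to_csv(
        path, sep="\t", index=False
    )


def read_trans_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"frag_id", "replicate_id", "n_trans"}
    if not required.issubset(df.columns):
        raise ValueError(f"trans-count TSV needs columns {sorted(required)}")
    return df


def write_trans_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["frag_id", "replicate_id", "n_trans"]].to_csv(path, sep="\t", index=False)


def read_gene_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"name", "chrom", "strand", "txStart", "txEnd", "biotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene TSV needs columns {sorted(required)}")
    return df


def write_gene_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[["name", "chrom", "strand", "txStart", "txEnd", "biotype"]].to_csv(
        path, sep="\t", index=False
    )
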