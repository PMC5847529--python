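import numpy as np
import pandas as pd
import pytest

from chicpeaks.genome import (
    CaptureRegion,
    FragmentMap,
    GenomicInterval,
    RiskSNP,
    define_loci,
    mark_captured,
)


def uniform_fragment_map(chrom_sizes: dict[str, int], frag_size: int) -> FragmentMap:
    """Fragment map with fixed-width fragments tiling each chromosome."""
    intervals = {}
    for chrom, size in chrom_sizes.items():
        bounds = list(range(0, size, frag_size)) + [size]
        bounds = sorted(set(bounds))
        intervals[chrom] = [
            GenomicInterval(chrom, a, b) for a, b in zip(bounds[:-1], bounds[1:])
        ]
    return FragmentMap.from_intervals(intervals)


@pytest.fixture
def megabase_map():
    """Two chromosomes of 1 Mb fragments (8 Mb + 3 Mb); first fragment of
    chrA is captured. Useful for distance-class boundary tests."""
    fm = uniform_fragment_map({"chrA": 8_000_000, "chrB": 3_000_000}, 1_000_000)
    region = CaptureRegion("regA", GenomicInterval("chrA", 0, 1_000_000))
    return mark_captured(fm, [region]), [region]


@pytest.fixture
def target_fixture():
    """Hand-built 3-cell-line / 3-locus / 6-gene scenario with known truth.

    chr1 is tiled by 100 fragments of 1 kb. Loci: A = region [10000,12000)
    (frags 10-11), B = [50000,52000) (frags 50-51), C = [80000,82000)
    (frags 80-81, no peaks). Hand-placed significant peaks give the direct
    targets A -> {GA1, GB2}, B -> {GB1}; the line1 inter-locus peak (11,50)
    adds adjacent targets A -> GB1 and B -> {GA1, GB2}.
    """
    fm = uniform_fragment_map({"chr1": 100_000}, 1_000)
    regions = [
        CaptureRegion("RA", GenomicInterval("chr1", 10_000, 12_000), ("rsA",)),
        CaptureRegion("RB", GenomicInterval("chr1", 50_000, 52_000), ("rsB",)),
        CaptureRegion("RC", GenomicInterval("chr1", 80_000, 82_000), ("rsC",)),
    ]
    snps = [
        RiskSNP("rsA", "chr1", 10_501),
        RiskSNP("rsB", "chr1", 50_501),
        RiskSNP("rsC", "chr1", 80_501),
    ]
    fm = mark_captured(fm, regions)
    loci = define_loci(regions, snps, merge_gap=0)
    genes = pd.DataFrame(
        [
            # name, chrom, strand, txStart, txEnd (1-based inclusive), biotype
            ("GA1", "chr1", "+", 20_501, 25_000, "coding"),   # TSS frag 20
            ("GA2", "chr1", "+", 8_001, 15_000, "coding"),    # spans rsA
            ("GA3", "chr1", "+", 30_001, 31_000, "coding"),   # TSS frag 30
            ("GB1", "chr1", "-", 52_001, 55_500, "coding"),   # TSS = txEnd -> frag 55
            ("GB2", "chr1", "+", 60_001, 61_000, "noncoding"),  # TSS frag 60
            ("GFar", "chr1", "+", 99_001, 99_900, "coding"),  # TSS frag 99
        ],
        columns=["name", "chrom", "strand", "txStart", "txEnd", "biotype"],
    )

    def calls(pairs):
        return pd.DataFrame(
            {
                "frag_lo": [p[0] for p in pairs],
                "frag_hi": [p[1] for p in pairs],
                "significant": True,
            }
        )

    peaks_by_line = {
        "line1": calls([(10, 20), (11, 30), (11, 50)]),
        "line2": calls([(11, 20), (50, 55), (10, 60)]),
        "line3": calls([(51, 55), (10, 99), (10, 60)]),
    }
    return {
        "fm": fm,
        "regions": regions,
        "snps": snps,
        "loci": loci,
        "genes": genes,
        "peaks_by_line": peaks_by_line,
    }
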