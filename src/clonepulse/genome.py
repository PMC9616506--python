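"""Genome model: 22 autosomes on a 1-Mb bin grid.

Chromosome lengths are GRCh38 autosome lengths rounded to the nearest
megabase. Sex chromosomes are excluded: the copy-number analyses modelled
here are dominated by autosomal aberrations.
"""

from __future__ import annotations

MB = 1_000_000

# GRCh38 autosome lengths in megabases (rounded).
AUTOSOME_MB: dict[str, int] = {
    "chr1": 249, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 182,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51,
}

AUTOSOMES: tuple[str, ...] = tuple(AUTOSOME_MB)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering: chr1..chr22, then X, Y, then anything else."""
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (int(name), "")
    if name == "X":
        return (23, "")
    if name == "Y":
        return (24, "")
    return (25, name)


def bin_grid(bin_size: int = MB) -> list[tuple[str, int, int]]:
    """1-Mb bins tiling the autosomes, BED convention (0-based half-open)."""
    bins: list[tuple[str, int, int]] = []
    for chrom in AUTOSOMES:
        n = AUTOSOME_MB[chrom]
        for i in range(n):
            bins.append((chrom, i * bin_size, (i + 1) * bin_size))
    return bins
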