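"""Genome coordinate scaffolding.

The pipeline works on a fixed locus grid: haplotype frequencies are
estimated every ``step`` bp at positions where a centered window of
``window`` bp fits entirely inside the chromosome, and sequencing
coverage is summarised in non-overlapping ``bin_size`` bp bins (the
terminal bin of a chromosome may be short).

All positions are 1-based and intervals are closed, except the BED-like
coverage surface (see :mod:`haplovolve.structural`) which is 0-based
half-open on disk only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeGrid", "default_toy_grid"]


@dataclass(frozen=True)
class GenomeGrid:
    """Locus grid, estimation windows and coverage bins for a genome.

    Parameters
    ----------
    chromosomes:
        Ordered chromosome names.
    lengths:
        Chromosome lengths in bp, parallel to ``chromosomes``.
    step:
        Spacing of haplotype-frequency loci in bp (default 1 kb).
    window:
        Width of the centered estimation window in bp (default 60 kb).
    bin_size:
        Width of coverage bins in bp (default 2 kb).
    """

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    step: int = 1_000
    window: int = 60_000
    bin_size: int = 2_000

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("chromosomes and lengths differ in length")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        if self.step <= 0 or self.window <= 0 or self.bin_size <= 0:
            raise ValueError("step, window and bin_size must be positive")
        for name, length in zip(self.chromosomes, self.lengths):
            if length < self.window:
                raise ValueError(
                    f"chromosome {name} ({length} bp) shorter than window "
                    f"({self.window} bp)"
                )

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.chromosomes.index(chrom)]

    def loci(self, chrom: str) -> np.ndarray:
        """1-based locus positions on ``chrom`` whose centered window fits.

        Positions are the multiples of ``step`` p with
        p - window/2 >= 1 and p + window/2 <= length.
        """
        length = self.length_of(chrom)
        half = self.window // 2
        first = ((half + 1 + self.step - 1) // self.step) * self.step
        last = length - half
        if first > last:
            return np.empty(0, dtype=np.int64)
        return np.arange(first, last + 1, self.step, dtype=np.int64)

    def all_loci(self) -> tuple[np.ndarray, np.ndarray]:
        """(chrom array, pos array) over all chromosomes, grid order."""
        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        for chrom in self.chromosomes:
            pos = self.loci(chrom)
            chroms.append(np.full(pos.size, chrom, dtype=object))
            positions.append(pos)
        return np.concatenate(chroms), np.concatenate(positions)

    def n_loci(self) -> int:
        return sum(self.loci(c).size for c in self.chromosomes)

    def window_of(self, chrom: str, pos: int) -> tuple[int, int]:
        """Closed 1-based interval of the estimation window centered at pos."""
        half = self.window // 2
        return pos - half, pos + half

    def bins(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Closed 1-based (start, end) arrays tiling ``chrom`` in bins.

        The terminal bin is truncated at the chromosome end.
        """
        length = self.length_of(chrom)
        starts = np.arange(1, length + 1, self.bin_size, dtype=np.int64)
        ends = np.minimum(starts + self.bin_size - 1, length)
        return starts, ends


def default_toy_grid(
    n_chromosomes: int = 4, chrom_length: int = 300_000, **kwargs
) -> GenomeGrid:
    """Desk-scale genome: ``n_chromosomes`` equal chromosomes.

    Real chromosome lengths can be passed to :class:`GenomeGrid` directly.
    """
    names = tuple(f"chr{i + 1:02d}" for i in range(n_chromosomes))
    return GenomeGrid(names, (chrom_length,) * n_chromosomes, **kwargs)
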