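"""Genome coordinate frame shared by the simulator, the HMM and the QTL scan.

Physical positions are base pairs (1-based where they refer to variants,
0-based half-open where they refer to BED exclusion intervals); genetic
positions are centimorgans obtained from physical positions through a
constant cM/Mb rate per genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Region:
    """A half-open exclusion interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    region_class: str = "other"  # centromere | telomere | TE | other

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, excluded regions and the genetic-to-physical scale.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    excluded_regions
        Regions (centromeres, telomeres, transposable elements) whose
        variants are dropped by the corrected filter.
    cm_per_mb
        Constant recombination rate used to convert physical gaps to
        genetic distances (cM per megabase).
    """

    chromosomes: tuple[tuple[str, int], ...]
    excluded_regions: tuple[Region, ...] = field(default_factory=tuple)
    cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for reg in self.excluded_regions:
            if reg.chrom not in lengths:
                raise ValueError(f"excluded region on unknown chromosome {reg.chrom}")
            if reg.start < 0 or reg.end > lengths[reg.chrom]:
                raise ValueError(f"excluded region outside {reg.chrom}")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, size in self.chromosomes:
            if name == chrom:
                return size
        raise KeyError(chrom)

    def genetic_length_cm(self, chrom: str) -> float:
        """Genetic length of one chromosome in centimorgans (per gamete)."""
        return self.length(chrom) / 1e6 * self.cm_per_mb

    def bp_to_cm(self, bp: float) -> float:
        return bp / 1e6 * self.cm_per_mb

    def total_bp(self) -> int:
        return sum(size for _, size in self.chromosomes)


def default_genome(cm_per_mb: float = 4.0) -> GenomeSpec:
    """Five-chromosome genome at Arabidopsis-like scale.

    30/20/23/19/27 Mb with a 2-Mb centromeric exclusion in the middle of
    each chromosome and 100-kb telomeric exclusions at both ends.
    """
    sizes = [30, 20, 23, 19, 27]
    chroms = tuple((f"Chr{i + 1}", s * 1_000_000) for i, s in enumerate(sizes))
    regions: list[Region] = []
    for name, length in chroms:
        mid = length // 2
        regions.append(Region(name, mid - 1_000_000, mid + 1_000_000, "centromere"))
        regions.append(Region(name, 0, 100_000, "telomere"))
        regions.append(Region(name, length - 100_000, length, "telomere"))
    return GenomeSpec(chromosomes=chroms, excluded_regions=tuple(regions), cm_per_mb=cm_per_mb)


def haldane_r(d_cm: float) -> float:
    """Recombination fraction from genetic distance (Haldane, no interference)."""
    import math

    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def haldane_cm(r: float) -> float:
    """Genetic distance in cM from a recombination fraction (Haldane inverse)."""
    import math

    if r >= 0.5:
        raise ValueError("recombination fraction must be < 0.5")
    return -50.0 * math.log(1.0 - 2.0 * r)
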