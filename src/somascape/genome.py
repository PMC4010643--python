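"""Genome coordinate model: chromosomes, centromeres, arms and a gene catalog.

External coordinates (files, dataclass fields) are 1-based inclusive, matching
VCF and the segment tables.  Interval algebra inside the package is 0-based
half-open; the helpers here do the conversion so callers never juggle the two.

The default model is a "mini-genome": the 22 human autosomes with lengths and
centromere positions scaled to 1/20 of GRCh37.  All the analyses in this
package are rate- or proportion-based, so they are invariant to this scaling,
and the mini-genome keeps simulated cohorts desk-sized.  A full-length model
can be built with ``human_autosomes(scale=1.0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

__all__ = ["Gene", "GenomeModel", "human_autosomes", "GRCH37_AUTOSOME_LENGTHS"]


# GRCh37 autosome lengths (bp) and approximate centromere midpoints (bp).
GRCH37_AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

_GRCH37_CENTROMERES: dict[str, int] = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000,
}

# Driver-gene loci (GRCh37-anchored start positions, rounded); scaled with the
# genome so that e.g. the MDM2 amplicon region sits on 12q as it does in vivo.
_GENE_LOCI: list[tuple[str, str, int, int]] = [
    ("ARID1A", "1", 27_020_000, 27_110_000),
    ("RYR2", "1", 237_200_000, 237_999_000),
    ("FGFR3", "4", 1_795_000, 1_810_000),
    ("FAT1", "4", 187_500_000, 187_640_000),
    ("CDKN1A", "6", 36_644_000, 36_655_000),
    ("CDKN2A", "9", 21_967_000, 21_995_000),
    ("TSC1", "9", 135_766_000, 135_820_000),
    ("MLL2", "12", 49_412_000, 49_453_000),
    ("MDM2", "12", 69_201_000, 69_240_000),
    ("FMN1", "15", 33_050_000, 33_400_000),
    ("B3GNT9", "16", 67_182_000, 67_186_000),
    ("TP53", "17", 7_571_000, 7_591_000),
    ("PIEZO2", "18", 10_670_000, 11_150_000),
]


@dataclass(frozen=True)
class Gene:
    """A gene interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: degenerate interval {self.start}-{self.end}")


@dataclass
class GenomeModel:
    """Chromosome lengths, centromere positions and a gene catalog.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs; lengths must be positive.
    centromeres
        Centromere position per chromosome, strictly inside the chromosome.
        The p arm is ``[1, centromere]``, the q arm ``(centromere, length]``.
    genes
        Gene catalog; every gene must lie within its chromosome.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")
            cen = self.centromeres.get(name)
            if cen is None:
                raise ValueError(f"chromosome {name}: no centromere position")
            if not 0 < cen < length:
                raise ValueError(f"chromosome {name}: centromere {cen} outside (0, {length})")
        self._gene_trees: dict[str, IntervalTree] = {}
        self._gene_index: dict[str, Gene] = {}
        for g in self.genes:
            if g.chrom not in self._lengths:
                raise ValueError(f"gene {g.name}: unknown chromosome {g.chrom}")
            if g.end > self._lengths[g.chrom]:
                raise ValueError(f"gene {g.name}: extends past chromosome end")
            # 0-based half-open internally
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start - 1, g.end, g)
            self._gene_index[g.name] = g

    # -- chromosome queries -------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chrom_length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def arm_of(self, chrom: str, pos: int) -> str:
        """Arm ('p' or 'q') containing 1-based position ``pos``."""
        return "p" if pos <= self.centromeres[chrom] else "q"

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        """1-based inclusive bounds of an arm."""
        cen = self.centromeres[chrom]
        if arm == "p":
            return 1, cen
        if arm == "q":
            return cen + 1, self._lengths[chrom]
        raise ValueError(f"unknown arm {arm!r}")

    @property
    def arms(self) -> list[tuple[str, str]]:
        return [(c, a) for c in self.chrom_names for a in ("p", "q")]

    # -- gene queries -------------------------------------------------------
    def gene(self, name: str) -> Gene:
        try:
            return self._gene_index[name]
        except KeyError:
            raise KeyError(f"gene {name!r} not in catalog") from None

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        """Genes overlapping a 1-based position."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos - 1)), key=lambda g: g.name)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes overlapping a 1-based inclusive interval by >= 1 bp."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start - 1, end)), key=lambda g: g.name)


def human_autosomes(scale: float = 1 / 20, genes: list[Gene] | None = None) -> GenomeModel:
    """The 22 human autosomes, optionally scaled down.

    With the default ``scale=1/20`` the genome totals ~154 Mb; gene catalog
    coordinates are scaled by the same factor so arm assignments are preserved.
    """
    chroms = [(c, max(2, int(L * scale))) for c, L in GRCH37_AUTOSOME_LENGTHS.items()]
    cens = {c: max(1, int(p * scale)) for c, p in _GRCH37_CENTROMERES.items()}
    if genes is None:
        genes = [
            Gene(n, c, max(1, int(s * scale)), max(2, int(e * scale)))
            for n, c, s, e in _GENE_LOCI
        ]
    return GenomeModel(chromosomes=chroms, centromeres=cens, genes=genes)
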